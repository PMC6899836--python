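"""Behavioural statistics of double-auction bidding sessions.

Covers the descriptive and inferential summaries used to characterize
cohorts: per-market transaction rates and profits, first-bid comparisons
(one-way ANOVA), the market discrimination index (MDI: mean BC bid minus
mean SC bid — how strongly a buyer separates the hard and easy markets),
the DL-compliance score (fraction of bid adjustments whose direction
matches the directional-learning prediction given the previous outcome in
the same market), bid-increment distributions conditioned on the previous
outcome, per-subject bid-trend slopes, Pearson correlations with profit,
and posterior-predictive bid-evolution curves of fitted agents.

Bid repetition (a zero increment) counts as DL-compliant under either
previous outcome; eligible trial pairs skip over lottery-excluded trials
(the "previous" trial is the previous *bid* trial of the same market).
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
from scipy import stats

from .core import MARKETS, Dataset, Session

__all__ = [
    "mdi",
    "dl_compliance",
    "transaction_rates",
    "profit",
    "first_bid_summary",
    "increment_distribution",
    "trend_slopes",
    "pearson_r",
    "posterior_predictive",
    "subject_metrics",
]


def profit(session: Session) -> float:
    """Total reward earned over the session (MU)."""
    return float(sum(t.reward for t in session.trials))


def mdi(session: Session) -> float:
    """Market discrimination index: mean BC bid minus mean SC bid (MU)."""
    bc = [t.bid for t in session.bid_trials("BC")]
    sc = [t.bid for t in session.bid_trials("SC")]
    if not bc or not sc:
        raise ValueError("MDI needs at least one bid in both BC and SC")
    return float(np.mean(bc) - np.mean(sc))


def _eligible_pairs(session: Session):
    """(previous_accepted, delta_bid) over consecutive bid-trial pairs
    within each market, skipping lottery-excluded trials."""
    for m in MARKETS:
        trials = session.bid_trials(m)
        for prev, cur in zip(trials, trials[1:]):
            yield prev.accepted, cur.bid - prev.bid


def dl_compliance(session: Session) -> dict[str, float]:
    """Fraction of eligible trials following the directional rule.

    A pair is compliant when the previous bid was accepted and the bid did
    not increase, or was rejected and the bid did not decrease (repeats
    count as compliant either way).  Returns overall and outcome-
    conditioned fractions plus the eligible-pair counts.
    """
    n = {"accepted": 0, "rejected": 0}
    ok = {"accepted": 0, "rejected": 0}
    for prev_accepted, db in _eligible_pairs(session):
        key = "accepted" if prev_accepted else "rejected"
        n[key] += 1
        compliant = db <= 1e-9 if prev_accepted else db >= -1e-9
        ok[key] += int(compliant)
    total = n["accepted"] + n["rejected"]
    if total == 0:
        raise ValueError("no eligible trial pairs for DL compliance")
    return {
        "overall": (ok["accepted"] + ok["rejected"]) / total,
        "after_acceptance": ok["accepted"] / n["accepted"] if n["accepted"] else np.nan,
        "after_rejection": ok["rejected"] / n["rejected"] if n["rejected"] else np.nan,
        "n_pairs": total,
    }


def transaction_rates(dataset: Dataset) -> dict[str, float]:
    """Per-market fraction of entered trials that cleared."""
    out = {}
    for m in MARKETS:
        entered = accepted = 0
        for s in dataset.sessions:
            for t in s.bid_trials(m):
                entered += 1
                accepted += int(t.accepted)
        out[m] = accepted / entered if entered else np.nan
    return out


def first_bid_summary(dataset: Dataset) -> dict:
    """Per-market mean first bids and a one-way ANOVA across markets.

    Groups are each subject's first bid per market; F has (k-1, N-k)
    degrees of freedom.
    """
    if len(dataset.sessions) < 2:
        raise ValueError("need >= 2 subjects for a first-bid comparison")
    groups = {}
    for m in MARKETS:
        vals = []
        for s in dataset.sessions:
            trials = s.bid_trials(m)
            if trials:
                vals.append(trials[0].bid)
        if not vals:
            raise ValueError(f"no first bids in market {m}")
        groups[m] = np.asarray(vals, dtype=float)
    if all(np.ptp(g) == 0 for g in groups.values()) and len(
        {g[0] for g in groups.values()}
    ) > 1:
        raise ValueError("zero within-group variance: F is undefined")
    f_stat, p = stats.f_oneway(*groups.values())
    n = sum(len(g) for g in groups.values())
    return {
        "means": {m: float(g.mean()) for m, g in groups.items()},
        "F": float(f_stat),
        "df": (len(groups) - 1, n - len(groups)),
        "p": float(p),
    }


def increment_distribution(
    dataset: Dataset, previous_outcome: str = "accepted"
) -> dict:
    """Pooled bid-increment distribution conditioned on the previous outcome.

    Returns the raw increments, a histogram on fixed 0.1 MU bins, and
    summary quantiles (median, quartiles) plus skewness.
    """
    want = previous_outcome == "accepted"
    deltas = [
        db
        for s in dataset.sessions
        for prev_acc, db in _eligible_pairs(s)
        if prev_acc == want
    ]
    deltas = np.round(np.asarray(deltas, dtype=float), 1)
    edges = np.round(np.arange(-10.05, 10.15, 0.1), 2)
    counts, _ = np.histogram(deltas, bins=edges) if len(deltas) else (np.zeros(len(edges) - 1, dtype=int), edges)
    return {
        "deltas": deltas,
        "bin_edges": edges,
        "counts": counts,
        "median": float(np.median(deltas)) if len(deltas) else np.nan,
        "q1": float(np.percentile(deltas, 25)) if len(deltas) else np.nan,
        "q3": float(np.percentile(deltas, 75)) if len(deltas) else np.nan,
        "skewness": float(stats.skew(deltas)) if len(deltas) > 2 else np.nan,
        "n": int(len(deltas)),
    }


def trend_slopes(dataset: Dataset) -> dict:
    """Per-subject, per-market OLS slope of bid on trial index (MU/trial),
    with a one-sample group t-test per market."""
    slopes = {m: [] for m in MARKETS}
    for s in dataset.sessions:
        for m in MARKETS:
            trials = s.bid_trials(m)
            if len(trials) < 3:
                raise ValueError(f"subject {s.subject_id}: <3 bid trials in {m}")
            x = np.array([t.trial_in_market for t in trials], dtype=float)
            if np.ptp(x) == 0:
                raise ValueError("constant trial index")
            y = np.array([t.bid for t in trials], dtype=float)
            slopes[m].append(float(np.polyfit(x, y, 1)[0]))
    out = {}
    for m in MARKETS:
        arr = np.asarray(slopes[m])
        if len(arr) > 1 and arr.std(ddof=1) > 0:
            t_stat, p = stats.ttest_1samp(arr, 0.0)
        else:
            t_stat, p = np.nan, np.nan
        out[m] = {
            "slopes": arr,
            "mean": float(arr.mean()),
            "t": float(t_stat),
            "p": float(p),
        }
    return out


def pearson_r(x, y) -> dict:
    """Pearson correlation with t statistic, df and Fisher-z 95% CI."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need matched samples of size >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance input")
    r, p = stats.pearsonr(x, y)
    n = len(x)
    df = n - 2
    t = r * np.sqrt(df / max(1.0 - r**2, 1e-300))
    if abs(r) < 1.0:
        z = np.arctanh(r)
        half = 1.959963984540054 / np.sqrt(n - 3)
        ci = (float(np.tanh(z - half)), float(np.tanh(z + half)))
    else:
        ci = (float(r), float(r))
    return {"r": float(r), "t": float(t), "df": df, "p": float(p), "ci95": ci}


def subject_metrics(dataset: Dataset) -> pd.DataFrame:
    """One row of summary metrics per subject."""
    rows = []
    for s in dataset.sessions:
        comp = dl_compliance(s)
        row = {
            "subject_id": s.subject_id,
            "profit": profit(s),
            "mdi": mdi(s),
            "dl_compliance": comp["overall"],
            "dl_compliance_after_acceptance": comp["after_acceptance"],
            "dl_compliance_after_rejection": comp["after_rejection"],
        }
        for m in MARKETS:
            trials = s.bid_trials(m)
            bids = [t.bid for t in trials]
            row[f"mean_bid_{m}"] = float(np.mean(bids)) if bids else np.nan
            row[f"first_bid_{m}"] = bids[0] if bids else np.nan
            row[f"transaction_rate_{m}"] = (
                float(np.mean([t.accepted for t in trials])) if trials else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)


def posterior_predictive(
    model: str,
    params: dict[str, float],
    cohort_config,
    n_reps: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate fitted agents and average their tracked quantity per trial.

    For DL models the tracked quantity is the preferred bid before each
    trial; for RL models the argmax of the action-value function (in MU).
    Returns a tidy frame with columns ``rep, market, trial, tracked``.
    """
    from .cohort import simulate_cohort
    from .fitting import prepare
    from .models import TILE_CENTRES, GRID, init_state, is_rl, update

    rows = []
    root = np.random.SeedSequence(seed)
    for rep, child in enumerate(root.spawn(n_reps)):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        config = replace(
            cohort_config, model=model, params=params, master_seed=sub_seed
        )
        dataset = simulate_cohort(config)
        data = prepare(dataset)
        centres = TILE_CENTRES if model == "rw_coarse" else GRID
        tracked = {m: np.zeros(config.n_blocks) for m in MARKETS}
        counts = {m: np.zeros(config.n_blocks) for m in MARKETS}
        for sess in dataset.sessions:
            state = init_state(
                model,
                params,
                prior=data.beta_priors if is_rl(model) else None,
                initial_bids=config.initial_bids,
            )
            seen = {m: 0 for m in MARKETS}
            for t in sess.trials:
                i = seen[t.market]
                seen[t.market] += 1
                if is_rl(model):
                    val = centres[int(np.argmax(state.Q[t.market]))]
                else:
                    val = state.dl[t.market].A
                tracked[t.market][i] += val
                counts[t.market][i] += 1
                if t.entered:
                    state = update(
                        model, params, state, t.market, t.bid, t.accepted, t.reward
                    )
        for m in MARKETS:
            mean = tracked[m] / np.maximum(counts[m], 1)
            for i, v in enumerate(mean):
                rows.append(
                    {"rep": rep, "market": m, "trial": i + 1, "tracked": float(v)}
                )
    return pd.DataFrame(rows)
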