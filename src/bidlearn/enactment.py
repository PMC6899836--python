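"""Model enactment: trial-level learning-signal regressors.

A fitted directional-learning agent is replayed through each observed
session, forced to choose the same bids the subject chose and fed the same
outcomes.  Before each update the trace records:

* ``pbv_pre`` — the preferred bid value ``PBV = 10 - A`` (the payoff the
  current preferred bid would earn), using the pre-update ``A`` because
  the prediction error must precede the update it drives;
* ``ds`` — the directional signature, +1 for accepted and -1 for rejected
  bids (acceptance, not the sign of the prediction error, is primary: the
  two can disagree when an accepted bid exceeds the preferred bid);
* ``pseudo_rpe`` — ``reward - pbv_pre``, the prediction-error analogue in
  which the expectation is the preferred bid's value.

Signals are z-scored *pooled across subjects* before use as parametric
regressors, matching how between-subject differences enter group models.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import Dataset
from .models import MODELS, init_state, is_dl, update

__all__ = ["enact", "zscore_pooled", "write_regressor_tsv", "read_regressor_tsv"]

SIGNALS = ("pbv_pre", "ds", "pseudo_rpe")


def enact(
    model: str,
    params: dict[str, float],
    dataset: Dataset,
    initial_bids: dict[str, float] | None = None,
    zscore: bool = True,
) -> pd.DataFrame:
    """Replay a DL model through observed sessions, one row per bid trial.

    When ``initial_bids`` is omitted they are derived from the dataset
    (mean first-trial bid per market), exactly as in likelihood fitting.
    """
    if not is_dl(model):
        raise ValueError(f"enactment requires a DL model, got {model!r}")
    params = MODELS[model].validate(params)
    if initial_bids is None:
        from .fitting import prepare

        initial_bids = prepare(dataset).initial_bids
    rows = []
    for sess in dataset.sessions:
        state = init_state(model, params, initial_bids=initial_bids)
        for t in sess.trials:
            if not t.entered:
                continue
            if t.accepted is None:
                raise ValueError(
                    f"missing outcome on entered trial {t.subject_id}/{t.market}"
                )
            A_pre = state.dl[t.market].A
            pbv_pre = 10.0 - A_pre
            rows.append(
                {
                    "subject_id": sess.subject_id,
                    "market": t.market,
                    "trial_in_market": t.trial_in_market,
                    "bid": t.bid,
                    "accepted": int(t.accepted),
                    "reward": t.reward,
                    "preferred_bid_pre": A_pre,
                    "pbv_pre": pbv_pre,
                    "ds": 1 if t.accepted else -1,
                    "pseudo_rpe": t.reward - pbv_pre,
                    "onset": t.onset,
                    "duration": t.duration,
                }
            )
            state = update(model, params, state, t.market, t.bid, t.accepted, t.reward)
    trace = pd.DataFrame(rows)
    if trace.empty:
        raise ValueError("dataset contains no entered trials to enact")
    if trace["onset"].isna().all():
        trace = trace.drop(columns=["onset", "duration"])
    if zscore:
        for name in SIGNALS:
            trace = zscore_pooled(trace, name)
    return trace


def zscore_pooled(trace: pd.DataFrame, signal: str) -> pd.DataFrame:
    """Standardize one signal across all subjects' trials (``z_<signal>``)."""
    x = trace[signal].to_numpy(dtype=float)
    if len(x) < 2 or np.ptp(x) == 0:
        raise ValueError(f"signal {signal!r} is degenerate (no variance)")
    sd = x.std(ddof=0)
    out = trace.copy()
    out[f"z_{signal}"] = (x - x.mean()) / sd
    return out


def write_regressor_tsv(trace: pd.DataFrame, path: str | Path) -> None:
    """Write the trace as a tab-separated table with stable column order."""
    if trace.empty:
        raise ValueError("empty enactment trace")
    lead = [
        c
        for c in (
            "subject_id",
            "market",
            "trial_in_market",
            "onset",
            "duration",
            "bid",
            "accepted",
            "reward",
            "preferred_bid_pre",
            "pbv_pre",
            "ds",
            "pseudo_rpe",
        )
        if c in trace.columns
    ]
    rest = [c for c in trace.columns if c not in lead]
    trace[lead + rest].to_csv(path, sep="\t", index=False, na_rep="n/a")


def read_regressor_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["n/a"], keep_default_na=False)
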