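"""Synthetic opponents and cohorts.

The original task replayed prerecorded human opponents; here the opponent
side of each market is emulated as draws from truncated Gaussians centred
on a market-specific clearing price (the internal price that asks and
competitor bids scatter around), optionally drifting linearly over trials.

Default clearing prices order the markets by difficulty the way the
observed transaction rates do (SC easiest, BC hardest): asks of 3.5 MU per
SC seller, 4.5 in NC, 4.0 in BC, with a BC competitor bidding around
5.5 MU, all with spread 1.0 MU and truncated to [0, 10].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .core import (
    MARKETS,
    MARKET_TYPES,
    Dataset,
    Session,
    TrialRecord,
    market_schedule,
    snap_to_grid,
)
from .models import (
    GRID,
    MODELS,
    REFERENCE_FFX_ESTIMATES,
    REFERENCE_INITIAL_BIDS,
    AgentState,
    BetaPrior,
    init_state,
    policy_probs,
    update,
)

__all__ = [
    "OpponentParams",
    "OpponentPool",
    "CohortConfig",
    "make_opponent_pool",
    "simulate_session",
    "simulate_cohort",
    "truncnorm_draws",
    "DEFAULT_OPPONENTS",
]


@dataclass(frozen=True)
class OpponentParams:
    """Truncated-Gaussian generator for one market's opponent series.

    ``mu_asks`` holds one clearing-price mean per seller; ``mu_bid`` the
    competitor-buyer mean (BC only).  ``drift`` shifts every mean linearly
    per trial (MU/trial).  Values are truncated to [0, 10].
    """

    mu_asks: tuple[float, ...]
    mu_bid: float | None = None
    sigma: float = 1.0
    drift: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0 (0 gives constant series)")
        for mu in self.mu_asks + ((self.mu_bid,) if self.mu_bid is not None else ()):
            if not 0.0 <= mu <= 10.0:
                raise ValueError(f"opponent mean {mu} outside [0, 10]")


DEFAULT_OPPONENTS: dict[str, OpponentParams] = {
    "SC": OpponentParams(mu_asks=(3.5, 3.5)),
    "NC": OpponentParams(mu_asks=(4.5,)),
    "BC": OpponentParams(mu_asks=(4.0,), mu_bid=5.5),
}


def truncnorm_draws(
    mu, sigma: float, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Gaussian draws truncated to [0, 10] by inverse-CDF sampling.

    ``mu`` may be a scalar or a per-draw array (for drifting means).
    """
    from scipy import stats

    mu = np.broadcast_to(np.asarray(mu, dtype=float), (size,))
    u = rng.random(size)
    if sigma == 0:  # degenerate: constant at the (clipped) mean
        return np.clip(mu.copy(), 0.0, 10.0)
    a, b = (0.0 - mu) / sigma, (10.0 - mu) / sigma
    lo, hi = stats.norm.cdf(a), stats.norm.cdf(b)
    return mu + sigma * stats.norm.ppf(lo + u * (hi - lo))


@dataclass
class OpponentPool:
    """Per-market opponent series for one subject, reproducible by seed."""

    ask_series: dict[str, np.ndarray]  # market -> (n_sellers, n_trials)
    competitor_bid_series: dict[str, np.ndarray]  # market -> (n_trials,)
    seed: int

    def asks(self, market_label: str, trial: int) -> list[float]:
        return [float(x) for x in self.ask_series[market_label][:, trial]]

    def competitor_bids(self, market_label: str, trial: int) -> list[float]:
        if market_label not in self.competitor_bid_series:
            return []
        return [float(self.competitor_bid_series[market_label][trial])]

    def n_trials(self, market_label: str) -> int:
        return self.ask_series[market_label].shape[1]


@dataclass
class CohortConfig:
    """Everything needed to simulate a cohort of synthetic subjects."""

    n_subjects: int = 27
    n_blocks: int = 24
    model: str = "dl_lepto"
    params: dict[str, float] = field(
        default_factory=lambda: dict(REFERENCE_FFX_ESTIMATES["dl_lepto"])
    )
    opponents: dict[str, OpponentParams] = field(
        default_factory=lambda: dict(DEFAULT_OPPONENTS)
    )
    initial_bids: dict[str, float] = field(
        default_factory=lambda: dict(REFERENCE_INITIAL_BIDS)
    )
    beta_prior: BetaPrior = field(default_factory=lambda: BetaPrior(2.0, 2.0, 10.0))
    lottery: bool = True
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        MODELS[self.model].validate(self.params)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "opponents" in raw:
            raw["opponents"] = {
                m: OpponentParams(
                    mu_asks=tuple(v["mu_asks"]),
                    mu_bid=v.get("mu_bid"),
                    sigma=v.get("sigma", 1.0),
                    drift=v.get("drift", 0.0),
                )
                for m, v in raw["opponents"].items()
            }
        if "beta_prior" in raw:
            raw["beta_prior"] = BetaPrior(**raw["beta_prior"])
        return cls(**raw)


def _subject_seed(master_seed: int, subject_index: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(master_seed), int(subject_index), stream])
    )


def make_opponent_pool(config: CohortConfig, subject_index: int) -> OpponentPool:
    """Draw one subject's opponent series (seeded from master seed + index)."""
    rng = _subject_seed(config.master_seed, subject_index, 0)
    n = config.n_blocks
    asks: dict[str, np.ndarray] = {}
    comp: dict[str, np.ndarray] = {}
    for m in MARKETS:
        op = config.opponents[m]
        trial_drift = op.drift * np.arange(n)
        rows = [
            truncnorm_draws(mu + trial_drift, op.sigma, n, rng) for mu in op.mu_asks
        ]
        asks[m] = np.vstack(rows)
        if op.mu_bid is not None:
            comp[m] = np.round(
                [
                    snap_to_grid(x)
                    for x in truncnorm_draws(op.mu_bid + trial_drift, op.sigma, n, rng)
                ],
                1,
            )
    return OpponentPool(
        ask_series=asks, competitor_bid_series=comp, seed=int(config.master_seed)
    )


def simulate_session(
    model: str,
    params: dict[str, float],
    pool: OpponentPool,
    schedule: list[tuple[str, bool]],
    seed: int | np.random.Generator,
    subject_id: str = "sim",
    initial_bids: dict[str, float] | None = None,
    beta_prior: BetaPrior | dict[str, BetaPrior] | None = None,
    state: AgentState | None = None,
) -> Session:
    """Play one agent through a schedule against an opponent pool.

    On each entered trial the agent samples a grid bid from its policy, the
    market resolves it, and the agent updates; lottery-excluded trials
    leave the agent state untouched.  The emitted records carry the
    ground-truth ask series for audit.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if state is None:
        state = init_state(model, params, prior=beta_prior, initial_bids=initial_bids)
    seen: list[str] = []
    counters = {m: 0 for m in MARKETS}
    trials: list[TrialRecord] = []
    for block, (m, entered) in enumerate(schedule):
        if m not in seen:
            seen.append(m)
        t = counters[m]
        if t >= pool.n_trials(m):
            raise ValueError(f"opponent pool exhausted for market {m}")
        counters[m] += 1
        if not entered:
            trials.append(
                TrialRecord(
                    subject_id=subject_id,
                    market=m,
                    block_index=block // 3 + 1,
                    trial_in_market=t + 1,
                    entered=False,
                )
            )
            continue
        probs = policy_probs(model, params, state, m)
        bid = float(GRID[rng.choice(len(GRID), p=probs)])
        asks = pool.asks(m, t)
        comp = pool.competitor_bids(m, t)
        accepted, reward, disclosed = _resolve(m, bid, asks, comp, rng)
        trials.append(
            TrialRecord(
                subject_id=subject_id,
                market=m,
                block_index=block // 3 + 1,
                trial_in_market=t + 1,
                entered=True,
                bid=bid,
                accepted=accepted,
                reward=reward,
                disclosed_competitor_bid=disclosed,
                ground_truth_asks=tuple(asks),
            )
        )
        state = update(model, params, state, m, bid, accepted, reward)
    return Session(subject_id=subject_id, market_sequence=tuple(seen), trials=trials)


def _resolve(m, bid, asks, comp, rng):
    from .core import resolve_trial

    return resolve_trial(MARKET_TYPES[m], bid, asks, comp, tie_rng=rng)


def simulate_cohort(config: CohortConfig) -> Dataset:
    """Simulate ``n_subjects`` independent sessions under one config."""
    sessions = []
    for i in range(config.n_subjects):
        pool = make_opponent_pool(config, i)
        sched_rng = _subject_seed(config.master_seed, i, 1)
        sequence_id = 1 + int(sched_rng.integers(6))
        schedule = market_schedule(
            sequence_id, config.n_blocks, sched_rng if config.lottery else None
        )
        agent_rng = _subject_seed(config.master_seed, i, 2)
        sessions.append(
            simulate_session(
                config.model,
                config.params,
                pool,
                schedule,
                agent_rng,
                subject_id=f"sub-{i + 1:03d}",
                initial_bids=config.initial_bids,
                beta_prior=config.beta_prior,
            )
        )
    return Dataset(sessions=sessions)
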