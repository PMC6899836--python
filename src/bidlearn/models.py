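"""Adaptive learning models of repeated bidding.

Seven models are registered, spanning two families plus a benchmark:

Reinforcement learning (value caching, softmax policy)
    ``rw_coarse``
        Rescorla-Wagner delta rule on an 11-tile binning of the bid grid.
    ``rw_fine``
        The same rule on the native 101-point grid.
    ``counterfactual_rl``
        Model-based RL exploiting auction logic: an accepted bid implies
        every higher bid would also have been accepted (each moves toward
        its own counterfactual payoff ``10 - i``); a rejected bid implies
        every lower bid would also have been rejected (each moves toward 0).

Directional learning (action caching, no value function)
    A single preferred bid ``A_m`` is tracked per market ``m`` and nudged
    up after rejections and down (toward the accepted bid) after
    acceptances.  Choice noise around ``A_m`` is Gaussian (``dl_gauss``)
    or two-sided Laplace with outcome-contingent side scales (leptokurtic:
    ``dl_naive``, ``dl_lepto``).

    The delta rule for ``dl_gauss``/``dl_lepto`` operates on the preferred
    bid *value* ``V = 10 - A`` (the payoff the preferred bid would earn):
    ``V <- V + alpha * (r - V)``, i.e. ``A <- A + alpha * ((10 - r) - A)``.
    Acceptance of bid ``b`` (``r = 10 - b``) therefore pulls ``A`` toward
    ``b``; rejection (``r = 0``) pushes ``A`` toward 10.  ``dl_naive``
    instead applies fixed nudges ``-n_up`` / ``+n_down``.

    ``dl_lepto`` adds an exploration-mixture parameter ``k``: total
    probability mass ``k`` is placed on bids strictly below ``A`` (the
    risky, profit-seeking side for a buyer) and ``1 - k`` at or above
    ``A``, each side weighted by its Laplace density.

``null``
    Uniform probability over the 101 bids, zero free parameters.

Continuous densities are evaluated at the grid points and renormalized,
so every policy is an exact distribution over the 101 bids.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import MARKETS, bid_grid, bid_index

__all__ = [
    "ModelSpec",
    "MODELS",
    "BetaPrior",
    "AgentState",
    "fit_beta_prior",
    "init_state",
    "policy_probs",
    "update",
    "log_lik_bid",
    "is_dl",
    "is_rl",
    "model_class",
    "REFERENCE_FFX_ESTIMATES",
    "REFERENCE_INITIAL_BIDS",
    "LOG_FLOOR",
]

GRID = bid_grid()
N_GRID = len(GRID)

#: Log-probability floor applied instead of -inf for numerically
#: impossible bids (e.g. a bid many sigma from the preferred bid).
LOG_FLOOR = -745.0

#: Tile index of every grid bid for the coarse 11-tile action space: tile j
#: holds the bids that round (half up) to j MU, giving sizes 5, 10x9, 6.
TILE_OF_BID = np.minimum((np.arange(N_GRID) + 5) // 10, 10)
N_TILES = 11
TILE_SIZES = np.bincount(TILE_OF_BID, minlength=N_TILES)
TILE_CENTRES = np.arange(N_TILES, dtype=float)


@dataclass(frozen=True)
class ModelSpec:
    """Name, ordered parameter names and box bounds of one model."""

    name: str
    param_names: tuple[str, ...]
    bounds: tuple[tuple[float, float], ...]

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def validate(self, params: dict[str, float]) -> dict[str, float]:
        """Check completeness and bounds; returns a plain float dict."""
        out = {}
        for name, (lo, hi) in zip(self.param_names, self.bounds):
            if name not in params:
                raise ValueError(f"{self.name}: missing parameter {name!r}")
            v = float(params[name])
            if not lo <= v <= hi:
                raise ValueError(
                    f"{self.name}: {name}={v} outside bounds [{lo}, {hi}]"
                )
            out[name] = v
        return out

    def to_vector(self, params: dict[str, float]) -> np.ndarray:
        return np.array([params[n] for n in self.param_names], dtype=float)

    def to_dict(self, vector) -> dict[str, float]:
        return {n: float(v) for n, v in zip(self.param_names, vector)}


_SIGMA_BOUNDS = (0.01, 10.0)

MODELS: dict[str, ModelSpec] = {
    spec.name: spec
    for spec in [
        ModelSpec("rw_coarse", ("alpha", "beta"), ((0.0, 1.0), (0.0, 50.0))),
        ModelSpec("rw_fine", ("alpha", "beta"), ((0.0, 1.0), (0.0, 50.0))),
        ModelSpec(
            "counterfactual_rl", ("alpha", "beta"), ((0.0, 1.0), (0.0, 50.0))
        ),
        ModelSpec("dl_gauss", ("alpha", "sigma"), ((0.0, 1.0), _SIGMA_BOUNDS)),
        ModelSpec(
            "dl_naive",
            ("n_up", "n_down", "sigma_a", "sigma_r"),
            ((0.0, 5.0), (0.0, 5.0), _SIGMA_BOUNDS, _SIGMA_BOUNDS),
        ),
        ModelSpec(
            "dl_lepto",
            ("alpha", "sigma_a", "sigma_r", "sigma_0", "k"),
            ((0.0, 1.0), _SIGMA_BOUNDS, _SIGMA_BOUNDS, _SIGMA_BOUNDS, (0.0, 1.0)),
        ),
        ModelSpec("null", (), ()),
    ]
}

DL_MODELS = ("dl_gauss", "dl_naive", "dl_lepto")
RL_MODELS = ("rw_coarse", "rw_fine", "counterfactual_rl")


def is_dl(name: str) -> bool:
    return name in DL_MODELS


def is_rl(name: str) -> bool:
    return name in RL_MODELS


def model_class(name: str) -> str:
    """``"DL"``, ``"RL"`` or ``"null"``."""
    if is_dl(name):
        return "DL"
    if is_rl(name):
        return "RL"
    if name == "null":
        return "null"
    raise ValueError(f"unknown model {name!r}")


# Fixed-effects estimates reported for the original task cohort, used as
# canonical generator settings for synthetic cohorts and recovery studies.
REFERENCE_FFX_ESTIMATES: dict[str, dict[str, float]] = {
    "dl_lepto": {
        "alpha": 0.53,
        "sigma_a": 0.70,
        "sigma_r": 0.79,
        "sigma_0": 0.65,
        "k": 0.39,
    },
    "dl_gauss": {"alpha": 0.38, "sigma": 1.09},
    "dl_naive": {"n_up": 0.20, "n_down": 0.06, "sigma_a": 1.06, "sigma_r": 1.16},
    "counterfactual_rl": {"alpha": 0.09, "beta": 1.00},
    "rw_coarse": {"alpha": 0.00, "beta": 0.99},
    "rw_fine": {"alpha": 0.01, "beta": 1.042},
    "null": {},
}

#: Mean first-trial bids per market in the original cohort; the default
#: initial preferred bids of generating DL agents.
REFERENCE_INITIAL_BIDS: dict[str, float] = {"SC": 4.96, "NC": 5.13, "BC": 6.55}


@dataclass(frozen=True)
class BetaPrior:
    """Beta-shaped prior over action values, rescaled to the task.

    The support is stretched from [0, 1] to the bid range [0, 10] and the
    range rescaled so prior values span [0, ``c``] MU:
    ``Q0(i) = c * pdf_Beta(i/10; a, b) / max(pdf)``, with the maximum taken
    over the evaluation points.
    """

    a: float
    b: float
    c: float = 10.0

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0 or self.c < 0:
            raise ValueError("BetaPrior needs a, b > 0 and c >= 0")

    def values(self, bids: np.ndarray) -> np.ndarray:
        """Prior action values at the given bids (MU)."""
        x = np.clip(np.asarray(bids, dtype=float) / 10.0, 1e-6, 1.0 - 1e-6)
        pdf = stats.beta.pdf(x, self.a, self.b)
        return self.c * pdf / pdf.max()


def fit_beta_prior(first_bids, c: float = 10.0) -> BetaPrior:
    """Maximum-likelihood Beta fit to first-trial bids (rescaled to [0,1]).

    Values are clamped away from {0, 1} by 1e-3 before fitting.  A
    degenerate sample (all identical) falls back to moment matching with a
    variance floor of 1e-4.
    """
    bids = np.asarray(list(first_bids), dtype=float)
    if len(bids) < 3:
        raise ValueError("need at least 3 first bids to fit a prior")
    if bids.min() < 0 or bids.max() > 10:
        raise ValueError("first bids must lie in [0, 10]")
    x = np.clip(bids / 10.0, 1e-3, 1.0 - 1e-3)
    if np.ptp(x) < 1e-12:
        m, v = float(np.mean(x)), 1e-4
        common = m * (1 - m) / v - 1.0
        return BetaPrior(a=max(m * common, 1e-3), b=max((1 - m) * common, 1e-3), c=c)
    a, b, _, _ = stats.beta.fit(x, floc=0.0, fscale=1.0)
    return BetaPrior(a=float(a), b=float(b), c=c)


@dataclass
class DLState:
    """Preferred bid and last outcome of a directional learner (one market)."""

    A: float
    last_outcome: str = "none"  # none | accepted | rejected


@dataclass
class AgentState:
    """Per-market learner state.

    RL models hold an action-value vector ``Q[m]`` (11 tiles or 101 grid
    points, in MU); DL models hold a continuous preferred bid ``A`` in
    [0, 10] MU plus the previous outcome.  The null model is stateless.
    """

    model: str
    Q: dict[str, np.ndarray] = field(default_factory=dict)
    dl: dict[str, DLState] = field(default_factory=dict)

    def copy(self) -> "AgentState":
        return AgentState(
            model=self.model,
            Q={m: q.copy() for m, q in self.Q.items()},
            dl={m: DLState(s.A, s.last_outcome) for m, s in self.dl.items()},
        )


def init_state(
    model: str,
    params: dict[str, float] | None = None,
    prior: BetaPrior | dict[str, BetaPrior] | None = None,
    initial_bids: dict[str, float] | None = None,
) -> AgentState:
    """Initialize learner state for all three markets.

    RL models take a :class:`BetaPrior` (one shared, or one per market)
    evaluated at their bin centres; DL models take per-market initial
    preferred bids (defaults: the reference first-trial means).
    """
    spec = MODELS[model]
    if params is not None:
        spec.validate(params)
    state = AgentState(model=model)
    if is_rl(model):
        if prior is None:
            raise ValueError(f"{model} needs a BetaPrior to initialize Q")
        priors = prior if isinstance(prior, dict) else {m: prior for m in MARKETS}
        centres = TILE_CENTRES if model == "rw_coarse" else GRID
        for m in MARKETS:
            state.Q[m] = priors[m].values(centres)
    elif is_dl(model):
        bids = dict(initial_bids or REFERENCE_INITIAL_BIDS)
        for m in MARKETS:
            if not 0.0 <= bids[m] <= 10.0:
                raise ValueError(f"initial preferred bid for {m} outside [0, 10]")
            state.dl[m] = DLState(A=float(bids[m]))
    elif model != "null":
        raise ValueError(f"unknown model {model!r}")
    return state


def _laplace_side_scales(model: str, params: dict[str, float], outcome: str):
    """(scale_below, scale_above) of the two-sided Laplace policy."""
    if model == "dl_naive":
        if outcome == "none":
            mid = 0.5 * (params["sigma_a"] + params["sigma_r"])
            return mid, mid
        return params["sigma_a"], params["sigma_r"]
    # dl_lepto: the outcome-congruent side gets its own scale, the
    # opposite side the neutral sigma_0.
    if outcome == "accepted":
        return params["sigma_a"], params["sigma_0"]
    if outcome == "rejected":
        return params["sigma_0"], params["sigma_r"]
    return params["sigma_0"], params["sigma_0"]


def _lepto_probs(A: float, k: float, s_below: float, s_above: float) -> np.ndarray:
    """dl_lepto mixture: mass k strictly below A, 1-k at or above."""
    below = GRID < A - 1e-12
    w_below = np.where(below, np.exp(-(A - GRID) / s_below), 0.0)
    w_above = np.where(~below, np.exp(-np.abs(GRID - A) / s_above), 0.0)
    sb, sa = w_below.sum(), w_above.sum()
    if sb <= 0:  # A at the bottom of the grid: no explorative side exists
        return w_above / sa
    p = k * w_below / sb + (1.0 - k) * w_above / sa
    return p / p.sum()


def policy_probs(
    model: str,
    params: dict[str, float],
    state: AgentState | None,
    market_label: str,
) -> np.ndarray:
    """Probability of each of the 101 grid bids under the current policy."""
    if model == "null":
        return np.full(N_GRID, 1.0 / N_GRID)
    spec = MODELS[model]
    params = spec.validate(params)
    if state is None or state.model != model:
        raise ValueError("state not initialized for this model")

    if is_rl(model):
        Q = state.Q[market_label]
        z = params["beta"] * Q
        z = z - z.max()
        bin_p = np.exp(z)
        bin_p /= bin_p.sum()
        if model == "rw_coarse":
            return bin_p[TILE_OF_BID] / TILE_SIZES[TILE_OF_BID]
        return bin_p

    dl = state.dl[market_label]
    if model == "dl_gauss":
        w = np.exp(-((GRID - dl.A) ** 2) / (2.0 * params["sigma"] ** 2))
        return w / w.sum()
    if model == "dl_naive":
        s_below, s_above = _laplace_side_scales(model, params, dl.last_outcome)
        scale = np.where(GRID < dl.A - 1e-12, s_below, s_above)
        w = np.exp(-np.abs(GRID - dl.A) / scale) / (2.0 * scale)
        return w / w.sum()
    # dl_lepto
    s_below, s_above = _laplace_side_scales(model, params, dl.last_outcome)
    k = params["k"] if dl.last_outcome != "none" else 0.5
    return _lepto_probs(dl.A, k, s_below, s_above)


def update(
    model: str,
    params: dict[str, float],
    state: AgentState,
    market_label: str,
    bid: float,
    accepted: bool,
    reward: float,
) -> AgentState:
    """Apply one trial's outcome; returns a new state (input untouched)."""
    expect = 10.0 - bid if accepted else 0.0
    if abs(reward - expect) > 1e-9:
        raise ValueError(f"reward {reward} inconsistent with accepted={accepted}")
    params = MODELS[model].validate(params)
    new = state.copy()
    idx = bid_index(bid)

    if model in ("rw_coarse", "rw_fine"):
        Q = new.Q[market_label]
        j = TILE_OF_BID[idx] if model == "rw_coarse" else idx
        Q[j] += params["alpha"] * (reward - Q[j])
    elif model == "counterfactual_rl":
        Q = new.Q[market_label]
        a = params["alpha"]
        if accepted:
            # every bid >= b would also have cleared, earning 10 - i
            Q[idx:] += a * ((10.0 - GRID[idx:]) - Q[idx:])
        else:
            # every bid <= b would also have been rejected, earning 0
            Q[: idx + 1] += a * (0.0 - Q[: idx + 1])
    elif model in ("dl_gauss", "dl_lepto"):
        dl = new.dl[market_label]
        # delta rule on the preferred bid value V = 10 - A
        dl.A = float(np.clip(dl.A + params["alpha"] * ((10.0 - reward) - dl.A), 0.0, 10.0))
        dl.last_outcome = "accepted" if accepted else "rejected"
    elif model == "dl_naive":
        dl = new.dl[market_label]
        step = -params["n_up"] if accepted else params["n_down"]
        dl.A = float(np.clip(dl.A + step, 0.0, 10.0))
        dl.last_outcome = "accepted" if accepted else "rejected"
    elif model != "null":
        raise ValueError(f"unknown model {model!r}")
    return new


class FloorCounter:
    """Counts how often a zero-probability bid hit the log floor."""

    def __init__(self) -> None:
        self.count = 0


def log_lik_bid(
    model: str,
    params: dict[str, float],
    state: AgentState | None,
    market_label: str,
    bid: float,
    floor_counter: FloorCounter | None = None,
) -> float:
    """Log probability of one grid bid under the current policy.

    Numerically impossible bids return :data:`LOG_FLOOR` (never ``-inf``),
    incrementing ``floor_counter`` when given.
    """
    if model == "null":
        return -math.log(N_GRID)
    p = policy_probs(model, params, state, market_label)[bid_index(bid)]
    if p <= 0 or not np.isfinite(np.log(p)) or np.log(p) < LOG_FLOOR:
        if floor_counter is not None:
            floor_counter.count += 1
        return LOG_FLOOR
    return float(np.log(p))
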