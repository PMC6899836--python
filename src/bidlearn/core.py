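"""Task environment for the repeated double-auction bidding game.

Subjects act as buyers in three market types that differ in the number of
competing traders:

* ``SC`` (seller competition): two sellers, one buyer (the subject),
* ``NC`` (no competition): one seller, one buyer,
* ``BC`` (buyer competition): one seller, two buyers (subject + competitor).

On each entered trial the subject places a bid on a discrete grid
0.0, 0.1, ..., 10.0 MU (monetary units).  The highest buyer bid is pitted
against the lowest seller ask; the transaction clears when the highest bid
is at or above the lowest ask.  A cleared bid ``b`` pays ``10 - b`` MU; a
failed transaction pays nothing.  Market types are looped in blocks of
three in one of the six fixed orders, and a lottery excludes the subject
from one of every six trials.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "MARKETS",
    "MarketType",
    "TrialRecord",
    "Session",
    "Dataset",
    "bid_grid",
    "bid_index",
    "snap_to_grid",
    "resolve_trial",
    "market_schedule",
    "market_sequence",
]

#: Canonical market labels in block order of sequence 1.
MARKETS = ("SC", "NC", "BC")

_N_GRID = 101


@dataclass(frozen=True)
class MarketType:
    """One of the three buyer/seller competition structures."""

    label: str
    n_sellers: int
    n_competitor_buyers: int

    def __post_init__(self) -> None:
        expected = {"SC": (2, 0), "NC": (1, 0), "BC": (1, 1)}
        if self.label not in expected:
            raise ValueError(f"unknown market label {self.label!r}")
        if (self.n_sellers, self.n_competitor_buyers) != expected[self.label]:
            raise ValueError(
                f"market {self.label} must have sellers/competitors "
                f"{expected[self.label]}, got "
                f"{(self.n_sellers, self.n_competitor_buyers)}"
            )


def market(label: str) -> MarketType:
    """Return the canonical :class:`MarketType` for a label."""
    counts = {"SC": (2, 0), "NC": (1, 0), "BC": (1, 1)}
    if label not in counts:
        raise ValueError(f"unknown market label {label!r}")
    return MarketType(label, *counts[label])


MARKET_TYPES = {m: market(m) for m in MARKETS}


@dataclass
class TrialRecord:
    """A single trial of one subject's session.

    ``bid``/``accepted`` are ``None`` on lottery-excluded trials.
    ``disclosed_competitor_bid`` is present only in BC trials where the
    competitor outbid the subject (the task reveals that bid).
    ``ground_truth_asks`` is carried only in simulation logs.
    """

    subject_id: str
    market: str
    block_index: int
    trial_in_market: int
    entered: bool
    bid: float | None = None
    accepted: bool | None = None
    reward: float = 0.0
    disclosed_competitor_bid: float | None = None
    ground_truth_asks: tuple[float, ...] | None = None
    onset: float | None = None
    duration: float | None = None

    def __post_init__(self) -> None:
        if self.entered:
            if self.bid is None or self.accepted is None:
                raise ValueError("entered trial needs bid and accepted flag")
            if abs(self.bid - snap_to_grid(self.bid)) > 1e-9:
                raise ValueError(f"bid {self.bid} is off the 0.1 MU grid")
            expect = 10.0 - self.bid if self.accepted else 0.0
            if abs(self.reward - expect) > 1e-9:
                raise ValueError(
                    f"reward {self.reward} inconsistent with bid {self.bid} "
                    f"accepted={self.accepted}"
                )
        else:
            if self.bid is not None or self.accepted is not None:
                raise ValueError("lottery-excluded trial cannot carry a bid")
            if self.reward != 0.0:
                raise ValueError("lottery-excluded trial has zero reward")
        if self.disclosed_competitor_bid is not None and self.market != "BC":
            raise ValueError("competitor bids are disclosed only in BC")


@dataclass
class Session:
    """Ordered trials of one subject (24 trials per market by default)."""

    subject_id: str
    market_sequence: tuple[str, ...]
    trials: list[TrialRecord] = field(default_factory=list)

    def bid_trials(self, market_label: str | None = None) -> list[TrialRecord]:
        """Entered trials, optionally restricted to one market, in order."""
        return [
            t
            for t in self.trials
            if t.entered and (market_label is None or t.market == market_label)
        ]


@dataclass
class Dataset:
    """A cohort of sessions with unique subject ids."""

    sessions: list[Session] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.sessions]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate subject_id in dataset")

    def __len__(self) -> int:
        return len(self.sessions)

    def n_bid_trials(self) -> int:
        return sum(len(s.bid_trials()) for s in self.sessions)


def bid_grid() -> np.ndarray:
    """The 101-point action grid 0.0, 0.1, ..., 10.0 MU."""
    return np.round(np.arange(_N_GRID) * 0.1, 1)


_GRID = bid_grid()


def bid_index(bid: float) -> int:
    """Index of a grid bid; raises if the value is off the grid."""
    idx = int(round(bid * 10))
    if not 0 <= idx < _N_GRID or abs(_GRID[idx] - bid) > 1e-9:
        raise ValueError(f"bid {bid} is not on the 0.1 MU grid")
    return idx


def snap_to_grid(x: float) -> float:
    """Nearest grid bid; exact half-steps (e.g. 3.15) round up."""
    if not 0.0 <= x <= 10.0:
        raise ValueError(f"bid {x} outside [0, 10]")
    # round-half-up at 0.05 resolution, robust to float representation
    return float(_GRID[min(int(math.floor(x * 10 + 0.5 + 1e-9)), _N_GRID - 1)])


def resolve_trial(
    market_type: MarketType,
    bid: float,
    asks: list[float],
    competitor_bids: list[float] | None = None,
    tie_rng: np.random.Generator | None = None,
) -> tuple[bool, float, float | None]:
    """Resolve one auction trial from the subject's point of view.

    The subject transacts iff their bid is the (tie-broken) highest buyer
    bid and that bid is at or above the lowest ask.  Ties between equal
    buyer bids are broken by a fair coin from ``tie_rng``.  Returns
    ``(accepted, reward, disclosed_competitor_bid)``.
    """
    competitor_bids = list(competitor_bids or [])
    if len(asks) != market_type.n_sellers:
        raise ValueError(
            f"{market_type.label} needs {market_type.n_sellers} asks, got {len(asks)}"
        )
    if len(competitor_bids) != market_type.n_competitor_buyers:
        raise ValueError(
            f"{market_type.label} needs {market_type.n_competitor_buyers} "
            f"competitor bids, got {len(competitor_bids)}"
        )
    bid = float(_GRID[bid_index(bid)])

    disclosed = None
    is_highest = True
    for cb in competitor_bids:
        if cb > bid:
            is_highest = False
            disclosed = float(cb)
        elif cb == bid:
            if tie_rng is None:
                raise ValueError("tie_rng required to break an equal-bid tie")
            if tie_rng.random() < 0.5:
                is_highest = False

    accepted = is_highest and bid >= min(asks)
    # reward lives on the same 0.1 MU grid as the bid; keep it canonical
    reward = round(10.0 - bid, 1) if accepted else 0.0
    return accepted, reward, disclosed


def market_sequence(sequence_id: int) -> tuple[str, ...]:
    """One of the six fixed market-type block orders (1-based id)."""
    perms = list(itertools.permutations(MARKETS))
    if not 1 <= sequence_id <= 6:
        raise ValueError(f"sequence_id must be 1..6, got {sequence_id}")
    return perms[sequence_id - 1]


def market_schedule(
    sequence_id: int,
    n_blocks: int,
    lottery_seed: int | np.random.Generator | None = 0,
) -> list[tuple[str, bool]]:
    """Blocked market order with the 1-in-6 lottery applied.

    The market permutation repeats ``n_blocks`` times; in every disjoint
    window of six scheduled trials, exactly one uniformly placed trial is
    lottery-excluded (``entered=False``).  A trailing partial window of
    ``w`` trials is excluded with probability ``w/6``.  Pass
    ``lottery_seed=None`` to disable the lottery entirely.
    """
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    seq = market_sequence(sequence_id)
    markets = [m for _ in range(n_blocks) for m in seq]
    entered = [True] * len(markets)
    if lottery_seed is not None:
        rng = (
            lottery_seed
            if isinstance(lottery_seed, np.random.Generator)
            else np.random.default_rng(lottery_seed)
        )
        for start in range(0, len(markets), 6):
            width = min(6, len(markets) - start)
            pos = int(rng.integers(6))
            if pos < width:
                entered[start + pos] = False
    return list(zip(markets, entered))
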