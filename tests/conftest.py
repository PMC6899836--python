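"""Shared fixtures: hand-built sessions and small simulated cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from bidlearn.core import Dataset, Session, TrialRecord, bid_grid
from bidlearn.cohort import CohortConfig, simulate_cohort
from bidlearn.models import REFERENCE_FFX_ESTIMATES

GRID = bid_grid()


def make_trial(
    subject_id: str,
    market: str,
    block: int,
    trial_in_market: int,
    bid: float | None,
    accepted: bool | None = None,
) -> TrialRecord:
    """Build a consistent TrialRecord (reward derived from the outcome)."""
    if bid is None:
        return TrialRecord(subject_id, market, block, trial_in_market, entered=False)
    return TrialRecord(
        subject_id,
        market,
        block,
        trial_in_market,
        entered=True,
        bid=bid,
        accepted=accepted,
        reward=round(10.0 - bid, 1) if accepted else 0.0,
    )


def make_session(subject_id: str, per_market: dict[str, list[tuple]]) -> Session:
    """Session from ``{market: [(bid, accepted) | None, ...]}`` lists.

    Markets are interleaved block-wise (SC, NC, BC) so chronological
    order within each market follows the list order.
    """
    trials: list[TrialRecord] = []
    n = max(len(v) for v in per_market.values())
    for block in range(n):
        for m in ("SC", "NC", "BC"):
            seq = per_market.get(m, [])
            if block >= len(seq):
                continue
            item = seq[block]
            if item is None:
                trials.append(make_trial(subject_id, m, block + 1, block + 1, None))
            else:
                bid, accepted = item
                trials.append(
                    make_trial(subject_id, m, block + 1, block + 1, bid, accepted)
                )
    return Session(subject_id=subject_id, market_sequence=("SC", "NC", "BC"), trials=trials)


def random_session(rng: np.random.Generator, subject_id="r", n_per_market=5) -> Session:
    """Random grid bids with random outcomes, all three markets."""
    per_market = {}
    for m in ("SC", "NC", "BC"):
        per_market[m] = [
            (float(GRID[rng.integers(101)]), bool(rng.integers(2)))
            for _ in range(n_per_market)
        ]
    return make_session(subject_id, per_market)


@pytest.fixture(scope="session")
def small_lepto_cohort() -> Dataset:
    """Six subjects simulated from dl_lepto at the reference estimates."""
    return simulate_cohort(
        CohortConfig(
            n_subjects=6,
            model="dl_lepto",
            params=dict(REFERENCE_FFX_ESTIMATES["dl_lepto"]),
            master_seed=2024,
        )
    )


@pytest.fixture(scope="session")
def two_subject_dataset() -> Dataset:
    """Tiny hand-sized simulated dataset for I/O round trips."""
    return simulate_cohort(
        CohortConfig(n_subjects=2, n_blocks=6, master_seed=7)
    )
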