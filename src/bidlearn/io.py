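"""Tab-separated event-table I/O (BIDS events.tsv style).

The canonical dialect is a UTF-8, tab-separated table with a header row and
``n/a`` for missing values, one row per trial:

``subject_id  market  block  trial_in_market  entered  bid  accepted
reward  competitor_bid`` (+ optional ``onset``, ``duration``).

External dialects with different column names can be adapted through a
column-mapping config (a YAML/dict ``{canonical_name: file_name}``).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import Dataset, Session, TrialRecord, market_sequence, snap_to_grid

__all__ = ["read_events_tsv", "write_events_tsv", "dataset_to_frame", "frame_to_dataset"]

REQUIRED_COLUMNS = [
    "subject_id",
    "market",
    "block",
    "trial_in_market",
    "entered",
    "bid",
    "accepted",
    "reward",
    "competitor_bid",
]
OPTIONAL_COLUMNS = ["onset", "duration"]

_NA = "n/a"


def dataset_to_frame(dataset: Dataset) -> pd.DataFrame:
    """Flatten a :class:`Dataset` to a canonical events table."""
    rows = []
    has_onset = any(
        t.onset is not None for s in dataset.sessions for t in s.trials
    )
    for session in dataset.sessions:
        for t in session.trials:
            row = {
                "subject_id": session.subject_id,
                "market": t.market,
                "block": t.block_index,
                "trial_in_market": t.trial_in_market,
                "entered": int(t.entered),
                "bid": t.bid,
                "accepted": None if t.accepted is None else int(t.accepted),
                "reward": t.reward,
                "competitor_bid": t.disclosed_competitor_bid,
            }
            if has_onset:
                row["onset"] = t.onset
                row["duration"] = t.duration
            rows.append(row)
    return pd.DataFrame(rows)


def write_events_tsv(dataset: Dataset, path: str | Path) -> None:
    """Write the canonical tab-separated event table (``n/a`` for missing)."""
    frame = dataset_to_frame(dataset)
    frame.to_csv(path, sep="\t", index=False, na_rep=_NA)


class EventsParseError(ValueError):
    """Structured parse failure naming the offending column."""

    def __init__(self, column: str, message: str):
        self.column = column
        super().__init__(f"column {column!r}: {message}")


def _load_mapping(column_map: str | Path | dict | None) -> dict:
    if column_map is None:
        return {}
    if isinstance(column_map, (str, Path)):
        with open(column_map) as fh:
            cfg = yaml.safe_load(fh) or {}
        return cfg.get("columns", cfg)
    return dict(column_map)


def frame_to_dataset(frame: pd.DataFrame, snap: bool = False) -> Dataset:
    """Build a :class:`Dataset` from a canonical events table."""
    for col in REQUIRED_COLUMNS:
        if col not in frame.columns:
            raise EventsParseError(col, "missing required column")
    sessions: dict[str, Session] = {}
    for _, row in frame.iterrows():
        sid = str(row["subject_id"])
        entered = bool(int(row["entered"]))
        bid = accepted = None
        comp = None if pd.isna(row["competitor_bid"]) else float(row["competitor_bid"])
        if entered:
            try:
                bid = float(row["bid"])
            except (TypeError, ValueError) as exc:
                raise EventsParseError("bid", f"non-numeric value {row['bid']!r}") from exc
            if np.isnan(bid):
                raise EventsParseError("bid", "missing bid on an entered trial")
            snapped = snap_to_grid(bid)
            if abs(snapped - bid) > 1e-9:
                if not snap:
                    raise EventsParseError(
                        "bid", f"off-grid bid {bid} (pass snap=True to round)"
                    )
                bid = snapped
            accepted = bool(int(row["accepted"]))
        if row["market"] not in ("SC", "NC", "BC"):
            raise EventsParseError("market", f"unknown market label {row['market']!r}")
        record = TrialRecord(
            subject_id=sid,
            market=str(row["market"]),
            block_index=int(row["block"]),
            trial_in_market=int(row["trial_in_market"]),
            entered=entered,
            bid=bid,
            accepted=accepted,
            reward=float(row["reward"]),
            disclosed_competitor_bid=comp,
            onset=None if "onset" not in row or pd.isna(row.get("onset")) else float(row["onset"]),
            duration=None
            if "duration" not in row or pd.isna(row.get("duration"))
            else float(row["duration"]),
        )
        if sid not in sessions:
            sessions[sid] = Session(subject_id=sid, market_sequence=(), trials=[])
        sessions[sid].trials.append(record)
    out = []
    for sess in sessions.values():
        seen: list[str] = []
        for t in sess.trials:
            if t.market not in seen:
                seen.append(t.market)
        sess.market_sequence = tuple(seen) if len(seen) == 3 else market_sequence(1)
        out.append(sess)
    return Dataset(sessions=out)


def read_events_tsv(
    path: str | Path,
    column_map: str | Path | dict | None = None,
    snap: bool = False,
) -> Dataset:
    """Read an events table, optionally renaming columns via a mapping config.

    ``column_map`` maps canonical names to the file's names, e.g.
    ``{"subject_id": "participant"}``.  ``snap=True`` rounds off-grid bids
    to the nearest 0.1 MU instead of rejecting them.
    """
    frame = pd.read_csv(
        path, sep="\t", na_values=[_NA], keep_default_na=False, dtype={0: str}
    )
    mapping = _load_mapping(column_map)
    if mapping:
        frame = frame.rename(columns={v: k for k, v in mapping.items()})
    if "subject_id" in frame.columns:
        frame["subject_id"] = frame["subject_id"].astype(str)
    return frame_to_dataset(frame, snap=snap)
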