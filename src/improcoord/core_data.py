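"""Domain types and I/O for one ensemble performance.

A performance is represented by two aligned 1 Hz matrices — a binary
"musical action" matrix (one row per musician: 1 = playing, 0 = silent)
and a continuous "directional intention" matrix with values in [0, 1]
(0 = intend to change the group's music, 1 = intend to support it,
0.5 = neutral) — together with an expert segmentation of the piece into
formal sequences and per-musician metadata (instrument family, seat
position, experience, pairwise familiarity ratings).

Intention sliders emit timestamped on-change events; :func:`resample_to_1hz`
converts an event log into a 1 Hz series by sample-and-hold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "DegenerateSeriesError",
    "InstrumentFamily",
    "MusicianProfile",
    "ActionSeries",
    "IntentionSeries",
    "Segmentation",
    "EnsembleRecording",
    "SummaryStats",
    "summarize",
    "resample_to_1hz",
    "build_recording",
    "segmentation_stats",
    "read_recording",
    "write_recording",
]

NEUTRAL_SLIDER = 0.5

INSTRUMENT_FAMILIES = ("winds", "strings", "inharmonic")


class ValidationError(ValueError):
    """Raised when input data violate the domain contracts."""


class DegenerateSeriesError(ValueError):
    """Raised when a series is constant and a statistic is undefined on it."""


class InstrumentFamily:
    """Namespace of the three instrument families (winds, strings, inharmonic)."""

    WINDS = "winds"
    STRINGS = "strings"
    INHARMONIC = "inharmonic"

    @staticmethod
    def validate(value: str) -> str:
        if value not in INSTRUMENT_FAMILIES:
            raise ValidationError(
                f"unknown instrument family {value!r}; expected one of {INSTRUMENT_FAMILIES}"
            )
        return value


@dataclass(frozen=True)
class MusicianProfile:
    """Metadata for one musician.

    ``familiarity_ratings`` maps partner id -> rating in {0, 1, 2}
    (0 = never played together outside the ensemble, 1 = rarely,
    2 = frequently).
    """

    musician_id: str
    instrument_family: str
    seat_index: int
    years_in_ensemble: float
    years_cfi: float
    familiarity_ratings: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        InstrumentFamily.validate(self.instrument_family)
        if self.seat_index < 0:
            raise ValidationError(f"{self.musician_id}: seat_index must be non-negative")
        if self.years_in_ensemble < 0 or self.years_cfi < 0:
            raise ValidationError(f"{self.musician_id}: year counts must be non-negative")
        if self.musician_id in self.familiarity_ratings:
            raise ValidationError(f"{self.musician_id}: self-rating not allowed")
        for partner, rating in self.familiarity_ratings.items():
            if rating not in (0, 1, 2):
                raise ValidationError(
                    f"{self.musician_id}->{partner}: familiarity rating {rating!r} not in {{0,1,2}}"
                )


@dataclass(frozen=True)
class ActionSeries:
    """One musician's binary play/silence series at 1 Hz."""

    musician_id: str
    values: np.ndarray
    t0: int = 0

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 1:
            raise ValidationError(f"{self.musician_id}: action series must be 1-D")
        if not np.isin(values, (0, 1)).all():
            raise ValidationError(
                f"{self.musician_id}: action values must be 0/1, got "
                f"{sorted(set(np.unique(values)) - {0, 1})}"
            )
        object.__setattr__(self, "values", values.astype(np.int8))

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class IntentionSeries:
    """One musician's continuous intention series at 1 Hz, values in [0, 1]."""

    musician_id: str
    values: np.ndarray
    t0: int = 0

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1:
            raise ValidationError(f"{self.musician_id}: intention series must be 1-D")
        if not np.isfinite(values).all():
            raise ValidationError(f"{self.musician_id}: intention values must be finite")
        if (values < 0).any() or (values > 1).any():
            raise ValidationError(f"{self.musician_id}: intention values must lie in [0, 1]")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class Segmentation:
    """Boundary times (seconds) splitting the performance into sequences.

    Boundaries start at 0, end at the performance duration, and are strictly
    increasing. Sequences are half-open intervals ``[start, end)`` so that
    durations sum exactly to the total length.
    """

    boundaries: tuple

    def __init__(self, boundaries: Iterable[float]) -> None:
        bounds = tuple(float(b) for b in boundaries)
        if len(bounds) < 2:
            raise ValidationError("segmentation needs at least two boundaries")
        if bounds[0] != 0:
            raise ValidationError(f"first boundary must be 0, got {bounds[0]}")
        if any(b1 >= b2 for b1, b2 in zip(bounds, bounds[1:])):
            raise ValidationError(f"boundaries must be strictly increasing: {bounds}")
        object.__setattr__(self, "boundaries", bounds)

    @property
    def sequences(self) -> list[tuple[float, float]]:
        """Half-open ``(start, end)`` intervals."""
        return list(zip(self.boundaries, self.boundaries[1:]))

    @property
    def durations(self) -> np.ndarray:
        return np.diff(self.boundaries)

    @property
    def duration_s(self) -> float:
        return self.boundaries[-1]

    def __len__(self) -> int:
        return len(self.boundaries) - 1


@dataclass(frozen=True)
class SummaryStats:
    """Mean / sample SD (n-1) summary; ``sd`` is None when n < 2."""

    mean: float
    sd: float | None
    n: int
    min: float
    max: float


def summarize(values: Sequence[float]) -> SummaryStats:
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValidationError("cannot summarize an empty sequence")
    sd = float(np.std(arr, ddof=1)) if arr.size >= 2 else None
    return SummaryStats(
        mean=float(arr.mean()), sd=sd, n=int(arr.size),
        min=float(arr.min()), max=float(arr.max()),
    )


@dataclass(frozen=True)
class EnsembleRecording:
    """One performance: profiles, action/intention matrices, segmentation.

    Matrices are (musicians x seconds) with one row per id in
    ``action_ids`` / ``intention_ids``. Fewer intention rows than action
    rows is allowed (sliders can be lost to technical faults).
    ``silent_ids`` lists musicians whose action row is all-zero; they are
    kept in the matrices but flagged so the analysis can exclude them.
    """

    profiles: tuple
    actions: np.ndarray
    action_ids: tuple
    intentions: np.ndarray
    intention_ids: tuple
    segmentation: Segmentation
    silent_ids: tuple = ()

    @property
    def duration_s(self) -> int:
        return int(self.actions.shape[1])

    @property
    def profile_map(self) -> dict[str, MusicianProfile]:
        return {p.musician_id: p for p in self.profiles}

    def action_series(self, musician_id: str) -> ActionSeries:
        row = self.action_ids.index(musician_id)
        return ActionSeries(musician_id, self.actions[row])

    def intention_series(self, musician_id: str) -> IntentionSeries:
        row = self.intention_ids.index(musician_id)
        return IntentionSeries(musician_id, self.intentions[row])


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def resample_to_1hz(
    events: Sequence[tuple[float, float]],
    duration_s: int,
    initial_value: float = NEUTRAL_SLIDER,
    musician_id: str = "",
) -> IntentionSeries:
    """Resample a slider event log to a 1 Hz series by sample-and-hold.

    The value at integer second ``t`` is the value of the last event with
    timestamp <= 1000*t ms; before any event it is ``initial_value``
    (default 0.5, the slider's neutral middle position). Sliders emit on
    change, so holding the last value is the physical semantics.

    Parameters
    ----------
    events:
        ``(timestamp_ms, value)`` pairs; sorted by timestamp if not already.
    duration_s:
        Length of the output series in seconds (>= 1).
    """
    if duration_s < 1:
        raise ValidationError(f"duration_s must be >= 1, got {duration_s}")
    if not (0.0 <= initial_value <= 1.0):
        raise ValidationError(f"initial_value {initial_value} outside [0, 1]")
    evs = sorted(events, key=lambda e: e[0])
    for ts, val in evs:
        if ts < 0:
            raise ValidationError(f"negative event timestamp {ts}")
        if not (0.0 <= val <= 1.0):
            raise ValidationError(f"event value {val} outside [0, 1]")
    out = np.full(int(duration_s), float(initial_value))
    if evs:
        stamps = np.array([e[0] for e in evs], dtype=float)
        vals = np.array([e[1] for e in evs], dtype=float)
        seconds_ms = np.arange(duration_s, dtype=float) * 1000.0
        # index of last event at or before each second; -1 -> initial value
        idx = np.searchsorted(stamps, seconds_ms, side="right") - 1
        mask = idx >= 0
        out[mask] = vals[idx[mask]]
    return IntentionSeries(musician_id, out)


def build_recording(
    profiles: Sequence[MusicianProfile],
    action_rows: Mapping[str, Sequence[int]],
    intention_rows: Mapping[str, Sequence[float]],
    segmentation: Segmentation,
) -> EnsembleRecording:
    """Assemble and validate an :class:`EnsembleRecording`.

    All rows must share one length equal to the segmentation's total
    duration. Intention rows may cover only a subset of the musicians with
    action rows. All-silent musicians are flagged in ``silent_ids`` (they
    carry no pairwise information and are excluded downstream).
    """
    known = {p.musician_id for p in profiles}
    for rid in list(action_rows) + list(intention_rows):
        if rid not in known:
            raise ValidationError(f"row id {rid!r} has no matching musician profile")
    if not action_rows:
        raise ValidationError("at least one action row is required")

    lengths = {len(v) for v in action_rows.values()} | {len(v) for v in intention_rows.values()}
    if len(lengths) != 1:
        raise ValidationError(f"rows have inconsistent lengths: {sorted(lengths)}")
    duration = lengths.pop()
    if duration != int(segmentation.duration_s):
        raise ValidationError(
            f"row length {duration} does not match segmentation duration "
            f"{segmentation.duration_s}"
        )

    action_ids = tuple(action_rows)
    intention_ids = tuple(intention_rows)
    actions = np.vstack(
        [ActionSeries(mid, np.asarray(action_rows[mid])).values for mid in action_ids]
    )
    if intention_ids:
        intentions = np.vstack(
            [IntentionSeries(mid, np.asarray(intention_rows[mid])).values for mid in intention_ids]
        )
    else:
        intentions = np.empty((0, duration))
    silent = tuple(mid for mid, row in zip(action_ids, actions) if not row.any())

    seats = [p.seat_index for p in profiles]
    if len(set(seats)) != len(seats):
        raise ValidationError("seat_index values must be unique within an ensemble")

    return EnsembleRecording(
        profiles=tuple(profiles),
        actions=actions,
        action_ids=action_ids,
        intentions=intentions,
        intention_ids=intention_ids,
        segmentation=segmentation,
        silent_ids=silent,
    )


def segmentation_stats(seg: Segmentation) -> SummaryStats:
    """Mean and sample SD (n-1 denominator) of the sequence durations."""
    return summarize(seg.durations)


# ---------------------------------------------------------------------------
# CSV interfaces
#
# actions.csv / intentions.csv: wide, first column musician_id, then t0..t{T-1}
# slider_events.csv: long, musician_id,timestamp_ms,value
# segmentation.csv: single column boundary_s
# musicians.csv: musician_id,instrument_family,seat_index,years_in_ensemble,years_cfi
# familiarity.csv: rater_id,partner_id,rating
# ---------------------------------------------------------------------------

def _wide_frame(ids: Sequence[str], matrix: np.ndarray) -> pd.DataFrame:
    cols = [f"t{t}" for t in range(matrix.shape[1])]
    df = pd.DataFrame(matrix, columns=cols)
    df.insert(0, "musician_id", list(ids))
    return df


def write_recording(recording: EnsembleRecording, out_dir: str | Path) -> dict[str, Path]:
    """Write a recording to the five-file CSV layout; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    paths["actions"] = out / "actions.csv"
    _wide_frame(recording.action_ids, recording.actions).to_csv(paths["actions"], index=False)

    paths["intentions"] = out / "intentions.csv"
    _wide_frame(recording.intention_ids, recording.intentions).to_csv(
        paths["intentions"], index=False, float_format="%.17g"
    )

    paths["segmentation"] = out / "segmentation.csv"
    pd.DataFrame({"boundary_s": recording.segmentation.boundaries}).to_csv(
        paths["segmentation"], index=False
    )

    paths["musicians"] = out / "musicians.csv"
    pd.DataFrame(
        [
            {
                "musician_id": p.musician_id,
                "instrument_family": p.instrument_family,
                "seat_index": p.seat_index,
                "years_in_ensemble": p.years_in_ensemble,
                "years_cfi": p.years_cfi,
            }
            for p in recording.profiles
        ]
    ).to_csv(paths["musicians"], index=False)

    paths["familiarity"] = out / "familiarity.csv"
    fam_rows = [
        {"rater_id": p.musician_id, "partner_id": partner, "rating": rating}
        for p in recording.profiles
        for partner, rating in sorted(p.familiarity_ratings.items())
    ]
    pd.DataFrame(fam_rows, columns=["rater_id", "partner_id", "rating"]).to_csv(
        paths["familiarity"], index=False
    )
    return paths


def read_recording(in_dir: str | Path) -> EnsembleRecording:
    """Read a recording from the CSV layout written by :func:`write_recording`."""
    src = Path(in_dir)

    musicians = pd.read_csv(src / "musicians.csv")
    fam_path = src / "familiarity.csv"
    fam = pd.read_csv(fam_path) if fam_path.exists() else pd.DataFrame(
        columns=["rater_id", "partner_id", "rating"]
    )
    ratings: dict[str, dict[str, int]] = {}
    for row in fam.itertuples(index=False):
        ratings.setdefault(str(row.rater_id), {})[str(row.partner_id)] = int(row.rating)

    profiles = [
        MusicianProfile(
            musician_id=str(row.musician_id),
            instrument_family=str(row.instrument_family),
            seat_index=int(row.seat_index),
            years_in_ensemble=float(row.years_in_ensemble),
            years_cfi=float(row.years_cfi),
            familiarity_ratings=ratings.get(str(row.musician_id), {}),
        )
        for row in musicians.itertuples(index=False)
    ]

    seg = Segmentation(pd.read_csv(src / "segmentation.csv")["boundary_s"].tolist())

    def _read_wide(path: Path) -> dict[str, np.ndarray]:
        if not path.exists():
            return {}
        df = pd.read_csv(path)
        if df.empty:
            return {}
        return {
            str(row[0]): np.asarray(row[1:], dtype=float)
            for row in df.itertuples(index=False)
        }

    action_rows = {k: v.astype(int) for k, v in _read_wide(src / "actions.csv").items()}
    intention_rows = _read_wide(src / "intentions.csv")
    return build_recording(profiles, action_rows, intention_rows, seg)
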