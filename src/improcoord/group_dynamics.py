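"""Group-level per-second statistics and the windowed alignment contrast.

Three per-second summaries describe the whole ensemble:

* fraction playing — percentage of musicians playing at each second;
* mean intention — mean slider value at each second (where the group as a
  whole wants to take the music);
* group alignment — ``|#{x_i > 0.5} - #{x_i < 0.5}| / N``: 1 when all
  musicians push in the same direction, 0 when the group splits in half.
  Neutral sliders (exactly 0.5) count in neither camp.

The windowed analysis contrasts alignment inside windows centered on each
sequence's temporal middle against windows centered on the junctions
between sequences, each window spanning ``halfwidth_s`` seconds on either
side of the center with the center itself excluded (16 s halfwidth gives
32 points per window).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .core_data import Segmentation, ValidationError
from .pairwise_coordination import AnalysisConfig, ComparisonResult, scramble

logger = logging.getLogger(__name__)

__all__ = [
    "AlignmentSeries",
    "WindowMask",
    "fraction_playing",
    "mean_intention",
    "group_alignment",
    "alignment_series",
    "null_alignment",
    "window_indices",
    "compare_windows",
    "alignment_vs_mean",
    "compute_alignment_series",
]


@dataclass(frozen=True)
class AlignmentSeries:
    """Per-second group statistics for one performance."""

    t: np.ndarray
    fraction_playing: np.ndarray   # percentage, [0, 100]
    mean_intention: np.ndarray     # [0, 1]
    alignment: np.ndarray          # [0, 1]
    null_alignment: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.t)


@dataclass(frozen=True)
class WindowMask:
    """Second indices covered by middle or junction windows."""

    kind: str                      # "middle" or "junction"
    halfwidth_s: int
    centers: tuple
    indices: np.ndarray

    def __len__(self) -> int:
        return len(self.indices)


def fraction_playing(actions: np.ndarray) -> np.ndarray:
    """Percentage of musicians playing at each second (column mean x 100)."""
    actions = np.asarray(actions)
    if actions.size == 0:
        raise ValidationError("empty action matrix")
    return 100.0 * actions.mean(axis=0)


def mean_intention(intentions: np.ndarray) -> np.ndarray:
    """Mean slider value at each second."""
    intentions = np.asarray(intentions, dtype=float)
    if intentions.size == 0:
        raise ValidationError("empty intention matrix")
    return intentions.mean(axis=0)


def group_alignment(slider_column: Sequence[float]) -> float:
    """``|#support - #change| / N`` for one second's slider values.

    Support is a value > 0.5, change a value < 0.5; exactly neutral values
    count in neither set but still contribute to the denominator.
    """
    col = np.asarray(slider_column, dtype=float)
    if col.size == 0:
        raise ValidationError("empty slider column")
    support = int((col > 0.5).sum())
    change = int((col < 0.5).sum())
    return abs(support - change) / col.size


def _alignment_per_second(intentions: np.ndarray) -> np.ndarray:
    intentions = np.asarray(intentions, dtype=float)
    support = (intentions > 0.5).sum(axis=0)
    change = (intentions < 0.5).sum(axis=0)
    return np.abs(support - change) / intentions.shape[0]


def alignment_series(intentions: np.ndarray) -> np.ndarray:
    """Group alignment at every second of an intention matrix."""
    intentions = np.asarray(intentions, dtype=float)
    if intentions.size == 0:
        raise ValidationError("empty intention matrix")
    return _alignment_per_second(intentions)


def null_alignment(
    intentions: np.ndarray,
    config: AnalysisConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Chance-level alignment from independently time-scrambled musician rows.

    Each surrogate scrambles every musician's row independently ("fake
    combinations of musicians"); the per-second alignment is averaged over
    ``config.n_surrogates`` surrogates.
    """
    intentions = np.asarray(intentions, dtype=float)
    if intentions.size == 0:
        raise ValidationError("empty intention matrix")
    rng = config.rng() if rng is None else rng
    acc = np.zeros(intentions.shape[1])
    for _ in range(config.n_surrogates):
        scrambled = np.vstack([scramble(row, rng) for row in intentions])
        acc += _alignment_per_second(scrambled)
    return acc / config.n_surrogates


def window_indices(
    seg: Segmentation, kind: str, halfwidth_s: int = 16
) -> WindowMask:
    """Second indices of middle or junction windows.

    Middle centers are ``floor((start + end) / 2)`` of each sequence;
    junction centers are the internal boundaries plus the final boundary,
    so both kinds yield one window per sequence.  Each window covers
    ``halfwidth_s`` seconds strictly before and after its center (center
    excluded) and is clipped to ``[0, T)``.  Overlap between windows from
    distinct centers is allowed but warned about.
    """
    if halfwidth_s < 0:
        raise ValidationError("halfwidth_s must be >= 0")
    if kind == "middle":
        centers = [int((start + end) // 2) for start, end in seg.sequences]
    elif kind == "junction":
        centers = [int(b) for b in seg.boundaries[1:]]
    else:
        raise ValidationError(f"unknown window kind {kind!r}")

    duration = int(seg.duration_s)
    index_list: list[int] = []
    for c in centers:
        lo = np.arange(c - halfwidth_s, c)
        hi = np.arange(c + 1, c + halfwidth_s + 1)
        window = np.concatenate([lo, hi])
        index_list.extend(int(i) for i in window if 0 <= i < duration)

    unique = np.array(sorted(set(index_list)), dtype=int)
    n_overlap = len(index_list) - len(unique)
    if n_overlap > 0:
        warnings.warn(
            f"{kind} windows overlap at {n_overlap} second(s); indices deduplicated",
            stacklevel=2,
        )
    return WindowMask(kind=kind, halfwidth_s=halfwidth_s, centers=tuple(centers), indices=unique)


def compare_windows(
    alignment: Sequence[float],
    middle: WindowMask,
    junction: WindowMask,
    pooled: bool = False,
) -> ComparisonResult:
    """t-test of alignment inside middle windows vs. junction windows.

    Welch's unequal-variance test by default; ``pooled=True`` gives the
    classical equal-variance test.
    """
    alignment = np.asarray(alignment, dtype=float)
    if len(middle) == 0 or len(junction) == 0:
        raise ValidationError("window masks must be non-empty")
    shared = set(middle.indices.tolist()) & set(junction.indices.tolist())
    if shared:
        warnings.warn(
            f"middle and junction windows share {len(shared)} second(s)", stacklevel=2
        )
    mid_vals = alignment[middle.indices]
    jct_vals = alignment[junction.indices]
    if np.ptp(mid_vals) == 0 and np.ptp(jct_vals) == 0:
        return ComparisonResult(
            t=0.0, df=len(mid_vals) + len(jct_vals) - 2, p=1.0, d=None,
            mean_real=float(mid_vals.mean()), mean_null=float(jct_vals.mean()),
            degenerate=True,
        )
    res = stats.ttest_ind(mid_vals, jct_vals, equal_var=pooled)
    pooled_sd = np.sqrt(
        (
            (len(mid_vals) - 1) * mid_vals.var(ddof=1)
            + (len(jct_vals) - 1) * jct_vals.var(ddof=1)
        )
        / (len(mid_vals) + len(jct_vals) - 2)
    )
    d = float((mid_vals.mean() - jct_vals.mean()) / pooled_sd) if pooled_sd > 0 else None
    df = (
        len(mid_vals) + len(jct_vals) - 2
        if pooled
        else float(res.df) if hasattr(res, "df") else len(mid_vals) + len(jct_vals) - 2
    )
    return ComparisonResult(
        t=float(res.statistic), df=float(df), p=float(res.pvalue), d=d,
        mean_real=float(mid_vals.mean()), mean_null=float(jct_vals.mean()),
    )


def alignment_vs_mean(
    alignment: Sequence[float], mean_intention_series: Sequence[float]
) -> tuple[float, float]:
    """Spearman correlation between per-second alignment and mean slider value."""
    a = np.asarray(alignment, dtype=float)
    m = np.asarray(mean_intention_series, dtype=float)
    if a.size != m.size:
        raise ValidationError(f"length mismatch: {a.size} vs {m.size}")
    if np.ptp(a) == 0 or np.ptp(m) == 0:
        raise ValidationError("constant series: correlation degenerate")
    rho, p = stats.spearmanr(a, m)
    return float(rho), float(p)


def compute_alignment_series(
    actions: np.ndarray,
    intentions: np.ndarray,
    config: AnalysisConfig,
    with_null: bool = True,
) -> AlignmentSeries:
    """Assemble the full per-second group summary for one recording."""
    frac = fraction_playing(actions)
    mean_int = mean_intention(intentions)
    align = alignment_series(intentions)
    null = null_alignment(intentions, config) if with_null else None
    return AlignmentSeries(
        t=np.arange(len(frac)),
        fraction_playing=frac,
        mean_intention=mean_int,
        alignment=align,
        null_alignment=null,
    )
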