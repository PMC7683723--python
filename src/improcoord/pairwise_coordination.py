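"""Per-pair coordination statistics with time-scrambled null calibration.

For every unordered pair of musicians the pipeline computes:

* **causal density** — the mean of the two directed Granger-significance
  indicators ``(1[p_ab < alpha] + 1[p_ba < alpha]) / 2``, so a pair scores
  0, 0.5 or 1 depending on whether neither, one, or both directions of
  forward prediction are significant.  A continuous alternative (mean of
  the two F statistics) is available via ``AnalysisConfig.density_scale``.
* **correlation** — Spearman's rho between binary action series, Pearson's
  rho between continuous intention series, with a significance
  classification (positive / negative / none).
* **sonic organization** — ``|rho|`` of the action correlation: coordination
  regardless of sign, so that co-playing and turn-taking both count.
* **mean slider distance** — the time-averaged ``|x_t - y_t|`` between two
  intention series; smaller means more congruent intentions.

Chance levels come from surrogate series obtained by uniformly permuting
each series' time indices, which preserves the value distribution while
destroying all temporal structure.

Granger tests are plain restricted-vs-unrestricted least-squares F tests:
the unrestricted model predicts ``y_t`` from a constant, ``L`` own lags and
``L`` lags of ``x``; the restricted model drops the ``x`` lags.  Before
testing, each series is checked for stationarity with an augmented
Dickey-Fuller test and linearly detrended if the test fails to reject a
unit root.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import stats

from .core_data import (
    ActionSeries,
    DegenerateSeriesError,
    EnsembleRecording,
    IntentionSeries,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AnalysisConfig",
    "PairCoordination",
    "ComparisonResult",
    "SurrogateSummary",
    "check_stationarity_and_detrend",
    "select_max_lag",
    "granger_pvalues",
    "granger_fstats",
    "causal_density",
    "scramble",
    "phase_randomize",
    "null_distribution",
    "action_correlation",
    "sonic_organization",
    "intention_correlation",
    "mean_slider_distance",
    "block_permutation_pvalue",
    "compare_to_null",
    "all_pairs",
]


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable parameters for the pairwise analysis.

    ``max_lag`` is the Granger model order in seconds (default 16, the
    order selected on the original orchestra dataset).  ``n_surrogates``
    controls the time-scrambled null (1 reproduces a single-draw design).
    """

    max_lag: int = 16
    alpha: float = 0.05
    n_surrogates: int = 100
    rng_seed: int = 0
    lag_candidates: tuple = tuple(range(1, 21))
    stationarity_alpha: float = 0.05
    density_scale: str = "binary"        # "binary" -> {0, 0.5, 1}; "fstat" -> mean F
    surrogate_kind: str = "permutation"  # or "phase" for phase randomization

    def __post_init__(self) -> None:
        if self.max_lag < 1:
            raise ValidationError("max_lag must be >= 1")
        if not (0 < self.alpha < 1):
            raise ValidationError("alpha must lie in (0, 1)")
        if self.n_surrogates < 1:
            raise ValidationError("n_surrogates must be >= 1")
        if self.density_scale not in ("binary", "fstat"):
            raise ValidationError(f"unknown density_scale {self.density_scale!r}")
        if self.surrogate_kind not in ("permutation", "phase"):
            raise ValidationError(f"unknown surrogate_kind {self.surrogate_kind!r}")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.rng_seed)


@dataclass(frozen=True)
class SurrogateSummary:
    """Samples of a metric on scrambled copies, with mean and sample SD."""

    samples: np.ndarray
    mean: float
    sd: float | None

    @classmethod
    def from_samples(cls, samples: Sequence[float]) -> "SurrogateSummary":
        arr = np.asarray(samples, dtype=float)
        sd = float(np.std(arr, ddof=1)) if arr.size >= 2 else None
        return cls(samples=arr, mean=float(arr.mean()), sd=sd)


@dataclass
class PairCoordination:
    """All per-pair metrics for one unordered pair of musicians."""

    id_a: str
    id_b: str
    causal_density: float | None = None
    p_ab: float | None = None
    p_ba: float | None = None
    rho: float | None = None
    rho_p: float | None = None
    sonic_organization: float | None = None
    mean_slider_distance: float | None = None
    classification: str = "none"
    null_causal_density: SurrogateSummary | None = None
    null_rho: SurrogateSummary | None = None
    null_abs_rho: SurrogateSummary | None = None
    null_distance: SurrogateSummary | None = None
    degenerate: bool = False
    degenerate_reason: str | None = None


@dataclass(frozen=True)
class ComparisonResult:
    """Paired or two-sample t-test summary with Cohen's d."""

    t: float
    df: float
    p: float
    d: float | None
    mean_real: float
    mean_null: float
    degenerate: bool = False


# ---------------------------------------------------------------------------
# Stationarity and lag selection
# ---------------------------------------------------------------------------

def check_stationarity_and_detrend(
    series: Sequence[float], level: float = 0.05
) -> tuple[np.ndarray, bool]:
    """ADF-test a series and linearly detrend it if non-stationarity is not rejected.

    Returns ``(series, was_detrended)``.  Detrending removes the
    least-squares linear trend (it does not difference).  A constant
    series is degenerate: no test or trend is defined for it.
    """
    from statsmodels.tsa.stattools import adfuller

    arr = np.asarray(series, dtype=float)
    if np.ptp(arr) == 0:
        raise DegenerateSeriesError("constant series: stationarity undefined")
    p_value = adfuller(arr, autolag="AIC")[1]
    if p_value >= level:
        t = np.arange(arr.size, dtype=float)
        slope, intercept = np.polyfit(t, arr, 1)
        return arr - (slope * t + intercept), True
    return arr, False


def _lag_design(x: np.ndarray, y: np.ndarray, lag: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Design matrices for predicting y_t: (target, restricted X, unrestricted X)."""
    n = y.size
    if n <= 3 * lag:
        raise ValidationError(f"series of length {n} too short for lag {lag}")
    target = y[lag:]
    own = np.column_stack([y[lag - k : n - k] for k in range(1, lag + 1)])
    cross = np.column_stack([x[lag - k : n - k] for k in range(1, lag + 1)])
    const = np.ones((n - lag, 1))
    restricted = np.hstack([const, own])
    unrestricted = np.hstack([const, own, cross])
    return target, restricted, unrestricted


def _rss(design: np.ndarray, target: np.ndarray) -> float:
    coef, residuals, rank, _ = np.linalg.lstsq(design, target, rcond=None)
    if rank < design.shape[1]:
        raise ValidationError(
            f"collinear lag design (rank {rank} < {design.shape[1]} columns)"
        )
    resid = target - design @ coef
    return float(resid @ resid)


def _granger_f(x: np.ndarray, y: np.ndarray, lag: int) -> tuple[float, float]:
    """F statistic and p-value for 'lags of x improve prediction of y'."""
    target, restricted, unrestricted = _lag_design(x, y, lag)
    rss_r = _rss(restricted, target)
    rss_u = _rss(unrestricted, target)
    df_den = target.size - unrestricted.shape[1]
    f = ((rss_r - rss_u) / lag) / (rss_u / df_den)
    f = max(f, 0.0)
    p = float(stats.f.sf(f, lag, df_den))
    return float(f), p


def granger_pvalues(
    x: Sequence[float], y: Sequence[float], lag: int
) -> tuple[float, float]:
    """Directed Granger F-test p-values ``(p_xy, p_yx)``.

    ``p_xy`` tests whether lags of ``x`` jointly improve the prediction of
    ``y`` beyond ``y``'s own lags (restricted vs. unrestricted OLS F test);
    ``p_yx`` is the symmetric test.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValidationError(f"length mismatch: {x.size} vs {y.size}")
    for name, arr in (("x", x), ("y", y)):
        if np.ptp(arr) == 0:
            raise DegenerateSeriesError(f"{name} is constant; Granger test undefined")
    _, p_xy = _granger_f(x, y, lag)
    _, p_yx = _granger_f(y, x, lag)
    return p_xy, p_yx


def granger_fstats(
    x: Sequence[float], y: Sequence[float], lag: int
) -> tuple[float, float]:
    """Directed Granger F statistics ``(f_xy, f_yx)``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    f_xy, _ = _granger_f(x, y, lag)
    f_yx, _ = _granger_f(y, x, lag)
    return f_xy, f_yx


def causal_density(
    x: Sequence[float], y: Sequence[float], config: AnalysisConfig
) -> float:
    """Per-pair causal density: mean of the two directed significance indicators.

    With the default binarized scale the result is 0, 0.5 or 1.  With
    ``density_scale="fstat"`` it is the mean of the two F statistics.
    """
    if config.density_scale == "fstat":
        f_xy, f_yx = granger_fstats(x, y, config.max_lag)
        return (f_xy + f_yx) / 2.0
    p_xy, p_yx = granger_pvalues(x, y, config.max_lag)
    return (float(p_xy < config.alpha) + float(p_yx < config.alpha)) / 2.0


def select_max_lag(
    recording: EnsembleRecording,
    candidates: Iterable[int] | None = None,
    dimension: str = "actions",
) -> int:
    """Select the Granger model order over the whole dataset by AIC/BIC.

    Fits the unrestricted bivariate lag regression for every ordered pair
    at every candidate order, averages AIC and BIC over pairs, and returns
    the order minimizing mean AIC.  If the BIC minimizer differs, the
    discrepancy is logged and the BIC minimizer is returned (BIC's heavier
    penalty is preferred for parsimony).
    """
    cands = sorted(set(candidates if candidates is not None else range(1, 21)))
    if not cands:
        raise ValidationError("no candidate lags supplied")
    series = _dimension_series(recording, dimension)
    ids = sorted(series)
    if len(ids) < 2:
        raise ValidationError("need at least two musicians for lag selection")
    max_cand = max(cands)
    for mid, arr in series.items():
        if arr.size <= 3 * max_cand:
            raise ValidationError(
                f"series for {mid} (length {arr.size}) too short for candidate lag {max_cand}"
            )

    detrended = {mid: _safe_detrend(arr) for mid, arr in series.items()}
    mean_aic = np.zeros(len(cands))
    mean_bic = np.zeros(len(cands))
    for ci, lag in enumerate(cands):
        aics, bics = [], []
        for a, b in combinations(ids, 2):
            for x, y in ((detrended[a], detrended[b]), (detrended[b], detrended[a])):
                if x is None or y is None:
                    continue
                target, _, unrestricted = _lag_design(x, y, lag)
                rss = _rss(unrestricted, target)
                n = target.size
                k = unrestricted.shape[1]
                ll_term = n * math.log(max(rss / n, 1e-300))
                aics.append(ll_term + 2 * k)
                bics.append(ll_term + k * math.log(n))
        if not aics:
            raise ValidationError("all pairs degenerate; cannot select lag")
        mean_aic[ci] = np.mean(aics)
        mean_bic[ci] = np.mean(bics)

    aic_choice = cands[int(np.argmin(mean_aic))]
    bic_choice = cands[int(np.argmin(mean_bic))]
    if aic_choice != bic_choice:
        logger.info(
            "AIC prefers lag %d but BIC prefers lag %d; using BIC", aic_choice, bic_choice
        )
        return bic_choice
    return aic_choice


# ---------------------------------------------------------------------------
# Surrogates
# ---------------------------------------------------------------------------

def scramble(series: Sequence[float], rng: np.random.Generator) -> np.ndarray:
    """Uniformly random permutation of the time indices (values preserved)."""
    arr = np.asarray(series)
    if arr.size == 0:
        raise ValidationError("cannot scramble an empty series")
    return arr[rng.permutation(arr.size)]


def phase_randomize(series: Sequence[float], rng: np.random.Generator) -> np.ndarray:
    """Phase-randomized surrogate: preserves the power spectrum, not the values."""
    arr = np.asarray(series, dtype=float)
    spectrum = np.fft.rfft(arr)
    phases = rng.uniform(0, 2 * np.pi, spectrum.size)
    phases[0] = 0.0
    if arr.size % 2 == 0:
        phases[-1] = 0.0
    return np.fft.irfft(np.abs(spectrum) * np.exp(1j * phases), n=arr.size)


def _surrogate_fn(config: AnalysisConfig):
    return phase_randomize if config.surrogate_kind == "phase" else scramble


def null_distribution(
    x: Sequence[float],
    y: Sequence[float],
    metric: Callable[[np.ndarray, np.ndarray], float],
    config: AnalysisConfig,
    rng: np.random.Generator | None = None,
) -> SurrogateSummary:
    """Evaluate a pair metric on independently scrambled copies of both series."""
    rng = config.rng() if rng is None else rng
    surrogate = _surrogate_fn(config)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    samples = [
        metric(surrogate(x, rng), surrogate(y, rng)) for _ in range(config.n_surrogates)
    ]
    return SurrogateSummary.from_samples(samples)


# ---------------------------------------------------------------------------
# Correlation metrics
# ---------------------------------------------------------------------------

def _classify(rho: float, p: float, alpha: float) -> str:
    if p < alpha and rho > 0:
        return "positive"
    if p < alpha and rho < 0:
        return "negative"
    return "none"


def action_correlation(
    a: ActionSeries | Sequence[int],
    b: ActionSeries | Sequence[int],
    alpha: float = 0.05,
) -> tuple[float, float, str]:
    """Spearman rank correlation between two binary action series.

    Returns ``(rho, p, classification)`` where the classification is
    "positive" (co-playing), "negative" (turn-taking) or "none".
    """
    va = np.asarray(a.values if isinstance(a, ActionSeries) else a, dtype=float)
    vb = np.asarray(b.values if isinstance(b, ActionSeries) else b, dtype=float)
    if va.size != vb.size:
        raise ValidationError(f"length mismatch: {va.size} vs {vb.size}")
    if np.ptp(va) == 0 or np.ptp(vb) == 0:
        raise DegenerateSeriesError("constant series: correlation undefined")
    rho, p = stats.spearmanr(va, vb)
    return float(rho), float(p), _classify(float(rho), float(p), alpha)


def sonic_organization(
    a: ActionSeries | Sequence[int], b: ActionSeries | Sequence[int]
) -> float:
    """``|Spearman rho|`` between two action series: association regardless of sign."""
    rho, _, _ = action_correlation(a, b)
    return abs(rho)


def intention_correlation(
    x: IntentionSeries | Sequence[float],
    y: IntentionSeries | Sequence[float],
    alpha: float = 0.05,
) -> tuple[float, float, str]:
    """Pearson correlation between two intention series, with classification."""
    vx = np.asarray(x.values if isinstance(x, IntentionSeries) else x, dtype=float)
    vy = np.asarray(y.values if isinstance(y, IntentionSeries) else y, dtype=float)
    if vx.size != vy.size:
        raise ValidationError(f"length mismatch: {vx.size} vs {vy.size}")
    if np.ptp(vx) == 0 or np.ptp(vy) == 0:
        raise DegenerateSeriesError("constant series: correlation undefined")
    rho, p = stats.pearsonr(vx, vy)
    return float(rho), float(p), _classify(float(rho), float(p), alpha)


def mean_slider_distance(
    x: IntentionSeries | Sequence[float], y: IntentionSeries | Sequence[float]
) -> float:
    """Time-averaged absolute distance between two intention series."""
    vx = np.asarray(x.values if isinstance(x, IntentionSeries) else x, dtype=float)
    vy = np.asarray(y.values if isinstance(y, IntentionSeries) else y, dtype=float)
    if vx.size != vy.size:
        raise ValidationError(f"length mismatch: {vx.size} vs {vy.size}")
    return float(np.mean(np.abs(vx - vy)))


def block_permutation_pvalue(
    x: Sequence[float],
    y: Sequence[float],
    statistic: Callable[[np.ndarray, np.ndarray], float],
    block_s: int = 30,
    n_permutations: int = 999,
    rng: np.random.Generator | None = None,
) -> float:
    """Two-sided block-permutation p-value for a pairwise statistic.

    Circularly shifts ``y`` by random multiples of ``block_s`` seconds,
    preserving autocorrelation within blocks; an autocorrelation-honest
    alternative to the parametric correlation p-values.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    observed = abs(statistic(x, y))
    n_blocks = max(x.size // block_s, 1)
    count = 0
    for _ in range(n_permutations):
        shift = int(rng.integers(1, n_blocks + 1)) * block_s
        if abs(statistic(x, np.roll(y, shift))) >= observed:
            count += 1
    return (count + 1) / (n_permutations + 1)


# ---------------------------------------------------------------------------
# Real-vs-null comparison
# ---------------------------------------------------------------------------

def compare_to_null(
    real_values: Sequence[float], null_values: Sequence[float]
) -> ComparisonResult:
    """Paired t-test of per-pair real metrics against per-pair null summaries.

    Cohen's d is mean(difference) / sd(difference) with df = n - 1.  When
    the differences have zero variance the result is flagged degenerate.
    """
    real = np.asarray(real_values, dtype=float)
    null = np.asarray(null_values, dtype=float)
    if real.size != null.size:
        raise ValidationError(f"length mismatch: {real.size} vs {null.size}")
    if real.size < 2:
        raise ValidationError("need at least two pairs for a paired t-test")
    diff = real - null
    sd = diff.std(ddof=1)
    if sd == 0:
        return ComparisonResult(
            t=0.0 if diff.mean() == 0 else math.inf,
            df=real.size - 1, p=1.0 if diff.mean() == 0 else 0.0,
            d=None, mean_real=float(real.mean()), mean_null=float(null.mean()),
            degenerate=True,
        )
    t_stat, p = stats.ttest_rel(real, null)
    return ComparisonResult(
        t=float(t_stat), df=real.size - 1, p=float(p),
        d=float(diff.mean() / sd),
        mean_real=float(real.mean()), mean_null=float(null.mean()),
    )


# ---------------------------------------------------------------------------
# Whole-ensemble driver
# ---------------------------------------------------------------------------

def _dimension_series(recording: EnsembleRecording, dimension: str) -> dict[str, np.ndarray]:
    if dimension == "actions":
        ids = [m for m in recording.action_ids if m not in recording.silent_ids]
        rows = {m: recording.actions[recording.action_ids.index(m)].astype(float) for m in ids}
    elif dimension == "intentions":
        rows = {
            m: recording.intentions[recording.intention_ids.index(m)]
            for m in recording.intention_ids
        }
    else:
        raise ValidationError(f"unknown dimension {dimension!r}")
    return rows


def _safe_detrend(arr: np.ndarray) -> np.ndarray | None:
    try:
        out, _ = check_stationarity_and_detrend(arr)
        return out
    except DegenerateSeriesError:
        return None


def all_pairs(
    recording: EnsembleRecording,
    dimension: str,
    config: AnalysisConfig,
    compute_nulls: bool = True,
) -> list[PairCoordination]:
    """Compute :class:`PairCoordination` for every unordered pair on one dimension.

    Silent musicians are excluded from the action dimension.  Constant
    series yield degenerate-flagged entries (kept in the output, excluded
    from group comparisons), so the count is always ``n*(n-1)/2`` over the
    retained musicians.
    """
    series = _dimension_series(recording, dimension)
    ids = sorted(series)
    if len(ids) < 2:
        raise ValidationError(f"need >= 2 musicians on dimension {dimension!r}")
    rng = config.rng()
    surrogate = _surrogate_fn(config)

    detrended = {mid: _safe_detrend(series[mid]) for mid in ids}

    def _pair_density(xs: np.ndarray, ys: np.ndarray) -> float:
        p_xy, p_yx = granger_pvalues(xs, ys, config.max_lag)
        return (float(p_xy < config.alpha) + float(p_yx < config.alpha)) / 2.0

    results: list[PairCoordination] = []
    for id_a, id_b in combinations(ids, 2):
        raw_a, raw_b = series[id_a], series[id_b]
        pair = PairCoordination(id_a=id_a, id_b=id_b)
        if np.ptp(raw_a) == 0 or np.ptp(raw_b) == 0:
            pair.degenerate = True
            pair.degenerate_reason = "constant series"
            results.append(pair)
            continue

        det_a, det_b = detrended[id_a], detrended[id_b]
        p_ab, p_ba = granger_pvalues(det_a, det_b, config.max_lag)
        pair.p_ab, pair.p_ba = p_ab, p_ba
        if config.density_scale == "fstat":
            f_ab, f_ba = granger_fstats(det_a, det_b, config.max_lag)
            pair.causal_density = (f_ab + f_ba) / 2.0
        else:
            pair.causal_density = (
                float(p_ab < config.alpha) + float(p_ba < config.alpha)
            ) / 2.0

        if dimension == "actions":
            rho, rho_p, cls = action_correlation(raw_a, raw_b, config.alpha)
            pair.rho, pair.rho_p, pair.classification = rho, rho_p, cls
            pair.sonic_organization = abs(rho)
        else:
            rho, rho_p, cls = intention_correlation(raw_a, raw_b, config.alpha)
            pair.rho, pair.rho_p, pair.classification = rho, rho_p, cls
            pair.mean_slider_distance = mean_slider_distance(raw_a, raw_b)

        if compute_nulls:
            dens, rhos, abs_rhos, dists = [], [], [], []
            for _ in range(config.n_surrogates):
                sa = surrogate(det_a, rng)
                sb = surrogate(det_b, rng)
                dens.append(_pair_density(sa, sb))
                ra = surrogate(raw_a, rng)
                rb = surrogate(raw_b, rng)
                if dimension == "actions":
                    s_rho = stats.spearmanr(ra, rb)[0]
                    rhos.append(float(s_rho))
                    abs_rhos.append(abs(float(s_rho)))
                else:
                    s_rho = stats.pearsonr(ra, rb)[0]
                    rhos.append(float(s_rho))
                    dists.append(mean_slider_distance(ra, rb))
            pair.null_causal_density = SurrogateSummary.from_samples(dens)
            pair.null_rho = SurrogateSummary.from_samples(rhos)
            if dimension == "actions":
                pair.null_abs_rho = SurrogateSummary.from_samples(abs_rhos)
            else:
                pair.null_distance = SurrogateSummary.from_samples(dists)

        results.append(pair)
    return results
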