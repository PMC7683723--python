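"""Relational and individual predictors of coordination, and their regressions.

Relational (pair-level) factors:

* familiarity — mean of the two directed 0/1/2 ratings;
* spatial proximity — number of musicians seated between the pair
  (``|seat_a - seat_b| - 1`` along the seating order);
* instrumental proximity — 1 if the two musicians share an instrument
  family, else 0.

Individual (musician-level) factors:

* expertise — mean of years in the ensemble and years practicing
  collective free improvisation;
* familiarity with others — mean of that musician's pair familiarities;
* spatial eccentricity — mean over partners of the musicians-between
  count (higher = more peripheral seat);
* instrument family — winds / strings / inharmonic, entered as three
  pairwise contrasts (w/i, w/s, s/i).

Pair-level outcomes are regressed on the relational factors in a linear
mixed model with crossed random intercepts for the two member musicians
(the standard remedy for dyadic non-independence).  Musician-level
outcomes (one row per musician) use ordinary least squares with
heteroskedasticity-robust standard errors.  Each term additionally gets a
likelihood-ratio chi-square from comparing the full model against the
model without that term (ML fits).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import EnsembleRecording, MusicianProfile, ValidationError
from .pairwise_coordination import PairCoordination

logger = logging.getLogger(__name__)

__all__ = [
    "RelationalFactors",
    "IndividualFactors",
    "RegressionResult",
    "pair_familiarity",
    "spatial_metrics",
    "expertise",
    "build_factor_table",
    "fit_mixed_regression",
    "fit_individual_regression",
]

FAMILY_CONTRASTS = (
    ("w/i", "winds", "inharmonic"),
    ("w/s", "winds", "strings"),
    ("s/i", "strings", "inharmonic"),
)


@dataclass(frozen=True)
class RelationalFactors:
    id_a: str
    id_b: str
    familiarity: float            # mean of the two directed ratings, [0, 2]
    spatial_proximity: int        # musicians seated between the pair
    instrumental_proximity: int   # 1 = same family


@dataclass(frozen=True)
class IndividualFactors:
    musician_id: str
    expertise: float
    familiarity_with_others: float
    spatial_eccentricity: float
    instrument_family: str


@dataclass(frozen=True)
class RegressionResult:
    term: str
    beta: float
    se: float
    t: float
    df: float
    p: float
    model_comparison_chisq: float | None = None
    singular: bool = False


def pair_familiarity(r_ab: int, r_ba: int) -> float:
    """Mean of the two directed familiarity ratings."""
    for r in (r_ab, r_ba):
        if r not in (0, 1, 2):
            raise ValidationError(f"familiarity rating {r!r} not in {{0,1,2}}")
    return (r_ab + r_ba) / 2.0


def spatial_metrics(
    profiles: Sequence[MusicianProfile],
    circular: bool = False,
) -> tuple[dict[frozenset, int], dict[str, float]]:
    """Per-pair seat proximity and per-musician eccentricity.

    Proximity is the number of musicians seated between the pair:
    ``|seat_a - seat_b| - 1`` along the (linear) seating order, or the
    shorter way around when ``circular``.  Eccentricity is a musician's
    mean proximity over all partners.
    """
    seats = {p.musician_id: p.seat_index for p in profiles}
    if len(set(seats.values())) != len(seats):
        raise ValidationError("duplicate seat indices")
    n = len(profiles)
    proximity: dict[frozenset, int] = {}
    for a, b in combinations(sorted(seats), 2):
        gap = abs(seats[a] - seats[b])
        if circular:
            gap = min(gap, n - gap)
        proximity[frozenset((a, b))] = gap - 1
    eccentricity = {
        m: float(np.mean([proximity[frozenset((m, o))] for o in seats if o != m]))
        for m in seats
    }
    return proximity, eccentricity


def expertise(profile: MusicianProfile) -> float:
    """Mean of years in the ensemble and years practicing CFI."""
    return (profile.years_in_ensemble + profile.years_cfi) / 2.0


def build_factor_table(
    recording: EnsembleRecording,
    pair_results: Sequence[PairCoordination],
    circular_seating: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Join coordination outcomes to relational and individual predictors.

    Returns ``(pair_table, individual_table)``.  The pair table has one
    row per non-degenerate pair with the coordination metrics and the
    three relational factors; the individual table has one row per
    musician appearing in the pair results, with each coordination metric
    averaged over that musician's partners and the four individual
    factors.
    """
    prof = recording.profile_map
    proximity, eccentricity = spatial_metrics(recording.profiles, circular=circular_seating)

    metric_cols = ("causal_density", "rho", "sonic_organization", "mean_slider_distance")
    rows = []
    for pair in pair_results:
        if pair.degenerate:
            logger.info("pair (%s, %s) degenerate (%s); excluded from factor table",
                        pair.id_a, pair.id_b, pair.degenerate_reason)
            continue
        for mid in (pair.id_a, pair.id_b):
            if mid not in prof:
                raise ValidationError(f"no profile for musician {mid!r}")
        pa, pb = prof[pair.id_a], prof[pair.id_b]
        if pair.id_b not in pa.familiarity_ratings or pair.id_a not in pb.familiarity_ratings:
            raise ValidationError(
                f"missing directed familiarity rating within pair ({pair.id_a}, {pair.id_b})"
            )
        rows.append(
            {
                "id_a": pair.id_a,
                "id_b": pair.id_b,
                "familiarity": pair_familiarity(
                    pa.familiarity_ratings[pair.id_b], pb.familiarity_ratings[pair.id_a]
                ),
                "spatial_proximity": proximity[frozenset((pair.id_a, pair.id_b))],
                "instrumental_proximity": int(pa.instrument_family == pb.instrument_family),
                **{c: getattr(pair, c) for c in metric_cols},
            }
        )
    pair_table = pd.DataFrame(rows)

    musicians = sorted(set(pair_table["id_a"]) | set(pair_table["id_b"])) if len(pair_table) else []
    ind_rows = []
    for mid in musicians:
        mask = (pair_table["id_a"] == mid) | (pair_table["id_b"] == mid)
        sub = pair_table[mask]
        p = prof[mid]
        row = {
            "musician_id": mid,
            "expertise": expertise(p),
            "familiarity_with_others": float(sub["familiarity"].mean()),
            "spatial_eccentricity": eccentricity[mid],
            "instrument_family": p.instrument_family,
        }
        for c in metric_cols:
            vals = sub[c].dropna()
            row[c] = float(vals.mean()) if len(vals) else np.nan
        ind_rows.append(row)
    individual_table = pd.DataFrame(ind_rows)
    return pair_table, individual_table


# ---------------------------------------------------------------------------
# Model fitting
# ---------------------------------------------------------------------------

def _lrt_chisq(full_ll: float, reduced_ll: float) -> float:
    return max(2.0 * (full_ll - reduced_ll), 0.0)


def fit_mixed_regression(
    table: pd.DataFrame,
    response: str,
    fixed_terms: Sequence[str],
    grouping: str = "crossed",
) -> list[RegressionResult]:
    """Pair-level mixed regression with crossed random intercepts.

    Fits ``response ~ fixed_terms`` with random intercepts for musician A
    and musician B (``grouping="crossed"``), via variance components over
    a single super-group.  ``grouping="none"`` drops the random effects
    and falls back to OLS.  t statistics use a normal df approximation
    (the fitting machinery provides no Satterthwaite df; the downgrade is
    logged).  Each term's likelihood-ratio chi-square comes from ML fits
    of the full model vs. the model without that term.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    data = table.dropna(subset=[response, *fixed_terms]).copy()
    if len(data) < len(fixed_terms) + 2:
        raise ValidationError(f"too few rows ({len(data)}) to fit {response}")
    for term in fixed_terms:
        if np.ptp(data[term].to_numpy(dtype=float)) == 0:
            raise ValidationError(f"predictor {term!r} has zero variance")

    formula = f"{response} ~ " + " + ".join(fixed_terms)

    if grouping == "none":
        return fit_individual_regression(data, response, fixed_terms)
    if grouping != "crossed":
        raise ValidationError(f"unknown grouping {grouping!r}")

    data["_one"] = 1
    vc = {"musician_a": "0 + C(id_a)", "musician_b": "0 + C(id_b)"}

    def _fit(form: str, reml: bool):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(form, data, groups=data["_one"], vc_formula=vc, re_formula="0")
            return model.fit(reml=reml, method="lbfgs", maxiter=200)

    fit = _fit(formula, reml=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fe_params = fit.fe_params
        bse_fe = fit.bse_fe
    singular = bool(getattr(fit, "converged", True) is False) or bool(
        np.isnan([bse_fe[t] for t in fixed_terms]).any()
    )
    logger.info("mixed-model t tests use a normal df approximation (no Satterthwaite)")

    full_ml = _fit(formula, reml=False)
    lrt: dict[str, float] = {}
    for term in fixed_terms:
        reduced_terms = [t for t in fixed_terms if t != term] or ["1"]
        reduced = _fit(f"{response} ~ " + " + ".join(reduced_terms), reml=False)
        lrt[term] = _lrt_chisq(full_ml.llf, reduced.llf)

    results = []
    for term in fixed_terms:
        beta = float(fe_params[term])
        se = float(bse_fe[term])
        z = beta / se if se > 0 else np.nan
        p = float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else np.nan
        results.append(
            RegressionResult(
                term=term, beta=beta, se=se, t=float(z), df=np.inf, p=p,
                model_comparison_chisq=lrt[term], singular=singular,
            )
        )
    return results


def fit_individual_regression(
    table: pd.DataFrame,
    response: str,
    fixed_terms: Sequence[str],
    family_column: str | None = None,
) -> list[RegressionResult]:
    """Musician-level OLS with heteroskedasticity-robust (HC3) errors.

    When ``family_column`` names the instrument-family column, three
    pairwise family contrasts (w/i, w/s, s/i) are reported in addition to
    the continuous terms, computed as linear combinations of the fitted
    family coefficients.
    """
    import statsmodels.formula.api as smf

    terms = list(fixed_terms)
    if family_column:
        terms.append(f"C({family_column})")
    data = table.dropna(subset=[response, *fixed_terms]).copy()
    if len(data) < len(terms) + 2:
        raise ValidationError(f"too few rows ({len(data)}) to fit {response}")

    formula = f"{response} ~ " + " + ".join(terms)
    fit = smf.ols(formula, data).fit(cov_type="HC3")
    full_ml = smf.ols(formula, data).fit()
    df_resid = float(fit.df_resid)

    results = []
    for term in fixed_terms:
        reduced_terms = [t for t in terms if t != term] or ["1"]
        reduced = smf.ols(f"{response} ~ " + " + ".join(reduced_terms), data).fit()
        chisq = _lrt_chisq(full_ml.llf, reduced.llf)
        beta = float(fit.params[term])
        se = float(fit.bse[term])
        t = beta / se if se > 0 else np.inf
        results.append(
            RegressionResult(
                term=term, beta=beta, se=se, t=float(t), df=df_resid,
                p=float(2 * stats.t.sf(abs(t), df_resid)),
                model_comparison_chisq=chisq,
            )
        )

    if family_column:
        reduced = smf.ols(
            f"{response} ~ " + " + ".join(fixed_terms or ["1"]), data
        ).fit()
        family_chisq = _lrt_chisq(full_ml.llf, reduced.llf)
        levels = sorted(data[family_column].unique())
        baseline = levels[0]

        def _coef_name(level: str) -> str | None:
            return None if level == baseline else f"C({family_column})[T.{level}]"

        cov = fit.cov_params()
        for label, fam1, fam2 in FAMILY_CONTRASTS:
            n1, n2 = _coef_name(fam1), _coef_name(fam2)
            vec = pd.Series(0.0, index=fit.params.index)
            if n1 is not None:
                vec[n1] = 1.0
            if n2 is not None:
                vec[n2] = -1.0
            beta = float(vec @ fit.params)
            se = float(np.sqrt(vec @ cov @ vec))
            t = beta / se if se > 0 else 0.0
            results.append(
                RegressionResult(
                    term=label, beta=beta, se=se, t=float(t), df=df_resid,
                    p=float(2 * stats.t.sf(abs(t), df_resid)),
                    model_comparison_chisq=family_chisq,
                )
            )
    return results
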