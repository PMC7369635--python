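"""The regional trait–MT map (SRM): trait transform, age models, correlations.

The map is built in three steps: (1) the two questionnaire assessments are
averaged and square-root transformed to tame the positive skew of
endorsement rates; (2) each region's MT is regressed on age centered at 14
years, yielding the baseline MT at 14 (MT14), the annual rate of change
(dMT), and age-corrected residuals; (3) the residuals are correlated with
the transformed trait, using Pearson's r unless a Lilliefors-style
Kolmogorov–Smirnov test rejects normality for either variable (then
Spearman), with Benjamini–Hochberg FDR across the regional family.

Sensitivity variants: partial correlations controlling for additional
covariates, a forced-Spearman robust mode, and Euler-number image-quality
exclusion.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors
from statsmodels.stats.multitest import multipletests

from srmtx.exceptions import (
    DegenerateInputError,
    EstimationError,
    InvalidConfigError,
)

log = logging.getLogger(__name__)

AGE_CENTER = 14.0  # years; intercepts are "MT at age 14"
MIN_PAIRS = 8  # minimum complete pairs for a regional correlation


# ---------------------------------------------------------------------------
# trait


def combine_and_transform_trait(trait: pd.DataFrame) -> pd.DataFrame:
    """Average available timepoints and apply the square-root transform.

    Expects columns ``subject_id``, ``score_t1``, ``score_t2`` (either may be
    missing per subject).  Subjects missing both assessments are dropped with
    a log entry.
    """
    scores = trait[["score_t1", "score_t2"]]
    if (scores < 0).any().any():
        raise DegenerateInputError("trait scores must be non-negative")
    if (scores > 1).any().any():
        raise DegenerateInputError("trait scores must lie in [0, 1]")
    combined = scores.mean(axis=1, skipna=True)
    missing_both = combined.isna()
    if missing_both.any():
        dropped = trait.loc[missing_both, "subject_id"].tolist()
        log.warning("dropping %d subjects with no trait assessment: %s",
                    len(dropped), dropped[:10])
    out = pd.DataFrame(
        {
            "subject_id": trait["subject_id"],
            "combined_score": combined,
            "transformed_score": np.sqrt(combined),
        }
    )
    return out.loc[~missing_both].reset_index(drop=True)


# ---------------------------------------------------------------------------
# age model


@dataclass
class AgeModelFit:
    """Per-region linear age model: MT ~ MT14 + dMT·(age − 14)."""

    mt14: pd.Series  # intercept at age 14, per region
    dmt: pd.Series  # slope per year, per region
    residuals: pd.DataFrame  # subjects × regions


def fit_regional_age_model(mt: pd.DataFrame, ages: pd.Series | np.ndarray) -> AgeModelFit:
    """Ordinary least squares of each region's MT on (age − 14)."""
    ages = np.asarray(ages, dtype=float)
    if len(ages) != len(mt):
        raise EstimationError("ages and MT matrix have different lengths")
    if len(ages) < 3:
        raise EstimationError("need at least 3 subjects for the age model")
    if np.var(ages) == 0:
        raise EstimationError("zero age variance: slope is unidentifiable")
    design = np.column_stack([np.ones_like(ages), ages - AGE_CENTER])
    values = mt.to_numpy(dtype=float)
    coef, *_ = np.linalg.lstsq(design, values, rcond=None)
    resid = values - design @ coef
    return AgeModelFit(
        mt14=pd.Series(coef[0], index=mt.columns, name="mt14"),
        dmt=pd.Series(coef[1], index=mt.columns, name="dmt"),
        residuals=pd.DataFrame(resid, index=mt.index, columns=mt.columns),
    )


# ---------------------------------------------------------------------------
# correlation estimator gate


def select_estimator(x, y, alpha: float = 0.05) -> str:
    """Choose ``pearson`` or ``spearman`` via a normality gate.

    Runs a Lilliefors-style one-sample KS test (normal with estimated mean
    and s.d.) on each input; Spearman is selected iff normality is rejected
    for either at ``alpha``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < MIN_PAIRS or len(y) < MIN_PAIRS:
        raise DegenerateInputError(f"need at least {MIN_PAIRS} observations")
    for name, v in (("x", x), ("y", y)):
        if np.ptp(v) == 0:
            raise DegenerateInputError(f"input {name} is constant")
    for v in (x, y):
        _, p = lilliefors(v, dist="norm", pvalmethod="table")
        if p < alpha:
            return "spearman"
    return "pearson"


def correlate(x, y, method: str) -> tuple[float, float]:
    """Two-tailed correlation by the named estimator."""
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown estimator {method!r}")
    return float(r), float(p)


# ---------------------------------------------------------------------------
# SRM map


def _srm_from_residuals(
    residuals: pd.DataFrame,
    trait_values: np.ndarray,
    alpha: float = 0.05,
    force_spearman: bool = False,
) -> pd.DataFrame:
    if np.ptp(trait_values) == 0:
        raise DegenerateInputError("trait is constant")
    rows = []
    for region in residuals.columns:
        v = residuals[region].to_numpy(dtype=float)
        ok = np.isfinite(v) & np.isfinite(trait_values)
        if ok.sum() < MIN_PAIRS:
            log.warning("region %s has <%d complete pairs; excluded from FDR",
                        region, MIN_PAIRS)
            rows.append((region, "none", np.nan, np.nan))
            continue
        xv, yv = v[ok], trait_values[ok]
        if np.ptp(xv) == 0:
            rows.append((region, "none", np.nan, np.nan))
            continue
        method = "spearman" if force_spearman else select_estimator(xv, yv, alpha)
        r, p = correlate(xv, yv, method)
        rows.append((region, method, r, p))
    out = pd.DataFrame(rows, columns=["region", "estimator", "r", "p"])
    tested = out["p"].notna()
    q = np.full(len(out), np.nan)
    if tested.any():
        q[tested.to_numpy()] = multipletests(
            out.loc[tested, "p"], alpha=alpha, method="fdr_bh"
        )[1]
    out["q"] = q
    out["sig_nominal"] = out["p"] < alpha
    out["sig_fdr"] = out["q"] < alpha
    return out


def compute_srm(
    age_fit: AgeModelFit,
    trait: pd.DataFrame,
    alpha: float = 0.05,
    force_spearman: bool = False,
) -> pd.DataFrame:
    """Regional correlation map of age-corrected MT residuals vs. the trait.

    ``trait`` is the output of :func:`combine_and_transform_trait`; subjects
    are aligned on ``subject_id`` against the residual matrix index.
    """
    trait = trait.set_index("subject_id")["transformed_score"]
    residuals = age_fit.residuals
    common = residuals.index.intersection(trait.index)
    if len(common) < MIN_PAIRS:
        raise DegenerateInputError("fewer than 8 subjects shared by MT and trait")
    residuals = residuals.loc[common]
    return _srm_from_residuals(
        residuals, trait.loc[common].to_numpy(dtype=float), alpha, force_spearman
    )


def global_association(
    mt: pd.DataFrame,
    trait: pd.DataFrame,
    ages: pd.Series | np.ndarray,
    force_spearman: bool = False,
) -> tuple[float, float]:
    """Trait correlation with global MT (region-averaged, age-adjusted).

    Returns (R², two-tailed p).
    """
    global_mt = mt.mean(axis=1).to_frame("global")
    fit = fit_regional_age_model(global_mt, ages)
    srm = _srm_from_residuals(
        fit.residuals,
        trait.set_index("subject_id")
        .loc[mt.index, "transformed_score"]
        .to_numpy(dtype=float),
        force_spearman=force_spearman,
    )
    r, p = srm.loc[0, "r"], srm.loc[0, "p"]
    return float(r**2), float(p)


# ---------------------------------------------------------------------------
# covariate sensitivity


def _design_matrix(subjects: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    cols = []
    for cov in covariates:
        if cov not in subjects.columns:
            raise InvalidConfigError(f"unknown covariate {cov!r}")
        col = subjects[cov]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, prefix=cov, drop_first=True, dtype=float)
            cols.append(dummies)
        else:
            series = col.astype(float)
            if cov == "age":
                series = series - AGE_CENTER
            cols.append(series.to_frame(cov))
    design = pd.concat(cols, axis=1)
    design.insert(0, "intercept", 1.0)
    return design


def _check_collinearity(design: pd.DataFrame) -> None:
    x = design.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(x)
    if rank == x.shape[1]:
        return
    offenders = []
    for j, name in enumerate(design.columns):
        others = np.delete(x, j, axis=1)
        if np.linalg.matrix_rank(others) == rank:
            offenders.append(name)
    raise EstimationError(
        f"collinear covariate columns: {offenders or list(design.columns)}"
    )


def covariate_adjusted_srm(
    mt: pd.DataFrame,
    trait: pd.DataFrame,
    subjects: pd.DataFrame,
    covariates: list[str],
    alpha: float = 0.05,
    force_spearman: bool = False,
) -> pd.DataFrame:
    """Partial-correlation SRM map controlling for the named covariates.

    Both the regional MT values and the transformed trait are residualized
    on the covariate design (categoricals dummy-coded) before correlation;
    the FDR family is the same regional family as :func:`compute_srm`.
    """
    subjects = subjects.set_index("subject_id")
    trait_s = trait.set_index("subject_id")["transformed_score"]
    common = mt.index.intersection(trait_s.index).intersection(subjects.index)
    subjects = subjects.loc[common]
    complete = subjects[covariates].notna().all(axis=1)
    if not complete.all():
        dropped = subjects.index[~complete].tolist()
        log.warning("dropping %d subjects with incomplete covariates: %s",
                    len(dropped), dropped[:10])
    keep = subjects.index[complete]
    design = _design_matrix(subjects.loc[keep].reset_index(), covariates)
    _check_collinearity(design)
    x = design.to_numpy(dtype=float)
    hat = x @ np.linalg.pinv(x)
    mt_resid = mt.loc[keep].to_numpy(dtype=float)
    mt_resid = mt_resid - hat @ mt_resid
    tr = trait_s.loc[keep].to_numpy(dtype=float)
    tr_resid = tr - hat @ tr
    residuals = pd.DataFrame(mt_resid, index=keep, columns=mt.columns)
    if np.ptp(tr_resid) == 0:
        raise DegenerateInputError("trait is constant after covariate adjustment")
    return _srm_from_residuals(residuals, tr_resid, alpha, force_spearman)


# ---------------------------------------------------------------------------
# image-quality QC


@dataclass
class EulerQCResult:
    rho_before: float
    p_before: float
    rho_after: float
    p_after: float
    excluded: pd.Series  # boolean mask indexed by subject_id


def euler_qc(
    subjects: pd.DataFrame, mt: pd.DataFrame, exclusion_fraction: float = 0.10
) -> EulerQCResult:
    """Euler-number image-quality check.

    Reports the Spearman correlation between Euler number and global MT,
    flags the worst ``floor(fraction·n)`` subjects (most negative Euler
    first, ties broken by subject id), and reports the correlation again
    after their exclusion.
    """
    if not (0.0 < exclusion_fraction < 1.0):
        raise InvalidConfigError("exclusion_fraction must lie in (0, 1)")
    subjects = subjects.set_index("subject_id").loc[mt.index]
    euler = subjects["euler_number"].astype(float)
    if euler.isna().any():
        raise DegenerateInputError("Euler numbers missing for some subjects")
    global_mt = mt.mean(axis=1)
    rho_before, p_before = stats.spearmanr(euler, global_mt)
    n_excl = math.floor(exclusion_fraction * len(subjects))
    order = sorted(zip(euler, euler.index))  # most negative first, id tiebreak
    flagged = {sid for _, sid in order[:n_excl]}
    mask = pd.Series(
        [sid in flagged for sid in mt.index], index=mt.index, name="excluded"
    )
    kept = ~mask
    rho_after, p_after = stats.spearmanr(euler[kept], global_mt[kept])
    return EulerQCResult(
        rho_before=float(rho_before),
        p_before=float(p_before),
        rho_after=float(rho_after),
        p_after=float(p_after),
        excluded=mask,
    )
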