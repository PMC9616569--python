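"""Case-control association of CNVR genotypes with gout.

Three covariate models mirror a staged adjustment design: unadjusted;
Model 1 adds age and sex; Model 2 adds genotyping batch and the first ten
genetic principal components.  The exposure is carrier status (CN != 2)
versus diploid by default, with a dose coding (copies deviating from two)
available.  Fits are maximum-likelihood logistic regressions with Wald
inference; complete separation is reported explicitly, never silently.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

logger = logging.getLogger(__name__)

Z95 = 1.96

MODEL_COVARIATES: Mapping[str, tuple[str, ...]] = {
    "unadjusted": (),
    "model1": ("age", "sex"),
    "model2": ("age", "sex", "batch") + tuple(f"pc{i}" for i in range(1, 11)),
}


@dataclass
class AssocResult:
    """One association fit: odds ratio (or linear effect), Wald 95% CI and p."""

    label: str
    model: str
    estimate: float  # OR for logistic, slope for linear
    ci_low: float
    ci_high: float
    p_value: float
    n_case_carrier: int = 0
    n_case_ref: int = 0
    n_control_carrier: int = 0
    n_control_ref: int = 0
    n_used: int = 0
    separation: bool = False
    log_scale_se: float = float("nan")

    @property
    def log_or(self) -> float:
        return float(np.log(self.estimate))

    def summary(self) -> str:
        flag = " [separation]" if self.separation else ""
        return (
            f"{self.label} ({self.model}): OR={self.estimate:.3g} "
            f"[{self.ci_low:.3g}; {self.ci_high:.3g}], P={self.p_value:.3g}, "
            f"n={self.n_used}{flag}"
        )


def code_burden_carrier(matrix: pd.DataFrame, region_ids: Sequence[str]) -> pd.Series:
    """1 if CN != 2 at any region in the set, 0 if diploid at every region
    in the set; calls outside the set are ignored."""
    missing = [r for r in region_ids if r not in matrix.columns]
    if missing:
        raise KeyError(f"regions not in genotype matrix: {missing}")
    carrier = (matrix[list(region_ids)] != 2).any(axis=1).astype(int)
    carrier.name = "carrier"
    return carrier


def code_dose(matrix: pd.DataFrame, region_ids: Sequence[str]) -> pd.Series:
    """Dose coding: total copies deviating from two across the region set."""
    missing = [r for r in region_ids if r not in matrix.columns]
    if missing:
        raise KeyError(f"regions not in genotype matrix: {missing}")
    dose = (matrix[list(region_ids)] - 2).abs().sum(axis=1)
    dose.name = "dose"
    return dose


def _design(df: pd.DataFrame, exposure: str, covariates: Sequence[str]) -> tuple[pd.DataFrame, pd.DataFrame]:
    use = df.dropna(subset=[exposure, "gout", *covariates])
    dropped = len(df) - len(use)
    if dropped:
        logger.info("dropping %d individuals with missing model covariates", dropped)
    X = pd.DataFrame({"exposure": use[exposure].astype(float)}, index=use.index)
    for cov in covariates:
        if cov == "batch" or use[cov].dtype == object:
            dummies = pd.get_dummies(use[cov], prefix=cov, drop_first=True, dtype=float)
            X = pd.concat([X, dummies], axis=1)
        else:
            X[cov] = use[cov].astype(float)
    X = sm.add_constant(X, has_constant="add")
    return use, X


def logistic_assoc(
    df: pd.DataFrame,
    exposure: str,
    model: str = "model2",
    label: str = "",
) -> AssocResult:
    """Logistic regression of gout on an exposure under a covariate model.

    ``df`` needs columns ``gout``, the exposure, and the model covariates.
    """
    covariates = MODEL_COVARIATES[model]
    use, X = _design(df, exposure, covariates)
    y = use["gout"].astype(float)
    if y.nunique() < 2:
        raise ValueError("need both cases and controls")
    if use[exposure].nunique() < 2:
        raise ValueError(f"exposure {exposure!r} is constant")

    separation = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PerfectSeparationWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
            beta = float(fit.params["exposure"])
            se = float(fit.bse["exposure"])
            converged = bool(fit.mle_retvals.get("converged", True))
        except (PerfectSeparationError, np.linalg.LinAlgError):
            beta, se, converged = 0.0, float("inf"), False
    if not converged or not np.isfinite(se) or se > 50:
        separation = True
        logger.warning("separation or non-convergence for %s (%s)", label or exposure, model)

    carrier = use[exposure] != 0
    case = use["gout"] == 1
    if separation:
        or_, lo, hi, p = float("nan"), 0.0, float("inf"), float("nan")
    else:
        or_ = float(np.exp(beta))
        lo = float(np.exp(beta - Z95 * se))
        hi = float(np.exp(beta + Z95 * se))
        p = float(2 * stats.norm.sf(abs(beta / se)))
    return AssocResult(
        label=label or exposure,
        model=model,
        estimate=or_,
        ci_low=lo,
        ci_high=hi,
        p_value=p,
        n_case_carrier=int((carrier & case).sum()),
        n_case_ref=int((~carrier & case).sum()),
        n_control_carrier=int((carrier & ~case).sum()),
        n_control_ref=int((~carrier & ~case).sum()),
        n_used=len(use),
        separation=separation,
        log_scale_se=se,
    )


def linear_urate_assoc(
    df: pd.DataFrame,
    exposure: str,
    model: str = "model2",
    label: str = "",
) -> AssocResult:
    """OLS of serum urate on the exposure in the control stratum only."""
    controls = df[df["gout"] == 0]
    covariates = MODEL_COVARIATES[model]
    use = controls.dropna(subset=["urate", exposure, *covariates])
    if use[exposure].nunique() < 2:
        raise ValueError(f"exposure {exposure!r} is constant in controls")
    X = pd.DataFrame({"exposure": use[exposure].astype(float)}, index=use.index)
    for cov in covariates:
        if cov == "batch" or use[cov].dtype == object:
            X = pd.concat(
                [X, pd.get_dummies(use[cov], prefix=cov, drop_first=True, dtype=float)], axis=1
            )
        else:
            X[cov] = use[cov].astype(float)
    X = sm.add_constant(X, has_constant="add")
    fit = sm.OLS(use["urate"].astype(float), X).fit()
    beta = float(fit.params["exposure"])
    se = float(fit.bse["exposure"])
    return AssocResult(
        label=label or exposure,
        model=model,
        estimate=beta,
        ci_low=beta - Z95 * se,
        ci_high=beta + Z95 * se,
        p_value=float(fit.pvalues["exposure"]),
        n_used=len(use),
        log_scale_se=se,
    )


@dataclass
class RankTestResult:
    statistic: float
    p_value: float
    test: str  # "kruskal-wallis" or "mann-whitney"
    pairwise: pd.DataFrame | None = None  # BH-adjusted pairwise comparisons


def group_rank_test(
    values: Sequence[float],
    groups: Sequence,
    alternative: str = "two-sided",
) -> RankTestResult:
    """Compare a biomarker across copy-number genotype classes.

    Two groups: Mann-Whitney U (exact for small tie-free samples, else the
    normal approximation with continuity correction).  More: Kruskal-Wallis H with tie correction, followed by
    pairwise Mann-Whitney tests corrected by Benjamini-Hochberg.
    """
    s = pd.Series(values).astype(float)
    g = pd.Series(list(groups))
    by = {lvl: s[(g == lvl).to_numpy()].to_numpy() for lvl in g.unique()}
    if len(by) < 2:
        raise ValueError("need at least two groups")
    for lvl, arr in by.items():
        if len(arr) == 0:
            raise ValueError(f"group {lvl!r} is empty")
    levels = sorted(by)
    if len(by) == 2:
        a, b = (by[l] for l in levels)
        res = stats.mannwhitneyu(a, b, alternative=alternative, use_continuity=True, method="auto")
        return RankTestResult(float(res.statistic), float(res.pvalue), "mann-whitney")
    h, p = stats.kruskal(*(by[l] for l in levels))
    pairs = list(combinations(levels, 2))
    raw = [
        stats.mannwhitneyu(by[x], by[y], alternative=alternative, use_continuity=True,
                           method="auto").pvalue
        for x, y in pairs
    ]
    adj = multipletests(raw, method="fdr_bh")[1]
    pairwise = pd.DataFrame(
        {"group_a": [x for x, _ in pairs], "group_b": [y for _, y in pairs],
         "p_raw": raw, "p_fdr": adj}
    )
    return RankTestResult(float(h), float(p), "kruskal-wallis", pairwise)


def association_table(results: Sequence[AssocResult]) -> pd.DataFrame:
    """Flat results table (regenerates byte-identically from fixed inputs)."""
    return pd.DataFrame(
        [
            {
                "label": r.label,
                "model": r.model,
                "n_case_carrier": r.n_case_carrier,
                "n_case_ref": r.n_case_ref,
                "n_control_carrier": r.n_control_carrier,
                "n_control_ref": r.n_control_ref,
                "or": r.estimate,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "p": r.p_value,
                "separation": r.separation,
            }
            for r in results
        ]
    )
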