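"""Inverse-variance meta-analysis of log odds ratios across sample subsets.

Fixed-effects pooling weights each subset by the inverse of its squared
standard error.  The DerSimonian-Laird random-effects estimator adds a
between-study variance tau^2 derived from Cochran's Q.  Heterogeneity is
summarised by Q, its chi-square p-value, and I^2 = max(0, (Q - df)/Q).

When printed odds ratios and 95% confidence intervals are the available
inputs, standard errors are recovered as (ln hi - ln lo) / 3.92.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

Z95 = 1.96


@dataclass(frozen=True)
class StudyEstimate:
    label: str
    log_or: float
    se: float

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValueError("standard error must be positive")


@dataclass
class HeterogeneityStats:
    q: float
    df: int
    i2: float  # percent
    p_het: float
    degenerate: bool = False  # single study


@dataclass
class MetaResult:
    pooled_or: float
    ci_low: float
    ci_high: float
    p_value: float
    method: str  # "fixed" or "random"
    tau2: float
    het: HeterogeneityStats
    k: int

    def summary(self) -> str:
        return (
            f"{self.method}-effects meta of {self.k} subsets: "
            f"OR={self.pooled_or:.2f} [{self.ci_low:.2f}; {self.ci_high:.2f}], "
            f"P={self.p_value:.3g}; Q={self.het.q:.2f} (df={self.het.df}), "
            f"I2={self.het.i2:.0f}%, tau2={self.tau2:.3f}"
        )


def se_from_ci(or_estimate: float, ci_low: float, ci_high: float, label: str = "") -> StudyEstimate:
    """Recover a log-OR and its SE from a printed OR and 95% CI."""
    if not (0 < ci_low <= or_estimate <= ci_high):
        raise ValueError(f"inconsistent OR/CI: {or_estimate} ({ci_low}, {ci_high})")
    if ci_low == ci_high:
        raise ValueError("degenerate confidence interval")
    return StudyEstimate(
        label=label,
        log_or=float(np.log(or_estimate)),
        se=float((np.log(ci_high) - np.log(ci_low)) / (2 * Z95)),
    )


def _pool(y: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    mu = float((w * y).sum() / w.sum())
    se = float(1.0 / np.sqrt(w.sum()))
    return mu, se


def heterogeneity(estimates: Sequence[StudyEstimate]) -> HeterogeneityStats:
    """Cochran's Q against the fixed-effects pooled estimate, with I^2."""
    y = np.array([e.log_or for e in estimates])
    w = np.array([1.0 / e.se**2 for e in estimates])
    if len(y) < 2:
        return HeterogeneityStats(q=0.0, df=0, i2=0.0, p_het=1.0, degenerate=True)
    mu, _ = _pool(y, w)
    q = float((w * (y - mu) ** 2).sum())
    df = len(y) - 1
    i2 = 100.0 * max(0.0, (q - df) / q) if q > 0 else 0.0
    p_het = float(stats.chi2.sf(q, df))
    return HeterogeneityStats(q=q, df=df, i2=i2, p_het=p_het)


def fixed_effects_meta(estimates: Sequence[StudyEstimate]) -> MetaResult:
    """Inverse-variance fixed-effects pooling."""
    if len(estimates) < 1:
        raise ValueError("at least one estimate is required")
    y = np.array([e.log_or for e in estimates])
    w = np.array([1.0 / e.se**2 for e in estimates])
    mu, se = _pool(y, w)
    return _result(mu, se, "fixed", 0.0, heterogeneity(estimates), len(estimates))


def dersimonian_laird_meta(estimates: Sequence[StudyEstimate]) -> MetaResult:
    """DerSimonian-Laird random-effects pooling.

    tau^2 = max(0, (Q - df) / (sum w - sum w^2 / sum w)) with fixed-effects
    weights; when Q <= df the result coincides with fixed effects.
    """
    if len(estimates) < 2:
        raise ValueError("random-effects pooling needs at least two estimates")
    het = heterogeneity(estimates)
    y = np.array([e.log_or for e in estimates])
    w = np.array([1.0 / e.se**2 for e in estimates])
    denom = w.sum() - (w**2).sum() / w.sum()
    tau2 = max(0.0, (het.q - het.df) / denom) if denom > 0 else 0.0
    w_star = 1.0 / (np.array([e.se**2 for e in estimates]) + tau2)
    mu, se = _pool(y, w_star)
    return _result(mu, se, "random", tau2, het, len(estimates))


def meta_analyze(
    estimates: Sequence[StudyEstimate],
    method: str = "auto",
    i2_threshold: float = 50.0,
) -> MetaResult:
    """Pool subset estimates; ``auto`` selects random effects when I^2
    exceeds the threshold (heterogeneous subsets), fixed effects otherwise."""
    if method == "fixed":
        return fixed_effects_meta(estimates)
    if method == "random":
        return dersimonian_laird_meta(estimates)
    if method != "auto":
        raise ValueError(f"unknown method {method!r}")
    if len(estimates) < 2:
        return fixed_effects_meta(estimates)
    het = heterogeneity(estimates)
    if het.i2 > i2_threshold:
        return dersimonian_laird_meta(estimates)
    return fixed_effects_meta(estimates)


def _result(mu: float, se: float, method: str, tau2: float, het: HeterogeneityStats, k: int) -> MetaResult:
    return MetaResult(
        pooled_or=float(np.exp(mu)),
        ci_low=float(np.exp(mu - Z95 * se)),
        ci_high=float(np.exp(mu + Z95 * se)),
        p_value=float(2 * stats.norm.sf(abs(mu / se))),
        method=method,
        tau2=tau2,
        het=het,
        k=k,
    )
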