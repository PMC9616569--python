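"""Published worked-example inputs for the meta-analysis layer.

A gout CNV association study in Aotearoa NZ Polynesian sample subsets
(Eastern Polynesian, Western Polynesian, and mixed Eastern-Western
Polynesian) reported per-subset odds ratios with 95% confidence intervals
for a pooled seven-region burden test and for individual CNV regions, under
three covariate models (unadjusted; Model 1: age + sex; Model 2: Model 1 +
genotyping batch + ten principal components).  Those printed subset
estimates are bundled here as inputs so the pooled (meta-analysed) values
can be recomputed from scratch.

Each entry is (OR, CI low, CI high).
"""

from __future__ import annotations

from .meta import StudyEstimate, se_from_ci

SUBSETS = ("EP", "WP", "EPWP")

#: Seven-region burden test, per subset and covariate model.
BURDEN_ESTIMATES: dict[str, dict[str, tuple[float, float, float]]] = {
    "unadjusted": {
        "EP": (1.39, 1.12, 1.73),
        "WP": (2.44, 1.83, 3.25),
        "EPWP": (2.34, 1.08, 5.16),
    },
    "model1": {
        "EP": (1.30, 1.01, 1.67),
        "WP": (2.77, 1.96, 3.93),
        "EPWP": (3.18, 1.33, 8.06),
    },
    "model2": {
        "EP": (1.21, 0.94, 1.58),
        "WP": (2.43, 1.69, 3.52),
        "EPWP": (2.48, 0.79, 8.13),
    },
}

#: Per-region subset estimates for the individually tested regions.
REGION_ESTIMATES: dict[str, dict[str, dict[str, tuple[float, float, float]]]] = {
    "CNVR1": {
        "unadjusted": {"WP": (1.60, 1.05, 2.45), "EP": (1.36, 1.02, 1.81), "EPWP": (5.66, 1.57, 26.74)},
        "model2": {"WP": (1.72, 1.03, 2.92), "EP": (1.10, 0.79, 1.54), "EPWP": (6.33, 1.24, 43.16)},
    },
    "CNVR6": {
        "unadjusted": {"WP": (1.75, 1.04, 3.01), "EP": (1.84, 0.97, 3.60), "EPWP": (5.29, 1.15, 37.34)},
        "model2": {"WP": (1.71, 0.91, 3.31), "EP": (1.92, 0.91, 4.15), "EPWP": (3.21, 0.51, 27.77)},
    },
    "CNVR7": {
        "unadjusted": {"WP": (1.69, 1.02, 2.85), "EP": (1.83, 0.81, 4.38), "EPWP": (4.98, 0.61, 102.41)},
        "model2": {"WP": (1.76, 0.95, 3.37), "EP": (1.20, 0.47, 3.31), "EPWP": (2.00, 0.17, 53.25)},
    },
}

#: Burden-test carrier counts per subset: (case carriers, case total,
#: control carriers, control total).
BURDEN_COUNTS: dict[str, tuple[int, int, int, int]] = {
    "EP": (255, 668, 221, 637),
    "WP": (224, 391, 123, 267),
    "EPWP": (23, 41, 22, 55),
}

#: Control-stratum CN=1 carrier count at the most common deletion region in
#: the Eastern Polynesian subset: (carriers, total controls).
CNVR1_EP_CONTROL_CN1: tuple[int, int] = (88, 637)


def study_estimates(table: dict[str, tuple[float, float, float]]) -> list[StudyEstimate]:
    """Convert a {subset: (OR, lo, hi)} table to StudyEstimate inputs,
    preserving subset order EP, WP, EPWP."""
    return [
        se_from_ci(*table[s], label=s) for s in SUBSETS if s in table
    ]
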