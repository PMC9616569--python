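"""Call-level and sample-level quality control.

Call filters remove segments with weak support (<10 SNPs), short length
(<5 kb) or low confidence (<40).  Sample filters remove noisy arrays: LRR
standard deviation > 0.28, waviness factor outside [-0.05, 0.05], or a CNV
count above the cohort's 85th percentile.  All thresholds are strict
(">" removes, "=" keeps) and configurable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import CNVCall, SignalProfile

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CallFilterConfig:
    min_snps: int = 10
    min_length: int = 5000
    min_confidence: float = 40.0

    def __post_init__(self) -> None:
        if self.min_snps < 0 or self.min_length < 0 or self.min_confidence < 0:
            raise ValueError("filter thresholds must be non-negative")


@dataclass(frozen=True)
class SampleFilterConfig:
    max_lrr_sd: float = 0.28
    max_abs_waviness: float = 0.05
    count_percentile: float = 0.85


@dataclass
class SampleQCStats:
    sample_id: str
    lrr_sd: float
    waviness_factor: float
    cnv_count: int = 0


@dataclass
class FilterResult:
    kept: list = field(default_factory=list)
    removed: list = field(default_factory=list)  # (item, reason) pairs

    @property
    def removal_reasons(self) -> pd.Series:
        return pd.Series([r for _, r in self.removed], dtype=object).value_counts()


def filter_calls(calls: Sequence[CNVCall], config: CallFilterConfig | None = None) -> FilterResult:
    """Partition calls into kept and removed-with-first-failing-reason."""
    config = config or CallFilterConfig()
    out = FilterResult()
    for c in calls:
        if c.numsnp < config.min_snps:
            out.removed.append((c, f"numsnp<{config.min_snps}"))
        elif c.length < config.min_length:
            out.removed.append((c, f"length<{config.min_length}"))
        elif not (c.confidence >= config.min_confidence):  # NaN confidence also fails
            out.removed.append((c, f"confidence<{config.min_confidence}"))
        else:
            out.kept.append(c)
    logger.info(
        "call filter: kept %d, removed %d of %d", len(out.kept), len(out.removed), len(calls)
    )
    return out


def compute_sample_stats(
    profile: SignalProfile,
    calls: Sequence[CNVCall],
    gc: pd.Series | np.ndarray | None = None,
    bin_size: int = 1_000_000,
) -> SampleQCStats:
    """Per-sample noise statistics.

    ``lrr_sd`` is the SD of the GC-adjusted track (when a GC model is
    given), so genomic waves do not inflate the noise estimate.  The
    waviness factor summarises long-range dispersion of the raw track: the
    SD of 1-Mb-bin median LRR, signed by the correlation of bin medians
    with bin GC content (positive waviness tracks GC).
    """
    if len(profile) == 0:
        raise ValueError("profile is empty")
    if gc is not None:
        from .hmm import gc_adjust_lrr

        lrr = gc_adjust_lrr(profile, gc).data["lrr"].to_numpy(dtype=float)
    else:
        lrr = profile.data["lrr"].to_numpy(dtype=float)
    lrr_sd = float(np.nanstd(lrr, ddof=1)) if np.isfinite(lrr).sum() > 1 else 0.0

    df = profile.data.copy()
    df["_bin"] = df["position"] // bin_size
    if gc is not None:
        df["_gc"] = np.asarray(gc, dtype=float)
    grouped = df.groupby(["chromosome", "_bin"], sort=True)
    medians = grouped["lrr"].median()
    if len(medians) < 2:
        logger.warning("sample %s: <2 genomic bins; waviness set to 0", profile.sample_id)
        wf = 0.0
    else:
        sd = float(medians.std(ddof=1))
        sign = 1.0
        if gc is not None:
            bin_gc = grouped["_gc"].mean()
            if bin_gc.std(ddof=0) > 0 and medians.std(ddof=0) > 0:
                corr = float(np.corrcoef(medians.to_numpy(), bin_gc.to_numpy())[0, 1])
                sign = math.copysign(1.0, corr) if corr != 0 else 1.0
        wf = sign * sd
    return SampleQCStats(
        sample_id=profile.sample_id,
        lrr_sd=lrr_sd,
        waviness_factor=wf,
        cnv_count=len(calls),
    )


def sample_count_threshold(counts: Sequence[int], percentile: float = 0.85) -> int:
    """Nearest-rank percentile of per-sample CNV counts: the smallest count
    c such that at least ceil(percentile * n) counts are <= c."""
    if len(counts) == 0:
        raise ValueError("counts must be non-empty")
    ordered = sorted(counts)
    rank = math.ceil(percentile * len(ordered))
    rank = min(max(rank, 1), len(ordered))
    return ordered[rank - 1]


def filter_samples(
    stats: Sequence[SampleQCStats],
    count_threshold: int | None = None,
    config: SampleFilterConfig | None = None,
) -> FilterResult:
    """Remove samples with lrr_sd > 0.28, |waviness| > 0.05 or CNV count
    above the cohort percentile threshold (strict inequalities)."""
    config = config or SampleFilterConfig()
    if count_threshold is None:
        count_threshold = sample_count_threshold(
            [s.cnv_count for s in stats], config.count_percentile
        )
    out = FilterResult()
    for s in stats:
        if s.lrr_sd > config.max_lrr_sd:
            out.removed.append((s, f"lrr_sd>{config.max_lrr_sd}"))
        elif abs(s.waviness_factor) > config.max_abs_waviness:
            out.removed.append((s, f"|waviness|>{config.max_abs_waviness}"))
        elif s.cnv_count > count_threshold:
            out.removed.append((s, f"cnv_count>{count_threshold}"))
        else:
            out.kept.append(s)
    logger.info(
        "sample filter: kept %d, removed %d (count threshold %d)",
        len(out.kept),
        len(out.removed),
        count_threshold,
    )
    return out
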