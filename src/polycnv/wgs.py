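"""Validation of array CNV genotypes against WGS read depth.

Each chromosome is divided into fixed bins (1 kb by default); the copy
number of a region is estimated from the ratio of its median bin depth to
the sample's background depth (autosomal median outside called regions),
and compared with the array genotype for exact-match concordance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass
class ConcordanceReport:
    """Exact-match agreement between array and depth genotypes."""

    detail: pd.DataFrame  # sample_id, region_id, array_cn, depth_cn, agree
    per_region: pd.Series  # percent agreement per region
    overall: float  # unweighted mean of per-region percentages

    def summary(self) -> str:
        lines = [f"{rid}: {pct:.1f}%" for rid, pct in self.per_region.items()]
        return "concordance " + ", ".join(lines) + f"; average {self.overall:.1f}%"


def bin_depth(coverage: pd.DataFrame, bin_size: int = 1000) -> pd.DataFrame:
    """Aggregate interval coverage into fixed bins (0-based half-open).

    ``coverage`` has columns chromosome, start, end, depth (0-based
    half-open intervals; bases not covered by any interval count as depth
    0).  Bin depth is the mean per-base coverage over the bin; a trailing
    partial bin is averaged over its actual width.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    frames = []
    for chrom, sub in coverage.groupby("chromosome", sort=True):
        length = int(sub["end"].max())
        n_bins = int(np.ceil(length / bin_size))
        totals = np.zeros(n_bins)
        for start, end, depth in sub[["start", "end", "depth"]].itertuples(index=False):
            b0 = int(start) // bin_size
            b1 = (int(end) - 1) // bin_size
            for b in range(b0, b1 + 1):
                lo = max(int(start), b * bin_size)
                hi = min(int(end), (b + 1) * bin_size)
                totals[b] += depth * (hi - lo)
        starts = np.arange(n_bins) * bin_size
        ends = np.minimum(starts + bin_size, length)
        widths = (ends - starts).astype(float)
        frames.append(
            pd.DataFrame(
                {"chromosome": str(chrom), "start": starts, "end": ends, "depth": totals / widths}
            )
        )
    return pd.concat(frames, ignore_index=True)


def _region_bins(depth: pd.DataFrame, chromosome: str, start: int, end: int) -> pd.DataFrame:
    """Bins wholly inside the 1-based inclusive region [start, end]."""
    return depth[
        (depth["chromosome"] == str(chromosome))
        & (depth["start"] >= start - 1)
        & (depth["end"] <= end)
    ]


def background_depth(depth: pd.DataFrame, exclude: Sequence[tuple[str, int, int]] = ()) -> float:
    """Per-sample background: median bin depth outside all called regions."""
    mask = np.ones(len(depth), dtype=bool)
    for chrom, start, end in exclude:
        inside = (
            (depth["chromosome"] == str(chrom))
            & (depth["end"] > start - 1)
            & (depth["start"] < end)
        )
        mask &= ~inside.to_numpy()
    vals = depth.loc[mask, "depth"].to_numpy(dtype=float)
    if len(vals) == 0:
        raise ValueError("no background bins left after excluding regions")
    return float(np.median(vals))


def estimate_region_cn(
    depth: pd.DataFrame,
    chromosome: str,
    start: int,
    end: int,
    background: float,
) -> int | None:
    """Integer copy number from the median region bin depth.

    CN = round(2 x median/background), clipped to [0, 4]; exact .5 ratios
    round away from two (toward the more extreme state).  Regions covered by
    fewer than three whole bins are not called (returns None).
    """
    if background <= 0:
        raise ValueError("background depth must be positive")
    bins = _region_bins(depth, chromosome, start, end)
    if len(bins) < 3:
        return None
    ratio = float(np.median(bins["depth"].to_numpy(dtype=float))) / background
    c = 2.0 * ratio
    frac = c - np.floor(c)
    if abs(frac - 0.5) < 1e-9:
        cn = int(np.ceil(c)) if c >= 2 else int(np.floor(c))
    else:
        cn = int(round(c))
    return int(np.clip(cn, 0, 4))


def depth_genotype_matrix(
    depths: dict[str, pd.DataFrame],
    regions: Sequence[tuple[str, str, int, int]],
) -> pd.DataFrame:
    """Depth-based CN per (sample, region); regions are
    (region_id, chromosome, start, end) with 1-based inclusive bounds."""
    region_spans = [(chrom, start, end) for _, chrom, start, end in regions]
    rows = {}
    for sid, depth in depths.items():
        bg = background_depth(depth, exclude=region_spans)
        rows[sid] = {
            rid: estimate_region_cn(depth, chrom, start, end, bg)
            for rid, chrom, start, end in regions
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "sample_id"
    return out


def concordance(array_matrix: pd.DataFrame, depth_matrix: pd.DataFrame) -> ConcordanceReport:
    """Exact CN agreement between array and depth genotypes.

    Restricted to shared samples and regions; per-region percentages are
    averaged unweighted into the overall figure.  No-calls (missing depth
    CN) are excluded from the denominator.
    """
    samples = array_matrix.index.intersection(depth_matrix.index)
    regions = array_matrix.columns.intersection(depth_matrix.columns)
    if len(samples) == 0 or len(regions) == 0:
        raise ValueError("array and depth genotypes share no samples or regions")
    rows = []
    for sid in samples:
        for rid in regions:
            d = depth_matrix.loc[sid, rid]
            if d is None or (isinstance(d, float) and np.isnan(d)):
                continue
            a = int(array_matrix.loc[sid, rid])
            rows.append(
                {"sample_id": sid, "region_id": rid, "array_cn": a, "depth_cn": int(d),
                 "agree": a == int(d)}
            )
    detail = pd.DataFrame(rows)
    if detail.empty:
        raise ValueError("no comparable (sample, region) pairs")
    per_region = detail.groupby("region_id")["agree"].mean() * 100.0
    return ConcordanceReport(
        detail=detail,
        per_region=per_region,
        overall=float(per_region.mean()),
    )
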