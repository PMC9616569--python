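"""CNV region (CNVR) construction, genotype assignment and classification.

Overlapping per-sample calls (any >= 1 bp overlap, transitively) are merged
into regions spanning the outermost boundaries of their union.  Each
individual is then assigned an integer copy number per region, group
carrier frequencies are tabulated, and regions are classified as specific
to / amplified in a target population group relative to comparator groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import pandas as pd

from .core import CNVCall

logger = logging.getLogger(__name__)


class Specificity(str, Enum):
    SPECIFIC = "specific"
    AMPLIFIED = "amplified"
    SHARED = "shared"
    RARE = "rare"


@dataclass
class CNVRegion:
    """A merged region: outermost bounds of a connected component of
    pairwise-overlapping calls (1-based inclusive)."""

    region_id: str
    chromosome: str
    start: int
    end: int
    member_calls: list[CNVCall] = field(default_factory=list)

    @property
    def n_carriers(self) -> int:
        return len({c.sample_id for c in self.member_calls})

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def merge_calls_to_cnvrs(
    calls: Sequence[CNVCall],
    min_carriers: int = 10,
) -> tuple[list[CNVRegion], list[CNVRegion]]:
    """Merge overlapping calls into regions.

    Returns ``(reported, all_regions)``: regions carried by fewer than
    ``min_carriers`` distinct individuals are excluded from the reported set
    but retained in the full list.  Input order does not matter.
    """
    regions: list[CNVRegion] = []
    by_chrom: dict[str, list[CNVCall]] = {}
    for c in calls:
        by_chrom.setdefault(c.chromosome, []).append(c)
    for chrom in sorted(by_chrom):
        chrom_calls = sorted(by_chrom[chrom], key=lambda c: (c.start, c.end))
        current: list[CNVCall] = []
        cur_end = -1
        for c in chrom_calls:
            if current and c.start > cur_end:  # inclusive coords: touching at end+1 does not overlap
                regions.append(_make_region(chrom, current))
                current = []
                cur_end = -1
            current.append(c)
            cur_end = max(cur_end, c.end)
        if current:
            regions.append(_make_region(chrom, current))
    for i, r in enumerate(regions, start=1):
        r.region_id = f"CNVR{i}"
    reported = [r for r in regions if r.n_carriers >= min_carriers]
    logger.info("merged %d calls into %d regions (%d with >=%d carriers)",
                len(calls), len(regions), len(reported), min_carriers)
    return reported, regions


def _make_region(chrom: str, members: list[CNVCall]) -> CNVRegion:
    return CNVRegion(
        region_id="",
        chromosome=chrom,
        start=min(c.start for c in members),
        end=max(c.end for c in members),
        member_calls=list(members),
    )


def assign_genotypes(
    regions: Sequence[CNVRegion],
    sample_ids: Sequence[str],
) -> pd.DataFrame:
    """Copy-number genotype matrix (individuals x regions), default diploid.

    An individual's CN at a region is that of their member call when the
    call covers >= 50% of the region or lies wholly within it (always true
    for member calls, since regions span their union); with several member
    calls the largest overlap wins, ties resolved toward the lower CN.
    """
    matrix = pd.DataFrame(2, index=pd.Index(sample_ids, name="sample_id"),
                          columns=[r.region_id for r in regions], dtype=int)
    for r in regions:
        per_sample: dict[str, tuple[int, int]] = {}  # sample -> (overlap, cn)
        for c in r.member_calls:
            if c.sample_id not in matrix.index:
                continue
            overlap = min(c.end, r.end) - max(c.start, r.start) + 1
            covers = overlap >= 0.5 * r.length or (c.start >= r.start and c.end <= r.end)
            if not covers:
                continue
            prev = per_sample.get(c.sample_id)
            if prev is None or (overlap, -c.cn) > (prev[0], -prev[1]):
                if prev is not None:
                    logger.debug(
                        "sample %s has multiple calls at %s; keeping larger overlap",
                        c.sample_id, r.region_id,
                    )
                per_sample[c.sample_id] = (overlap, c.cn)
        for sid, (_, cn) in per_sample.items():
            matrix.loc[sid, r.region_id] = cn
    return matrix


def carrier_frequency(matrix: pd.DataFrame, region_id: str, sample_ids: Sequence[str]) -> float:
    """Carrier frequency (percent) among the given individuals: share with
    CN != 2 at the region."""
    subset = matrix.loc[list(sample_ids), region_id]
    if len(subset) == 0:
        raise ValueError("cannot compute a frequency over an empty group")
    return 100.0 * float((subset != 2).sum()) / len(subset)


def classify_specificity(
    target_freq: float,
    comparator_freqs: Mapping[str, float],
    common_threshold: float = 2.0,
    amplified_threshold: float = 1.0,
) -> Specificity:
    """Classify a region for a target group from control-stratum carrier
    frequencies (percent): rare unless common (> 2%) in the target; then
    specific if absent from all comparators, amplified if < 1% in all
    comparators, otherwise shared."""
    if not comparator_freqs:
        raise ValueError("at least one comparator group is required")
    if target_freq <= common_threshold:
        return Specificity.RARE
    if all(f == 0.0 for f in comparator_freqs.values()):
        return Specificity.SPECIFIC
    if all(f < amplified_threshold for f in comparator_freqs.values()):
        return Specificity.AMPLIFIED
    return Specificity.SHARED


def region_table(
    regions: Sequence[CNVRegion],
    matrix: pd.DataFrame,
    cohort: pd.DataFrame,
    target_group: str | None = None,
    comparator_groups: Sequence[str] = (),
) -> pd.DataFrame:
    """Summary table per region: bounds, carrier counts, per-group control
    frequencies and (optionally) the specificity class for a target group."""
    controls = cohort[cohort["gout"] == 0]
    rows = []
    for r in regions:
        row = {
            "region_id": r.region_id,
            "chromosome": r.chromosome,
            "start": r.start,
            "end": r.end,
            "length": r.length,
            "n_carriers": r.n_carriers,
        }
        if "group" in cohort.columns:
            for grp, sub in controls.groupby("group"):
                ids = [s for s in sub["sample_id"] if s in matrix.index]
                row[f"ctrl_freq_{grp}"] = carrier_frequency(matrix, r.region_id, ids) if ids else float("nan")
            if target_group is not None:
                comp = {g: row.get(f"ctrl_freq_{g}", 0.0) for g in comparator_groups}
                row["specificity"] = classify_specificity(
                    row.get(f"ctrl_freq_{target_group}", 0.0), comp
                ).value
        rows.append(row)
    return pd.DataFrame(rows)
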