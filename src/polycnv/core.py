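"""Core in-memory containers shared across the pipeline.

Coordinates are 1-based inclusive throughout the library (matching the
region notation used for array CNV calls); conversion to BED's 0-based
half-open convention happens only at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SIGNAL_COLUMNS = ["snp_id", "chromosome", "position", "lrr", "baf"]


def _normalize_chrom(c) -> str:
    s = str(c)
    return s[3:] if s.lower().startswith("chr") else s


@dataclass
class SignalProfile:
    """One sample's ordered per-SNP LRR/BAF track.

    ``data`` holds columns ``snp_id, chromosome, position, lrr, baf`` sorted
    by (chromosome, position); missing intensities are NaN.
    """

    sample_id: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SIGNAL_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"signal profile missing columns: {missing}")
        df = self.data.copy()
        df["chromosome"] = df["chromosome"].map(_normalize_chrom)
        if not df[["chromosome", "position"]].equals(
            df[["chromosome", "position"]].sort_values(["chromosome", "position"])
        ):
            df = df.sort_values(["chromosome", "position"], kind="mergesort")
        if df.duplicated(["chromosome", "position"]).any():
            raise ValueError("duplicate (chromosome, position) in signal profile")
        self.data = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.data["chromosome"]))


@dataclass(frozen=True, order=True)
class CNVCall:
    """One contiguous non-diploid segment in one sample (1-based inclusive)."""

    sample_id: str
    chromosome: str
    start: int
    end: int
    cn: int
    numsnp: int
    confidence: float = field(default=float("nan"), compare=False)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"call start {self.start} > end {self.end}")
        if self.cn == 2 or self.cn not in (0, 1, 3, 4):
            raise ValueError(f"call copy number must be in {{0,1,3,4}}, got {self.cn}")
        if self.numsnp < 1:
            raise ValueError("a call must be supported by at least one SNP")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class TruthSet:
    """Ground-truth CNV events embedded by the generator.

    ``events``: columns ``sample_id, chromosome, start, end, cn, locus``.
    ``carriers``: boolean frame indexed by sample with one column per locus.
    """

    events: pd.DataFrame
    carriers: pd.DataFrame

    def events_for(self, sample_id: str) -> pd.DataFrame:
        return self.events[self.events["sample_id"] == sample_id]

    def carrier_of(self, sample_id: str, locus: str) -> bool:
        return bool(self.carriers.loc[sample_id, locus])


def sample_cn_track(truth: TruthSet, sample_id: str, chromosome: str, positions: np.ndarray) -> np.ndarray:
    """Integer copy number at each position for one sample (default 2)."""
    cn = np.full(len(positions), 2, dtype=int)
    ev = truth.events_for(sample_id)
    for _, row in ev[ev["chromosome"] == str(chromosome)].iterrows():
        mask = (positions >= row["start"]) & (positions <= row["end"])
        cn[mask] = int(row["cn"])
    return cn
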