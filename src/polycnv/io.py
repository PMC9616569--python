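"""Readers and writers for the pipeline's line-oriented text formats.

Formats: intensity ("signal") files in the tab-delimited dialect used by
array CNV callers (Name/Chr/Position plus per-sample "Log R Ratio" and
"B Allele Freq" columns), 4-column PFB tables, one-call-per-line CNV call
text, tab-delimited covariate tables, BED-like depth files and CNVR BED
export.  All writers are deterministic; reader/writer pairs are exact
inverses on valid data (numeric fields to the printed precision).

Internal coordinates are 1-based inclusive; BED export is 0-based half-open.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import CNVCall, SignalProfile, _normalize_chrom

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# signal (intensity) files
# ---------------------------------------------------------------------------

def write_signal_file(profile: SignalProfile, path: str | Path) -> None:
    sid = profile.sample_id
    df = profile.data
    with open(path, "w") as fh:
        fh.write(f"Name\tChr\tPosition\t{sid}.Log R Ratio\t{sid}.B Allele Freq\n")
        for snp, chrom, pos, lrr, baf in df[
            ["snp_id", "chromosome", "position", "lrr", "baf"]
        ].itertuples(index=False):
            l = "NA" if pd.isna(lrr) else f"{lrr:.4f}"
            b = "NA" if pd.isna(baf) else f"{baf:.4f}"
            fh.write(f"{snp}\t{chrom}\t{pos}\t{l}\t{b}\n")


def read_signal_file(path: str | Path) -> SignalProfile:
    df = pd.read_csv(path, sep="\t", dtype={"Chr": str}, na_values=["NA", ""])
    cols = {c.lower(): c for c in df.columns}
    for required in ("name", "chr", "position"):
        if required not in cols:
            raise FormatError(f"signal file {path} missing required column {required!r}")
    lrr_col = _find_suffix_column(df.columns, ".Log R Ratio", "LRR")
    baf_col = _find_suffix_column(df.columns, ".B Allele Freq", "BAF")
    if lrr_col is None:
        raise FormatError(f"signal file {path} missing a Log R Ratio column")
    if baf_col is None:
        raise FormatError(f"signal file {path} missing a B Allele Freq column")
    sample_id = lrr_col.rsplit(".", 1)[0] if lrr_col.endswith(".Log R Ratio") else Path(path).stem
    out = pd.DataFrame(
        {
            "snp_id": df[cols["name"]],
            "chromosome": df[cols["chr"]].map(_normalize_chrom),
            "position": df[cols["position"]].astype(int),
            "lrr": pd.to_numeric(df[lrr_col], errors="coerce"),
            "baf": pd.to_numeric(df[baf_col], errors="coerce"),
        }
    )
    if not out[["chromosome", "position"]].equals(
        out[["chromosome", "position"]].sort_values(["chromosome", "position"])
    ):
        logger.warning("signal file %s was not sorted; sorting", path)
    return SignalProfile(sample_id=sample_id, data=out)


def _find_suffix_column(columns: Iterable[str], suffix: str, plain: str) -> str | None:
    for c in columns:
        if c.endswith(suffix):
            return c
    for c in columns:
        if c.strip().upper() == plain:
            return c
    return None


# ---------------------------------------------------------------------------
# PFB tables
# ---------------------------------------------------------------------------

def write_pfb(table: pd.DataFrame, path: str | Path) -> None:
    """Write a 4-column PFB table; PFB is clipped to [0.01, 0.99] on write
    to guard downstream likelihoods against degenerate allele frequencies."""
    with open(path, "w") as fh:
        fh.write("Name\tChr\tPosition\tPFB\n")
        for snp, chrom, pos, pfb in table[["snp_id", "chromosome", "position", "pfb"]].itertuples(
            index=False
        ):
            fh.write(f"{snp}\t{chrom}\t{pos}\t{np.clip(pfb, 0.01, 0.99):.6f}\n")


def read_pfb(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"Chr": str})
    df = df.rename(
        columns={"Name": "snp_id", "Chr": "chromosome", "Position": "position", "PFB": "pfb"}
    )
    df["chromosome"] = df["chromosome"].map(_normalize_chrom)
    if ((df["pfb"] < 0) | (df["pfb"] > 1)).any():
        raise FormatError(f"PFB file {path} contains values outside [0, 1]")
    return df[["snp_id", "chromosome", "position", "pfb"]]


# ---------------------------------------------------------------------------
# CNV call text
# ---------------------------------------------------------------------------

_CALL_RE = re.compile(r"^chr(?P<chrom>\S+):(?P<start>\d+)-(?P<end>\d+)$")


def write_calls(calls: Sequence[CNVCall], path: str | Path) -> None:
    ordered = sorted(calls, key=lambda c: (c.sample_id, c.chromosome, c.start, c.end))
    with open(path, "w") as fh:
        for c in ordered:
            fh.write(
                f"chr{c.chromosome}:{c.start}-{c.end}\tnumsnp={c.numsnp}\t"
                f"length={c.length}\tcn={c.cn}\t{c.sample_id}\tconf={c.confidence:.3f}\n"
            )


def read_calls(path: str | Path) -> list[CNVCall]:
    calls: list[CNVCall] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise FormatError(f"{path}:{lineno}: expected 6 tab-separated fields")
            m = _CALL_RE.match(fields[0])
            if m is None:
                raise FormatError(f"{path}:{lineno}: malformed region token {fields[0]!r}")
            try:
                calls.append(
                    CNVCall(
                        sample_id=fields[4],
                        chromosome=_normalize_chrom(m["chrom"]),
                        start=int(m["start"]),
                        end=int(m["end"]),
                        cn=int(fields[3].split("=", 1)[1]),
                        numsnp=int(fields[1].split("=", 1)[1]),
                        confidence=float(fields[5].split("=", 1)[1]),
                    )
                )
            except (IndexError, ValueError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return calls


# ---------------------------------------------------------------------------
# covariate tables
# ---------------------------------------------------------------------------

def write_covariates(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_covariates(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "batch": str, "group": str})
    for required in ("sample_id", "gout"):
        if required not in df.columns:
            raise FormatError(f"covariate table {path} missing column {required!r}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise FormatError(f"covariate table {path} has duplicate sample_id {dup!r}")
    n_missing = int(df.drop(columns=["sample_id"]).isna().any(axis=1).sum())
    if n_missing:
        logger.info(
            "covariate table %s: %d individuals have missing covariates; they are "
            "excluded per model at fit time",
            path,
            n_missing,
        )
    return df


# ---------------------------------------------------------------------------
# depth files and region export
# ---------------------------------------------------------------------------

def write_depth(depth: pd.DataFrame, path: str | Path) -> None:
    """BED-like depth: chromosome, start (0-based), end (exclusive), depth."""
    depth[["chromosome", "start", "end", "depth"]].to_csv(
        path, sep="\t", index=False, header=False, float_format="%.4f"
    )


def read_depth(path: str | Path, sample_id: str | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=["chromosome", "start", "end", "depth"], dtype={0: str})
    df["chromosome"] = df["chromosome"].map(_normalize_chrom)
    if sample_id is not None:
        df.insert(0, "sample_id", sample_id)
    return df


def write_regions_bed(regions: pd.DataFrame, path: str | Path) -> None:
    """Export regions to BED (0-based half-open) with id, carrier count and
    specificity class in columns 4-6."""
    with open(path, "w") as fh:
        for row in regions.itertuples(index=False):
            fh.write(
                f"{row.chromosome}\t{row.start - 1}\t{row.end}\t{row.region_id}\t"
                f"{row.n_carriers}\t{getattr(row, 'specificity', '.')}\n"
            )


def write_truth(truth_events: pd.DataFrame, path: str | Path) -> None:
    truth_events.to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"sample_id": str, "chromosome": str, "locus": str})
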