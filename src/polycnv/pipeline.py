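"""End-to-end pipeline: simulate -> call -> qc -> regions -> assoc -> meta
-> validate, driven by one config and one seed.

Every stage reads only files written by earlier stages, so the pipeline can
resume: a stage is skipped when its outputs exist and their digests match
the manifest from a previous run with the same config; once any stage
re-runs, all downstream stages re-run too.  A corrupted intermediate file
therefore triggers recomputation from that stage onward.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping

import pandas as pd
import yaml

from . import __version__
from . import io as pio
from .association import association_table, code_burden_carrier, logistic_assoc
from .config import CohortConfig
from .core import SignalProfile
from .hmm import call_cnvs, compile_pfb, default_params
from .meta import StudyEstimate, meta_analyze
from .qc import (
    CallFilterConfig,
    compute_sample_stats,
    filter_calls,
    filter_samples,
    sample_count_threshold,
)
from .regions import assign_genotypes, merge_calls_to_cnvrs, region_table
from .synthetic import render_lrr_baf, render_wgs_depth, simulate_cohort, simulate_snp_map
from .wgs import concordance, depth_genotype_matrix

logger = logging.getLogger(__name__)

STAGES = ("simulate", "call", "qc", "regions", "assoc", "meta", "validate")


@dataclass
class PipelineConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    out_dir: str = "polycnv_run"
    n_wgs_samples: int = 40
    min_region_carriers: int = 10
    assoc_model: str = "model2"
    meta_method: str = "auto"
    call_filter: CallFilterConfig = field(default_factory=CallFilterConfig)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "cohort" in raw:
            raw["cohort"] = CohortConfig.from_dict(raw["cohort"])
        if "call_filter" in raw:
            raw["call_filter"] = CallFilterConfig(**raw["call_filter"])
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(
            {
                "cohort": self.cohort.to_dict(),
                "n_wgs_samples": self.n_wgs_samples,
                "min_region_carriers": self.min_region_carriers,
                "assoc_model": self.assoc_model,
                "meta_method": self.meta_method,
                "call_filter": vars(self.call_filter),
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()


def demo_config(out_dir: str = "polycnv_demo", seed: int = 0) -> PipelineConfig:
    """Small single-chromosome demo cohort (runs end to end in minutes)."""
    from .config import CnvLocus

    freq = {"EP": 0.15, "WP": 0.10, "EPWP": 0.12}
    cohort = CohortConfig(
        n_cases=250,
        n_controls=250,
        chromosome_lengths={"1": 10_000_000},
        cnv_loci=(
            CnvLocus("1", 2_000_001, 2_250_000, cn=1, frequency=freq, odds_ratio=1.8, name="del_a"),
            CnvLocus("1", 5_000_001, 5_300_000, cn=3,
                     frequency={"EP": 0.08, "WP": 0.08, "EPWP": 0.08}, odds_ratio=1.0, name="dup_a"),
            CnvLocus("1", 8_000_001, 8_200_000, cn=1,
                     frequency={"EP": 0.05, "WP": 0.05, "EPWP": 0.05}, odds_ratio=1.3, name="del_b"),
        ),
        seed=seed,
    )
    return PipelineConfig(cohort=cohort, out_dir=out_dir)


# ---------------------------------------------------------------------------


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    version: str
    config_hash: str
    stages: dict = field(default_factory=dict)  # stage -> {file: digest}
    timestamps: dict = field(default_factory=dict)

    def save(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(vars(self), fh, indent=2, sort_keys=True)

    @classmethod
    def load(cls, path: Path) -> "RunManifest":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(**raw)


class PipelineError(RuntimeError):
    pass


def run_pipeline(config: PipelineConfig, resume: bool = True) -> RunManifest:
    """Execute all stages in order; returns the manifest of output digests."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    previous: RunManifest | None = None
    if resume and manifest_path.exists():
        try:
            prev = RunManifest.load(manifest_path)
            if prev.config_hash == config.config_hash():
                previous = prev
        except (json.JSONDecodeError, TypeError):
            logger.warning("unreadable manifest; re-running all stages")

    manifest = RunManifest(version=__version__, config_hash=config.config_hash())
    stage_fns: Mapping[str, Callable[[PipelineConfig, Path], list[Path]]] = {
        "simulate": _stage_simulate,
        "call": _stage_call,
        "qc": _stage_qc,
        "regions": _stage_regions,
        "assoc": _stage_assoc,
        "meta": _stage_meta,
        "validate": _stage_validate,
    }
    dirty = False
    for stage in STAGES:
        fn = stage_fns[stage]
        if previous is not None and not dirty and _stage_up_to_date(previous, stage, out):
            logger.info("stage %s up to date; skipped", stage)
            manifest.stages[stage] = previous.stages[stage]
            manifest.timestamps[stage] = previous.timestamps.get(stage, "")
            continue
        dirty = True
        logger.info("running stage %s", stage)
        t0 = time.time()
        try:
            outputs = fn(config, out)
        except Exception as exc:
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
        manifest.stages[stage] = {str(p.relative_to(out)): _digest(p) for p in outputs}
        manifest.timestamps[stage] = f"{time.time() - t0:.1f}s"
        manifest.save(manifest_path)
    manifest.save(manifest_path)
    return manifest


def _stage_up_to_date(previous: RunManifest, stage: str, out: Path) -> bool:
    recorded = previous.stages.get(stage)
    if not recorded:
        return False
    for rel, digest in recorded.items():
        p = out / rel
        if not p.exists() or _digest(p) != digest:
            return False
    return True


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def _stage_simulate(config: PipelineConfig, out: Path) -> list[Path]:
    cc = config.cohort
    snp_map = simulate_snp_map(cc)
    cohort, truth = simulate_cohort(cc, snp_map)
    sig_dir = out / "signals"
    sig_dir.mkdir(exist_ok=True)
    outputs = []
    map_path = out / "snp_map.tsv"
    snp_map.to_csv(map_path, sep="\t", index=False, float_format="%.6f")
    outputs.append(map_path)
    cov_path = out / "covariates.tsv"
    pio.write_covariates(cohort, cov_path)
    outputs.append(cov_path)
    truth_path = out / "truth.tsv"
    pio.write_truth(truth.events, truth_path)
    outputs.append(truth_path)
    for row in cohort.itertuples(index=False):
        profile = render_lrr_baf(row.sample_id, truth, snp_map, cc, batch=row.batch)
        p = sig_dir / f"{row.sample_id}.txt"
        pio.write_signal_file(profile, p)
        outputs.append(p)
    depth_dir = out / "depth"
    depth_dir.mkdir(exist_ok=True)
    for sid in cohort["sample_id"].iloc[: config.n_wgs_samples]:
        depth = render_wgs_depth(sid, truth, cc)
        p = depth_dir / f"{sid}.bed"
        pio.write_depth(depth, p)
        outputs.append(p)
    return outputs


def _load_profiles(config: PipelineConfig, out: Path) -> tuple[pd.DataFrame, list[SignalProfile]]:
    cohort = pio.read_covariates(out / "covariates.tsv")
    profiles = [pio.read_signal_file(out / "signals" / f"{sid}.txt") for sid in cohort["sample_id"]]
    return cohort, profiles


def _stage_call(config: PipelineConfig, out: Path) -> list[Path]:
    cohort, profiles = _load_profiles(config, out)
    controls = set(cohort.loc[cohort["gout"] == 0, "sample_id"])
    pfb = compile_pfb([p for p in profiles if p.sample_id in controls])
    pfb_path = out / "cohort.pfb"
    pio.write_pfb(pfb, pfb_path)
    pfb = pio.read_pfb(pfb_path)
    snp_map = pd.read_csv(out / "snp_map.tsv", sep="\t", dtype={"chromosome": str})
    gc = snp_map.set_index("snp_id")["gc_local"]
    params = default_params(baf_sd=config.cohort.baf_noise_sd)
    calls = []
    for profile in profiles:
        calls.extend(call_cnvs(profile, pfb, gc.loc[profile.data["snp_id"]].to_numpy(), params))
    calls_path = out / "calls.txt"
    pio.write_calls(calls, calls_path)
    return [pfb_path, calls_path]


def _stage_qc(config: PipelineConfig, out: Path) -> list[Path]:
    cohort, profiles = _load_profiles(config, out)
    calls = pio.read_calls(out / "calls.txt")
    cf = filter_calls(calls, config.call_filter)
    snp_map = pd.read_csv(out / "snp_map.tsv", sep="\t", dtype={"chromosome": str})
    gc = snp_map.set_index("snp_id")["gc_local"]
    by_sample: dict[str, list] = {}
    for c in cf.kept:
        by_sample.setdefault(c.sample_id, []).append(c)
    stats = [
        compute_sample_stats(p, by_sample.get(p.sample_id, []), gc.loc[p.data["snp_id"]].to_numpy())
        for p in profiles
    ]
    threshold = sample_count_threshold([s.cnv_count for s in stats])
    sf = filter_samples(stats, threshold)
    kept_samples = {s.sample_id for s in sf.kept}
    kept_calls = [c for c in cf.kept if c.sample_id in kept_samples]

    kept_path = out / "calls_kept.txt"
    pio.write_calls(kept_calls, kept_path)
    removed_path = out / "calls_removed.tsv"
    pd.DataFrame(
        [{"sample_id": c.sample_id, "chromosome": c.chromosome, "start": c.start,
          "end": c.end, "cn": c.cn, "reason": reason} for c, reason in cf.removed]
    ).to_csv(removed_path, sep="\t", index=False)
    stats_path = out / "sample_stats.tsv"
    removed_reasons = {s.sample_id: r for s, r in sf.removed}
    pd.DataFrame(
        [{"sample_id": s.sample_id, "lrr_sd": s.lrr_sd, "waviness_factor": s.waviness_factor,
          "cnv_count": s.cnv_count, "kept": s.sample_id in kept_samples,
          "reason": removed_reasons.get(s.sample_id, "")} for s in stats]
    ).to_csv(stats_path, sep="\t", index=False, float_format="%.6g")
    return [kept_path, removed_path, stats_path]


def _stage_regions(config: PipelineConfig, out: Path) -> list[Path]:
    cohort = pio.read_covariates(out / "covariates.tsv")
    kept_samples = pd.read_csv(out / "sample_stats.tsv", sep="\t")
    kept_ids = kept_samples.loc[kept_samples["kept"], "sample_id"].astype(str).tolist()
    calls = pio.read_calls(out / "calls_kept.txt")
    reported, all_regions = merge_calls_to_cnvrs(calls, config.min_region_carriers)
    matrix = assign_genotypes(all_regions, kept_ids)
    matrix_path = out / "genotypes.tsv"
    matrix.to_csv(matrix_path, sep="\t")
    table = region_table(all_regions, matrix, cohort[cohort["sample_id"].isin(kept_ids)])
    table["reported"] = table["region_id"].isin({r.region_id for r in reported})
    table_path = out / "regions.tsv"
    table.to_csv(table_path, sep="\t", index=False, float_format="%.4f")
    bed_path = out / "regions.bed"
    pio.write_regions_bed(table, bed_path)
    return [matrix_path, table_path, bed_path]


def _stage_assoc(config: PipelineConfig, out: Path) -> list[Path]:
    cohort = pio.read_covariates(out / "covariates.tsv")
    matrix = pd.read_csv(out / "genotypes.tsv", sep="\t", index_col="sample_id")
    regions = pd.read_csv(out / "regions.tsv", sep="\t")
    reported = regions.loc[regions["reported"], "region_id"].tolist()
    results = []
    if reported:
        carrier = code_burden_carrier(matrix, reported)
        df = cohort.set_index("sample_id").join(carrier, how="inner").reset_index()
        for grp, sub in df.groupby("group"):
            try:
                results.append(
                    logistic_assoc(sub, "carrier", model=config.assoc_model,
                                   label=f"burden:{grp}")
                )
            except ValueError as exc:
                logger.warning("burden association skipped for %s: %s", grp, exc)
    path = out / "assoc.tsv"
    association_table(results).to_csv(path, sep="\t", index=False, float_format="%.6g")
    return [path]


def _stage_meta(config: PipelineConfig, out: Path) -> list[Path]:
    assoc = pd.read_csv(out / "assoc.tsv", sep="\t")
    path = out / "meta.tsv"
    rows = []
    usable = assoc[~assoc["separation"].astype(bool)] if len(assoc) else assoc
    if len(usable) >= 2:
        import numpy as np

        ests = []
        for _, r in usable.iterrows():
            se = (np.log(r["ci_high"]) - np.log(r["ci_low"])) / (2 * 1.96)
            ests.append(StudyEstimate(label=r["label"], log_or=float(np.log(r["or"])), se=float(se)))
        res = meta_analyze(ests, method=config.meta_method)
        rows.append(
            {"analysis": "burden", "method": res.method, "k": res.k,
             "pooled_or": res.pooled_or, "ci_low": res.ci_low, "ci_high": res.ci_high,
             "p": res.p_value, "q": res.het.q, "i2": res.het.i2, "tau2": res.tau2,
             "p_het": res.het.p_het}
        )
    pd.DataFrame(rows, columns=["analysis", "method", "k", "pooled_or", "ci_low", "ci_high",
                                "p", "q", "i2", "tau2", "p_het"]).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )
    return [path]


def _stage_validate(config: PipelineConfig, out: Path) -> list[Path]:
    matrix = pd.read_csv(out / "genotypes.tsv", sep="\t", index_col="sample_id")
    regions = pd.read_csv(out / "regions.tsv", sep="\t")
    reported = regions[regions["reported"]]
    depth_dir = out / "depth"
    depths = {
        p.stem: pio.read_depth(p) for p in sorted(depth_dir.glob("*.bed"))
    }
    path = out / "concordance.tsv"
    region_spec = [
        (r.region_id, str(r.chromosome), int(r.start), int(r.end))
        for r in reported.itertuples(index=False)
    ]
    shared = [sid for sid in depths if sid in matrix.index]
    if not region_spec or not shared:
        pd.DataFrame(columns=["region_id", "pct_agree"]).to_csv(path, sep="\t", index=False)
        return [path]
    depth_matrix = depth_genotype_matrix({s: depths[s] for s in shared}, region_spec)
    report = concordance(matrix.loc[shared, [r[0] for r in region_spec]], depth_matrix)
    per = report.per_region.rename("pct_agree").reset_index()
    per.loc[len(per)] = ["overall", report.overall]
    per.to_csv(path, sep="\t", index=False, float_format="%.2f")
    return [path]
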