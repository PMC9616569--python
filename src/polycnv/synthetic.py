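"""Synthetic case-control cohort generator.

Emulates the data a SNP-array CNV study works from: a SNP map with a smooth
GC-content track, per-individual covariates and gout status from a logistic
model, embedded deletions (CN 0/1) and duplications (CN 3/4) at configured
loci, per-SNP LRR/BAF signal tracks with GC-driven waves and batch offsets,
and matched WGS read depth in fixed bins.

All randomness flows from ``CohortConfig.seed`` through named substreams, so
a fixed seed reproduces every output byte-identically.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import CohortConfig, ConfigurationError
from .core import SignalProfile, TruthSet, sample_cn_track

# substream tags, combined with the config seed to derive independent streams
_STREAM_MAP = 11
_STREAM_COHORT = 23
_STREAM_SIGNAL = 37
_STREAM_DEPTH = 53
_STREAM_BIOMARKER = 67

PC_COLUMNS = [f"pc{i}" for i in range(1, 11)]


def _rng(config: CohortConfig, stream: int, *extra: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stream, *map(int, extra)])


def simulate_snp_map(config: CohortConfig) -> pd.DataFrame:
    """Simulate the SNP map: ids, sorted positions, true PFB and local GC.

    The GC track is an AR(1) (Ornstein-Uhlenbeck) process in genomic
    position with correlation length ``gc_corr_length``, so nearby SNPs share
    GC context while distant ones are nearly independent.
    """
    rng = _rng(config, _STREAM_MAP)
    frames = []
    offset = 0
    for chrom, length in config.chromosome_lengths.items():
        n = int(round(length / 1e6 * config.snp_density))
        if n < 1:
            raise ConfigurationError(f"chromosome {chrom!r} yields no SNPs at this density")
        positions = np.sort(rng.choice(np.arange(1, length + 1), size=n, replace=False))
        pfb = rng.uniform(0.02, 0.98, size=n)
        # OU process: z_{i+1} = rho z_i + sqrt(1-rho^2) eps
        z = np.empty(n)
        z[0] = rng.standard_normal()
        steps = np.diff(positions)
        eps = rng.standard_normal(n - 1) if n > 1 else np.empty(0)
        for i, (d, e) in enumerate(zip(steps, eps)):
            rho = np.exp(-d / config.gc_corr_length)
            z[i + 1] = rho * z[i] + np.sqrt(1.0 - rho * rho) * e
        gc = np.clip(config.gc_mean + config.gc_sd * z, 0.0, 1.0)
        frames.append(
            pd.DataFrame(
                {
                    "snp_id": [f"rs{offset + i + 1}" for i in range(n)],
                    "chromosome": str(chrom),
                    "position": positions.astype(int),
                    "pfb_true": pfb,
                    "gc_local": gc,
                }
            )
        )
        offset += n
    return pd.concat(frames, ignore_index=True)


def _simulate_pool(config: CohortConfig, n: int, rng: np.random.Generator) -> pd.DataFrame:
    groups = list(config.groups)
    props = np.array([config.groups[g] for g in groups], dtype=float)
    batches = list(config.batch_effects)
    cm = config.covariate_model

    df = pd.DataFrame(
        {
            "group": rng.choice(groups, size=n, p=props / props.sum()),
            "age": np.clip(rng.normal(50.0, 15.0, size=n), 18.0, 95.0),
            "sex": rng.integers(0, 2, size=n),  # 1 = male
            "batch": rng.choice(batches, size=n),
        }
    )
    for col in PC_COLUMNS:
        df[col] = rng.standard_normal(n)

    logit = np.full(n, cm.intercept, dtype=float)
    logit += cm.age_per_decade * (df["age"].to_numpy() - 50.0) / 10.0
    logit += cm.sex * df["sex"].to_numpy()
    logit += df["batch"].map(dict(cm.batch)).to_numpy(dtype=float)
    for coef, col in zip(cm.pcs, PC_COLUMNS):
        logit += coef * df[col].to_numpy()

    for j, locus in enumerate(config.cnv_loci):
        freq = df["group"].map(dict(locus.frequency)).to_numpy(dtype=float)
        carrier = rng.random(n) < freq
        df[f"carrier_{j}"] = carrier
        logit += np.log(locus.odds_ratio) * carrier

    p = 1.0 / (1.0 + np.exp(-logit))
    df["gout"] = (rng.random(n) < p).astype(int)
    # serum urate (mmol/l): higher in cases and in men, floored at a
    # physiological minimum
    urate = 0.31 + 0.05 * df["gout"] + 0.04 * df["sex"] + rng.normal(0.0, 0.06, size=n)
    df["urate"] = np.clip(urate, 0.05, None)
    return df


def simulate_cohort(config: CohortConfig, snp_map: pd.DataFrame | None = None) -> tuple[pd.DataFrame, TruthSet]:
    """Simulate individuals and the truth set of their embedded CNVs.

    Carrier status is drawn per locus per group at the configured population
    frequency; gout is then drawn from the logistic covariate model with
    ln(OR) x carrier terms.  Exact case/control counts are achieved by
    stratified selection from a simulated pool (deterministic given seed);
    if the pool cannot supply enough of either stratum after bounded
    enlargement, an explicit error is raised.
    """
    rng = _rng(config, _STREAM_COHORT)
    need = config.n_cases + config.n_controls
    pool_n = max(2 * need, 200)
    for _attempt in range(6):
        pool = _simulate_pool(config, pool_n, rng)
        cases = pool[pool["gout"] == 1]
        controls = pool[pool["gout"] == 0]
        if len(cases) >= config.n_cases and len(controls) >= config.n_controls:
            break
        pool_n *= 2
    else:
        raise ConfigurationError(
            "could not achieve requested case/control counts; the covariate "
            "model yields too few of one stratum"
        )

    chosen = pd.concat(
        [cases.iloc[: config.n_cases], controls.iloc[: config.n_controls]]
    ).reset_index(drop=True)
    chosen.insert(0, "sample_id", [f"S{i + 1:05d}" for i in range(len(chosen))])

    carrier_cols = [c for c in chosen.columns if c.startswith("carrier_")]
    locus_names = [loc.name or f"locus{j + 1}" for j, loc in enumerate(config.cnv_loci)]
    carriers = pd.DataFrame(
        {name: chosen[col].to_numpy() for name, col in zip(locus_names, carrier_cols)},
        index=chosen["sample_id"],
    )
    carriers.index.name = "sample_id"

    rows = []
    for j, (locus, name) in enumerate(zip(config.cnv_loci, locus_names)):
        for sid in carriers.index[carriers[name]] if name in carriers else []:
            rows.append(
                {
                    "sample_id": sid,
                    "chromosome": str(locus.chromosome),
                    "start": locus.start,
                    "end": locus.end,
                    "cn": locus.cn,
                    "locus": name,
                }
            )
    events = pd.DataFrame(rows, columns=["sample_id", "chromosome", "start", "end", "cn", "locus"])

    cohort = chosen.drop(columns=carrier_cols)
    return cohort, TruthSet(events=events, carriers=carriers)


def _draw_baf(cn: np.ndarray, pfb: np.ndarray, rng: np.random.Generator, noise_sd: float) -> np.ndarray:
    """BAF per SNP given copy number: allele counts are binomial in the B
    allele frequency (Hardy-Weinberg), noise is Gaussian clipped to [0,1]
    (which yields the point-mass-plus-half-Gaussian boundary behaviour);
    CN=0 has no alleles and emits uniform noise."""
    n = len(cn)
    baf = np.empty(n)
    uniform = rng.random(n)  # drawn unconditionally to keep streams aligned
    noise = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else np.zeros(n)
    for copies in (1, 2, 3, 4):
        mask = cn == copies
        if not mask.any():
            continue
        b_alleles = rng.binomial(copies, pfb[mask])
        baf[mask] = b_alleles / copies
    zero = cn == 0
    baf[~zero] = np.clip(baf[~zero] + noise[~zero], 0.0, 1.0)
    baf[zero] = uniform[zero]
    return baf


def render_lrr_baf(
    sample_id: str,
    truth: TruthSet,
    snp_map: pd.DataFrame,
    config: CohortConfig,
    batch: str | None = None,
) -> SignalProfile:
    """Render one sample's LRR/BAF track from its true copy-number state.

    LRR = state mean + wave_amplitude x (gc - mean gc) + batch offset +
    Gaussian noise; BAF bands follow the allelic ratios of the state.
    """
    rng = _rng(config, _STREAM_SIGNAL, _stable_hash(sample_id))
    frames = []
    gc_center = float(snp_map["gc_local"].mean())
    batch_offset = float(config.batch_effects.get(batch, 0.0)) if batch is not None else 0.0
    means = dict(config.lrr_means)
    for chrom, sub in snp_map.groupby("chromosome", sort=False):
        pos = sub["position"].to_numpy()
        cn = sample_cn_track(truth, sample_id, str(chrom), pos)
        lrr = np.array([means[c] for c in cn], dtype=float)
        lrr += config.wave_amplitude * (sub["gc_local"].to_numpy() - gc_center)
        lrr += batch_offset
        if config.lrr_noise_sd > 0:
            lrr += rng.normal(0.0, config.lrr_noise_sd, size=len(pos))
        baf = _draw_baf(cn, sub["pfb_true"].to_numpy(), rng, config.baf_noise_sd)
        frames.append(
            pd.DataFrame(
                {
                    "snp_id": sub["snp_id"].to_numpy(),
                    "chromosome": str(chrom),
                    "position": pos,
                    "lrr": lrr,
                    "baf": baf,
                }
            )
        )
    return SignalProfile(sample_id=sample_id, data=pd.concat(frames, ignore_index=True))


def render_wgs_depth(
    sample_id: str,
    truth: TruthSet,
    config: CohortConfig,
    bin_size: int = 1000,
) -> pd.DataFrame:
    """Per-bin WGS read depth for one sample (BED-like, 0-based half-open).

    Bin depth is Poisson with mean background_depth x CN/2, so homozygous
    deletions sit near zero and duplications near 1.5x background.
    """
    if bin_size <= 0:
        raise ConfigurationError("bin_size must be positive")
    rng = _rng(config, _STREAM_DEPTH, _stable_hash(sample_id))
    frames = []
    for chrom, length in config.chromosome_lengths.items():
        starts = np.arange(0, length, bin_size)
        ends = np.minimum(starts + bin_size, length)
        mid = (starts + ends + 1) // 2  # 1-based midpoint for CN lookup
        cn = sample_cn_track(truth, sample_id, str(chrom), mid)
        lam = config.background_depth * cn / 2.0
        depth = rng.poisson(lam).astype(float)
        frames.append(
            pd.DataFrame(
                {"chromosome": str(chrom), "start": starts, "end": ends, "depth": depth}
            )
        )
    out = pd.concat(frames, ignore_index=True)
    out.insert(0, "sample_id", sample_id)
    return out


def simulate_biomarker(
    cohort: pd.DataFrame,
    genotype: pd.Series,
    config: CohortConfig,
) -> pd.Series:
    """Log-normal serum biomarker levels with genotype-dependent medians.

    ``genotype`` maps sample_id -> copy number at the biomarker locus; the
    defaults give CN=0 < CN=1 < CN=2 in expectation (pg/ml).
    """
    rng = _rng(config, _STREAM_BIOMARKER)
    medians = dict(config.biomarker_medians)
    mu = genotype.map(lambda c: np.log(medians.get(int(c), medians[2])))
    vals = np.exp(mu.to_numpy(dtype=float) + rng.normal(0.0, config.biomarker_log_sd, size=len(mu)))
    return pd.Series(vals, index=genotype.index, name="biomarker")


def _stable_hash(s: str) -> int:
    """Deterministic 31-bit hash of a string (process-independent)."""
    h = 0
    for ch in s:
        h = (h * 131 + ord(ch)) % 2_147_483_647
    return h
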