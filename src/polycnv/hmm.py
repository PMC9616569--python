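"""Hidden Markov model segmentation of LRR/BAF tracks into copy-number states.

The model follows the conventional six-state parameterization for SNP-array
CNV calling: CN0 (homozygous deletion), CN1 (heterozygous deletion), CN2
(diploid), CN2-LOH (copy-neutral loss of heterozygosity), CN3 and CN4
(duplications).  Emissions are the product of a Gaussian on LRR and a
state-specific BAF mixture whose component locations are the allelic ratios
implied by the state, weighted by Hardy-Weinberg genotype frequencies from
the per-SNP population B-allele frequency (PFB).  Transition probabilities
relax toward the stationary distribution with inter-SNP distance, so distant
SNPs are nearly independent.

Copy-neutral LOH runs are detected but never emitted as CNV calls; only
CN != 2 segments become calls.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import norm

from .core import CNVCall, SignalProfile

logger = logging.getLogger(__name__)

_LOG_FLOOR = -60.0  # floor on any per-SNP log emission term


@dataclass(frozen=True)
class HMMState:
    name: str
    cn: int  # integer copy number (LOH shares cn=2)
    lrr_mean: float
    lrr_sd: float
    loh: bool = False


@dataclass(frozen=True)
class HMMParams:
    """Parameters of the copy-number HMM.

    ``transition_base`` is the per-adjacent-SNP transition matrix at zero
    distance; over distance d the effective matrix is
    exp(-d/D) * base + (1 - exp(-d/D)) * stationary, which interpolates
    toward independence at large gaps.
    """

    states: tuple[HMMState, ...]
    transition_base: np.ndarray
    distance_scale: float = 100_000.0  # D, bp
    baf_sd: float = 0.03  # SD of each BAF mixture component

    def __post_init__(self) -> None:
        tb = np.asarray(self.transition_base, dtype=float)
        if tb.shape != (len(self.states), len(self.states)):
            raise ValueError("transition matrix shape does not match state count")
        if not np.allclose(tb.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition matrix rows must sum to 1")
        if (tb < 0).any():
            raise ValueError("transition probabilities must be non-negative")
        cns = [s.cn for s in self.states if not s.loh]
        means = [s.lrr_mean for s in self.states if not s.loh]
        if any(m2 < m1 for (c1, m1), (c2, m2) in zip(sorted(zip(cns, means)), sorted(zip(cns, means))[1:])):
            raise ValueError("lrr_mean must be non-decreasing in copy number")
        if any(s.lrr_sd <= 0 for s in self.states) or self.baf_sd <= 0:
            raise ValueError("all SDs must be positive")
        object.__setattr__(self, "transition_base", tb)

    @property
    def stationary(self) -> np.ndarray:
        """Stationary distribution of the base transition matrix."""
        vals, vecs = np.linalg.eig(self.transition_base.T)
        i = int(np.argmin(np.abs(vals - 1.0)))
        pi = np.real(vecs[:, i])
        pi = np.abs(pi)
        return pi / pi.sum()

    @property
    def preference_order(self) -> np.ndarray:
        """State indices ordered by tie-break preference: smaller |CN - 2|
        first, plain CN2 before LOH, deletions before duplications."""
        keys = [(abs(s.cn - 2), 1 if s.loh else 0, s.cn) for s in self.states]
        return np.array(sorted(range(len(self.states)), key=lambda i: keys[i]), dtype=int)

    def with_overrides(self, **kwargs) -> "HMMParams":
        return replace(self, **kwargs)


def default_params(baf_sd: float = 0.03) -> HMMParams:
    """Default six-state parameterization (LRR units)."""
    states = (
        HMMState("CN0", 0, -3.0, 1.3),
        HMMState("CN1", 1, -0.66, 0.28),
        HMMState("CN2", 2, 0.0, 0.21),
        HMMState("CN2-LOH", 2, 0.0, 0.21, loh=True),
        HMMState("CN3", 3, 0.40, 0.24),
        HMMState("CN4", 4, 0.68, 0.30),
    )
    n = len(states)
    tb = np.zeros((n, n))
    idx_cn2 = 2
    for i, s in enumerate(states):
        stay = 0.999 if (s.cn == 2 and not s.loh) else 0.95
        tb[i, i] = stay
        leave = 1.0 - stay
        if i == idx_cn2:
            tb[i, [j for j in range(n) if j != i]] = leave / (n - 1)
        else:
            others = [j for j in range(n) if j != i and j != idx_cn2]
            tb[i, idx_cn2] = leave * 0.8
            tb[i, others] = leave * 0.2 / len(others)
    return HMMParams(states=states, transition_base=tb, baf_sd=baf_sd)


# ---------------------------------------------------------------------------
# PFB compilation and GC adjustment
# ---------------------------------------------------------------------------

def compile_pfb(profiles: Sequence[SignalProfile]) -> pd.DataFrame:
    """Population frequency of the B allele: mean non-missing BAF per SNP
    across reference samples, clipped to [0.01, 0.99]."""
    if not profiles:
        raise ValueError("at least one reference sample is required")
    base = profiles[0].data[["snp_id", "chromosome", "position"]].reset_index(drop=True)
    mat = np.stack([p.data["baf"].to_numpy(dtype=float) for p in profiles])
    for p in profiles:
        if len(p.data) != len(base) or not (p.data["snp_id"].to_numpy() == base["snp_id"].to_numpy()).all():
            raise ValueError("all reference samples must share the same SNP map")
    import warnings as _warnings

    with np.errstate(invalid="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN SNPs handled below
        pfb = np.nanmean(mat, axis=0)
    all_missing = np.isnan(pfb)
    if all_missing.any():
        logger.warning("%d SNPs have no non-missing BAF; PFB set to 0.5", int(all_missing.sum()))
        pfb[all_missing] = 0.5
    out = base.copy()
    out["pfb"] = np.clip(pfb, 0.01, 0.99)
    return out


def gc_adjust_lrr(profile: SignalProfile, gc: pd.Series | np.ndarray) -> SignalProfile:
    """Regress LRR on local GC content (single slope per sample) and remove
    the fitted wave: adjusted = LRR - slope x (gc - mean gc).

    Removing a fitted linear term can only shrink the track variance.
    """
    gc = np.asarray(gc, dtype=float)
    if len(gc) != len(profile.data):
        raise ValueError("GC vector length does not match profile")
    lrr = profile.data["lrr"].to_numpy(dtype=float)
    ok = ~np.isnan(lrr)
    if np.var(gc[ok]) == 0:
        logger.warning("constant GC track for sample %s; no adjustment applied", profile.sample_id)
        return profile
    gcen = gc - gc[ok].mean()
    slope = float(np.dot(gcen[ok], lrr[ok] - lrr[ok].mean()) / np.dot(gcen[ok], gcen[ok]))
    adjusted = lrr - slope * gcen
    df = profile.data.copy()
    df["lrr"] = adjusted
    return SignalProfile(sample_id=profile.sample_id, data=df)


# ---------------------------------------------------------------------------
# emissions
# ---------------------------------------------------------------------------

def _baf_mixture(state: HMMState, pfb: np.ndarray) -> tuple[np.ndarray, np.ndarray] | None:
    """Component locations (ratios) and per-SNP weights for a state's BAF
    mixture; None means uniform emission (CN0 carries no allelic signal)."""
    if state.cn == 0:
        return None
    if state.loh:
        ratios = np.array([0.0, 1.0])
        weights = np.stack([1.0 - pfb, pfb], axis=1)
        return ratios, weights
    k = state.cn
    ratios = np.arange(k + 1) / k
    # binomial(k, pfb) genotype weights per SNP
    weights = np.stack(
        [math.comb(k, j) * pfb**j * (1.0 - pfb) ** (k - j) for j in range(k + 1)], axis=1
    )
    return ratios, weights


def _component_logdensity(baf: np.ndarray, ratio: float, sd: float) -> np.ndarray:
    """Log density/mass of a clipped-Gaussian BAF component centred at
    ``ratio``: boundary components keep their clipped point mass at 0/1."""
    out = norm.logpdf(baf, loc=ratio, scale=sd)
    if ratio == 0.0:
        out = np.where(baf == 0.0, np.log(0.5), out)
        out = np.where(baf == 1.0, norm.logsf(1.0, loc=0.0, scale=sd) + np.log(2.0) - 50.0, out)
    elif ratio == 1.0:
        out = np.where(baf == 1.0, np.log(0.5), out)
        out = np.where(baf == 0.0, norm.logcdf(0.0, loc=1.0, scale=sd) + np.log(2.0) - 50.0, out)
    else:
        # interior components put vanishing mass exactly on the boundary
        out = np.where((baf == 0.0) | (baf == 1.0), norm.logpdf(3.5 * sd, 0.0, sd), out)
    return out


def emission_loglik(
    lrr: np.ndarray,
    baf: np.ndarray,
    pfb: np.ndarray,
    params: HMMParams,
) -> np.ndarray:
    """Log emission likelihood, shape (n_snps, n_states).

    Missing BAF (NaN) contributes the LRR term only (the BAF factor is
    marginalised out); missing LRR likewise drops the LRR term.
    """
    n = len(lrr)
    out = np.zeros((n, len(params.states)))
    lrr_ok = ~np.isnan(lrr)
    baf_ok = ~np.isnan(baf)
    safe_baf = np.where(baf_ok, baf, 0.5)
    for j, st in enumerate(params.states):
        term = np.zeros(n)
        term[lrr_ok] = norm.logpdf(lrr[lrr_ok], loc=st.lrr_mean, scale=st.lrr_sd)
        mix = _baf_mixture(st, pfb)
        if mix is None:
            bterm = np.zeros(n)  # uniform density 1 on [0,1]
            bterm[safe_baf == 0.0] = _LOG_FLOOR
            bterm[safe_baf == 1.0] = _LOG_FLOOR
        else:
            ratios, weights = mix
            comp = np.stack(
                [_component_logdensity(safe_baf, float(r), params.baf_sd) for r in ratios], axis=1
            )
            with np.errstate(divide="ignore"):
                bterm = logsumexp(comp + np.log(np.maximum(weights, 1e-300)), axis=1)
        term = term + np.where(baf_ok, bterm, 0.0)
        out[:, j] = np.maximum(term, _LOG_FLOOR)
    return out


# ---------------------------------------------------------------------------
# Viterbi decoding
# ---------------------------------------------------------------------------

def _log_transition(params: HMMParams, distance: float, stationary: np.ndarray) -> np.ndarray:
    w = math.exp(-distance / params.distance_scale)
    a = w * params.transition_base + (1.0 - w) * stationary[np.newaxis, :]
    with np.errstate(divide="ignore"):
        return np.log(a)


def _preferred_argmax(scores: np.ndarray, pref: np.ndarray) -> int:
    """Index of the maximum, breaking exact ties by preference order."""
    best = scores.max()
    for i in pref:
        if scores[i] == best:
            return int(i)
    return int(np.argmax(scores))  # pragma: no cover


def viterbi_path(
    lrr: np.ndarray,
    baf: np.ndarray,
    pfb: np.ndarray,
    positions: np.ndarray,
    params: HMMParams,
) -> np.ndarray:
    """Maximum-a-posteriori state path for one chromosome (state indices)."""
    emis = emission_loglik(lrr, baf, pfb, params)
    n, k = emis.shape
    pref = params.preference_order
    stationary = params.stationary
    with np.errstate(divide="ignore"):
        log_pi = np.log(stationary)
    delta = log_pi + emis[0]
    psi = np.zeros((n, k), dtype=int)
    for t in range(1, n):
        la = _log_transition(params, float(positions[t] - positions[t - 1]), stationary)
        cand = delta[:, np.newaxis] + la  # cand[s_prev, s]
        # argmax over rows reordered by preference: first max wins the tie
        psi[t] = pref[np.argmax(cand[pref, :], axis=0)]
        delta = cand[psi[t], np.arange(k)] + emis[t]
    path = np.empty(n, dtype=int)
    path[-1] = _preferred_argmax(delta, pref)
    for t in range(n - 2, -1, -1):
        path[t] = psi[t + 1, path[t + 1]]
    return path


def viterbi_segment(
    profile: SignalProfile,
    pfb: pd.DataFrame,
    params: HMMParams | None = None,
) -> list[CNVCall]:
    """Segment a profile into CNV calls: maximal runs of identical non-diploid
    states become calls bounded by their first/last SNP (1-based inclusive).

    LOH runs (CN=2 with absent heterozygote band) are decoded but not called.
    """
    params = params or default_params()
    merged = profile.data.merge(
        pfb[["snp_id", "pfb"]], on="snp_id", how="left", validate="one_to_one"
    )
    if merged["pfb"].isna().any():
        raise ValueError("PFB table does not cover all SNPs in the profile")
    calls: list[CNVCall] = []
    for chrom, sub in merged.groupby("chromosome", sort=False):
        if len(sub) < 2:
            logger.warning("chromosome %s has <2 SNPs; skipped", chrom)
            continue
        path = viterbi_path(
            sub["lrr"].to_numpy(dtype=float),
            sub["baf"].to_numpy(dtype=float),
            sub["pfb"].to_numpy(dtype=float),
            sub["position"].to_numpy(),
            params,
        )
        calls.extend(_runs_to_calls(path, sub, profile.sample_id, params))
    return sorted(calls)


def _runs_to_calls(path: np.ndarray, sub: pd.DataFrame, sample_id: str, params: HMMParams) -> list[CNVCall]:
    pos = sub["position"].to_numpy()
    calls = []
    start = 0
    for i in range(1, len(path) + 1):
        if i == len(path) or path[i] != path[start]:
            st = params.states[path[start]]
            if st.cn != 2:
                calls.append(
                    CNVCall(
                        sample_id=sample_id,
                        chromosome=str(sub["chromosome"].iloc[0]),
                        start=int(pos[start]),
                        end=int(pos[i - 1]),
                        cn=st.cn,
                        numsnp=i - start,
                    )
                )
            start = i
    return calls


# ---------------------------------------------------------------------------
# confidence and the full caller
# ---------------------------------------------------------------------------

def confidence_score(
    call: CNVCall,
    profile: SignalProfile,
    pfb: pd.DataFrame,
    params: HMMParams | None = None,
) -> float:
    """Log-likelihood of the call's SNPs under the called state minus under
    diploid, summed over SNPs (additive in supporting evidence)."""
    params = params or default_params()
    merged = profile.data.merge(pfb[["snp_id", "pfb"]], on="snp_id", how="left")
    sub = merged[
        (merged["chromosome"] == call.chromosome)
        & (merged["position"] >= call.start)
        & (merged["position"] <= call.end)
    ]
    emis = emission_loglik(
        sub["lrr"].to_numpy(dtype=float),
        sub["baf"].to_numpy(dtype=float),
        sub["pfb"].to_numpy(dtype=float),
        params,
    )
    state_idx = {s.cn: i for i, s in enumerate(params.states) if not s.loh}
    return float((emis[:, state_idx[call.cn]] - emis[:, state_idx[2]]).sum())


def call_cnvs(
    profile: SignalProfile,
    pfb: pd.DataFrame,
    gc: pd.Series | np.ndarray | None = None,
    params: HMMParams | None = None,
) -> list[CNVCall]:
    """GC-adjust, segment, and score one sample's profile. Deterministic."""
    params = params or default_params()
    if gc is not None:
        profile = gc_adjust_lrr(profile, gc)
    raw = viterbi_segment(profile, pfb, params)
    return [
        CNVCall(
            sample_id=c.sample_id,
            chromosome=c.chromosome,
            start=c.start,
            end=c.end,
            cn=c.cn,
            numsnp=c.numsnp,
            confidence=confidence_score(c, profile, pfb, params),
        )
        for c in raw
    ]
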