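"""Caller contracts: PFB compilation, GC-wave adjustment, Viterbi
segmentation (with an exhaustive-enumeration oracle) and confidence scores."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from polycnv.core import SignalProfile
from polycnv.hmm import (
    HMMParams,
    HMMState,
    _log_transition,
    call_cnvs,
    compile_pfb,
    confidence_score,
    default_params,
    emission_loglik,
    gc_adjust_lrr,
    viterbi_path,
    viterbi_segment,
)

from conftest import snp_index


def _profile_from_arrays(lrr, baf, sample_id="S1", chromosome="1"):
    n = len(lrr)
    return SignalProfile(
        sample_id=sample_id,
        data=pd.DataFrame(
            {
                "snp_id": [f"rs{i}" for i in range(n)],
                "chromosome": chromosome,
                "position": np.arange(1, n + 1) * 10_000,
                "lrr": np.asarray(lrr, dtype=float),
                "baf": np.asarray(baf, dtype=float),
            }
        ),
    )


def _pfb_for(profile, value=0.5):
    return pd.DataFrame(
        {
            "snp_id": profile.data["snp_id"],
            "chromosome": profile.data["chromosome"],
            "position": profile.data["position"],
            "pfb": value,
        }
    )


class TestCompilePfb:
    @pytest.mark.parametrize(
        "bafs,expected",
        [
            ([0.0, 0.5, 1.0], 0.5),
            ([0.0, 0.0, 0.0], 0.01),  # clipped at the degenerate boundary
            ([0.48, 0.52, 1.0, 0.0, 0.5], 0.5),
        ],
    )
    def test_mean_baf(self, bafs, expected):
        profiles = [_profile_from_arrays([0.0], [b], sample_id=f"S{i}") for i, b in enumerate(bafs)]
        pfb = compile_pfb(profiles)
        assert pfb["pfb"].iloc[0] == pytest.approx(expected)

    def test_all_missing_falls_back_to_half(self):
        profiles = [_profile_from_arrays([0.0], [np.nan], sample_id=f"S{i}") for i in range(3)]
        assert compile_pfb(profiles)["pfb"].iloc[0] == 0.5

    def test_matches_nanmean_oracle(self):
        rng = np.random.default_rng(0)
        mat = rng.random((6, 40))
        mat[rng.random((6, 40)) < 0.1] = np.nan
        profiles = [
            _profile_from_arrays(np.zeros(40), mat[i], sample_id=f"S{i}") for i in range(6)
        ]
        pfb = compile_pfb(profiles)["pfb"].to_numpy()
        expected = np.clip(np.nanmean(mat, axis=0), 0.01, 0.99)
        np.testing.assert_allclose(pfb, expected)


class TestGcAdjust:
    def test_pure_wave_removed_exactly(self):
        rng = np.random.default_rng(1)
        gc = rng.uniform(0.3, 0.6, 500)
        lrr = 0.8 * (gc - gc.mean())
        prof = _profile_from_arrays(lrr, np.full(500, 0.5))
        adj = gc_adjust_lrr(prof, gc)
        np.testing.assert_allclose(adj.data["lrr"].to_numpy(), 0.0, atol=1e-12)

    def test_uncorrelated_gc_is_noop_up_to_fitted_slope(self):
        rng = np.random.default_rng(2)
        n = 2000
        gc = rng.uniform(0.3, 0.6, n)
        lrr = rng.normal(0, 0.2, n)
        adj = gc_adjust_lrr(_profile_from_arrays(lrr, np.full(n, 0.5)), gc)
        # the fitted slope is O(1/sqrt n); the track is essentially unchanged
        np.testing.assert_allclose(adj.data["lrr"], lrr, atol=0.02)

    def test_constant_gc_is_noop(self):
        lrr = np.array([0.1, -0.2, 0.3])
        prof = _profile_from_arrays(lrr, np.full(3, 0.5))
        adj = gc_adjust_lrr(prof, np.full(3, 0.4))
        np.testing.assert_array_equal(adj.data["lrr"], lrr)

    def test_adjustment_shrinks_wave_noise(self):
        rng = np.random.default_rng(3)
        n = 10_000
        gc = rng.uniform(0.3, 0.6, n)
        lrr = 0.5 * (gc - gc.mean()) + rng.normal(0, 0.2, n)
        adj = gc_adjust_lrr(_profile_from_arrays(lrr, np.full(n, 0.5)), gc)
        assert adj.data["lrr"].std() < np.std(lrr)


def _three_state_params() -> HMMParams:
    states = (
        HMMState("CN1", 1, -0.66, 0.28),
        HMMState("CN2", 2, 0.0, 0.21),
        HMMState("CN3", 3, 0.40, 0.24),
    )
    tb = np.array(
        [
            [0.95, 0.045, 0.005],
            [0.003, 0.994, 0.003],
            [0.005, 0.045, 0.95],
        ]
    )
    return HMMParams(states=states, transition_base=tb, baf_sd=0.03)


def _brute_force_path(lrr, baf, pfb, positions, params):
    """Exhaustive max over all state paths, same tie-break preference."""
    emis = emission_loglik(lrr, baf, pfb, params)
    n, k = emis.shape
    stationary = params.stationary
    log_pi = np.log(stationary)
    trans = [
        _log_transition(params, float(positions[t] - positions[t - 1]), stationary)
        for t in range(1, n)
    ]
    best_score, best_path = -np.inf, None
    for path in itertools.product(range(k), repeat=n):
        score = log_pi[path[0]] + emis[0, path[0]]
        for t in range(1, n):
            score += trans[t - 1][path[t - 1], path[t]] + emis[t, path[t]]
        if score > best_score:  # ties are measure-zero for continuous inputs
            best_score, best_path = score, path
    return np.array(best_path), best_score


class TestViterbi:
    def test_noise_free_diploid_has_no_calls(self):
        rng = np.random.default_rng(4)
        n = 300
        baf = rng.choice([0.0, 0.5, 1.0], size=n, p=[0.25, 0.5, 0.25])
        prof = _profile_from_arrays(np.zeros(n), baf)
        assert viterbi_segment(prof, _pfb_for(prof)) == []

    @pytest.mark.parametrize("n_snps", [2, 3, 5, 8, 10])
    def test_matches_exhaustive_enumeration(self, n_snps):
        params = _three_state_params()
        rng = np.random.default_rng(100 + n_snps)
        for _ in range(4):
            lrr = rng.normal(0, 0.5, n_snps)
            baf = rng.random(n_snps)
            pfb = rng.uniform(0.05, 0.95, n_snps)
            positions = np.cumsum(rng.integers(1_000, 200_000, n_snps))
            path = viterbi_path(lrr, baf, pfb, positions, params)
            expected, best_score = _brute_force_path(lrr, baf, pfb, positions, params)
            np.testing.assert_array_equal(path, expected)

    def test_deletion_segment_recovered(self, noisy_config, noisy_data):
        truth = noisy_data["truth"]
        carriers = truth.carriers.index[truth.carriers["del"]]
        sid = carriers[0]
        prof = noisy_data["profiles"][sid]
        gc = noisy_data["map"]["gc_local"].to_numpy()
        calls = [c for c in call_cnvs(prof, noisy_data["pfb"], gc) if c.cn == 1]
        assert len(calls) == 1
        call = calls[0]
        m = noisy_data["map"]
        assert abs(snp_index(m, "1", call.start) - snp_index(m, "1", 1_000_001)) <= 5
        assert abs(snp_index(m, "1", call.end) - snp_index(m, "1", 1_300_000)) <= 5

    def test_duplication_segment_recovered(self, noisy_config, noisy_data):
        truth = noisy_data["truth"]
        sid = truth.carriers.index[truth.carriers["dup"]][0]
        prof = noisy_data["profiles"][sid]
        gc = noisy_data["map"]["gc_local"].to_numpy()
        calls = [c for c in call_cnvs(prof, noisy_data["pfb"], gc) if c.cn == 3]
        assert len(calls) == 1
        assert calls[0].start < 3_250_000 and calls[0].end > 3_000_001

    def test_calls_never_overlap_within_sample(self, noisy_data):
        gc = noisy_data["map"]["gc_local"].to_numpy()
        for prof in list(noisy_data["profiles"].values())[:6]:
            calls = call_cnvs(prof, noisy_data["pfb"], gc)
            for a, b in zip(calls, calls[1:]):
                if a.chromosome == b.chromosome:
                    assert a.end < b.start

    def test_deterministic(self, noisy_data):
        prof = next(iter(noisy_data["profiles"].values()))
        gc = noisy_data["map"]["gc_local"].to_numpy()
        assert call_cnvs(prof, noisy_data["pfb"], gc) == call_cnvs(prof, noisy_data["pfb"], gc)


class TestConfidence:
    def test_noise_free_deletion_score_is_snp_sum(self):
        """The call score equals the sum of independent per-SNP log ratios."""
        n = 50
        baf = np.tile([0.0, 1.0], n // 2)
        prof = _profile_from_arrays(np.full(n, -0.66), baf)
        pfb = _pfb_for(prof)
        params = default_params()
        calls = viterbi_segment(prof, pfb, params)
        assert len(calls) == 1 and calls[0].numsnp == n
        score = confidence_score(calls[0], prof, pfb, params)
        # independent single-SNP oracle
        per_snp = [
            float(
                emission_loglik(np.array([-0.66]), np.array([b]), np.array([0.5]), params)[0, 1]
                - emission_loglik(np.array([-0.66]), np.array([b]), np.array([0.5]), params)[0, 2]
            )
            for b in baf
        ]
        assert score == pytest.approx(sum(per_snp), rel=1e-9)

    def test_score_additive_in_duplicated_evidence(self):
        n = 20
        baf = np.tile([0.0, 1.0], n // 2)
        prof1 = _profile_from_arrays(np.full(n, -0.66), baf)
        prof2 = _profile_from_arrays(np.full(2 * n, -0.66), np.tile(baf, 2))
        params = default_params()
        c1 = viterbi_segment(prof1, _pfb_for(prof1), params)[0]
        c2 = viterbi_segment(prof2, _pfb_for(prof2), params)[0]
        s1 = confidence_score(c1, prof1, _pfb_for(prof1), params)
        s2 = confidence_score(c2, prof2, _pfb_for(prof2), params)
        assert s2 == pytest.approx(2 * s1, rel=1e-9)

    def test_diploid_evidence_scores_zero_against_itself(self):
        params = default_params()
        emis = emission_loglik(np.zeros(5), np.full(5, 0.5), np.full(5, 0.5), params)
        assert float((emis[:, 2] - emis[:, 2]).sum()) == 0.0


def test_recall_weakly_decreases_with_noise():
    """Raising the array noise cannot improve carrier recall."""
    from polycnv.config import CnvLocus, CohortConfig
    from polycnv.synthetic import render_lrr_baf, simulate_cohort, simulate_snp_map

    recalls = []
    for noise in (0.10, 0.25, 0.40):
        cfg = CohortConfig(
            n_cases=8,
            n_controls=8,
            chromosome_lengths={"1": 3_000_000},
            cnv_loci=(
                CnvLocus("1", 1_000_001, 1_400_000, cn=1,
                         frequency={"EP": 0.6, "WP": 0.6, "EPWP": 0.6}, name="del"),
            ),
            lrr_noise_sd=noise,
            seed=21,
        )
        m = simulate_snp_map(cfg)
        cohort, truth = simulate_cohort(cfg, m)
        pfb = None
        hits = total = 0
        for row in cohort.itertuples(index=False):
            if not truth.carrier_of(row.sample_id, "del"):
                continue
            total += 1
            prof = render_lrr_baf(row.sample_id, truth, m, cfg, batch=row.batch)
            if pfb is None:
                pfb = _pfb_for_map(m)
            calls = call_cnvs(prof, pfb, m["gc_local"].to_numpy())
            if any(c.cn == 1 and c.start < 1_400_000 and c.end > 1_000_001 for c in calls):
                hits += 1
        recalls.append(hits / total if total else 1.0)
    assert recalls[0] >= recalls[1] >= recalls[2]


def _pfb_for_map(snp_map):
    return pd.DataFrame(
        {
            "snp_id": snp_map["snp_id"],
            "chromosome": snp_map["chromosome"],
            "position": snp_map["position"],
            "pfb": np.clip(snp_map["pfb_true"], 0.01, 0.99),
        }
    )
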