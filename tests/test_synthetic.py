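"""Generator contracts: SNP map structure, cohort sampling, signal semantics
and WGS depth rendering."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from polycnv.config import CnvLocus, CohortConfig, ConfigurationError, CovariateModel
from polycnv.synthetic import (
    render_lrr_baf,
    render_wgs_depth,
    simulate_biomarker,
    simulate_cohort,
    simulate_snp_map,
)

from conftest import ALL_GROUPS, uniform_freq


def _autocorr(x: np.ndarray, lag: int) -> float:
    x = x - x.mean()
    return float(np.dot(x[:-lag], x[lag:]) / np.dot(x, x))


class TestSnpMap:
    def test_density_and_ordering(self):
        cfg = CohortConfig(chromosome_lengths={"1": 10_000_000}, snp_density=100.0)
        m = simulate_snp_map(cfg)
        assert len(m) == 1000
        assert m["position"].is_monotonic_increasing
        assert (np.diff(m["position"]) > 0).all()

    def test_same_seed_identical(self):
        cfg = CohortConfig(seed=42)
        pd.testing.assert_frame_equal(simulate_snp_map(cfg), simulate_snp_map(cfg))

    def test_gc_track_is_locally_correlated(self):
        cfg = CohortConfig(chromosome_lengths={"1": 20_000_000}, seed=5)
        gc = simulate_snp_map(cfg)["gc_local"].to_numpy()
        assert _autocorr(gc, 10) > _autocorr(gc, 500)
        assert _autocorr(gc, 10) > 0.3  # neighbours share GC context

    def test_bounds_and_errors(self):
        m = simulate_snp_map(CohortConfig())
        assert m["pfb_true"].between(0, 1).all()
        assert m["gc_local"].between(0, 1).all()
        with pytest.raises(ConfigurationError):
            CohortConfig(chromosome_lengths={"1": 0})


class TestCohort:
    def test_zero_frequency_means_no_carriers(self):
        cfg = CohortConfig(
            n_cases=50,
            n_controls=50,
            cnv_loci=(CnvLocus("1", 1_000_001, 1_200_000, cn=1, frequency=uniform_freq(0.0)),),
            seed=1,
        )
        _, truth = simulate_cohort(cfg)
        assert truth.events.empty
        assert not truth.carriers.to_numpy().any()

    def test_exact_stratum_sizes(self):
        cfg = CohortConfig(n_cases=120, n_controls=80, seed=2)
        cohort, _ = simulate_cohort(cfg)
        assert (cohort["gout"] == 1).sum() == 120
        assert (cohort["gout"] == 0).sum() == 80
        assert cohort["sample_id"].is_unique

    def test_null_locus_balanced_between_strata(self):
        # with OR = 1 the carrier frequency difference between cases and
        # controls should sit within 3 binomial SDs of zero
        f = 0.2
        cfg = CohortConfig(
            n_cases=5000,
            n_controls=5000,
            cnv_loci=(CnvLocus("1", 1_000_001, 1_200_000, cn=1, frequency=uniform_freq(f),
                               odds_ratio=1.0, name="null"),),
            seed=3,
        )
        cohort, truth = simulate_cohort(cfg)
        carrier = truth.carriers["null"].reindex(cohort["sample_id"]).to_numpy()
        case = (cohort["gout"] == 1).to_numpy()
        diff = carrier[case].mean() - carrier[~case].mean()
        sd = np.sqrt(f * (1 - f) * (1 / case.sum() + 1 / (~case).sum()))
        assert abs(diff) < 3 * sd

    def test_control_frequency_matches_configuration(self):
        f = 0.10
        cfg = CohortConfig(
            n_cases=100,
            n_controls=5000,
            cnv_loci=(CnvLocus("1", 1_000_001, 1_200_000, cn=1, frequency=uniform_freq(f),
                               odds_ratio=1.0, name="null"),),
            seed=4,
        )
        cohort, truth = simulate_cohort(cfg)
        controls = cohort.loc[cohort["gout"] == 0, "sample_id"]
        obs = truth.carriers.loc[controls, "null"].mean()
        assert abs(obs - f) < 3 * np.sqrt(f * (1 - f) / len(controls))

    def test_unachievable_counts_fail_loudly(self):
        cfg = CohortConfig(
            n_cases=500,
            n_controls=0,
            covariate_model=CovariateModel(intercept=-30.0, batch={"b1": 0.0, "b2": 0.0}),
            seed=5,
        )
        with pytest.raises(ConfigurationError, match="case/control"):
            simulate_cohort(cfg)


class TestSignals:
    def test_noise_free_diploid_track(self, clean_config):
        cfg = CohortConfig(
            n_cases=1, n_controls=1,
            chromosome_lengths={"1": 2_000_000},
            lrr_noise_sd=0.0, baf_noise_sd=0.0, wave_amplitude=0.0,
            batch_effects={"b1": 0.0},
            covariate_model=CovariateModel(batch={"b1": 0.0}),
            seed=6,
        )
        m = simulate_snp_map(cfg)
        cohort, truth = simulate_cohort(cfg, m)
        prof = render_lrr_baf(cohort["sample_id"].iloc[0], truth, m, cfg,
                              batch=cohort["batch"].iloc[0])
        assert (prof.data["lrr"] == 0).all()
        assert prof.data["baf"].isin([0.0, 0.5, 1.0]).all()

    def test_noise_free_deletion_band_structure(self, clean_config):
        m = simulate_snp_map(clean_config)
        cohort, truth = simulate_cohort(clean_config, m)
        sid = cohort["sample_id"].iloc[0]
        prof = render_lrr_baf(sid, truth, m, clean_config, batch="b1")
        inside = prof.data["position"].between(1_000_001, 1_400_000)
        assert (prof.data.loc[inside, "lrr"] == -0.66).all()
        assert not (prof.data.loc[inside, "baf"] == 0.5).any()
        assert prof.data.loc[inside, "baf"].isin([0.0, 1.0]).all()
        dup = prof.data["position"].between(3_000_001, 3_400_000)
        assert (prof.data.loc[dup, "lrr"] == 0.40).all()
        assert prof.data.loc[dup, "baf"].isin([0.0, 1 / 3, 2 / 3, 1.0]).all()

    def test_segment_mean_lrr_obeys_clt_bound(self):
        cfg = CohortConfig(
            n_cases=1, n_controls=1,
            chromosome_lengths={"1": 4_000_000},
            snp_density=100.0,
            cnv_loci=(CnvLocus("1", 1_000_001, 3_000_000, cn=1, frequency=uniform_freq(1.0)),),
            wave_amplitude=0.0,
            batch_effects={"b1": 0.0},
            covariate_model=CovariateModel(batch={"b1": 0.0}),
            seed=8,
        )
        m = simulate_snp_map(cfg)
        cohort, truth = simulate_cohort(cfg, m)
        prof = render_lrr_baf(cohort["sample_id"].iloc[0], truth, m, cfg, batch="b1")
        seg = prof.data[prof.data["position"].between(1_000_001, 3_000_000)]
        assert len(seg) >= 150
        tol = 3 * cfg.lrr_noise_sd / np.sqrt(len(seg))
        assert abs(seg["lrr"].mean() - (-0.66)) < tol

    def test_same_seed_renders_identical_signal(self, noisy_config, noisy_data):
        sid = noisy_data["cohort"]["sample_id"].iloc[0]
        again = render_lrr_baf(sid, noisy_data["truth"], noisy_data["map"], noisy_config,
                               batch=noisy_data["cohort"]["batch"].iloc[0])
        pd.testing.assert_frame_equal(noisy_data["profiles"][sid].data, again.data)


class TestDepth:
    def _one_sample(self, cn, seed):
        cfg = CohortConfig(
            n_cases=1, n_controls=1,
            chromosome_lengths={"1": 1_000_000},
            cnv_loci=(CnvLocus("1", 200_001, 700_000, cn=cn, frequency=uniform_freq(1.0)),)
            if cn != 2 else (),
            seed=seed,
        )
        cohort, truth = simulate_cohort(cfg)
        sid = cohort["sample_id"].iloc[0]
        return cfg, render_wgs_depth(sid, truth, cfg, bin_size=1000)

    def test_diploid_background_depth(self):
        cfg, depth = self._one_sample(2, 9)
        # 1000 Poisson(30) bins: mean within 3 SDs of 30
        assert abs(depth["depth"].mean() - 30.0) < 3 * np.sqrt(30.0 / len(depth))

    @pytest.mark.parametrize("cn,ratio", [(1, 0.5), (3, 1.5), (0, 0.0)])
    def test_cnv_depth_ratio(self, cn, ratio):
        cfg, depth = self._one_sample(cn, 10 + cn)
        inside = depth[(depth["start"] >= 200_000) & (depth["end"] <= 700_000)]
        lam = 30.0 * ratio
        obs = inside["depth"].mean() / 30.0
        tol = 3 * np.sqrt(max(lam, 0.04) / len(inside)) / 30.0
        assert abs(obs - ratio) < max(tol, 0.01)


def test_biomarker_medians_ordered_by_copy_number():
    cfg = CohortConfig(n_cases=300, n_controls=300, seed=12)
    cohort, _ = simulate_cohort(cfg)
    rng = np.random.default_rng(0)
    genotype = pd.Series(rng.choice([0, 1, 2], size=len(cohort)), index=cohort["sample_id"])
    levels = simulate_biomarker(cohort, genotype, cfg)
    med = levels.groupby(genotype).median()
    assert med[0] < med[1] < med[2]
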