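import numpy as np
import pytest
from scipy.stats import multivariate_normal

import mrkit as mk
from mrkit.simdata import SimConfigError, bvn_cdf, _make_variants


def small_cfg(**kw):
    base = dict(m_snps=30, n_causal=30, n_exposure=5000, n_outcome=5000,
                n_ref=1000, h2_x=0.05, seed=1)
    base.update(kw)
    return mk.SimConfig(**base)


class TestConfig:
    @pytest.mark.parametrize("kw", [
        dict(n_causal=60, m_snps=50),
        dict(h2_x=1.0),
        dict(pleio_fraction=1.5),
        dict(block_size=100, m_snps=50),
        dict(maf_range=(0.001, 0.4)),
        dict(outcome_type="binary", prevalence=0.0),
        dict(pleiotropy_mode="weird"),
    ])
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(SimConfigError):
            small_cfg(**kw)


class TestBvnCdf:
    def test_matches_scipy_mvn(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            h, k = rng.normal(0, 1.5, 2)
            r = rng.uniform(-0.95, 0.95)
            ref = multivariate_normal(mean=[0, 0], cov=[[1, r], [r, 1]]).cdf([h, k])
            assert bvn_cdf(h, k, r) == pytest.approx(ref, abs=1e-10)

    def test_zero_threshold_closed_form(self):
        # P(Z1<0, Z2<0) = 1/4 + arcsin(rho)/(2 pi)
        for r in (-0.6, 0.0, 0.5, 0.9):
            assert bvn_cdf(0.0, 0.0, r) == pytest.approx(
                0.25 + np.arcsin(r) / (2 * np.pi), abs=1e-9)


class TestReferencePanelSim:
    def test_determinism(self):
        a = mk.simulate_reference_panel(small_cfg())
        b = mk.simulate_reference_panel(small_cfg())
        assert np.array_equal(a.dosages, b.dosages)
        assert a.variants == b.variants

    def test_independent_snps_have_null_r2(self):
        panel = mk.simulate_reference_panel(small_cfg(ld_rho=0.0, n_ref=2000))
        m = len(panel.variants)
        vals = [panel.r2(i, j) for i in range(m) for j in range(i + 1, m)]
        assert np.mean(vals) <= 3 / panel.n_ref

    def test_ld_target_realized_in_dosage_r2(self):
        # dosage-level r^2 should match ld_rho^2 = 0.81; near-equal MAFs keep
        # the target attainable (high LD requires similar allele frequencies)
        r2s = []
        for seed in range(5):
            cfg = small_cfg(ld_rho=0.9, block_size=10, maf_range=(0.29, 0.31),
                            n_ref=5000, seed=seed)
            panel = mk.simulate_reference_panel(cfg)
            r2s += [panel.r2(j - 1, j) for j in range(1, 30) if j % 10 != 0]
        assert abs(np.mean(r2s) - 0.81) < 0.05

    def test_eaf_matches_configured_maf(self):
        cfg = small_cfg(n_ref=4000)
        panel = mk.simulate_reference_panel(cfg)
        _, mafs = _make_variants(cfg)
        sample_eaf = panel.dosages.mean(axis=0) / 2
        tol = 4 * np.sqrt(mafs * (1 - mafs) / (2 * cfg.n_ref))
        assert np.all(np.abs(sample_eaf - mafs) < tol)


class TestTwoSampleStats:
    def test_determinism_and_truth_shape(self):
        e1, o1, t1 = mk.simulate_two_sample_stats(small_cfg())
        e2, o2, t2 = mk.simulate_two_sample_stats(small_cfg())
        assert [r.beta for r in e1.records] == [r.beta for r in e2.records]
        assert [r.beta for r in o1.records] == [r.beta for r in o2.records]
        assert np.array_equal(t1.gamma, t2.gamma)
        assert len(t1.gamma) == len(t1.alpha) == 30

    def test_se_scales_inverse_sqrt_heterozygosity(self):
        # se_j ~ sigma / sqrt(2 n p_j q_j): the MAF-0.1 SNP's se exceeds the
        # MAF-0.5 SNP's by sqrt(0.25/0.09) ~ 1.67; check the whole profile
        cfg = mk.SimConfig(m_snps=60, n_causal=1, h2_x=0.001, n_exposure=20000,
                           n_outcome=2000, n_ref=100, maf_range=(0.05, 0.5), seed=4)
        exp, _, _ = mk.simulate_two_sample_stats(cfg)
        eaf = np.array([r.eaf for r in exp.records])
        se = np.array([r.se for r in exp.records])
        scaled = se * np.sqrt(2 * eaf * (1 - eaf))
        assert np.std(scaled) / np.mean(scaled) < 0.10
        lo, hi = scaled.min(), scaled.max()
        assert hi / lo < 1.3  # flat after heterozygosity scaling

    def test_exposure_pve_near_h2(self):
        cfg = small_cfg(n_exposure=20000)
        exp, _, _ = mk.simulate_two_sample_stats(cfg)
        pve = sum(2 * r.eaf * (1 - r.eaf) * r.beta**2 for r in exp.records)
        assert pve == pytest.approx(cfg.h2_x, rel=0.35)

    def test_binary_outcome_case_count_and_scale(self):
        cfg = small_cfg(outcome_type="binary", prevalence=0.2, n_outcome=8000)
        _, outc, _ = mk.simulate_two_sample_stats(cfg)
        assert outc.trait_type == "binary"
        n_cases = outc.records[0].n_cases
        assert n_cases == pytest.approx(0.2 * 8000, abs=2)

    def test_score_approximation_close_to_exact_logistic(self):
        cfg = small_cfg(m_snps=6, n_causal=6, block_size=6, h2_x=0.05, n_outcome=6000,
                        outcome_type="binary", prevalence=0.25)
        _, approx, _ = mk.simulate_two_sample_stats(cfg)
        cfg_exact = small_cfg(m_snps=6, n_causal=6, block_size=6, h2_x=0.05, n_outcome=6000,
                              outcome_type="binary", prevalence=0.25,
                              exact_logistic=True)
        _, exact, _ = mk.simulate_two_sample_stats(cfg_exact)
        b1 = np.array([r.beta for r in approx.records])
        b2 = np.array([r.beta for r in exact.records])
        assert np.corrcoef(b1, b2)[0, 1] > 0.99
        assert np.max(np.abs(b1 - b2)) < 0.25 * np.std(b2) + 0.02

    def test_sample_overlap_reuses_exposure_genotypes(self):
        full = small_cfg(overlap_fraction=1.0, theta=1.0, h2_x=0.2)
        none = small_cfg(overlap_fraction=0.0, theta=1.0, h2_x=0.2)
        # identical x in both samples under full overlap makes exposure and
        # outcome betas strongly collinear
        e_f, o_f, _ = mk.simulate_two_sample_stats(full)
        e_n, o_n, _ = mk.simulate_two_sample_stats(none)
        def corr(e, o):
            return np.corrcoef([r.beta for r in e.records], [r.beta for r in o.records])[0, 1]
        assert corr(e_f, o_f) > corr(e_n, o_n)


class TestHarmonizationNoise:
    def test_zero_fractions_identity(self):
        exp, _, _ = mk.simulate_two_sample_stats(small_cfg())
        same = mk.inject_harmonization_noise(exp, 0.0, 0.0, seed=3)
        assert same.records == exp.records

    def test_total_swap_negates_all_betas(self):
        exp, _, _ = mk.simulate_two_sample_stats(small_cfg())
        swapped = mk.inject_harmonization_noise(exp, 1.0, 0.0, seed=3)
        for a, b in zip(exp.records, swapped.records):
            assert b.key.ea == a.key.oa and b.key.oa == a.key.ea
            assert b.beta == -a.beta
            assert b.eaf == pytest.approx(1 - a.eaf)

    def test_noise_then_harmonize_recovers_betas(self):
        exp, outc, _ = mk.simulate_two_sample_stats(small_cfg(seed=8))
        noisy = mk.inject_harmonization_noise(outc, 0.4, 0.4, seed=9)
        hset = mk.harmonize_tables(exp, noisy)
        orig = outc.by_position()
        recovered = [i for i in hset.instruments
                     if abs(i.beta_y - orig[i.key.position_id()].beta) < 1e-12]
        # every retained instrument must carry the original outcome effect
        assert len(recovered) == hset.n_iv
        assert hset.n_iv + len(hset.dropped) == len(exp)
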