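import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wpair import simulate as sim


class TestSolveHaplotypes:
    def test_worked_example_maf01_r2_024(self):
        hap = sim.solve_haplotypes(0.1, 0.1, 0.24)
        assert hap.d == pytest.approx(np.sqrt(0.24) * 0.09, rel=1e-12)
        assert hap.freqs[3] == pytest.approx(0.01 + np.sqrt(0.24) * 0.09, rel=1e-9)
        assert hap.r2 == pytest.approx(0.24, abs=1e-12)

    def test_zero_r2_gives_product_frequencies(self):
        hap = sim.solve_haplotypes(0.4, 0.4, 0.0)
        assert hap.freqs[3] == pytest.approx(0.16)
        np.testing.assert_allclose(
            hap.freqs, [0.36, 0.24, 0.24, 0.16], rtol=1e-12
        )

    def test_infeasible_r2_names_feasible_range(self):
        with pytest.raises(ValueError, match="feasible range"):
            sim.solve_haplotypes(0.01, 0.5, 0.9)

    @given(
        st.floats(0.01, 0.49),
        st.floats(0.01, 0.49),
        st.floats(0.0, 0.95),
    )
    @settings(max_examples=60, deadline=None)
    def test_analytic_r2_matches_target(self, maf1, maf2, frac):
        p1, q1, p2, q2 = maf1, 1 - maf1, maf2, 1 - maf2
        r2_max = min(p1 * q2, q1 * p2) ** 2 / (p1 * q1 * p2 * q2)
        target = frac * min(r2_max, 1.0)
        hap = sim.solve_haplotypes(maf1, maf2, target)
        assert hap.r2 == pytest.approx(target, abs=1e-12)
        assert hap.maf1 == pytest.approx(maf1, abs=1e-12)
        assert hap.maf2 == pytest.approx(maf2, abs=1e-12)


class TestGenotypeDistribution:
    def test_no_ld_het_het_probability(self):
        hap = sim.solve_haplotypes(0.5, 0.5, 0.0)
        probs = sim.genotype_distribution(hap)
        assert probs[3 * 1 + 1] == pytest.approx(0.25)

    def test_no_ld_factorizes_as_outer_product(self):
        hap = sim.solve_haplotypes(0.3, 0.15, 0.0)
        probs = sim.genotype_distribution(hap).reshape(3, 3)
        hwe1 = np.array([0.7**2, 2 * 0.3 * 0.7, 0.3**2])
        hwe2 = np.array([0.85**2, 2 * 0.15 * 0.85, 0.15**2])
        np.testing.assert_allclose(probs, np.outer(hwe1, hwe2), rtol=1e-12)

    def test_perfect_ld_only_concordant_categories(self):
        hap = sim.solve_haplotypes(0.2, 0.2, 1.0)
        probs = sim.genotype_distribution(hap).reshape(3, 3)
        off = probs - np.diag(np.diag(probs))
        np.testing.assert_allclose(off, 0.0, atol=1e-12)

    def test_sums_to_one(self):
        hap = sim.solve_haplotypes(0.13, 0.27, 0.1)
        assert sim.genotype_distribution(hap).sum() == pytest.approx(1.0)


class TestCaseControlDistributions:
    def test_null_penetrance_leaves_distribution_unchanged(self):
        probs = sim.genotype_distribution(sim.solve_haplotypes(0.3, 0.3, 0.0))
        pen = sim.PenetranceModel(form="logit_linear", alpha=-2.0)
        case, control, info = sim.case_control_distributions(probs, pen)
        np.testing.assert_allclose(case, probs, rtol=1e-12)
        np.testing.assert_allclose(control, probs, rtol=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_total_probability_identity(self, seed):
        rng = np.random.default_rng(seed)
        probs = sim.genotype_distribution(
            sim.solve_haplotypes(rng.uniform(0.05, 0.45), rng.uniform(0.05, 0.45), 0.0)
        )
        pen = sim.PenetranceModel(
            form="logit_linear",
            alpha=rng.normal(-2, 0.5),
            beta=rng.normal(0, 0.5),
            gamma=rng.normal(0, 0.5),
            interaction=rng.normal(0, 0.3),
        )
        case, control, info = sim.case_control_distributions(probs, pen)
        k = info["prevalence"]
        np.testing.assert_allclose(k * case + (1 - k) * control, probs, atol=1e-12)

    def test_positive_beta_enriches_cases(self):
        probs = sim.genotype_distribution(sim.solve_haplotypes(0.2, 0.2, 0.0))
        pen = sim.PenetranceModel(form="logit_linear", alpha=-2.2, beta=0.6)
        _, _, info = sim.case_control_distributions(probs, pen)
        assert info["case_maf1"] > info["control_maf1"]

    def test_degenerate_penetrance_rejected(self):
        probs = sim.genotype_distribution(sim.solve_haplotypes(0.2, 0.2, 0.0))
        pen = sim.PenetranceModel(form="table", log_odds=np.full((3, 3), 1e4))
        with pytest.raises(ValueError, match="penetrance"):
            sim.case_control_distributions(probs, pen)


class TestCalibration:
    def test_control_targets_hit_exactly(self):
        pen = sim.PenetranceModel(
            form="logit_linear", alpha=-2.2, beta=0.25, gamma=0.25, interaction=0.25
        )
        hap = sim.calibrate_control_scenario(0.1, 0.24, pen)
        _, control, _ = sim.case_control_distributions(
            sim.genotype_distribution(hap), pen
        )
        m = sim.dosage_moments(control)
        assert m["maf1"] == pytest.approx(0.1, abs=1e-9)
        assert m["r2"] == pytest.approx(0.24, abs=1e-9)

    def test_complex_stand_in_is_not_allelic(self):
        """The complex-effects table must not lie in the allelic model span."""
        u = np.repeat(np.arange(3), 3).astype(float)
        v = np.tile(np.arange(3), 3).astype(float)
        x = np.column_stack([np.ones(9), u, v, u * v])
        lo = sim.COMPLEX_EFFECTS_LOG_ODDS.ravel()
        resid = lo - x @ np.linalg.lstsq(x, lo, rcond=None)[0]
        assert np.linalg.norm(resid) > 0.1

    def test_rare_scenario_stated_group_mafs(self):
        sc = sim.scenario_rare_ld_complex()
        _, _, info = sim.case_control_distributions(
            sim.genotype_distribution(sc.haplotypes), sc.penetrance
        )
        assert info["control_maf1"] == pytest.approx(0.01, abs=1e-6)
        assert info["control_r2"] == pytest.approx(0.64, abs=1e-6)
        assert info["case_maf1"] == pytest.approx(0.03, abs=0.01)


class TestSampling:
    def test_deterministic_given_seed_and_index(self):
        sc = sim.scenario_null_common(replicates=2, seed=12)
        a = sim.sample_replicate(sc, 1)
        b = sim.sample_replicate(sc, 1)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)

    def test_exact_group_sizes(self):
        sc = sim.scenario_null_common(replicates=1, seed=13)
        _, _, ph = sim.sample_replicate(sc, 0)
        assert (ph == 1).sum() == 500
        assert (ph == 0).sum() == 500

    def test_empirical_frequencies_match_analytic(self):
        sc = sim.scenario_lowmaf_ld(replicates=100, seed=14)
        case, control, _ = sim.case_control_distributions(
            sim.genotype_distribution(sc.haplotypes), sc.penetrance
        )
        counts = np.zeros(9)
        total = 0
        for rep in range(sc.replicates):
            g1, g2, ph = sim.sample_replicate(sc, rep)
            ctrl = ph == 0
            cat = 3 * g1[ctrl] + g2[ctrl]
            counts += np.bincount(cat, minlength=9)
            total += ctrl.sum()
        emp = counts / total
        se = np.sqrt(control * (1 - control) / total)
        assert np.all(np.abs(emp - control) <= 3 * se + 1e-9)


class TestEmpiricalR2:
    def test_identical_vectors(self):
        g = np.array([0, 1, 2, 1, 0, 2])
        assert sim.empirical_r2(g, g) == pytest.approx(1.0)

    def test_independent_snps_near_zero(self):
        rng = np.random.default_rng(15)
        g1 = rng.binomial(2, 0.3, 100_000)
        g2 = rng.binomial(2, 0.3, 100_000)
        assert sim.empirical_r2(g1, g2) < 1e-3

    def test_monomorphic_is_nan(self):
        assert np.isnan(sim.empirical_r2([1, 1, 1], [0, 1, 2]))


class TestScenarioConfig:
    def test_yaml_roundtrip(self, tmp_path):
        sc = sim.scenario_rare_ld_complex(replicates=7, seed=3)
        path = tmp_path / "sc.yaml"
        sc.to_yaml(path)
        back = sim.Scenario.from_yaml(path)
        np.testing.assert_allclose(back.haplotypes.freqs, sc.haplotypes.freqs)
        np.testing.assert_allclose(
            back.penetrance.log_odds_matrix(), sc.penetrance.log_odds_matrix()
        )
        assert (back.replicates, back.seed, back.label) == (7, 3, "rare-ld-complex")

    def test_yaml_roundtrip_logit_linear(self, tmp_path):
        sc = sim.scenario_main_effects_common(seed=5)
        path = tmp_path / "sc.yaml"
        sc.to_yaml(path)
        back = sim.Scenario.from_yaml(path)
        assert back.penetrance.beta == sc.penetrance.beta
        np.testing.assert_allclose(back.haplotypes.freqs, sc.haplotypes.freqs)
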