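"""Matched controls, genetic values, and the three adaptation tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from altadapt.core import AscertainedSet, PopulationCovariance
from altadapt.polygenic import (ControlSets, estimate_population_covariance,
                                explained_gap_fraction, freq_diff_test,
                                genetic_values, outlier_test,
                                overdispersion_test, sample_matched_controls,
                                single_snp_value_gap)
from altadapt.simulate import (PopulationTree, SimulationConfig,
                               simulate_frequency_panel)

from conftest import make_ascertained, make_panel, random_ascertained


@pytest.fixture(scope="module")
def drift_panel():
    tree = PopulationTree.default()
    return simulate_frequency_panel(tree, SimulationConfig(n_snps=8_000),
                                    rng=np.random.default_rng(31))


class TestMatchedControls:
    def test_controls_share_maf_bin(self, drift_panel, rng):
        asc = random_ascertained(drift_panel, 15, rng)
        ctl = sample_matched_controls(asc, drift_panel, n_sets=50, rng=rng)
        panel_bins = drift_panel.table["maf_bin"].to_numpy()
        asc_bins = panel_bins[drift_panel.index_of(asc.table["snp"])]
        for b in range(ctl.n_sets):
            assert np.array_equal(panel_bins[ctl.indices[b]], asc_bins)

    def test_controls_exclude_ascertained_and_within_set_duplicates(
            self, drift_panel, rng):
        asc = random_ascertained(drift_panel, 20, rng)
        ctl = sample_matched_controls(asc, drift_panel, n_sets=40, rng=rng)
        asc_idx = set(drift_panel.index_of(asc.table["snp"]))
        for b in range(ctl.n_sets):
            row = ctl.indices[b]
            assert len(set(row)) == len(row)
            assert not (set(row) & asc_idx)

    def test_bvalue_matching_honoured(self, drift_panel, rng):
        asc = random_ascertained(drift_panel, 10, rng)
        ctl = sample_matched_controls(asc, drift_panel, n_sets=30,
                                      match_bvalue=True, rng=rng)
        bbins = drift_panel.table["bvalue_bin"].to_numpy()
        asc_b = bbins[drift_panel.index_of(asc.table["snp"])]
        for b in range(ctl.n_sets):
            assert np.array_equal(bbins[ctl.indices[b]], asc_b)

    def test_single_eligible_snp_used_every_set_with_warning(self, caplog):
        panel = make_panel({"A": [0.11, 0.11, 0.31, 0.33, 0.35],
                            "B": [0.11, 0.11, 0.31, 0.33, 0.35]})
        asc = make_ascertained(["s1"], [0.5])
        with caplog.at_level("WARNING", logger="altadapt"):
            ctl = sample_matched_controls(asc, panel, n_sets=100,
                                          seed=0)
        assert "low control diversity" in caplog.text
        assert np.all(ctl.indices == 1)  # s2 is the only bin-mate

    def test_empty_cell_raises_naming_the_snp(self):
        panel = make_panel({"A": [0.11, 0.31, 0.33], "B": [0.11, 0.31, 0.33]})
        asc = make_ascertained(["s1"], [0.5])
        with pytest.raises(ValueError, match="s1"):
            sample_matched_controls(asc, panel, n_sets=10, seed=0)

    def test_draws_uniform_over_cell(self):
        """Three eligible bin-mates are each drawn with frequency
        1/3 within Monte-Carlo error."""
        panel = make_panel({"A": [0.30, 0.302, 0.304, 0.306, 0.9],
                            "B": [0.30, 0.302, 0.304, 0.306, 0.9]})
        asc = make_ascertained(["s1"], [0.5])
        ctl = sample_matched_controls(asc, panel, n_sets=10_000, seed=1)
        counts = np.bincount(ctl.indices[:, 0], minlength=5) / 10_000
        assert counts[0] == 0.0
        for j in (1, 2, 3):
            assert counts[j] == pytest.approx(1 / 3, abs=0.02)

    def test_seeded_and_reproducible(self, drift_panel, rng):
        asc = random_ascertained(drift_panel, 10, rng)
        c1 = sample_matched_controls(asc, drift_panel, n_sets=20, seed=5)
        c2 = sample_matched_controls(asc, drift_panel, n_sets=20, seed=5)
        assert np.array_equal(c1.indices, c2.indices)


class TestGeneticValues:
    def test_single_snp_value(self):
        panel = make_panel({"A": [0.4], "B": [0.2]})
        asc = make_ascertained(["s1"], [0.5])
        gv = genetic_values(asc, panel, ["A"])
        assert gv.z[0] == pytest.approx(2 * 0.5 * 0.4)

    def test_hand_computed_fixture(self):
        """3 SNPs x 2 populations against direct summation by hand."""
        panel = make_panel({"A": [0.4, 0.1, 0.9], "B": [0.2, 0.3, 0.5]})
        asc = make_ascertained(["s1", "s2", "s3"], [0.5, 0.2, 0.1])
        gv = genetic_values(asc, panel, ["A", "B"])
        assert gv.z[0] == pytest.approx(0.62)
        assert gv.z[1] == pytest.approx(0.42)
        assert gv.v_a == pytest.approx(0.244)

    def test_inc_allele_orientation_flips_frequency(self):
        panel = make_panel({"A": [0.4], "B": [0.2]})
        asc = make_ascertained(["s1"], [0.5], inc_alleles=["A"])  # ref allele
        gv = genetic_values(asc, panel, ["A", "B"])
        assert gv.z[0] == pytest.approx(2 * 0.5 * 0.6)

    def test_all_zero_alphas_degenerate(self):
        panel = make_panel({"A": [0.4, 0.3], "B": [0.2, 0.5]})
        asc = make_ascertained(["s1", "s2"], [0.0, 0.0])
        gv = genetic_values(asc, panel, ["A", "B"])
        assert np.allclose(gv.z, 0.0)
        assert gv.v_a == 0.0
        with pytest.raises(ValueError, match="degenerate"):
            gv.standardized()

    def test_single_snp_gap_bookkeeping(self):
        assert single_snp_value_gap(0.386, 0.743) == pytest.approx(0.5736, abs=1e-4)
        assert explained_gap_fraction(0.386, 0.743, 1.1) == pytest.approx(
            0.5214, abs=1e-3)


class TestFreqDiff:
    def test_identical_populations_give_zero_statistic(self, drift_panel, rng):
        asc = random_ascertained(drift_panel, 10, rng)
        panel = drift_panel.copy()
        panel.table["LOW1"] = panel.table["TARGET"]
        ctl = sample_matched_controls(asc, panel, n_sets=99, rng=rng)
        res = freq_diff_test(asc, panel, "TARGET", "LOW1", ctl,
                             direction="lower")
        assert res.statistic == 0.0

    def test_plus_one_counting_rule(self):
        """Observed -0.30 against null means {-0.1, 0, +0.1}: one-sided
        lower p = (0+1)/(3+1)."""
        panel = make_panel({"A": [0.05, 0.2, 0.3, 0.4],
                            "B": [0.35, 0.3, 0.3, 0.3]})
        asc = make_ascertained(["s1"], [0.5])
        ctl = ControlSets(indices=np.array([[1], [2], [3]]),
                          ascertained_snps=["s1"], match_bvalue=False,
                          maf_source="mean",
                          inc_is_minor=np.array([True]))
        res = freq_diff_test(asc, panel, "A", "B", ctl, direction="lower")
        assert res.statistic == pytest.approx(-0.30)
        assert np.allclose(np.sort(res.extra["null_means"]),
                           [-0.1, 0.0, 0.1])
        assert res.p_empirical == pytest.approx(0.25)

    def test_shifted_ascertained_set_is_always_extreme(self):
        """popA = popB everywhere except a +0.2 shift at ascertained SNPs:
        no null set can reach the observed statistic, so p = 1/(B+1)."""
        rng = np.random.default_rng(41)
        base = rng.uniform(0.1, 0.7, size=2_000)
        panel = make_panel({"A": base.copy(), "B": base.copy()})
        asc_ids = [f"s{i}" for i in rng.choice(2_000, 20, replace=False) + 1]
        idx = panel.index_of(asc_ids)
        panel.table.loc[idx, "A"] = panel.table.loc[idx, "A"] + 0.2
        panel.annotate_bins(bvalues=panel.table["bvalue"].to_numpy())
        asc = make_ascertained(asc_ids, np.abs(rng.normal(0, 0.3, 20)))
        ctl = sample_matched_controls(asc, panel, n_sets=999, rng=rng)
        res = freq_diff_test(asc, panel, "A", "B", ctl, direction="higher")
        assert res.statistic == pytest.approx(0.2)
        assert res.p_empirical == pytest.approx(1 / 1000)

    def test_empirical_p_bounds_and_direction(self, drift_panel, rng):
        asc = random_ascertained(drift_panel, 10, rng)
        ctl = sample_matched_controls(asc, drift_panel, n_sets=200, rng=rng)
        for direction in ("lower", "higher"):
            res = freq_diff_test(asc, drift_panel, "TARGET", "LOW1", ctl,
                                 direction=direction)
            assert 1 / 201 <= res.p_empirical <= 1.0
        with pytest.raises(ValueError):
            freq_diff_test(asc, drift_panel, "TARGET", "LOW1", ctl,
                           direction="sideways")


class TestOverdispersion:
    def test_identical_genetic_values_give_zero_q(self, rng):
        panel = make_panel({"A": [0.3, 0.4], "B": [0.3, 0.4],
                            "C": [0.3, 0.4]})
        asc = make_ascertained(["s1", "s2"], [0.5, 0.2])
        ctl = ControlSets(indices=np.zeros((5, 2), dtype=int) + [[0, 1]],
                          ascertained_snps=["s1", "s2"], match_bvalue=False,
                          maf_source="mean",
                          inc_is_minor=np.array([True, True]))
        fcov = PopulationCovariance(np.eye(3) - 1 / 3, ["A", "B", "C"], 100)
        res = overdispersion_test(asc, panel, fcov, ctl)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_parametric == pytest.approx(1.0)

    def test_two_population_closed_form(self, drift_panel, rng):
        """M = 2: Q equals the explicit single-contrast quadratic form
        z_u^2 / f_u with u = (1, -1)/sqrt(2)."""
        asc = random_ascertained(drift_panel, 12, rng)
        pops = ["TARGET", "LOW1"]
        ctl = sample_matched_controls(asc, drift_panel, n_sets=50, rng=rng)
        fcov = estimate_population_covariance(drift_panel, pops,
                                              exclude_snps=asc.table["snp"])
        res = overdispersion_test(asc, drift_panel, fcov, ctl,
                                  populations=pops)
        gv = genetic_values(asc, drift_panel, pops)
        zp = gv.standardized()
        u = np.array([1.0, -1.0]) / np.sqrt(2)
        q_oracle = (u @ zp) ** 2 / (u @ fcov.matrix @ u)
        assert res.statistic == pytest.approx(q_oracle, rel=1e-9)
        assert res.extra["dof"] == 1

    def test_invariant_to_constant_shift_and_reordering(self, drift_panel,
                                                        rng):
        asc = random_ascertained(drift_panel, 12, rng)
        ctl = sample_matched_controls(asc, drift_panel, n_sets=50, rng=rng)
        pops = list(drift_panel.populations)
        fcov = estimate_population_covariance(drift_panel, pops,
                                              exclude_snps=asc.table["snp"])
        q1 = overdispersion_test(asc, drift_panel, fcov, ctl).statistic
        # reorder populations
        perm = pops[::-1]
        fcov_perm = estimate_population_covariance(
            drift_panel, perm, exclude_snps=asc.table["snp"])
        q2 = overdispersion_test(asc, drift_panel, fcov_perm, ctl,
                                 populations=perm).statistic
        assert q1 == pytest.approx(q2, rel=1e-9)

    def test_null_q_follows_chi_square_distribution(self):
        """Null drift replicates: Q matches chi^2_{M-1} (KS test)."""
        tree = PopulationTree.default()
        rng = np.random.default_rng(43)
        qs = []
        for _ in range(300):
            panel = simulate_frequency_panel(
                tree, SimulationConfig(n_snps=4_000), rng=rng)
            asc = random_ascertained(panel, 30, rng)
            fcov = estimate_population_covariance(
                panel, exclude_snps=asc.table["snp"])
            gv = genetic_values(asc, panel)
            from altadapt.polygenic import _pinv_quadratic
            qs.append(float(_pinv_quadratic(fcov.matrix,
                                            gv.standardized())[0]))
        ks = stats.kstest(qs, lambda x: stats.chi2.cdf(x, df=5))
        assert ks.pvalue > 0.01


class TestOutlier:
    def test_zero_deviation_gives_zero_statistic(self):
        panel = make_panel({"A": [0.3, 0.4], "B": [0.3, 0.4],
                            "C": [0.3, 0.4]})
        asc = make_ascertained(["s1", "s2"], [0.5, 0.2])
        ctl = ControlSets(indices=np.array([[0, 1]] * 5),
                          ascertained_snps=["s1", "s2"], match_bvalue=False,
                          maf_source="mean",
                          inc_is_minor=np.array([True, True]))
        fcov = PopulationCovariance(np.eye(3) - 1 / 3, ["A", "B", "C"], 100)
        res = outlier_test(asc, panel, ["A"], fcov, ctl)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_exchangeable_closed_form(self, drift_panel, rng):
        """Three exchangeable populations: the statistic matches
        brute-force MVN conditioning in the drop-one coordinate system."""
        asc = random_ascertained(drift_panel, 12, rng)
        pops = ["TARGET", "LOW1", "LOW2"]
        c = 0.015
        fmat = c * (np.eye(3) - np.ones((3, 3)) / 3)
        fcov = PopulationCovariance(fmat, pops, 1000)
        ctl = sample_matched_controls(asc, drift_panel, n_sets=50, rng=rng)
        res = outlier_test(asc, drift_panel, ["TARGET"], fcov, ctl,
                           populations=pops)
        zp = genetic_values(asc, drift_panel, pops).standardized()
        # oracle: subset {0}, conditioning on {1} (index 2 absorbs the
        # sum-zero constraint); explicit scalar MVN conditioning
        cond_mean = fmat[0, 1] / fmat[1, 1] * zp[1]
        cond_var = fmat[0, 0] - fmat[0, 1] ** 2 / fmat[1, 1]
        oracle = (zp[0] - cond_mean) / np.sqrt(cond_var)
        assert res.statistic == pytest.approx(oracle, rel=1e-9)

    def test_group_subset_supported(self, drift_panel, rng):
        asc = random_ascertained(drift_panel, 12, rng)
        ctl = sample_matched_controls(asc, drift_panel, n_sets=80, rng=rng)
        fcov = estimate_population_covariance(
            drift_panel, exclude_snps=asc.table["snp"])
        res = outlier_test(asc, drift_panel, ["TARGET", "SISTER"], fcov, ctl)
        assert np.isfinite(res.statistic)
        assert 1 / 81 <= res.p_empirical <= 1.0

    def test_subset_must_be_strict_and_known(self, drift_panel, rng):
        asc = random_ascertained(drift_panel, 8, rng)
        ctl = sample_matched_controls(asc, drift_panel, n_sets=10, rng=rng)
        fcov = estimate_population_covariance(drift_panel)
        with pytest.raises(ValueError):
            outlier_test(asc, drift_panel, list(drift_panel.populations),
                         fcov, ctl)
        with pytest.raises(ValueError):
            outlier_test(asc, drift_panel, [], fcov, ctl)
        with pytest.raises(KeyError):
            outlier_test(asc, drift_panel, ["ATLANTIS"], fcov, ctl)


class TestDropOneRerun:
    def test_excluding_a_dominant_snp_by_set_subtraction(self, drift_panel):
        """The single-locus exclusion analysis is a drop-one re-run: the
        same code path on the reduced set, no special casing."""
        rng = np.random.default_rng(53)
        asc = random_ascertained(drift_panel, 15, rng)
        # make one SNP dominate the signal
        asc.table.loc[0, "alpha"] = 5.0
        dropped = asc.drop_snps(asc.table.loc[0, "snp"])
        assert len(dropped) == len(asc) - 1
        ctl_full = sample_matched_controls(asc, drift_panel, n_sets=200,
                                           seed=3)
        ctl_drop = sample_matched_controls(dropped, drift_panel, n_sets=200,
                                           seed=3)
        full = freq_diff_test(asc, drift_panel, "TARGET", "LOW1", ctl_full)
        part = freq_diff_test(dropped, drift_panel, "TARGET", "LOW1",
                              ctl_drop)
        assert full.statistic != part.statistic
        assert 0 < part.p_empirical <= 1
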