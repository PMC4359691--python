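import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from bopscan import annotation as ann
from bopscan import dmr
from bopscan.simulate import CohortSpec, generate_cohort, generate_manifest

from conftest import two_group_design


def _design_with_cov(n, seed=0):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        {
            "intercept": np.ones(n),
            "group": rng.permutation([1.0] * (n // 2) + [0.0] * (n - n // 2)),
            "cov": rng.normal(size=n),
        },
        index=[f"s{i}" for i in range(n)],
    )
    return dmr.DesignMatrix(X=X, group_col="group", group_a="DSP", group_b="DSS")


class TestWindowManova:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("statistic", ["pillai", "wilks"])
    def test_matches_independent_multivariate_fit(self, seed, statistic):
        """Group-effect p agrees with statsmodels' MANOVA to near machine precision."""
        from statsmodels.multivariate.manova import MANOVA

        rng = np.random.default_rng(seed)
        design = _design_with_cov(30, seed)
        W = rng.normal(0.5, 0.1, size=(3, 30))
        p, degen = dmr.window_manova_p(W, design, statistic=statistic)
        assert not degen
        df = pd.DataFrame(W.T, columns=["y1", "y2", "y3"])
        df["group"] = design.X["group"].to_numpy()
        df["cov"] = design.X["cov"].to_numpy()
        table = MANOVA.from_formula("y1 + y2 + y3 ~ group + cov", data=df).mv_test()
        row = "Pillai's trace" if statistic == "pillai" else "Wilks' lambda"
        expected = table.results["group"]["stat"].loc[row, "Pr > F"]
        assert p == pytest.approx(float(expected), abs=1e-10)

    def test_strong_shift_is_detected(self):
        rng = np.random.default_rng(4)
        design = two_group_design(29, 29)
        W = rng.normal(0.4, 0.05, size=(3, 58))
        W[:, :29] += 0.3
        p, _ = dmr.window_manova_p(W, design)
        assert p < 1e-6

    def test_constant_probe_gives_degenerate_flag_not_crash(self):
        design = two_group_design(10, 10)
        W = np.vstack([np.full(20, 0.5), np.random.default_rng(0).normal(0.5, 0.1, (2, 20))])
        p, degen = dmr.window_manova_p(W, design)
        assert degen and p == 1.0

    def test_window_must_have_three_probes(self):
        design = two_group_design(5, 5)
        with pytest.raises(ValueError, match="3 probe rows"):
            dmr.window_manova_p(np.zeros((2, 10)), design)

    def test_too_few_samples_raise(self):
        design = two_group_design(3, 3)
        with pytest.raises(dmr.DesignError):
            dmr.window_manova_p(np.random.default_rng(0).normal(size=(3, 6)), design)


class TestScanBops:
    def _scan_fixture(self, sizes, n_a=15, n_b=15, seed=0):
        rng = np.random.default_rng(seed)
        rows, bops = [], []
        probes = []
        for b, size in enumerate(sizes):
            ids = tuple(f"b{b}p{i}" for i in range(size))
            bops.append(
                ann.Bop(
                    bop_id=f"B|I{b}|Island",
                    class_label="B",
                    region_key=(f"I{b}", "Island"),
                    chromosome="1",
                    probes=ids,
                    positions=tuple(range(10, 10 + 10 * size, 10)),
                )
            )
            probes.extend(ids)
        beta = pd.DataFrame(
            rng.uniform(0.3, 0.7, size=(len(probes), n_a + n_b)),
            index=probes,
            columns=[f"s{i}" for i in range(n_a + n_b)],
        )
        return bops, beta, two_group_design(n_a, n_b)

    def test_window_counts(self):
        bops, beta, design = self._scan_fixture([3, 5])
        results, _ = dmr.scan_bops(bops, beta, design, keep_window_ps=True)
        by_id = {r.bop_id: r for r in results}
        assert by_id["B|I0|Island"].n_windows == 1
        assert by_id["B|I1|Island"].n_windows == 3

    def test_min_never_exceeds_any_window_p(self):
        bops, beta, design = self._scan_fixture([4, 5, 6], seed=1)
        results, _ = dmr.scan_bops(bops, beta, design, keep_window_ps=True)
        for r in results:
            assert r.min_window_p == min(r.window_ps)
            assert all(r.min_window_p <= p for p in r.window_ps)

    def test_small_bops_are_excluded_with_reason(self):
        bops, beta, design = self._scan_fixture([2, 3])
        results, excluded = dmr.scan_bops(bops, beta, design)
        assert len(results) == 1
        assert excluded[0][0] == "B|I0|Island" and "2 probes" in excluded[0][1]

    def test_bop_with_probes_lost_to_qc_is_excluded(self):
        bops, beta, design = self._scan_fixture([4])
        beta = beta.drop(index=["b0p0", "b0p1"])  # only 2 probes left
        results, excluded = dmr.scan_bops(bops, beta, design)
        assert not results and "after QC" in excluded[0][1]

    def test_planted_bop_attains_smallest_p(self, planted_run):
        results = planted_run["results"]
        planted = set(planted_run["truth"].planted)
        best = min(results, key=lambda r: r.min_window_p)
        assert best.bop_id in planted

    def test_q_values_are_bh_of_min_p_within_class(self, planted_run):
        results = planted_run["results"]
        a_results = [r for r in results if r.class_label == "A"]
        expected = dmr.bh_adjust([r.min_window_p for r in a_results])
        np.testing.assert_allclose([r.q_value for r in a_results], expected)


class TestSiteAnova:
    def test_identical_groups_give_null_delta_and_degenerate_p(self):
        beta = pd.DataFrame([[0.4] * 10], index=["p1"], columns=[f"s{i}" for i in range(10)])
        res = dmr.site_anova(["p1"], beta, two_group_design(5, 5))
        assert res[0].delta == 0 and res[0].p_value == 1.0 and res[0].degenerate

    def test_equals_pooled_t_test_without_covariates(self):
        rng = np.random.default_rng(8)
        beta = pd.DataFrame(
            rng.uniform(0.2, 0.8, size=(5, 24)),
            index=[f"p{i}" for i in range(5)],
            columns=[f"s{i}" for i in range(24)],
        )
        design = two_group_design(12, 12)
        res = dmr.site_anova(list(beta.index), beta, design)
        for r in res:
            t = stats.ttest_ind(
                beta.loc[r.probe_id][:12], beta.loc[r.probe_id][12:], equal_var=True
            )
            assert r.p_value == pytest.approx(t.pvalue, abs=1e-10)

    def test_matches_type2_ols_f_test_with_covariates(self):
        import statsmodels.api as smapi

        rng = np.random.default_rng(9)
        design = _design_with_cov(40, seed=9)
        y = rng.normal(0.5, 0.1, size=40)
        beta = pd.DataFrame([y], index=["p1"], columns=design.sample_ids)
        res = dmr.site_anova(["p1"], beta, design)
        model = smapi.OLS(y, design.X[["intercept", "cov", "group"]]).fit()
        expected = float(model.pvalues["group"])  # single-df term: partial F == t^2
        assert res[0].p_value == pytest.approx(expected, abs=1e-10)

    def test_cell_composition_confounding_is_removed_by_adjustment(self):
        """A probe whose only group difference flows through cell proportions is
        significant unadjusted but null once proportions enter the design."""
        rng = np.random.default_rng(10)
        n = 60
        group = np.array([1.0] * 30 + [0.0] * 30)
        prop = np.clip(0.3 + 0.15 * group + rng.normal(0, 0.03, n), 0, 1)
        y = np.clip(0.4 + 0.8 * prop + rng.normal(0, 0.01, n), 0, 1)
        ids = [f"s{i}" for i in range(n)]
        beta = pd.DataFrame([y], index=["p1"], columns=ids)
        X0 = pd.DataFrame({"intercept": np.ones(n), "group": group}, index=ids)
        unadj = dmr.site_anova(
            ["p1"], beta, dmr.DesignMatrix(X=X0, group_col="group", group_a="a", group_b="b")
        )
        X1 = X0.assign(cell=prop)
        adj = dmr.site_anova(
            ["p1"], beta, dmr.DesignMatrix(X=X1, group_col="group", group_a="a", group_b="b")
        )
        assert unadj[0].p_value < 0.01
        assert adj[0].p_value > 0.05


class TestBHAdjust:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(dmr.bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_singleton_identity(self):
        np.testing.assert_allclose(dmr.bh_adjust([0.5]), [0.5])

    def test_empty_input(self):
        assert dmr.bh_adjust([]).size == 0

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
    def test_matches_statsmodels_and_dominates_p(self, ps):
        from statsmodels.stats.multitest import multipletests

        q = dmr.bh_adjust(ps)
        expected = multipletests(ps, method="fdr_bh")[1]
        np.testing.assert_allclose(q, expected, atol=1e-12)
        assert (q >= np.asarray(ps) - 1e-15).all()
        assert (q <= 1).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            dmr.bh_adjust([0.5, 1.5])


class TestDesign:
    def _sheet(self):
        rows = []
        for f in range(4):
            for i, g in enumerate(["DSP", "DSS", "DSM"]):
                rows.append(
                    {
                        "sample_id": f"F{f}_{g}",
                        "family": f"F{f}",
                        "group": g,
                        "sex": "M" if (f * 3 + i) % 2 else "F",
                        "batch": f"b{f % 2}",
                    }
                )
        return pd.DataFrame(rows).set_index("sample_id")

    def test_mothers_never_enter_the_case_sib_design(self):
        design = dmr.build_design(self._sheet())
        assert not any("DSM" in s for s in design.sample_ids)
        assert len(design.sample_ids) == 8

    def test_collinear_cell_fractions_raise(self):
        sheet = self._sheet()
        cases = sheet[sheet["group"].isin(["DSP", "DSS"])]
        props = pd.DataFrame(
            np.random.default_rng(0).dirichlet(np.ones(3), size=len(cases)),
            index=cases.index,
            columns=["t1", "t2", "t3"],
        )
        with pytest.raises(dmr.DesignError, match="rank"):
            dmr.build_design(sheet, cell_props=props, drop_cell_type="not_present")

    def test_single_level_covariate_is_dropped_not_fatal(self):
        sheet = self._sheet()
        sheet["batch"] = "b0"
        design = dmr.build_design(sheet)
        assert not any(c.startswith("batch") for c in design.X.columns)


class TestChromosomeDistribution:
    def _inputs(self, shift=0.0, seed=0, n_probes=40, n=10):
        rng = np.random.default_rng(seed)
        probes = [f"p{i}" for i in range(n_probes)]
        samples = [f"a{i}" for i in range(n)] + [f"b{i}" for i in range(n)]
        vals = rng.uniform(0.2, 0.6, size=(n_probes, 2 * n))
        vals[:, n:] = np.clip(vals[:, n:] + shift, 0, 1)
        beta = pd.DataFrame(vals, index=probes, columns=samples)
        annot = pd.DataFrame(
            {"chromosome": ["1"] * (n_probes // 2) + ["2"] * (n_probes - n_probes // 2)},
            index=pd.Index(probes, name="probe_id"),
        )
        groups = {"A": samples[:n], "B": samples[n:]}
        return beta, annot, groups

    def test_identical_groups_have_zero_statistic(self):
        beta, annot, groups = self._inputs()
        beta[groups["B"]] = beta[groups["A"]].to_numpy()
        results = dmr.chromosome_distribution_test(beta, annot, groups)
        assert all(r.ks_statistic == 0 and r.bonferroni_p == 1 for r in results)

    def test_shift_lower_bounds_ks_statistic(self):
        """For group2 = group1 + 0.2 the KS distance is >= 0.2 (checked against a
        brute-force ECDF sweep)."""
        beta, annot, groups = self._inputs(shift=0.2, seed=1, n_probes=100)
        results = dmr.chromosome_distribution_test(beta, annot, groups)
        for r in results:
            a = beta.loc[annot["chromosome"] == r.chromosome, groups["A"]].to_numpy().ravel()
            b = beta.loc[annot["chromosome"] == r.chromosome, groups["B"]].to_numpy().ravel()
            grid = np.unique(np.concatenate([a, b]))
            ecdf_gap = max(
                abs((a <= x).mean() - (b <= x).mean()) for x in grid
            )
            assert r.ks_statistic == pytest.approx(ecdf_gap, abs=1e-12)
            assert r.ks_statistic >= 0.2 - 1e-12

    def test_bonferroni_multiplies_by_test_count(self):
        beta, annot, groups = self._inputs(shift=0.05, seed=2)
        groups["C"] = groups["B"]  # 3 groups -> 3 comparisons x 2 chromosomes = 6 tests
        results = dmr.chromosome_distribution_test(beta, annot, groups)
        assert len(results) == 6
        for r in results:
            assert r.bonferroni_p == pytest.approx(min(1.0, r.p_value * 6))

    def test_histograms_are_densities_on_unit_interval(self):
        beta, annot, groups = self._inputs(seed=3)
        r = dmr.chromosome_distribution_test(beta, annot, groups)[0]
        assert len(r.histogram_a) == 100
        assert np.trapezoid(r.histogram_a, dx=0.01) == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        beta, annot, groups = self._inputs()
        groups["A"] = []
        with pytest.raises(ValueError, match="empty"):
            dmr.chromosome_distribution_test(beta, annot, groups)
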