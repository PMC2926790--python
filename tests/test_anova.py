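"""Nested ANOVA: projection oracle equivalence, F wiring, LS means, components."""

import dataclasses
import warnings

import numpy as np
import pandas as pd
import pytest
import scipy.stats

import xskew as xs
from xskew.anova import _fit_frame

from conftest import make_toy_frame


# ---------------------------------------------------------------------------
# independent oracle: one-hot dummy projection, rank-aware sequential SS


def _dummies(labels):
    labels = np.asarray(labels)
    return (labels[:, None] == np.unique(labels)[None, :]).astype(float)


def projection_oracle(frame):
    """Sequential SS by explicit least-squares projection on dummy designs.

    Builds cumulative one-hot design matrices for intercept, +gene,
    +mother, +individual, computes each model's residual sum of squares
    with lstsq, and takes successive differences.  Degrees of freedom are
    matrix-rank differences, so nesting confounds are handled exactly.
    """
    y = frame["y"].to_numpy()
    n = len(y)
    designs = [np.ones((n, 1))]
    for col in ["gene", "mother", "individual"]:
        designs.append(np.hstack([designs[-1], _dummies(frame[col])]))

    rss, rank = [], []
    for X in designs:
        beta, _, r, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        rss.append(float(resid @ resid))
        rank.append(int(np.linalg.matrix_rank(X)))

    ss = {
        "gene": rss[0] - rss[1],
        "mother": rss[1] - rss[2],
        "individual(mother)": rss[2] - rss[3],
        "residual": rss[3],
    }
    df = {
        "gene": rank[1] - rank[0],
        "mother": rank[2] - rank[1],
        "individual(mother)": rank[3] - rank[2],
        "residual": n - rank[3],
    }
    return ss, df


def random_design(rng, max_genes=4, max_ind=4, max_rep=3):
    rows = []
    n_genes = rng.integers(2, max_genes + 1)
    for g in range(n_genes):
        for cross in ["c1", "c2"]:
            n_ind = rng.integers(2, max_ind + 1)
            for i in range(n_ind):
                for _ in range(rng.integers(1, max_rep + 1)):
                    rows.append(
                        {
                            "gene": f"g{g}",
                            "mother": cross,
                            "individual": f"{cross}:i{i}",
                            "y": float(rng.normal()),
                        }
                    )
    return pd.DataFrame(rows)


class TestProjectionOracle:
    @pytest.mark.parametrize("seed", range(20))
    def test_sequential_ss_match_oracle_on_random_unbalanced_designs(self, seed):
        rng = np.random.default_rng(seed)
        frame = random_design(rng)
        tab, _ = _fit_frame(frame, "sequential", ["gene", "mother", "individual(mother)"])
        ss, df = projection_oracle(frame)
        for src in ss:
            assert tab.loc[src, "sum_sq"] == pytest.approx(ss[src], rel=1e-8, abs=1e-10)
            assert tab.loc[src, "df"] == df[src]

    def test_hand_built_toy_matches_oracle(self):
        frame = make_toy_frame(
            {
                ("gA", "c1", "i1"): [0.50], ("gA", "c1", "i2"): [0.60],
                ("gA", "c2", "i1"): [0.40], ("gA", "c2", "i2"): [0.45],
                ("gB", "c1", "i1"): [0.70], ("gB", "c1", "i2"): [0.75],
                ("gB", "c2", "i1"): [0.62], ("gB", "c2", "i2"): [0.68],
            }
        )
        tab, _ = _fit_frame(frame, "sequential", ["gene", "mother", "individual(mother)"])
        ss, _ = projection_oracle(frame)
        for src in ss:
            assert tab.loc[src, "sum_sq"] == pytest.approx(ss[src], abs=1e-12)

    def test_statsmodels_agrees_on_gene_mother_and_residual(self):
        # independent library route; statsmodels' naive C(individual) coding
        # miscounts the nested df, but the gene/mother/residual SS must agree
        smf = pytest.importorskip("statsmodels.formula.api")
        import statsmodels.api as sm

        frame = random_design(np.random.default_rng(42))
        tab, _ = _fit_frame(frame, "sequential", ["gene", "mother", "individual(mother)"])
        fit = smf.ols("y ~ C(gene) + C(mother) + C(individual)", data=frame).fit()
        aov = sm.stats.anova_lm(fit, typ=1)
        assert tab.loc["gene", "sum_sq"] == pytest.approx(aov.loc["C(gene)", "sum_sq"])
        assert tab.loc["mother", "sum_sq"] == pytest.approx(aov.loc["C(mother)", "sum_sq"])
        assert tab.loc["residual", "sum_sq"] == pytest.approx(aov.loc["Residual", "sum_sq"])

    def test_balanced_design_sequential_equals_type_iii_and_sums_to_total(self):
        rng = np.random.default_rng(3)
        frame = make_toy_frame(
            {
                (g, c, i): list(rng.normal(size=2))
                for g in ["gA", "gB", "gC"]
                for c in ["c1", "c2"]
                for i in ["i1", "i2", "i3"]
            }
        )
        t1, meta = _fit_frame(frame, "sequential", ["gene", "mother", "individual(mother)"])
        t3, _ = _fit_frame(frame, "type_iii", ["gene", "mother", "individual(mother)"])
        assert meta["balanced"]
        assert np.allclose(t1["sum_sq"], t3["sum_sq"])
        total = ((frame["y"] - frame["y"].mean()) ** 2).sum()
        assert t1["sum_sq"].sum() == pytest.approx(total)


class TestWiring:
    def test_f_ratios_use_the_nested_error_strata(self):
        ms = {
            "gene": 0.421723,
            "mother": 1.822754,
            "individual(mother)": 0.197085,
            "residual": 0.000804,
        }
        df = {"gene": 26, "mother": 1, "individual(mother)": 34, "residual": 1778}
        ft = xs.f_tests_from_mean_squares(ms, df)
        assert ft.loc["mother", "F"] == pytest.approx(
            ms["mother"] / ms["individual(mother)"]
        )
        assert round(ft.loc["mother", "F"], 2) == 9.25
        assert ft.loc["mother", "p"] == pytest.approx(0.0045, abs=5e-4)
        assert ft.loc["gene", "F"] == pytest.approx(ms["gene"] / ms["residual"], rel=1e-12)
        assert ft.loc["individual(mother)", "F"] == pytest.approx(
            ms["individual(mother)"] / ms["residual"]
        )

    def test_fitted_table_wiring_is_self_consistent(self, default_fit):
        tab = default_fit.table
        assert tab.loc["mother", "F"] == pytest.approx(
            tab.loc["mother", "mean_sq"] / tab.loc["individual(mother)", "mean_sq"]
        )
        assert tab.loc["mother", "error_stratum"] == "individual(mother)"
        assert tab.loc["gene", "error_stratum"] == "residual"

    def test_equal_cross_means_give_zero_mother_ss(self):
        # perfectly antisymmetric: each individual in c2 mirrors one in c1
        frame = make_toy_frame(
            {
                ("gA", "c1", "i1"): [0.4], ("gA", "c1", "i2"): [0.6],
                ("gA", "c2", "i1"): [0.6], ("gA", "c2", "i2"): [0.4],
                ("gB", "c1", "i1"): [0.3], ("gB", "c1", "i2"): [0.7],
                ("gB", "c2", "i1"): [0.7], ("gB", "c2", "i2"): [0.3],
            }
        )
        tab, _ = _fit_frame(frame, "sequential", ["gene", "mother", "individual(mother)"])
        assert tab.loc["mother", "sum_sq"] == pytest.approx(0.0, abs=1e-12)

    def test_single_individual_cross_is_rejected(self, tiny_params):
        table = xs.simulate_dataset(tiny_params, 0)
        keep = (table.data["cross_id"] == "PWDxAKR") | (
            table.data["individual_id"] == "AKRxPWD_F1"
        )
        crippled = xs.ExpressionTable(table.data[keep], table.annotations)
        with pytest.raises(xs.DesignError, match="single individual"):
            xs.fit_nested_anova(crippled)


class TestLsMeans:
    def test_noise_free_neutral_simulation_gives_half(self):
        genes = [xs.GeneParams(f"g{i}", "inactivated", eqtl_ratio=0.5) for i in range(3)]
        params = xs.SimulationParams(
            genes=genes, p_pat=0.5, measurement_sd=0.0, deterministic_f=True,
            n_females_per_cross=4, include_males=False,
        )
        res = xs.fit_nested_anova(xs.simulate_dataset(params, 0))
        lsm = xs.ls_means(res)
        assert np.allclose(lsm["ls_mean"], 0.5)

    def test_paper_scale_simulation_recovers_six_percent_bias(self, default_fit):
        lsm = xs.ls_means(default_fit)
        diff = lsm["ls_mean"].max() - lsm["ls_mean"].min()
        assert diff == pytest.approx(0.06, abs=0.03)
        # SE from the individual stratum at this design size
        assert lsm["se"].iloc[0] == pytest.approx(0.0146, abs=0.006)

    def test_se_uses_individual_stratum(self, default_fit):
        lsm = xs.ls_means(default_fit)
        ms_ind = default_fit.table.loc["individual(mother)", "mean_sq"]
        row = lsm.iloc[0]
        n_j = row["n_individuals"]
        c_j = default_fit.meta["obs_per_individual"]
        assert row["se"] == pytest.approx(np.sqrt(ms_ind / (n_j * c_j)), rel=1e-6)


class TestVarianceComponents:
    def test_printed_mean_squares_reproduce_reported_effect_ordering(self):
        # inject the published strata via a synthetic result shell
        tab = pd.DataFrame(
            {
                "sum_sq": [10.96479, 1.822754, 6.700906, 1.428698],
                "df": [26, 1, 34, 1778],
            },
            index=["gene", "mother", "individual(mother)", "residual"],
        )
        tab["mean_sq"] = tab["sum_sq"] / tab["df"]
        res = xs.AnovaResult(
            table=tab,
            data=pd.DataFrame(),
            spec=xs.AnovaModelSpec(),
            meta={
                "n_obs": 1944, "obs_per_individual": 54.0,
                "obs_per_gene": 72.0, "obs_per_cross": 972.0,
            },
        )
        vc = xs.variance_components(res)
        props = vc["prop_ems"]
        # cis-regulatory > sampling > parent-of-origin > residual
        assert props["gene"] > props["individual(mother)"] > props["mother"]
        assert props["individual(mother)"] == pytest.approx(0.309, abs=0.02)
        assert props["mother"] == pytest.approx(0.143, abs=0.02)
        assert props["gene"] == pytest.approx(0.483, abs=0.02)

    def test_noise_free_fit_has_negligible_residual_share(self):
        genes = [
            xs.GeneParams(f"g{i}", "inactivated", eqtl_ratio=r)
            for i, r in enumerate(np.linspace(0.4, 0.6, 5))
        ]
        params = xs.SimulationParams(
            genes=genes, measurement_sd=0.0, include_males=False,
            n_females_per_cross=10,
        )
        res = xs.fit_nested_anova(xs.simulate_dataset(params, 1))
        vc = xs.variance_components(res)
        assert vc["prop_ems"]["residual"] < 0.01

    def test_constant_data_flagged_degenerate(self):
        frame_vals = {
            (g, c, i): [0.5, 0.5]
            for g in ["gA", "gB"] for c in ["c1", "c2"] for i in ["i1", "i2"]
        }
        frame = make_toy_frame(frame_vals)
        tab, meta = _fit_frame(frame, "sequential", ["gene", "mother", "individual(mother)"])
        res = xs.AnovaResult(table=tab, data=frame, spec=xs.AnovaModelSpec(), meta=meta)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            vc = xs.variance_components(res)
        assert vc.attrs["degenerate"]
        assert vc["prop_ems"].isna().all()


class TestRankTransform:
    def test_idempotent_on_rank_valued_data(self):
        rng = np.random.default_rng(5)
        table = xs.simulate_dataset(xs.default_params(), rng)
        genes = table.genes_of_class(["inactivated"])
        raw = xs.fit_nested_anova(table, genes=genes)
        # replace the response by its own midranks: rank fit == raw fit on ranks
        ranked = table.data.copy()
        sel = (ranked["sex"] == "female") & ranked["gene_id"].isin(genes)
        ranked.loc[sel, "ref_fraction"] = scipy.stats.rankdata(
            ranked.loc[sel, "ref_fraction"]
        ) / (sel.sum() + 1.0)  # keep within [0,1]
        t2 = xs.ExpressionTable(ranked, table.annotations)
        rank_of_ranked = xs.rank_transform_anova(t2, genes=genes)
        rank_of_raw = xs.rank_transform_anova(table, genes=genes)
        assert np.allclose(
            rank_of_ranked.table["sum_sq"], rank_of_raw.table["sum_sq"]
        )

    def test_invariant_under_monotone_response_transform(self, default_table):
        genes = default_table.genes_of_class(["inactivated"])
        base = xs.rank_transform_anova(default_table, genes=genes)
        squashed = default_table.data.copy()
        squashed["ref_fraction"] = squashed["ref_fraction"] ** 3  # strictly monotone
        t2 = xs.ExpressionTable(squashed, default_table.annotations)
        other = xs.rank_transform_anova(t2, genes=genes)
        assert np.allclose(base.table["sum_sq"], other.table["sum_sq"])

    def test_parent_of_origin_detected_alike_in_raw_and_rank_fits(self):
        # the midrank transform should barely perturb the mother p-value on
        # paper-scale simulations, and both fits detect the effect in most seeds
        hits = 0
        for seed in range(12):
            table = xs.simulate_dataset(xs.default_params(), seed)
            p_raw = xs.fit_nested_anova(table).table.loc["mother", "p"]
            p_rank = xs.rank_transform_anova(table).table.loc["mother", "p"]
            assert np.log10(p_rank) == pytest.approx(np.log10(p_raw), abs=0.5)
            if p_raw < 0.05 and p_rank < 0.05:
                hits += 1
        assert hits >= 6


class TestPooledFit:
    def test_self_pooling_preserves_mother_f_on_balanced_data(self):
        genes = [xs.GeneParams(f"g{i}", "inactivated", eqtl_ratio=0.5) for i in range(4)]
        params = xs.SimulationParams(genes=genes, include_males=False,
                                     n_females_per_cross=6)
        t1 = xs.simulate_dataset(params, 0)
        relabeled = t1.data.copy()
        relabeled["strain_pair_id"] = "P2-Q2"
        relabeled["cross_id"] = relabeled["cross_id"].map(
            {"PWDxAKR": "P2xQ2", "AKRxPWD": "Q2xP2"}
        )
        relabeled["individual_id"] = "d_" + relabeled["individual_id"]
        t2 = xs.ExpressionTable(relabeled, t1.annotations)

        single = xs.fit_nested_anova(t1)
        pooled = xs.pooled_fit([t1, t2])
        # mother is a single shared orientation contrast (1 df), so exact
        # replication doubles its SS and MS while the individual-stratum MS
        # is unchanged: the F ratio doubles and the evidence sharpens
        assert pooled.table.loc["mother", "sum_sq"] == pytest.approx(
            2 * single.table.loc["mother", "sum_sq"], rel=1e-8
        )
        assert pooled.table.loc["individual(mother)", "mean_sq"] == pytest.approx(
            single.table.loc["individual(mother)", "mean_sq"], rel=1e-8
        )
        assert pooled.table.loc["mother", "F"] == pytest.approx(
            2 * single.table.loc["mother", "F"], rel=1e-6
        )

    def test_pooling_two_designs_sharpens_the_parent_effect(self):
        smaller = 0
        n_seeds = 10
        for seed in range(n_seeds):
            rng = np.random.SeedSequence(seed).spawn(2)
            t1 = xs.simulate_dataset(xs.default_params("PWD-AKR"),
                                     np.random.default_rng(rng[0]))
            t2 = xs.simulate_dataset(xs.default_params("B6-CAST"),
                                     np.random.default_rng(rng[1]))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pooled = xs.pooled_fit([t1, t2])
            p1 = xs.fit_nested_anova(t1).table.loc["mother", "p"]
            p2 = xs.fit_nested_anova(t2).table.loc["mother", "p"]
            if pooled.table.loc["mother", "p"] <= min(p1, p2):
                smaller += 1
        assert smaller > n_seeds / 2

    def test_gene_sets_restricted_to_intersection_with_warning(self):
        t1 = xs.simulate_dataset(xs.default_params("PWD-AKR"), 0)
        t2 = xs.simulate_dataset(xs.default_params("B6-CAST"), 1)
        with pytest.warns(UserWarning, match="shared"):
            pooled = xs.pooled_fit([t1, t2])
        n_common = len(
            set(t1.genes_of_class(["inactivated"]))
            & set(t2.genes_of_class(["inactivated"]))
        )
        assert pooled.table.loc["gene", "df"] == n_common - 1
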