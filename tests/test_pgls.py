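"""Pagel's-λ GLS: covariance construction, fitting, selection and tests."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import echoscale as es
from echoscale.errors import ModelError, NumericalError
from echoscale.pgls import (
    LambdaProfiler,
    build_design,
    gls_fit,
    lambda_transform,
    parse_formula,
)
from conftest import random_tree


def vcv_oracle(tree):
    """Path-enumeration oracle: C[i,j] = summed length of shared edges on
    the two root-to-tip paths."""
    t = tree.dendropy_tree
    tips = list(t.leaf_node_iter())
    paths = []
    for leaf in tips:
        edges = []
        nd = leaf
        while nd.parent_node is not None:
            edges.append((id(nd), nd.edge.length))
            nd = nd.parent_node
        paths.append(dict(edges))
    n = len(tips)
    C = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            shared = set(paths[i]) & set(paths[j])
            C[i, j] = sum(paths[i][e] for e in shared)
    return C, [l.taxon.label for l in tips]


class TestPhyloVcv:
    def test_three_tip_example(self):
        tree = es.PhyloTree.from_newick("((A:1,B:1):0.5,C:1.5);")
        C, labs = es.phylo_vcv(tree)
        i = {l: k for k, l in enumerate(labs)}
        assert C[i["A"], i["A"]] == pytest.approx(1.5)
        assert C[i["A"], i["B"]] == pytest.approx(0.5)
        assert C[i["A"], i["C"]] == 0.0

    def test_star_tree_is_diagonal(self):
        tree = es.PhyloTree.from_newick("(A:1,B:2,C:3,D:4);")
        C, _ = es.phylo_vcv(tree)
        assert np.allclose(C, np.diag(np.diag(C)))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_path_enumeration_oracle(self, seed):
        tree = random_tree(6, np.random.default_rng(seed))
        C, labs = es.phylo_vcv(tree)
        Co, labs_o = vcv_oracle(tree)
        assert labs == labs_o
        np.testing.assert_allclose(C, Co, atol=1e-12)


class TestLambdaTransform:
    def test_identity_and_zero(self):
        tree = es.PhyloTree.from_newick("((A:1,B:1):0.5,C:1.5);")
        C, _ = es.phylo_vcv(tree)
        np.testing.assert_allclose(lambda_transform(C, 1.0), C)
        np.testing.assert_allclose(lambda_transform(C, 0.0), np.diag(np.diag(C)))
        half = lambda_transform(C, 0.5)
        assert half[0, 1] == pytest.approx(0.25)
        np.testing.assert_allclose(np.diag(half), np.diag(C))

    @pytest.mark.parametrize("lam", [-0.1, 1.5])
    def test_domain_error(self, lam):
        with pytest.raises(ModelError):
            lambda_transform(np.eye(2), lam)


class TestGlsFit:
    def test_identity_v_equals_ols(self):
        rng = np.random.default_rng(7)
        X = np.column_stack([np.ones(30), rng.standard_normal(30)])
        y = 1.0 + 2.0 * X[:, 1] + rng.standard_normal(30)
        beta, _, _, _, _ = gls_fit(y, X, np.eye(30))
        ols = sm.OLS(y, X).fit()
        np.testing.assert_allclose(beta, ols.params, atol=1e-10)

    def test_exact_fit_zero_residual_rate(self):
        X = np.column_stack([np.ones(5), np.arange(5.0)])
        y = 3.0 - 0.5 * np.arange(5.0)
        beta, _, s2, _, _ = gls_fit(y, X, np.eye(5))
        np.testing.assert_allclose(beta, [3.0, -0.5], atol=1e-12)
        assert s2 == pytest.approx(0.0, abs=1e-20)

    def test_closed_form_oracle_4x4(self):
        # independent evaluation of (XᵀV⁻¹X)⁻¹XᵀV⁻¹y with explicit inverses
        V = np.array(
            [
                [2.0, 0.5, 0.0, 0.0],
                [0.5, 2.0, 0.0, 0.0],
                [0.0, 0.0, 1.5, 0.3],
                [0.0, 0.0, 0.3, 1.5],
            ]
        )
        X = np.column_stack([np.ones(4), [0.0, 1.0, 2.0, 3.0]])
        y = np.array([1.0, 2.0, 2.5, 4.0])
        Vi = np.linalg.inv(V)
        beta_oracle = np.linalg.inv(X.T @ Vi @ X) @ X.T @ Vi @ y
        beta, _, _, _, _ = gls_fit(y, X, V)
        np.testing.assert_allclose(beta, beta_oracle, atol=1e-10)

    def test_singular_inputs_rejected(self):
        X = np.column_stack([np.ones(4), np.ones(4)])
        with pytest.raises(NumericalError):
            gls_fit(np.arange(4.0), X, np.eye(4))
        with pytest.raises(NumericalError):
            gls_fit(np.arange(4.0), np.ones((4, 1)), np.zeros((4, 4)))


class TestProfileLambda:
    def test_grid_scan_oracle(self, yule100):
        C, labs = es.phylo_vcv(yule100)
        df = es.simulate_mvbm(yule100, [0.0], [[0.5]], seed=11)
        y = df.loc[labs, "x1"].to_numpy()
        X = np.ones((len(y), 1))
        lam_hat = es.profile_lambda(y, X, C, "REML")
        prof = LambdaProfiler(y, X, C)
        grid = np.arange(0.0, 1.0 + 1e-12, 0.001)
        vals = [prof.loglik(l, "REML") for l in grid]
        lam_grid = grid[int(np.argmax(vals))]
        assert abs(lam_hat - lam_grid) <= 0.002

    def test_bm_data_high_lambda(self, yule100):
        C, labs = es.phylo_vcv(yule100)
        X = np.ones((100, 1))
        hits = 0
        for rep in range(10):
            df = es.simulate_mvbm(yule100, [0.0], [[0.5]], seed=300 + rep)
            y = df.loc[labs, "x1"].to_numpy()
            if es.profile_lambda(y, X, C, "REML") > 0.9:
                hits += 1
        assert hits >= 9

    def test_permutation_destroys_signal(self, yule100):
        C, labs = es.phylo_vcv(yule100)
        X = np.ones((100, 1))
        rng = np.random.default_rng(99)
        hits = 0
        for rep in range(10):
            df = es.simulate_mvbm(yule100, [0.0], [[0.5]], seed=400 + rep)
            y = rng.permutation(df.loc[labs, "x1"].to_numpy())
            if es.profile_lambda(y, X, C, "REML") < 0.1:
                hits += 1
        assert hits >= 9

    def test_fast_path_matches_cholesky_path(self, yule100):
        C, labs = es.phylo_vcv(yule100)
        df = es.simulate_mvbm(yule100, [0.0], [[0.5]], seed=12)
        y = df.loc[labs, "x1"].to_numpy()
        X = np.column_stack([np.ones(100), np.arange(100.0)])
        prof = LambdaProfiler(y, X, C)
        assert prof._fast
        for lam in (0.0, 0.3, 0.8, 1.0):
            V = lambda_transform(C, lam)
            _, _, _, ll_ml, ll_reml = gls_fit(y, X, V)
            assert prof.loglik(lam, "ML") == pytest.approx(ll_ml, abs=1e-7)
            assert prof.loglik(lam, "REML") == pytest.approx(ll_reml, abs=1e-7)


class TestFormulas:
    def test_parse(self):
        resp, terms = parse_formula("log_peak ~ log_mass + emission + log_mass:emission")
        assert resp == "log_peak"
        assert terms == [("log_mass",), ("emission",), ("log_mass", "emission")]
        assert parse_formula("y ~ 1") == ("y", [])

    def test_treatment_coding_reference(self):
        df = pd.DataFrame(
            {"x": [1.0, 2.0, 3.0, 4.0], "g": ["oral", "nasal", "oral", "nasal"]}
        )
        X, names, slices, refs = build_design(df, [("x",), ("g",)])
        assert names == ["(Intercept)", "x", "g[oral]"]
        assert refs["g"] == "nasal"  # alphabetical reference level
        np.testing.assert_allclose(X[:, 2], [1, 0, 1, 0])

    def test_single_level_factor_rejected(self):
        df = pd.DataFrame({"x": [1.0, 2.0], "g": ["oral", "oral"]})
        with pytest.raises(ModelError):
            build_design(df, [("g",)])


class TestFitPgls:
    def test_self_regression(self, yule100):
        df = es.simulate_mvbm(yule100, [0.0], [[0.5]], seed=21)
        data = pd.DataFrame({"a": df["x1"], "b": df["x1"]})
        ds = es.AlignedDataset.from_frames(yule100, data)
        m = es.fit_pgls(ds, "a ~ b")
        assert m.coef["b"] == pytest.approx(1.0, abs=1e-8)
        assert m.coef["(Intercept)"] == pytest.approx(0.0, abs=1e-8)
        assert es.r2_lik(m) > 0.999

    def test_intercept_only_is_weighted_mean(self, balanced_tree):
        C, labs = es.phylo_vcv(balanced_tree)
        y = np.array([1.0, 2.0, 3.0, 5.0])
        ds = es.AlignedDataset.from_frames(
            balanced_tree, pd.DataFrame({"y": y}, index=labs)
        )
        m = es.fit_pgls(ds, "y ~ 1", lambda_=1.0)
        Ci = np.linalg.inv(C)
        ones = np.ones(4)
        expected = (ones @ Ci @ y) / (ones @ Ci @ ones)
        assert m.coef["(Intercept)"] == pytest.approx(expected, abs=1e-10)

    def test_lambda_zero_equals_ols(self, yule100):
        df = es.simulate_pgls_dataset(
            yule100, slope=-0.3, intercepts=2.0, lam=0.5, sigma2=0.05, seed=22
        )
        ds = es.AlignedDataset.from_frames(yule100, df)
        m = es.fit_pgls(ds, "log_peak ~ log_mass", lambda_=0.0)
        # tip-to-root distances are equal on an ultrametric tree, so λ=0 GLS
        # is exactly OLS
        sub = df.loc[yule100.tip_labels]
        X = sm.add_constant(sub["log_mass"].to_numpy())
        ols = sm.OLS(sub["log_peak"].to_numpy(), X).fit()
        np.testing.assert_allclose(
            m.coef.to_numpy(), ols.params, atol=1e-10
        )

    def test_reml_invariant_to_design_basis(self, yule100):
        df = es.simulate_pgls_dataset(
            yule100, slope=-0.3, intercepts={"nasal": 2.0, "oral": 1.8},
            lam=0.8, sigma2=0.05, seed=23,
        )
        data = df.copy()
        # same column space, different basis: recode the factor numerically
        data["g2"] = np.where(data["emission"] == "nasal", -1.0, 1.0)
        ds = es.AlignedDataset.from_frames(yule100, data)
        m1 = es.fit_pgls(ds, "log_peak ~ log_mass + emission")
        m2 = es.fit_pgls(ds, "log_peak ~ log_mass + g2")
        assert m1.loglik_reml == pytest.approx(m2.loglik_reml, abs=1e-6)
        assert m1.lambda_reml == pytest.approx(m2.lambda_reml, abs=1e-4)


class TestModelSelection:
    def _dataset(self, tree, seed, with_effect):
        # the clade-assigned covariate is confounded with phylogeny, so the
        # additive offset must be clearly larger than its ~0.13 SE for model
        # selection to have power
        icepts = {"nasal": 2.2, "oral": 1.8} if with_effect else 2.0
        df = es.simulate_pgls_dataset(
            tree, slope=-0.29, intercepts=icepts, lam=0.9, sigma2=0.03, seed=seed
        )
        if "emission" not in df.columns:
            df["emission"] = es.synthetic_data.root_clade_factor(tree)
        return es.AlignedDataset.from_frames(tree, df)

    CANDS = [
        "log_mass",
        "log_mass + emission",
        "log_mass + emission + log_mass:emission",
    ]

    def test_weights_sum_to_one(self, yule100):
        ds = self._dataset(yule100, 31, True)
        table, _ = es.model_selection(ds, "log_peak", self.CANDS)
        assert table["weight"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_duplicate_candidates_equal_weight(self, yule100):
        ds = self._dataset(yule100, 32, True)
        table, _ = es.model_selection(ds, "log_peak", ["log_mass", "log_mass"])
        np.testing.assert_allclose(table["weight"], [0.5, 0.5], atol=1e-12)

    def test_weights_invariant_to_order(self, yule100):
        ds = self._dataset(yule100, 33, True)
        t1, _ = es.model_selection(ds, "log_peak", self.CANDS)
        t2, _ = es.model_selection(ds, "log_peak", self.CANDS[::-1])
        w1 = t1.set_index("formula")["weight"]
        w2 = t2.set_index("formula")["weight"]
        np.testing.assert_allclose(w1.sort_index(), w2.sort_index(), atol=1e-8)

    def test_additive_model_wins_majority(self, yule300):
        # emission offset present, no interaction: the additive model should
        # take the lowest AIC most of the time
        wins = 0
        n_rep = 20
        for rep in range(n_rep):
            ds = self._dataset(yule300, 500 + rep, True)
            _, best = es.model_selection(ds, "log_peak", self.CANDS)
            if best.formula == "log_peak ~ log_mass + emission":
                wins += 1
        assert wins > n_rep / 2


class TestFitStatistics:
    def test_r2_lik_null_is_zero(self, yule100):
        df = es.simulate_mvbm(yule100, [0.0], [[0.4]], seed=41)
        ds = es.AlignedDataset.from_frames(yule100, pd.DataFrame({"y": df["x1"]}))
        null = es.fit_pgls(ds, "y ~ 1")
        assert es.r2_lik(null, null) == pytest.approx(0.0, abs=1e-12)

    def test_r2_lik_ten_tip_hand_formula(self):
        tree = es.simulate_yule_tree(10, seed=42, scale_height=1.0)
        df = es.simulate_pgls_dataset(
            tree, slope=1.0, intercepts=0.0, lam=1.0, sigma2=0.1, seed=43
        )
        ds = es.AlignedDataset.from_frames(tree, df)
        m = es.fit_pgls(ds, "log_peak ~ log_mass")
        null = es.fit_pgls(ds, "log_peak ~ 1")
        by_hand = 1.0 - np.exp(-2.0 * (m.loglik_ml - null.loglik_ml) / 10)
        assert es.r2_lik(m, null) == pytest.approx(by_hand, abs=1e-10)
        assert es.r2_lik(m) == pytest.approx(by_hand, abs=1e-10)

    def test_anova_single_term_equals_full_vs_null(self, yule100):
        df = es.simulate_pgls_dataset(
            tree=yule100, slope=-0.3, intercepts=2.0, lam=0.8, sigma2=0.05, seed=44
        )
        ds = es.AlignedDataset.from_frames(yule100, df)
        m = es.fit_pgls(ds, "log_peak ~ log_mass")
        table = es.anova_type3(m)
        from echoscale.pgls import full_vs_null_lr

        chisq, dof, p = full_vs_null_lr(m)
        assert table.loc[0, "Chisq"] == pytest.approx(chisq, abs=1e-8)
        assert table.loc[0, "df"] == dof

    def test_anova_chisq_equals_two_independent_fits(self):
        tree = es.simulate_yule_tree(8, seed=45, scale_height=1.0)
        df = es.simulate_pgls_dataset(
            tree, slope=-0.3, intercepts={"nasal": 2.0, "oral": 1.7},
            lam=1.0, sigma2=0.05, seed=46,
        )
        ds = es.AlignedDataset.from_frames(tree, df)
        full = es.fit_pgls(ds, "log_peak ~ log_mass + emission")
        reduced = es.fit_pgls(ds, "log_peak ~ log_mass")
        table = es.anova_type3(full).set_index("term")
        by_hand = 2.0 * (full.loglik_ml - reduced.loglik_ml)
        assert table.loc["emission", "Chisq"] == pytest.approx(
            max(by_hand, 0.0), abs=1e-6
        )

    def test_slope_ci_monotone_and_degenerate(self, yule100):
        df = es.simulate_pgls_dataset(
            yule100, slope=-0.3, intercepts=2.0, lam=0.8, sigma2=0.05, seed=47
        )
        ds = es.AlignedDataset.from_frames(yule100, df)
        m = es.fit_pgls(ds, "log_peak ~ log_mass")
        ci95 = es.slope_ci(m, 0.95)
        ci99 = es.slope_ci(m, 0.99)
        w95 = (ci95["high"] - ci95["low"])["log_mass"]
        w99 = (ci99["high"] - ci99["low"])["log_mass"]
        assert w99 > w95
        assert ci95.loc["log_mass", "low"] < m.coef["log_mass"] < ci95.loc["log_mass", "high"]
        # exact-fit data: SE = 0 and the interval collapses onto the estimate
        exact = es.simulate_pgls_dataset(
            yule100, slope=-0.3, intercepts=2.0, lam=0.8, sigma2=0.0, seed=48
        )
        ds0 = es.AlignedDataset.from_frames(yule100, exact)
        m0 = es.fit_pgls(ds0, "log_peak ~ log_mass", lambda_=1.0)
        ci0 = es.slope_ci(m0, 0.95)
        assert ci0.loc["log_mass", "low"] == pytest.approx(-0.3, abs=1e-6)
        assert ci0.loc["log_mass", "high"] == pytest.approx(-0.3, abs=1e-6)
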