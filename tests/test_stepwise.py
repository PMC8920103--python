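"""Univariate screen, VIF collinearity filter and the subset model search."""

import numpy as np
import pytest
import statsmodels.api as sm

from iamdelta.stepwise import (
    DescriptorMatrix,
    search_models,
    run_stepwise,
    univariate_screen,
    vif_filter,
)
from iamdelta.regress import fit_ols
from iamdelta.synthetic import SyntheticConfig, gen_descriptor_matrix


def _matrix(values, names=None, compounds=None):
    values = np.asarray(values, dtype=float)
    names = names or [f"c{i}" for i in range(values.shape[1])]
    compounds = compounds or [f"m{i}" for i in range(values.shape[0])]
    return DescriptorMatrix(compounds, list(names), values)


def _orthonormal_pair(n=40, rho=0.0, seed=0):
    """Two exactly-correlated columns built by Gram–Schmidt."""
    rng = np.random.default_rng(seed)
    a = rng.normal(size=n)
    b = rng.normal(size=n)
    a = (a - a.mean()) / a.std()
    b = b - b.mean()
    b -= (b @ a) / (a @ a) * a
    b /= b.std()
    return a, rho * a + np.sqrt(1 - rho**2) * b


class TestUnivariateScreen:
    def test_descriptor_equal_to_response_kept_with_r2_one(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=30)
        m = _matrix(np.column_stack([y, rng.normal(size=30)]), ["self", "noise"])
        kept = univariate_screen(m, y)
        assert kept[0].name == "self"
        assert kept[0].summary.r2 == pytest.approx(1.0)

    def test_reference_delta_descriptors_both_kept_dd2_first(
        self, reference_table, printed_deltas
    ):
        logbb = np.array([rec.logbb for rec in reference_table])
        m = _matrix(
            printed_deltas.loc[[r.name for r in reference_table]].to_numpy(),
            ["delta_mg", "delta_dd2"],
            [r.name for r in reference_table],
        )
        kept = univariate_screen(m, logbb)
        assert [s.name for s in kept] == ["delta_dd2", "delta_mg"]
        assert kept[0].summary.r2 >= kept[1].summary.r2

    def test_pure_noise_column_dropped_at_n56(self):
        rng = np.random.default_rng(42)
        y = rng.normal(size=56)
        noise = rng.normal(size=56)
        m = _matrix(np.column_stack([y + rng.normal(size=56), noise]), ["signal", "noise"])
        kept = univariate_screen(m, y)
        names = [s.name for s in kept]
        # confirm by direct computation that the noise column is sub-floor
        r2 = np.corrcoef(noise, y)[0, 1] ** 2
        assert r2 < 0.1
        assert "noise" not in names

    def test_constant_column_skipped_with_warning(self, caplog):
        import logging

        y = np.arange(10.0)
        m = _matrix(np.column_stack([y, np.ones(10)]), ["ok", "const"])
        with caplog.at_level(logging.WARNING, logger="iamdelta.stepwise"):
            kept = univariate_screen(m, y)
        assert [s.name for s in kept] == ["ok"]
        assert any("const" in msg for msg in caplog.messages)


class TestVifFilter:
    def test_orthogonal_columns_both_kept_with_unit_vif(self):
        a, b = _orthonormal_pair(rho=0.0)
        kept, vifs, removed = vif_filter(_matrix(np.column_stack([a, b]), ["a", "b"]))
        assert kept == ["a", "b"] and removed == []
        assert vifs["a"] == pytest.approx(1.0, abs=1e-9)
        assert vifs["b"] == pytest.approx(1.0, abs=1e-9)

    def test_duplicate_column_later_one_removed(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=25)
        z = rng.normal(size=25)
        m = _matrix(np.column_stack([x, z, x]), ["first", "other", "dup"])
        kept, _, removed = vif_filter(m)
        assert removed == ["dup"]
        assert kept == ["first", "other"]

    def test_correlation_095_matches_closed_form_then_removed(self):
        a, b = _orthonormal_pair(rho=0.95, seed=3)
        m = _matrix(np.column_stack([a, b]), ["a", "b"])
        # closed form for two predictors: VIF = 1/(1 - rho^2)
        X = np.column_stack([np.ones(len(a)), a, b])
        from statsmodels.stats.outliers_influence import variance_inflation_factor

        vif = variance_inflation_factor(X, 1)
        assert vif == pytest.approx(1.0 / (1.0 - 0.95**2), rel=1e-9)  # ~10.26
        kept, vifs, removed = vif_filter(m, threshold=5.0)
        assert len(kept) == 1 and len(removed) == 1
        assert all(v < 5.0 for v in vifs.values())

    def test_candidate_order_invariance_without_ties(self):
        rng = np.random.default_rng(9)
        base = rng.normal(size=(40, 3))
        coll = base[:, 0] * 0.97 + rng.normal(size=40) * 0.1
        m = _matrix(np.column_stack([base, coll]), ["a", "b", "c", "d"])
        kept1, _, _ = vif_filter(m, ["a", "b", "c", "d"])
        kept2, _, _ = vif_filter(m, ["d", "c", "b", "a"])
        assert set(kept1) == set(kept2)


class TestSearchModels:
    def test_single_candidate_reduces_to_fit_ols(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=20)
        y = 0.7 * x + rng.normal(size=20) * 0.2
        m = _matrix(x[:, None], ["only"])
        models = search_models(m, y, max_vars=3)
        assert len(models) == 1
        direct = fit_ols(x, y, ["only"])
        assert models[0].selected == ["only"]
        assert models[0].summary.r2 == pytest.approx(direct.r2)
        assert models[0].summary.q2_loo == pytest.approx(direct.q2_loo)

    def test_max_vars_one_matches_univariate_ranking(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(30, 4))
        y = X @ [1.0, 0.5, 0.0, 0.0] + rng.normal(size=30) * 0.3
        m = _matrix(X, ["a", "b", "c", "d"])
        models = search_models(m, y, max_vars=1, top=10)
        screened = univariate_screen(m, y, r2_min=0.0)
        by_name = {s.name: s.summary.r2 for s in screened}
        assert {m_.selected[0] for m_ in models} == set(by_name)
        for m_ in models:
            assert m_.summary.r2 == pytest.approx(by_name[m_.selected[0]])

    def test_planted_model_recovered_among_decoys(self):
        config = SyntheticConfig(seed=11, n_compounds=60, n_descriptors=15,
                                 planted={"d01": 0.8, "d02": -0.5, "d03": 0.3},
                                 collinear_pair=("d98", "d99"),  # disable collinearity
                                 descriptor_noise_sd=0.1)
        matrix, y, truths = gen_descriptor_matrix(config)
        models = search_models(matrix, y, max_vars=3, top=5)
        three_var = [m for m in models if len(m.selected) == 3]
        best = min(three_var, key=lambda m: -m.summary.q2_loo)
        assert set(best.selected) == set(truths["planted"])
        # coefficients recover the planted values within 3 coefficient SEs
        X = sm.add_constant(matrix.subset(sorted(best.selected)))
        fit = sm.OLS(y, X).fit()
        for j, name in enumerate(sorted(best.selected)):
            est = best.summary.coefficients[name]
            assert abs(est - truths["planted"][name]) < 3 * fit.bse[j + 1]

    def test_noiseless_planted_model_exact(self):
        config = SyntheticConfig(seed=2, n_compounds=40, n_descriptors=8,
                                 collinear_pair=("d98", "d99"),
                                 descriptor_noise_sd=0.0)
        matrix, y, truths = gen_descriptor_matrix(config)
        models = search_models(matrix, y, max_vars=3, top=3)
        best = models[0]
        assert set(best.selected) == set(truths["planted"])
        for name, coef in truths["planted"].items():
            assert best.summary.coefficients[name] == pytest.approx(coef, abs=1e-9)
        assert best.summary.intercept == pytest.approx(truths["intercept"], abs=1e-9)

    def test_exclusion_search_finds_planted_outlier(self):
        rng = np.random.default_rng(21)
        n = 30
        X = rng.normal(size=(n, 3))
        y = X @ [1.0, -0.5, 0.2] + rng.normal(size=n) * 0.2
        shifted = 7
        y[shifted] += 5 * 0.2 * 5  # +5 sd shift, amplified to dominate
        m = _matrix(X, ["a", "b", "c"])
        models = search_models(m, y, max_vars=3, exclusion_search=True, top=3)
        assert models[0].excluded_compound == m.compound_names[shifted]

    def test_decoy_never_lowers_best_insample_r2(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(40, 4))
        y = X @ [1.0, 0.4, 0.0, 0.0] + rng.normal(size=40) * 0.3
        m_small = _matrix(X[:, :3], ["a", "b", "c"])
        decoy = rng.normal(size=40)
        m_big = _matrix(np.column_stack([X[:, :3], decoy]), ["a", "b", "c", "z"])

        def best_r2(models, size):
            return max(m.summary.r2 for m in models if len(m.selected) == size)

        small = search_models(m_small, y, max_vars=2, top=100)
        big = search_models(m_big, y, max_vars=2, top=100)
        for size in (1, 2):
            assert best_r2(big, size) >= best_r2(small, size) - 1e-12

    def test_empty_candidate_set_rejected(self):
        m = DescriptorMatrix(["a", "b", "c", "d"], [], np.empty((4, 0)))
        with pytest.raises(ValueError, match="empty"):
            search_models(m, [1.0, 2.0, 3.0, 4.0])


class TestRunStepwise:
    def test_pipeline_screens_filters_and_ranks(self):
        config = SyntheticConfig(seed=17, n_compounds=60, n_descriptors=10,
                                 planted={"d01": 0.9, "d02": -0.6},
                                 collinear_pair=("d01", "d04"), collinear_rho=0.995,
                                 descriptor_noise_sd=0.1)
        matrix, y, _ = gen_descriptor_matrix(config)
        report = run_stepwise(matrix, y, max_vars=3)
        # the near-duplicate of the strongest planted descriptor must fall
        # to the VIF filter, and the survivors carry sub-threshold VIFs
        assert "d04" in report["vif_removed"] or "d01" in report["vif_removed"]
        assert all(v < 5.0 for v in report["vif"].values())
        assert report["models"][0].summary.q2_loo > 0.5
        assert not report["screen_table"].empty
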