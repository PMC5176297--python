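"""The three staged transforms: sentinels, log-shift, scaling, PCA."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mirensemble.errors import (
    DegenerateCovarianceError,
    DomainError,
    RankError,
    SchemaError,
)
from mirensemble.preprocess import (
    apply_pca,
    apply_transform,
    fit_pca,
    fit_transform,
    fit_transform_I,
    fit_transform_II,
    fit_transform_III,
)

# hand computation (cross-checked with sympy at 12 digits): with fitted
# bounds [-30, ln 3240] the mode-II map sends ln(1.0) = 0 to
# 2*(0+30)/(30+ln 3240) - 1 = 0.575492536809, the 0-sentinel -25 to
# 2*5/(30+ln 3240) - 1 = -0.7374148, NA (-30) to -1 and 3240 to +1.
LN3240 = math.log(3240.0)
SPAN = 30.0 + LN3240


@pytest.fixture
def promir_table(make_table):
    return make_table(
        {"ProMiR": ["NA", 0.0, 1.0, 3240.0], "MIReNA": ["Yes", "No", "Yes", "No"]},
        labels=[1, -1, 1, -1],
    )


class TestModeI:
    def test_binary_tokens_to_pm1(self, make_table):
        t = make_table(
            {"MIReNA": ["Yes", "No"], "TripletSVM": ["NA", "1"]},
            labels=[1, -1],
        )
        _, fm = fit_transform_I(t)
        assert fm.X.tolist() == [[1.0, -1.0], [-1.0, 1.0]]

    def test_numeric_minmax_affine(self, make_table):
        # x -> 2(x-min)/(max-min) - 1 sends {0, 45.5, 91} to {-1, 0, +1}
        t = make_table({"MiPred": [0.0, 45.5, 91.0]}, labels=[-1, 1, 1])
        params, fm = fit_transform_I(t)
        assert fm.X[:, 0].tolist() == [-1.0, 0.0, 1.0]
        ct = params.columns["MiPred"]
        assert (ct.norm_lo, ct.norm_hi) == (0.0, 91.0)

    def test_numeric_na_pools_with_zero(self, make_table):
        t = make_table({"ProMiR": ["NA", 0.0, 10.0]}, labels=[-1, -1, 1])
        _, fm = fit_transform_I(t)
        assert fm.X[0, 0] == fm.X[1, 0] == -1.0

    def test_output_bounds_and_extremes_attained(self, make_table):
        t = make_table({"MiPred": [3.0, 8.5, 77.0, 91.0]}, labels=[-1, -1, 1, 1])
        _, fm = fit_transform_I(t)
        assert fm.X.min() == -1.0 and fm.X.max() == 1.0
        assert np.all(np.abs(fm.X) <= 1.0)


class TestModeII:
    def test_sentinels_and_log(self, promir_table):
        params, fm = fit_transform_II(promir_table, ["ProMiR"])
        col = fm.X[:, 0]
        assert col[0] == -1.0                      # NA -> -30 -> min
        assert col[3] == 1.0                       # 3240 -> ln 3240 -> max
        assert col[1] == pytest.approx(2 * 5 / SPAN - 1, abs=1e-12)    # 0 -> -25
        assert col[2] == pytest.approx(2 * 30 / SPAN - 1, abs=1e-12)   # ln 1 = 0
        assert col[2] == pytest.approx(0.575492536809, abs=1e-9)
        ct = params.columns["ProMiR"]
        assert ct.log_shift and (ct.na_sentinel, ct.zero_sentinel) == (-30.0, -25.0)

    def test_sentinel_order_below_smallest_dialect_score(self, make_table):
        # ln 1e-10 = -23.03 stays above the 0-sentinel, which stays above NA
        t = make_table({"ProMiR": ["NA", 0.0, 1e-10, 3240.0]}, labels=[-1, -1, -1, 1])
        _, fm = fit_transform_II(t, ["ProMiR"])
        assert fm.X[0, 0] < fm.X[1, 0] < fm.X[2, 0] < fm.X[3, 0]

    def test_negative_value_in_log_column(self, make_table):
        t = make_table({"ProMiR": [-1.0, 2.0]}, labels=[-1, 1])
        with pytest.raises(DomainError):
            fit_transform_II(t, ["ProMiR"])

    def test_binary_only_equals_mode_I(self, make_table):
        t = make_table(
            {"MIReNA": ["Yes", "No", "No"], "TripletSVM": ["1", "NA", "1"]},
            labels=[1, -1, 1],
        )
        _, fm1 = fit_transform_I(t)
        _, fm2 = fit_transform_II(t, [])
        assert np.array_equal(fm1.X, fm2.X)

    @given(st.lists(st.floats(1e-8, 1e6), min_size=3, max_size=10, unique=True))
    def test_order_preserving_on_positive_scores(self, make_table, values):
        t = make_table({"ProMiR": list(values)}, labels=[1] * len(values))
        _, fm = fit_transform_II(t, ["ProMiR"])
        order_in = np.argsort(values)
        order_out = np.argsort(fm.X[:, 0])
        assert np.array_equal(order_in, order_out)


class TestPca:
    def test_diagonal_covariance_gives_identity(self):
        # columns already principal-axis aligned, variance 4 then 1
        X = np.array([[2.0, 0.0], [-2.0, 0.0], [0.0, 1.0], [0.0, -1.0]])
        E, means = fit_pca(X)
        assert np.allclose(E, np.eye(2))
        assert np.allclose(means, 0.0)

    def test_closed_form_2x2(self):
        # centered data with covariance proportional to [[2,1],[1,2]]:
        # eigenvectors (1,1)/sqrt2 (larger eigenvalue) and (1,-1)/sqrt2
        X = np.array([
            [1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0],
            [1.0, 1.0], [-1.0, -1.0],
        ])
        E, _ = fit_pca(X)
        r = 1 / math.sqrt(2)
        assert np.allclose(E, [[r, r], [r, -r]], atol=1e-12)

    def test_rotation_of_row(self):
        r = 1 / math.sqrt(2)
        E = np.array([[r, r], [r, -r]])
        out = apply_pca(np.array([[1.0, 1.0]]), E, np.zeros(2))
        assert np.allclose(out, [[math.sqrt(2), 0.0]])

    def test_orthonormal_and_norm_preserving(self):
        rng = np.random.default_rng(42)
        X = rng.normal(size=(50, 5))
        E, means = fit_pca(X)
        assert np.max(np.abs(E.T @ E - np.eye(5))) < 1e-8
        Y = apply_pca(X, E, means)
        assert np.allclose(
            np.linalg.norm(Y, axis=1), np.linalg.norm(X - means, axis=1), atol=1e-10
        )

    def test_variance_conserved(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(200, 4)) * [3.0, 1.0, 0.5, 0.1]
        E, means = fit_pca(X)
        Y = apply_pca(X, E, means)
        assert np.isclose(Y.var(axis=0, ddof=1).sum(), X.var(axis=0, ddof=1).sum(),
                          rtol=1e-8)

    def test_matches_sklearn_components(self):
        sklearn_pca = pytest.importorskip("sklearn.decomposition").PCA
        rng = np.random.default_rng(5)
        X = rng.normal(size=(80, 5)) @ rng.normal(size=(5, 5))
        E, _ = fit_pca(X)
        ref = sklearn_pca(n_components=5).fit(X).components_  # rows are PCs
        for j in range(5):
            cos = abs(float(ref[j] @ E[:, j]))
            assert cos == pytest.approx(1.0, abs=1e-8)

    def test_rank_and_degeneracy_errors(self):
        with pytest.raises(RankError):
            fit_pca(np.eye(3))
        with pytest.raises(DegenerateCovarianceError):
            fit_pca(np.ones((10, 2)))

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            apply_pca(np.zeros((3, 2)), np.eye(3), np.zeros(2))


class TestModeIII:
    def test_equals_stepwise_oracle(self, make_table):
        # independent step-by-step computation on a 4-sample, 2-column panel
        t = make_table(
            {"MiPred": [0.0, 30.0, 60.0, 91.0], "MIReNA": ["Yes", "No", "Yes", "No"]},
            labels=[1, -1, 1, -1],
        )
        lo, hi = 0.0, 91.0
        col0 = 2 * (np.array([0.0, 30.0, 60.0, 91.0]) - lo) / (hi - lo) - 1
        col1 = np.array([1.0, -1.0, 1.0, -1.0])
        Xii = np.column_stack([col0, col1])
        means = Xii.mean(axis=0)
        cov = np.cov(Xii.T, ddof=1)
        w, v = np.linalg.eigh(cov)
        v = v[:, np.argsort(-w)]
        for j in range(2):
            if v[np.argmax(np.abs(v[:, j])), j] < 0:
                v[:, j] = -v[:, j]
        expected = (Xii - means) @ v
        _, fm = fit_transform_III(t, [])
        assert np.allclose(fm.X, expected, atol=1e-12)

    def test_params_carry_rotation(self, promir_table):
        params, _ = fit_transform_III(promir_table, ["ProMiR"])
        assert params.eigenmatrix.shape == (2, 2)
        assert params.column_means.shape == (2,)

    def test_n_equals_m_is_rank_error(self, make_table):
        t = make_table(
            {"MIReNA": ["Yes", "No"], "TripletSVM": ["1", "NA"]},
            labels=[1, -1],
        )
        with pytest.raises(RankError):
            fit_transform_III(t, [])


class TestApplyTransform:
    def test_self_consistency(self, promir_table):
        for mode, log_cols in (("I", None), ("II", ["ProMiR"]), ("III", ["ProMiR"])):
            params, fm = fit_transform(promir_table, mode, log_cols)
            fm2 = apply_transform(params, promir_table)
            assert np.allclose(fm.X, fm2.X, atol=1e-12)

    def test_out_of_range_clipped(self, make_table):
        train = make_table({"MiPred": [0.0, 91.0]}, labels=[-1, 1])
        params, _ = fit_transform_I(train)
        fresh = make_table({"MiPred": [150.0, -5.0]}, labels=[1, -1])
        fm = apply_transform(params, fresh)
        assert fm.X[:, 0].tolist() == [1.0, -1.0]

    def test_binary_path_has_no_fit_state(self, make_table):
        train = make_table({"MIReNA": ["Yes", "No"]}, labels=[1, -1])
        params, _ = fit_transform_I(train)
        fresh = make_table({"MIReNA": ["No", "Yes"]}, labels=[-1, 1])
        assert apply_transform(params, fresh).X[:, 0].tolist() == [-1.0, 1.0]

    def test_constant_column_maps_to_zero(self, make_table):
        train = make_table({"MiPred": [5.0, 5.0], "MIReNA": ["Yes", "No"]},
                           labels=[1, -1])
        params, fm = fit_transform_I(train)
        assert params.columns["MiPred"].constant
        assert np.all(fm.X[:, 0] == 0.0)
        fresh = make_table({"MiPred": [9.0], "MIReNA": ["Yes"]}, labels=[1])
        assert apply_transform(params, fresh).X[0, 0] == 0.0

    def test_schema_mismatch(self, promir_table, make_table):
        params, _ = fit_transform_I(promir_table)
        other = make_table({"MIReNA": ["Yes"]}, labels=[1])
        with pytest.raises(SchemaError):
            apply_transform(params, other)

    def test_params_yaml_round_trip(self, promir_table, tmp_path):
        from mirensemble.preprocess import TransformParams

        params, _ = fit_transform_III(promir_table, ["ProMiR"])
        path = tmp_path / "params.yaml"
        params.to_yaml(path)
        again = TransformParams.from_yaml(path)
        fm1 = apply_transform(params, promir_table)
        fm2 = apply_transform(again, promir_table)
        assert np.allclose(fm1.X, fm2.X, atol=1e-12)
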