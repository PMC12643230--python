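"""PCF transform: fit/apply contract, VIF diagnostics, loadings."""

import numpy as np
import pytest

import retorder as ro
from retorder.pcf import fit_pcf, select_components, top_loadings, vif


def _random_counting_matrix(rng, n=50, p=20):
    return rng.poisson(3.0, size=(n, p)).astype(float)


class TestFitPCF:
    def test_rank_one_matrix_has_single_component(self, rng):
        pattern = rng.uniform(1, 4, size=12)
        coeffs = rng.uniform(-2, 2, size=30)
        X = np.outer(coeffs, pattern) + 5.0
        t = fit_pcf(X)
        ratio = t.explained_variance[0] / t.explained_variance.sum()
        assert ratio == pytest.approx(1.0, abs=1e-10)

    def test_diagonal_covariance_aligns_components_with_axes(self, rng):
        n = 400
        sds = np.array([5.0, 2.0, 0.5])
        cols = [rng.normal(0, sd, size=n) for sd in sds]
        X = np.column_stack([c - c.mean() for c in cols])
        t = fit_pcf(X)
        for comp_idx, axis in enumerate([0, 1, 2]):
            row = np.abs(t.components[comp_idx])
            assert row[axis] == pytest.approx(1.0, abs=0.05)

    def test_matches_dense_eigendecomposition_oracle(self, rng):
        X = _random_counting_matrix(rng)
        t = fit_pcf(X)
        Xc = X - X.mean(axis=0)
        cov = Xc.T @ Xc / (X.shape[0] - 1)
        evals, evecs = np.linalg.eigh(cov)
        evals, evecs = evals[::-1], evecs[:, ::-1]
        assert t.explained_variance == pytest.approx(evals[: t.n_components], rel=1e-8)
        scores = t.apply(X)
        oracle_scores = Xc @ evecs[:, : t.n_components]
        for j in range(t.n_components):
            col, ocol = scores[:, j], oracle_scores[:, j]
            assert np.allclose(col, ocol, atol=1e-7) or np.allclose(col, -ocol, atol=1e-7)

    def test_constant_columns_removed_and_recorded(self, rng):
        X = _random_counting_matrix(rng, p=6)
        X[:, 2] = 7.0
        t = fit_pcf(X)
        assert 2 not in t.kept_features
        assert t.n_features_in == 6

    def test_all_constant_matrix_rejected(self):
        with pytest.raises(ValueError, match="no variance"):
            fit_pcf(np.ones((10, 4)))

    def test_sign_convention_largest_loading_positive(self, rng):
        t = fit_pcf(_random_counting_matrix(rng))
        for row in t.components:
            assert row[np.argmax(np.abs(row))] > 0


class TestApplyPCF:
    def test_apply_reproduces_fit_scores(self, rng):
        X = _random_counting_matrix(rng)
        t = fit_pcf(X)
        assert np.allclose(t.apply(X), ro.apply_pcf(t, X))

    def test_center_vector_maps_to_origin(self, rng):
        X = _random_counting_matrix(rng)
        t = fit_pcf(X)
        full = np.zeros(t.n_features_in)
        full[t.kept_features] = t.center
        assert np.allclose(t.apply(full), 0.0, atol=1e-10)

    def test_new_molecule_projects_without_refit(self, rng):
        X = _random_counting_matrix(rng)
        t = fit_pcf(X)
        before = (t.center.copy(), t.components.copy())
        x_new = rng.poisson(3.0, size=X.shape[1]).astype(float)
        scores = t.apply(x_new)
        assert scores.shape == (1, t.n_components) and np.isfinite(scores).all()
        Xc = x_new[t.kept_features] - t.center
        assert np.allclose(scores[0], t.components @ Xc)
        assert np.array_equal(before[0], t.center)        # apply never refits
        assert np.array_equal(before[1], t.components)

    def test_length_mismatch_names_both_lengths(self, rng):
        t = fit_pcf(_random_counting_matrix(rng, p=20))
        with pytest.raises(ValueError, match="5.*20|20.*5"):
            t.apply(np.ones(5))

    def test_roundtrip_reconstruction(self, rng):
        X = _random_counting_matrix(rng, n=40, p=10)
        t = fit_pcf(X)
        scores = t.apply(X)
        recon = scores @ t.components + t.center
        Xk = X[:, t.kept_features]
        rel = np.abs(recon - Xk).max() / np.abs(Xk).max()
        assert rel < 1e-8

    def test_training_scores_are_decorrelated(self, rng):
        X = _random_counting_matrix(rng, n=60, p=15)
        t = fit_pcf(X)
        corr = np.corrcoef(t.apply(X), rowvar=False)
        off_diag = corr - np.diag(np.diag(corr))
        assert np.abs(off_diag).max() < 1e-8

    def test_json_roundtrip(self, rng, tmp_path):
        X = _random_counting_matrix(rng)
        t = fit_pcf(X)
        path = tmp_path / "t.json"
        t.to_json(path)
        back = ro.PCFTransform.from_json(path)
        assert np.allclose(back.apply(X), t.apply(X))


class TestVIF:
    def test_orthogonal_columns_give_unit_vif(self):
        n = 64
        # Exactly orthogonal mean-zero design from a Hadamard-like basis
        base = np.array([[1, 1, 1, 1], [1, -1, 1, -1], [1, 1, -1, -1], [1, -1, -1, 1]])
        X = np.tile(base, (n // 4, 1)).astype(float)[:, 1:]  # drop constant col
        values = vif(X)
        assert values == pytest.approx(np.ones(3), abs=1e-10)

    def test_duplicated_column_reports_infinity(self, rng):
        x = rng.normal(size=50)
        X = np.column_stack([x, x, rng.normal(size=50)])
        values = vif(X)
        assert np.isinf(values[0]) and np.isinf(values[1])

    def test_planted_near_collinear_column_exceeds_ten(self):
        rng = np.random.default_rng(42)
        n = 200
        x1, x2 = rng.normal(size=n), rng.normal(size=n)
        x3 = x1 + x2 + rng.normal(0, 0.01, size=n)
        X = np.column_stack([x1, x2, x3])
        values = vif(X)
        # closed-form oracle for column 3
        design = np.column_stack([np.ones(n), x1, x2])
        coef, *_ = np.linalg.lstsq(design, x3, rcond=None)
        resid = x3 - design @ coef
        r2 = 1 - resid @ resid / ((x3 - x3.mean()) @ (x3 - x3.mean()))
        assert values[2] == pytest.approx(1 / (1 - r2), rel=1e-8)
        assert values[2] > 10

    def test_constant_column_rejected(self, rng):
        X = np.column_stack([rng.normal(size=30), np.full(30, 2.0)])
        with pytest.raises(ValueError, match="constant"):
            vif(X)

    def test_wide_matrix_subsampled_with_warning(self, rng):
        X = rng.normal(size=(20, 40))
        with pytest.warns(UserWarning, match="subsample"):
            values = vif(X, max_features=10)
        assert np.isfinite(values[~np.isnan(values)]).all()
        assert np.sum(~np.isnan(values)) == 10


class TestSelectComponents:
    def test_full_truncation_is_identity(self, rng):
        t = fit_pcf(_random_counting_matrix(rng))
        same = select_components(t, t.n_components)
        assert np.array_equal(same.components, t.components)

    def test_truncation_keeps_leading_variance(self, rng):
        t = fit_pcf(_random_counting_matrix(rng, n=60, p=30))
        k = 10
        tk = select_components(t, k)
        assert tk.n_components == k
        assert tk.explained_variance.sum() == pytest.approx(
            t.explained_variance[:k].sum()
        )

    @pytest.mark.parametrize("k", [0, -1, 10_000])
    def test_out_of_range_k_rejected(self, rng, k):
        t = fit_pcf(_random_counting_matrix(rng))
        with pytest.raises(ValueError, match="k must be"):
            select_components(t, k)


class TestTopLoadings:
    def test_axis_aligned_component_found(self):
        rng = np.random.default_rng(3)
        n = 200
        X = rng.normal(0, 0.1, size=(n, 9))
        X[:, 7] += rng.normal(0, 10.0, size=n)  # dominant axis e_7
        t = fit_pcf(X)
        labels = [f"f{j}" for j in range(9)]
        (label, loading), *_ = top_loadings(t, 0, 1, labels)
        assert label == "f7"
        assert abs(loading) == pytest.approx(1.0, abs=0.01)

    def test_contract_five_entries_non_increasing(self, rng):
        t = fit_pcf(_random_counting_matrix(rng))
        labels = [f"f{j}" for j in range(20)]
        entries = top_loadings(t, 1, 5, labels)
        mags = [abs(v) for _, v in entries]
        assert len(entries) == 5
        assert mags == sorted(mags, reverse=True)

    def test_agrees_with_full_sort_oracle(self, rng):
        t = fit_pcf(_random_counting_matrix(rng))
        labels = [f"f{j}" for j in range(20)]
        got = top_loadings(t, 2, 20, labels)
        full = np.zeros(20)
        full[t.kept_features] = t.components[2]
        oracle = sorted(range(20), key=lambda j: (-abs(full[j]), j))
        assert [lab for lab, _ in got] == [labels[j] for j in oracle]

    def test_restriction_to_feature_block(self, rng):
        t = fit_pcf(_random_counting_matrix(rng))
        labels = [f"f{j}" for j in range(20)]
        got = top_loadings(t, 0, 3, labels, restrict_to=slice(0, 5))
        assert all(int(lab[1:]) < 5 for lab, _ in got)
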