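import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from circapal.pal import (
    ZeroVarianceError,
    compute_pal,
    fix_sign,
    normalize_rows,
    variance_fraction,
)

from conftest import make_pathway_matrix


def oracle_first_component(X):
    """Brute-force first singular component via the eigen-decomposition of
    X'X: independent of the SVD code path under test."""
    X = np.asarray(X, dtype=float)
    evals, evecs = np.linalg.eigh(X.T @ X)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    activity = evecs[:, order[0]]
    sigma1 = np.sqrt(evals[0])
    weights = X @ activity / sigma1 if sigma1 > 0 else np.zeros(X.shape[0])
    f = evals[0] / evals.sum()
    return f, activity, weights, np.sqrt(evals)


class TestNormalizeRows:
    def test_rows_become_zscores(self, small_design, rng):
        m = make_pathway_matrix(rng.normal(2.0, 3.0, size=(4, 12)),
                                small_design)
        out = normalize_rows(m)
        assert np.all(np.abs(out.values.mean(axis=1)) < 1e-10)
        np.testing.assert_allclose(out.values.std(axis=1, ddof=1), 1.0)

    def test_simple_row(self, small_design):
        m = make_pathway_matrix([[1, 2, 3] * 4, [5, 1, 2] * 4], small_design)
        out = normalize_rows(m)
        assert abs(out.values[0].mean()) < 1e-10
        assert abs(out.values[0].std(ddof=1) - 1.0) < 1e-12

    def test_constant_row_error_names_gene(self, small_design):
        m = make_pathway_matrix(
            [[5.0] * 12, [1, 2] * 6], small_design, gene_ids=["flat", "ok"]
        )
        with pytest.raises(ZeroVarianceError, match="flat"):
            normalize_rows(m)

    def test_drop_constant_policy(self, small_design):
        m = make_pathway_matrix(
            [[5.0] * 12, [1, 2] * 6, [3, 1] * 6], small_design,
            gene_ids=["flat", "a", "b"],
        )
        out = normalize_rows(m, policy="drop-constant")
        assert out.gene_ids == ["a", "b"]


class TestComputePAL:
    def test_identical_rows_are_rank_one(self, small_design, rng):
        row = rng.normal(size=12)
        m = normalize_rows(
            make_pathway_matrix(np.tile(row, (5, 1)), small_design)
        )
        pal = compute_pal(m)
        assert pal.variance_fraction == pytest.approx(1.0, abs=1e-12)

    def test_2x2_antisymmetric_example(self, rng):
        from circapal.data_io import TimeDesign
        d = TimeDesign((0.0, 12.0), replicates_per_time=1)
        m = make_pathway_matrix([[1.0, -1.0], [-1.0, 1.0]], d)
        pal = compute_pal(m)
        assert pal.variance_fraction == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(
            np.abs(pal.activity), np.full(2, 1 / np.sqrt(2)), atol=1e-12
        )

    def test_unit_norm_and_sorted_singular_values(self, small_design, rng):
        m = normalize_rows(
            make_pathway_matrix(rng.normal(size=(6, 12)), small_design)
        )
        pal = compute_pal(m)
        assert np.linalg.norm(pal.activity) == pytest.approx(1.0)
        assert np.linalg.norm(pal.weights) == pytest.approx(1.0)
        assert np.all(np.diff(pal.singular_values) <= 1e-12)
        assert 0.0 <= pal.variance_fraction <= 1.0

    def test_rank1_reconstruction_is_best(self, small_design, rng):
        m = normalize_rows(
            make_pathway_matrix(rng.normal(size=(5, 12)), small_design)
        )
        pal = compute_pal(m)
        recon = (pal.singular_values[0]
                 * np.outer(pal.weights, pal.activity))
        resid = np.sum((m.values - recon) ** 2)
        total = np.sum(m.values ** 2)
        assert resid / total == pytest.approx(1 - pal.variance_fraction,
                                              abs=1e-10)

    def test_matches_oracle_on_small_matrices(self, rng):
        """SVD path agrees with a brute-force eigen-decomposition oracle on
        random matrices up to 6x6."""
        from circapal.data_io import TimeDesign
        for trial in range(60):
            k = int(rng.integers(2, 7))
            t = int(rng.integers(2, 7))
            d = TimeDesign(tuple(np.linspace(0, 20, t)), 1)
            X = rng.normal(size=(k, t))
            pal = compute_pal(make_pathway_matrix(X, d))
            f, activity, weights, svals = oracle_first_component(X)
            assert pal.variance_fraction == pytest.approx(f, abs=1e-10)
            # vectors agree up to global sign
            dot = abs(np.dot(pal.activity, activity))
            if svals[0] - svals[1] > 1e-6:  # well-separated top component
                assert dot == pytest.approx(1.0, abs=1e-8)
            np.testing.assert_allclose(
                pal.singular_values[: min(k, t)], svals[: min(k, t)],
                atol=1e-10,
            )

    def test_sign_invariance_of_f(self, small_design, rng):
        X = rng.normal(size=(5, 12))
        p1 = compute_pal(make_pathway_matrix(X, small_design))
        p2 = compute_pal(make_pathway_matrix(-X, small_design))
        assert p1.variance_fraction == pytest.approx(p2.variance_fraction,
                                                     abs=1e-12)
        dot = abs(np.dot(p1.activity, p2.activity))
        assert dot == pytest.approx(1.0, abs=1e-10)

    def test_column_permutation_permutes_activity(self, small_design, rng):
        X = rng.normal(size=(5, 12))
        perm = rng.permutation(12)
        p1 = compute_pal(make_pathway_matrix(X, small_design))
        p2 = compute_pal(make_pathway_matrix(X[:, perm], small_design))
        assert p1.variance_fraction == pytest.approx(p2.variance_fraction,
                                                     abs=1e-12)
        dot = abs(np.dot(p1.activity[perm], p2.activity))
        assert dot == pytest.approx(1.0, abs=1e-10)

    def test_duplicated_gene_row_raises_f(self, small_design, rng):
        X = rng.normal(size=(4, 12))
        f1 = compute_pal(make_pathway_matrix(X, small_design)).variance_fraction
        # duplicate the gene that carries the dominant pattern
        pal = compute_pal(make_pathway_matrix(X, small_design))
        top = int(np.argmax(np.abs(pal.weights)))
        X2 = np.vstack([X, X[top]])
        f2 = compute_pal(make_pathway_matrix(X2, small_design)).variance_fraction
        assert f2 >= f1 - 1e-12

    def test_degenerate_shapes_rejected(self, rng):
        from circapal.data_io import TimeDesign
        d = TimeDesign((0.0, 6.0), 1)
        with pytest.raises(ValueError):
            compute_pal(make_pathway_matrix(np.ones((1, 2)), d))


class TestFixSign:
    def _pal(self, small_design, rng):
        return compute_pal(
            make_pathway_matrix(rng.normal(size=(4, 12)), small_design),
            canonical_sign=False,
        )

    def test_top_weight_positive(self, small_design, rng):
        pal = self._pal(small_design, rng)
        fixed = fix_sign(pal, mode="top_weight_positive")
        top = int(np.argmax(np.abs(fixed.weights)))
        assert fixed.weights[top] > 0
        # weights and activity flipped together: reconstruction unchanged
        np.testing.assert_allclose(
            np.outer(fixed.weights, fixed.activity),
            np.outer(pal.weights, pal.activity),
            atol=1e-12,
        )

    def test_idempotent_when_already_positive(self, small_design, rng):
        pal = fix_sign(self._pal(small_design, rng))
        again = fix_sign(pal)
        np.testing.assert_array_equal(pal.weights, again.weights)
        assert pal.sign_convention == again.sign_convention

    def test_reference_correlation_flip(self, small_design, rng):
        pal = self._pal(small_design, rng)
        ref = -pal.activity + rng.normal(0, 0.05, size=12)
        fixed = fix_sign(pal, mode="reference_correlation", reference=ref)
        a = fixed.activity - fixed.activity.mean()
        r = ref - ref.mean()
        assert a @ r > 0

    def test_zero_correlation_keeps_sign(self, small_design, rng, caplog):
        pal = self._pal(small_design, rng)
        ref = np.zeros(12)
        with caplog.at_level("WARNING"):
            fixed = fix_sign(pal, mode="reference_correlation", reference=ref)
        np.testing.assert_array_equal(fixed.activity, pal.activity)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1), st.integers(2, 6), st.integers(3, 8))
def test_variance_fraction_matches_oracle_property(seed, k, t):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(k, t))
    f_oracle, *_ = oracle_first_component(X)
    assert variance_fraction(X) == pytest.approx(f_oracle, abs=1e-10)
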