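import numpy as np
import pytest

from circapal.consensus import (
    AgreementMatrix,
    anova_filter,
    final_clusters,
    run_ensemble,
    select_consistent_subset,
    sign_align,
)
from circapal.rhythm import TimeProfile

OMEGA24 = 2 * np.pi / 24


def profiles_two_groups(design, n_a=4, n_b=4, noise=0.05, seed=0):
    """Well-separated sinusoid and anti-phase-shifted (quadrature) groups."""
    rng = np.random.default_rng(seed)
    t = np.asarray(design.time_points)
    out = []
    for i in range(n_a):
        out.append(TimeProfile(
            t, np.sin(OMEGA24 * t) + rng.normal(0, noise, t.size), f"a{i}"
        ))
    for i in range(n_b):
        out.append(TimeProfile(
            t, np.sin(OMEGA24 * t + np.pi / 2) + rng.normal(0, noise, t.size),
            f"b{i}",
        ))
    return out


class TestAnovaFilter:
    def test_strong_time_signal_kept(self, design54, rng):
        t = design54.sample_times()
        pal = np.sin(OMEGA24 * t) + rng.normal(0, 0.05, size=54)
        keep, p = anova_filter(pal, design54)
        assert keep and p < 0.01

    def test_pure_replicate_noise_mostly_dropped(self, design54):
        dropped = 0
        for seed in range(100):
            pal = np.random.default_rng(seed).normal(size=54)
            keep, _ = anova_filter(pal, design54)
            dropped += not keep
        # alpha = 0.01 null: expect ~99 dropped; allow binomial slack
        assert dropped >= 95

    def test_constant_pal_dropped(self, design54):
        keep, p = anova_filter(np.full(54, 1.23), design54)
        assert not keep and p == 1.0

    def test_exact_group_effect_without_noise(self, design54):
        idx = design54.time_index()
        keep, p = anova_filter(idx.astype(float), design54)
        assert keep and p == 0.0

    def test_needs_replicates(self):
        from circapal.data_io import TimeDesign
        d = TimeDesign((0.0, 6.0, 12.0), replicates_per_time=1)
        with pytest.raises(ValueError):
            anova_filter(np.arange(3.0), d)


class TestSignAlign:
    def test_x_and_minus_x_align(self, design54, rng):
        t = np.asarray(design54.time_points)
        x = np.sin(OMEGA24 * t) + rng.normal(0, 0.05, t.size)
        aligned = sign_align([
            TimeProfile(t, x, "p"), TimeProfile(t, -x, "m")
        ])
        c = np.corrcoef(aligned[0].values, aligned[1].values)[0, 1]
        assert c > 0.99

    def test_already_aligned_unchanged(self, design54, rng):
        t = np.asarray(design54.time_points)
        profs = [
            TimeProfile(t, np.sin(OMEGA24 * t) + rng.normal(0, 0.1, t.size),
                        f"p{i}")
            for i in range(3)
        ]
        aligned = sign_align(profs)
        for before, after in zip(profs, aligned):
            np.testing.assert_array_equal(before.values, after.values)

    def test_random_signs_end_up_nonnegative_pairwise(self, design54):
        rng = np.random.default_rng(7)
        t = np.asarray(design54.time_points)
        profs = [
            TimeProfile(
                t,
                rng.choice([-1.0, 1.0])
                * (np.sin(OMEGA24 * t + 0.2 * i)
                   + rng.normal(0, 0.05, t.size)),
                f"p{i}",
            )
            for i in range(6)
        ]
        aligned = sign_align(profs)
        X = np.stack([p.values for p in aligned])
        C = np.corrcoef(X)
        assert np.all(C >= -1e-9)

    def test_global_negation_invariant_downstream(self, design54):
        profs = profiles_two_groups(design54)
        flipped = [TimeProfile(p.times, -p.values, p.label) for p in profs]
        a1 = run_ensemble(sign_align(profs), k_range=(2, 3), seed=0)
        a2 = run_ensemble(sign_align(flipped), k_range=(2, 3), seed=0)
        np.testing.assert_allclose(a1.values, a2.values, atol=1e-12)


class TestRunEnsemble:
    def test_two_separated_groups(self, design54):
        profs = profiles_two_groups(design54)
        agreement = run_ensemble(profs, k_range=(2, 2), seed=0)
        A = agreement.values
        names = agreement.items
        in_a = np.array([n.startswith("a") for n in names])
        assert np.all(A[np.ix_(in_a, in_a)] > 0.9)
        assert np.all(A[np.ix_(in_a, ~in_a)] < 0.1)
        assert np.all(A[np.ix_(~in_a, ~in_a)] > 0.9)

    def test_symmetry_range_diagonal(self, design54):
        agreement = run_ensemble(profiles_two_groups(design54, noise=0.3),
                                 k_range=(2, 4), seed=1)
        A = agreement.values
        np.testing.assert_allclose(A, A.T, atol=1e-12)
        assert np.all((A >= 0) & (A <= 1))
        np.testing.assert_allclose(np.diag(A), 1.0)

    def test_run_count_bookkeeping(self, design54):
        agreement = run_ensemble(profiles_two_groups(design54),
                                 k_range=(2, 3), seed=0)
        # per k: 3 distance families x 3 metrics + 3 euclidean-only = 12
        assert agreement.n_runs <= 2 * 12
        assert agreement.n_runs >= 2 * 12 // 2  # >50% failures would raise

    def test_determinism_under_seed(self, design54):
        profs = profiles_two_groups(design54, noise=0.4)
        a1 = run_ensemble(profs, k_range=(2, 4), seed=5)
        a2 = run_ensemble(profs, k_range=(2, 4), seed=5)
        np.testing.assert_array_equal(a1.values, a2.values)

    def test_too_few_profiles(self, design54):
        with pytest.raises(ValueError):
            run_ensemble(profiles_two_groups(design54, n_a=1, n_b=1),
                         k_range=(2, 2))


class TestSelectConsistentSubset:
    def _agreement(self, A, names=None):
        A = np.asarray(A, dtype=float)
        names = names or [f"P{i}" for i in range(A.shape[0])]
        return AgreementMatrix(names, A, n_runs=10)

    def test_binary_agreement_keeps_everything(self):
        A = np.array([
            [1, 1, 0], [1, 1, 0], [0, 0, 1]
        ], dtype=float)
        kept = select_consistent_subset(self._agreement(A), delta=0.65)
        assert kept == ["P0", "P1", "P2"]

    def test_single_ambiguous_pair_removes_one(self):
        A = np.array([
            [1.0, 0.5, 1.0],
            [0.5, 1.0, 0.0],
            [1.0, 0.0, 1.0],
        ])
        kept = select_consistent_subset(self._agreement(A), delta=0.65)
        assert len(kept) == 2
        # removing either of the 0.5 pair resolves it; the tie-break picks
        # the member with lower mean agreement (P1)
        assert kept == ["P0", "P2"]

    def test_delta_one_keeps_only_binary(self):
        A = np.array([
            [1.0, 0.99, 0.0],
            [0.99, 1.0, 0.0],
            [0.0, 0.0, 1.0],
        ])
        kept = select_consistent_subset(self._agreement(A), delta=1.0)
        assert len(kept) == 2  # one of the 0.99 pair must go

    def test_retained_set_is_consistent_invariant(self, design54):
        profs = profiles_two_groups(design54, noise=0.5, seed=3)
        agreement = run_ensemble(profs, k_range=(2, 4), seed=3)
        kept = select_consistent_subset(agreement, delta=0.65)
        sub = agreement.restrict(kept).values
        off = ~np.eye(len(kept), dtype=bool)
        assert np.all((sub[off] >= 0.65) | (sub[off] <= 0.35))

    def test_delta_validated(self):
        with pytest.raises(ValueError):
            select_consistent_subset(self._agreement(np.eye(2)), delta=0.4)


class TestFinalClusters:
    def test_two_perfect_blocks(self, design54):
        profs = profiles_two_groups(design54, noise=0.02)
        A = np.zeros((8, 8))
        A[:4, :4] = 1.0
        A[4:, 4:] = 1.0
        np.fill_diagonal(A, 1.0)
        agreement = AgreementMatrix([p.label for p in profs], A, 10)
        result = final_clusters(agreement, profs, k_range=(2, 5))
        assert result.k_clusters == 2
        labels = np.asarray(result.labels)
        assert len(set(labels[:4])) == 1
        assert len(set(labels[4:])) == 1
        assert labels[0] != labels[-1]

    def test_identical_sinusoid_cluster_centroid_fit(self, design54):
        t = np.asarray(design54.time_points)
        profs = [
            TimeProfile(t, np.sin(OMEGA24 * t), f"s{i}") for i in range(4)
        ] + [
            TimeProfile(t, np.sin(OMEGA24 * t + np.pi / 2), f"q{i}")
            for i in range(3)
        ]
        A = np.eye(7)
        A[:4, :4] = 1.0
        A[4:, 4:] = 1.0
        agreement = AgreementMatrix([p.label for p in profs], A, 10)
        result = final_clusters(agreement, profs, k_range=(2, 4))
        for fit in result.centroid_fits:
            assert fit.correlation > 0.999
            assert fit.is_circadian

    def test_empty_agreement_rejected(self):
        with pytest.raises(ValueError):
            final_clusters(AgreementMatrix([], np.zeros((0, 0)), 1), [])
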