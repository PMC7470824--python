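"""The correlation classifier and representational distance against exhaustive oracles."""

import numpy as np
import pytest

from megword import decode, features, synthgen
from conftest import make_random_features


def bruteforce_decode(
    vectors: np.ndarray, labels: np.ndarray, candidates: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Exhaustive re-implementation: explicit pairwise np.corrcoef loops.

    Independent of the vectorised path: per test trial, correlate with every
    reference trial of each candidate (same-word references exclude the test
    trial), average within candidate, decode the max (ties -> smallest id),
    and compute d = within-mean minus the mean of the three foil means.
    """
    n = len(labels)
    decoded = np.empty(n, dtype=int)
    dist = np.empty(n)
    for t in range(n):
        means = {}
        for w in candidates[t]:
            refs = [s for s in range(n) if labels[s] == w and s != t]
            corrs = [np.corrcoef(vectors[t], vectors[s])[0, 1] for s in refs]
            means[w] = np.mean(corrs)
        best = max(sorted(means), key=lambda w: means[w])
        decoded[t] = best
        within = means[labels[t]]
        foils = [means[w] for w in candidates[t] if w != labels[t]]
        dist[t] = within - np.mean(foils)
    return decoded, dist


class TestLeaveOneOutClassifier:
    def test_matches_exhaustive_oracle(self):
        # seeded 4-word x 3-trial instance on a 2-gridpoint x 2-bin searchlight
        rng = np.random.default_rng(42)
        ft, labels, candidates = make_random_features(rng)
        res = decode.decode_full(ft, labels, candidates)
        dec_o, d_o = bruteforce_decode(ft.vectors(0), labels, candidates)
        assert np.array_equal(res.classification.decoded[:, 0], dec_o)
        assert np.allclose(res.distances.d[:, 0], d_o, atol=1e-12)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_oracle_on_larger_instances(self, seed):
        rng = np.random.default_rng(seed)
        ft, labels, candidates = make_random_features(
            rng, n_words=6, n_trials_per_word=4, n_points=2, n_bins=4
        )
        res = decode.decode_full(ft, labels, candidates)
        dec_o, d_o = bruteforce_decode(ft.vectors(0), labels, candidates)
        assert np.array_equal(res.classification.decoded[:, 0], dec_o)
        assert np.allclose(res.distances.d[:, 0], d_o, atol=1e-12)

    def test_identical_within_word_trials_decode_perfectly(self):
        # each word's trials identical, words mutually distinct -> performance 1
        rng = np.random.default_rng(7)
        patterns = rng.standard_normal((4, 8))
        labels = np.repeat(np.arange(4), 3)
        vectors = patterns[labels]
        ft = features.FeatureTensor(
            binned=vectors[:, None, :],
            searchlights=features.SearchlightIndex((np.array([0]),), np.inf),
            bin_ms=20.0,
            window_ms=160.0,
        )
        candidates = np.tile(np.arange(4), (12, 1))
        cm = decode.classify_loo(ft, labels, candidates)
        assert cm.performance[0] == 1.0

    def test_decoded_correct_implies_positive_distance(self):
        rng = np.random.default_rng(11)
        ft, labels, candidates = make_random_features(
            rng, n_words=4, n_trials_per_word=5, n_points=3, n_bins=5
        )
        res = decode.decode_full(ft, labels, candidates)
        correct = res.classification.decoded[:, 0] == labels
        assert np.all(res.distances.d[correct, 0] > 0)

    def test_affine_invariance_of_decodes_and_distance(self):
        rng = np.random.default_rng(13)
        ft, labels, candidates = make_random_features(rng, n_points=3, n_bins=4)
        res_a = decode.decode_full(ft, labels, candidates)
        ft_b = features.FeatureTensor(
            binned=ft.binned * 3.5 - 1.2,
            searchlights=ft.searchlights,
            bin_ms=ft.bin_ms,
            window_ms=ft.window_ms,
        )
        res_b = decode.decode_full(ft_b, labels, candidates)
        assert np.array_equal(
            res_a.classification.decoded, res_b.classification.decoded
        )
        assert np.allclose(res_a.distances.d, res_b.distances.d, atol=1e-10)

    def test_exact_tie_decodes_smallest_word_id(self):
        # two candidates with identical reference patterns -> tie -> lower id
        pattern_a = np.array([1.0, -1.0, 0.0, 0.0])
        pattern_b = np.array([0.0, 0.0, 1.0, -1.0])
        labels = np.array([0, 0, 1, 1, 2, 2, 3, 3])
        # words 0 and 1 share a pattern; words 2 and 3 share another
        vectors = np.vstack([pattern_a] * 4 + [pattern_b] * 4)
        ft = features.FeatureTensor(
            binned=vectors[:, None, :],
            searchlights=features.SearchlightIndex((np.array([0]),), np.inf),
            bin_ms=20.0,
            window_ms=80.0,
        )
        candidates = np.tile(np.arange(4), (8, 1))
        cm = decode.classify_loo(ft, labels, candidates)
        assert np.all(np.isin(cm.decoded[:, 0], [0, 2]))

    def test_label_permutations_average_to_chance(self):
        # signal-free instance: shuffled labels decode at 25% on average
        rng = np.random.default_rng(17)
        ft, labels, candidates = make_random_features(
            rng, n_words=4, n_trials_per_word=5, n_points=2, n_bins=6
        )
        perms = np.stack([rng.permutation(len(labels)) for _ in range(3000)])
        res = decode.decode_full(ft, labels, candidates, permutations=perms)
        assert abs(res.perm_performance.mean() - 0.25) < 0.02

    def test_missing_candidate_reference_rejected(self):
        rng = np.random.default_rng(19)
        ft, labels, candidates = make_random_features(rng)
        candidates = candidates.copy()
        candidates[0, 3] = 9  # word 9 has no trials at all
        with pytest.raises(ValueError, match="zero reference trials"):
            decode.classify_loo(ft, labels, candidates)

    def test_constant_feature_vector_rejected(self):
        rng = np.random.default_rng(23)
        ft, labels, candidates = make_random_features(rng)
        ft.binned[2] = 4.2
        with pytest.raises(ValueError, match="constant feature vector"):
            decode.classify_loo(ft, labels, candidates)

    def test_performance_averaged_across_categories(self):
        # category averaging weighs a small category equally with a large one
        rng = np.random.default_rng(29)
        ft, labels, candidates = make_random_features(
            rng, n_words=4, n_trials_per_word=4
        )
        categories = (labels >= 2).astype(int)
        res = decode.decode_full(ft, labels, candidates, categories)
        correct = res.classification.decoded[:, 0] == labels
        expected = np.mean(
            [correct[categories == c].mean() for c in (0, 1)]
        )
        assert res.classification.performance[0] == pytest.approx(expected)


class TestRepresentationalDistance:
    def test_orthogonal_foils_give_distance_one(self):
        # within-correlations all 1, foil correlations all 0 -> d = 1
        patterns = np.array(
            [
                [1.0, -1.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0],
                [0.0, 0.0, 1.0, -1.0, 0.0, 0.0, 0.0, 0.0],
                [0.0, 0.0, 0.0, 0.0, 1.0, -1.0, 0.0, 0.0],
                [0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 1.0, -1.0],
            ]
        )
        labels = np.repeat(np.arange(4), 2)
        vectors = patterns[labels]
        ft = features.FeatureTensor(
            binned=vectors[:, None, :],
            searchlights=features.SearchlightIndex((np.array([0]),), np.inf),
            bin_ms=20.0,
            window_ms=160.0,
        )
        candidates = np.tile(np.arange(4), (8, 1))
        dt = decode.representational_distance(ft, labels, candidates)
        assert np.allclose(dt.d, 1.0, atol=1e-12)

    def test_all_trials_identical_gives_zero(self):
        vectors = np.tile(np.array([1.0, 2.0, 4.0, 8.0]), (8, 1))
        labels = np.repeat(np.arange(4), 2)
        ft = features.FeatureTensor(
            binned=vectors[:, None, :],
            searchlights=features.SearchlightIndex((np.array([0]),), np.inf),
            bin_ms=20.0,
            window_ms=80.0,
        )
        candidates = np.tile(np.arange(4), (8, 1))
        dt = decode.representational_distance(ft, labels, candidates)
        assert np.allclose(dt.d, 0.0, atol=1e-12)

    def test_bounded_in_minus_two_two(self):
        rng = np.random.default_rng(31)
        ft, labels, candidates = make_random_features(
            rng, n_words=4, n_trials_per_word=6, n_points=2, n_bins=3
        )
        dt = decode.representational_distance(ft, labels, candidates)
        assert np.all(dt.d >= -2.0) and np.all(dt.d <= 2.0)


class TestCrossClassification:
    def _simulate_pair(self, shared: bool, gain: float, seed: int):
        grid = synthgen.make_grid(6.0, 12.0)
        cfg = synthgen.GeneratorConfig(
            n_words=8, n_categories=1, n_reps=5, n_conditions=2,
            grid_extent=12.0, n_samples=85, word_onset=5,
            pattern_gain=gain, noise_sd=1.0,
            shared_patterns_across_conditions=shared, seed=seed,
        )
        trials = features.zscore_trials(synthgen.generate_trials(cfg, grid))
        sls = features.build_searchlights(grid, 6.0)
        ft = features.extract_word_window(trials, sls)
        subs = {}
        for c in (0, 1):
            mask = trials.conditions == c
            subs[c] = (
                features.FeatureTensor(ft.binned[mask], sls, 20.0, 500.0),
                trials.words[mask],
                trials.candidates[mask],
            )
        return subs

    def test_identical_noise_free_reference_decodes_perfectly(self):
        # reference condition an exact copy, words noise-free and distinct
        rng = np.random.default_rng(37)
        patterns = rng.standard_normal((4, 12))
        labels = np.repeat(np.arange(4), 3)
        candidates = np.tile(np.arange(4), (12, 1))
        ft = features.FeatureTensor(
            binned=patterns[labels][:, None, :],
            searchlights=features.SearchlightIndex((np.array([0]),), np.inf),
            bin_ms=20.0,
            window_ms=240.0,
        )
        cm = decode.cross_classify(ft, labels, candidates, ft, labels)
        assert np.all(cm.performance == 1.0)

    def test_shared_templates_transfer_above_chance(self):
        subs = self._simulate_pair(shared=True, gain=2.0, seed=41)
        (ft0, w0, c0), (ft1, w1, _) = subs[0], subs[1]
        cm = decode.cross_classify(ft0, w0, c0, ft1, w1)
        assert cm.performance.mean() > 0.5

    def test_independent_templates_stay_at_chance(self):
        subs = self._simulate_pair(shared=False, gain=2.0, seed=43)
        (ft0, w0, c0), (ft1, w1, _) = subs[0], subs[1]
        cm = decode.cross_classify(ft0, w0, c0, ft1, w1)
        # 40 trials x 27 searchlights, correlated; generous binomial band
        assert abs(cm.performance.mean() - 0.25) < 0.15

    def test_missing_candidate_coverage_rejected(self):
        rng = np.random.default_rng(47)
        ft, labels, candidates = make_random_features(rng)
        ref_labels = labels.copy()
        ref_labels[ref_labels == 3] = 0  # word 3 absent from the reference set
        with pytest.raises(ValueError, match="zero reference trials"):
            decode.cross_classify(ft, labels, candidates, ft, ref_labels)
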