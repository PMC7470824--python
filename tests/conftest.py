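"""Shared fixtures and scaled-down study configurations for the test suite."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from megword import decode, features, neurobehav, stats, synthgen


@pytest.fixture(scope="session")
def small_grid() -> synthgen.SourceGrid:
    """5x5x5 lattice at 6 mm spacing (extent 24 mm)."""
    return synthgen.make_grid(6.0, 24.0)


@pytest.fixture(scope="session")
def tiny_grid() -> synthgen.SourceGrid:
    """3x3x3 lattice at 6 mm spacing."""
    return synthgen.make_grid(6.0, 12.0)


def make_random_features(
    rng: np.random.Generator,
    n_words: int = 4,
    n_trials_per_word: int = 3,
    n_points: int = 2,
    n_bins: int = 2,
) -> tuple[features.FeatureTensor, np.ndarray, np.ndarray]:
    """A single-searchlight feature tensor with 4-AFC candidate sets."""
    n_trials = n_words * n_trials_per_word
    labels = np.repeat(np.arange(n_words), n_trials_per_word)
    labels = rng.permutation(labels)
    candidates = np.empty((n_trials, 4), dtype=int)
    for t, w in enumerate(labels):
        foils = rng.choice(np.setdiff1d(np.arange(n_words), [w]), 3, replace=False)
        candidates[t] = np.concatenate([[w], foils])
    binned = rng.standard_normal((n_trials, n_points, n_bins))
    sls = features.SearchlightIndex(
        members=(np.arange(n_points),), radius=np.inf
    )
    ft = features.FeatureTensor(
        binned=binned, searchlights=sls, bin_ms=20.0, window_ms=20.0 * n_bins
    )
    return ft, labels, candidates


def recovery_config(seed: int) -> synthgen.GeneratorConfig:
    """Scaled-down single-condition design for neuro-behavioural recovery runs.

    8 words in one category on a 5x5x5 grid; a searchlight-sized ball of 7
    grid points around (-6, 0, 0) both carries the word patterns and drives
    single-trial accuracy through the logistic link (slope 3 on the
    standardised ground-truth distance).
    """
    grid = synthgen.make_grid(6.0, 24.0)
    centre = np.array([-6.0, 0.0, 0.0])
    region = np.flatnonzero(
        np.linalg.norm(grid.positions - centre, axis=1) <= 6.0 + 1e-9
    )
    return synthgen.GeneratorConfig(
        n_participants=14,
        n_words=8,
        n_categories=1,
        n_reps=12,
        n_conditions=1,
        grid_extent=24.0,
        n_samples=85,
        word_onset=5,
        pattern_gain=2.5,
        noise_sd=1.0,
        active_region=region,
        relevant_region=region,
        behaviour_slope=3.0,
        seed=seed,
    )


def run_recovery_replicate(seed: int, n_perm: int = 60, n_subsets: int = 10) -> dict:
    """One seeded end-to-end neuro-behavioural recovery run on the small design.

    Simulates the cohort, decodes representational distances, fits the
    balanced logistic link, builds the permutation t-map null and returns the
    significant clusters together with the ground-truth relevant region.
    """
    cfg = recovery_config(seed)
    grid = synthgen.make_grid(cfg.grid_spacing, cfg.grid_extent)
    sls = features.build_searchlights(grid, radius=8.5)
    adjacency = stats.grid_adjacency(grid)
    ss = np.random.SeedSequence(seed)
    rngs = [np.random.default_rng(c) for c in ss.spawn(3)]

    dists, accs = [], []
    for _ in range(cfg.n_participants):
        trials = synthgen.generate_trials(
            cfg, grid, seed=int(rngs[0].integers(2**31))
        )
        d_true = synthgen.ground_truth_distance(cfg, grid, trials)
        behaviour = synthgen.generate_behaviour(
            cfg, trials, d_true, seed=int(rngs[1].integers(2**31))
        )
        trials = features.zscore_trials(trials)
        ft = features.extract_word_window(trials, sls)
        res = decode.decode_full(ft, trials.words, trials.candidates)
        dists.append(res.distances.d)
        accs.append(behaviour["accuracy"].to_numpy())

    _, t_obs, t_perms = neurobehav.neurobehavioural_t_maps(
        dists, accs, n_perm=n_perm, n_subsets=n_subsets, rng=rngs[2]
    )
    flt = stats.critical_t(cfg.n_participants)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # coarse permutation count
        clusters = stats.cluster_perm_t(
            t_obs, t_perms, adjacency, first_level_t=flt, min_size=10
        )
    relevant = set(int(i) for i in cfg.relevant_region)
    return {
        "clusters": clusters,
        "relevant": relevant,
        "t_obs": t_obs,
        "significant": [
            c for c in clusters if c.p < 0.05 and relevant & set(c.members.tolist())
        ],
    }
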