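"""Shared simulated cohort for the numbered analysis scripts.

One deterministic cohort (seed 2026) at a desk scale that keeps every script
in the low minutes: 8 participants, the full 18-word / 2-category / 10-rep
design in 2 conditions on a 5x5x5 source lattice (6 mm spacing).  Word
patterns live in a 19-point ball around (-6, 0, 0) mm; the 7-point core of
that ball drives single-trial comprehension through the logistic link.

Scripts regenerate the cohort from the config instead of reading stored
arrays, so `results/` holds only small text tables.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from megword import decode, features, synthgen

SEED = 2026
RADIUS_MM = 12.0
N_PERM_CLASS = 120
RESULTS = Path(__file__).resolve().parent.parent / "results"


def build_config() -> tuple[synthgen.GeneratorConfig, synthgen.SourceGrid]:
    grid = synthgen.make_grid(6.0, 24.0)
    centre = np.array([-6.0, 0.0, 0.0])
    dist = np.linalg.norm(grid.positions - centre, axis=1)
    active = np.flatnonzero(dist <= 9.0)
    relevant = np.flatnonzero(dist <= 6.0 + 1e-9)
    cfg = synthgen.GeneratorConfig(
        n_participants=12,
        n_words=18,
        n_categories=2,
        n_reps=10,
        n_conditions=2,
        grid_extent=24.0,
        n_samples=90,
        word_onset=7,
        pattern_gain=1.5,
        noise_sd=1.0,
        active_region=active,
        relevant_region=relevant,
        behaviour_intercept=synthgen.calibrated_intercept(3.0, 0.7),
        behaviour_slope=3.0,
        seed=SEED,
    )
    return cfg, grid


def simulate_cohort():
    """Per participant: z-scored trials, behaviour table, binned features."""
    cfg, grid = build_config()
    sls = features.build_searchlights(grid, RADIUS_MM)
    rngs = [np.random.default_rng(c) for c in np.random.SeedSequence(SEED).spawn(2)]
    cohort = []
    for _ in range(cfg.n_participants):
        trials = synthgen.generate_trials(cfg, grid, seed=int(rngs[0].integers(2**31)))
        d_true = synthgen.ground_truth_distance(cfg, grid, trials)
        behaviour = synthgen.generate_behaviour(
            cfg, trials, d_true, seed=int(rngs[1].integers(2**31))
        )
        trials = features.zscore_trials(trials)
        feats = features.extract_word_window(trials, sls)
        cohort.append((trials, behaviour, feats))
    return cfg, grid, sls, cohort


def condition_features(trials, feats, condition):
    mask = trials.conditions == condition
    sub = features.FeatureTensor(
        binned=feats.binned[mask],
        searchlights=feats.searchlights,
        bin_ms=feats.bin_ms,
        window_ms=feats.window_ms,
    )
    return sub, mask


def decode_condition(trials, feats, condition, permutations=None):
    sub, mask = condition_features(trials, feats, condition)
    return (
        decode.decode_full(
            sub,
            trials.words[mask],
            trials.candidates[mask],
            trials.categories[mask],
            permutations=permutations,
        ),
        mask,
    )
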