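"""Synthetic source-space MEG data with known ground truth.

The generator emulates a word-comprehension experiment: on every trial one of
18 target words (9 "numbers", 9 "adjectives") is presented and the participant
picks it from four same-category alternatives.  Word identity is embedded in
source-space activity as a word-specific spatio-temporal template added to a
designated set of grid points ("active region") inside a 500 ms window, on top
of i.i.d. Gaussian noise.  Single-trial comprehension is generated from a
logistic link on the representational fidelity of the stimulus in a designated
"behaviour-relevant" region, so that the downstream neuro-behavioural analysis
has a recoverable ground truth.

All randomness flows through a single integer seed; runs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

__all__ = [
    "SourceGrid",
    "GeneratorConfig",
    "TrialTensor",
    "WordInventory",
    "make_grid",
    "generate_trials",
    "ground_truth_distance",
    "generate_behaviour",
    "calibrated_intercept",
    "generate_word_features",
    "generate_feature_driven_behaviour",
]

#: phoneme token alphabet used for synthetic phonological word forms (ARPAbet)
PHONEME_ALPHABET = (
    "AA AE AH AO AW AY B CH D DH EH ER EY F G HH IH IY JH K L M N NG "
    "OW OY P R S SH T TH UH UW V W Y Z ZH"
).split()


@dataclass(frozen=True)
class SourceGrid:
    """Regular cubic lattice of source grid points.

    Attributes
    ----------
    positions : (n_points, 3) float array, mm
    spacing : lattice spacing in mm
    """

    positions: np.ndarray
    spacing: float

    @property
    def n_points(self) -> int:
        return self.positions.shape[0]

    @property
    def hemisphere(self) -> np.ndarray:
        """Per-point hemisphere label by the sign of x: 'L', 'R' or 'M' (midline)."""
        x = self.positions[:, 0]
        return np.where(x < 0, "L", np.where(x > 0, "R", "M"))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": np.arange(self.n_points),
                "x": self.positions[:, 0],
                "y": self.positions[:, 1],
                "z": self.positions[:, 2],
                "hemisphere": self.hemisphere,
            }
        )


def make_grid(spacing: float, extent: float) -> SourceGrid:
    """Build the smallest regular cubic lattice covering ``[-extent/2, extent/2]^3``.

    Parameters
    ----------
    spacing : lattice spacing in mm (default design: 6 mm).
    extent : side length in mm of the cube to cover; ``0`` yields a single
        point at the origin.
    """
    if spacing <= 0:
        raise ValueError(f"grid spacing must be positive, got {spacing}")
    if extent < 0:
        raise ValueError(f"grid extent must be non-negative, got {extent}")
    m = int(np.ceil(extent / (2.0 * spacing)))
    axis = spacing * np.arange(-m, m + 1, dtype=float)
    xx, yy, zz = np.meshgrid(axis, axis, axis, indexing="ij")
    positions = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    return SourceGrid(positions=positions, spacing=float(spacing))


@dataclass
class GeneratorConfig:
    """Design constants of the simulated experiment.

    Defaults mirror the study design: 18 target words in two categories, each
    repeated 10 times per condition, 6 mm source grid, activity sampled at
    150 Hz, word window of 500 ms, and mean comprehension accuracy near 70 %.

    ``behaviour_intercept``/``behaviour_slope`` (b0, b1) are generator-only
    ground-truth parameters of the logistic link from representational
    distance to single-trial accuracy.
    """

    n_participants: int = 12
    n_words: int = 18
    n_categories: int = 2
    n_reps: int = 10
    n_conditions: int = 2
    grid_spacing: float = 6.0
    grid_extent: float = 60.0
    n_samples: int = 90
    sampling_rate: float = 150.0
    window_ms: float = 500.0
    word_onset: int = 7
    pattern_gain: float = 1.0
    noise_sd: float = 1.0
    active_region: np.ndarray | None = None
    relevant_region: np.ndarray | None = None
    behaviour_intercept: float = field(default_factory=lambda: float(logit(0.7)))
    behaviour_slope: float = 1.5
    shared_patterns_across_conditions: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_categories < 1 or self.n_words % self.n_categories:
            raise ValueError(
                f"n_words ({self.n_words}) must be divisible by n_categories "
                f"({self.n_categories})"
            )
        if self.n_words // self.n_categories < 4:
            raise ValueError("need at least 4 words per category for 4-AFC candidate sets")
        if self.n_reps < 2:
            raise ValueError(f"n_reps must be >= 2, got {self.n_reps}")
        if self.noise_sd <= 0:
            raise ValueError(f"noise_sd must be positive, got {self.noise_sd}")
        if self.n_conditions < 1:
            raise ValueError("need at least one condition")

    @property
    def window_samples(self) -> int:
        n = self.window_ms * self.sampling_rate / 1000.0
        if abs(n - round(n)) > 1e-9:
            raise ValueError("window_ms must span an integer number of samples")
        return int(round(n))

    def validate_regions(self, grid: SourceGrid) -> tuple[np.ndarray, np.ndarray]:
        """Resolve active/relevant regions against ``grid`` (None -> whole grid)."""
        active = (
            np.arange(grid.n_points)
            if self.active_region is None
            else np.asarray(self.active_region, dtype=int)
        )
        relevant = active if self.relevant_region is None else np.asarray(
            self.relevant_region, dtype=int
        )
        for name, region in (("active_region", active), ("relevant_region", relevant)):
            if region.size == 0:
                raise ValueError(f"{name} is empty")
            if region.min() < 0 or region.max() >= grid.n_points:
                raise ValueError(f"{name} contains indices outside the grid")
        return active, relevant


@dataclass
class TrialTensor:
    """Per-participant source-space activity with trial annotations.

    ``activity`` is (n_trials, n_grid_points, n_samples).  ``table`` holds one
    row per trial (word, category, condition, onset).  ``candidates`` holds
    the four response alternatives of each trial (always including the true
    word, all within the trial's category).  The generator ground truth
    (word templates and the active region) rides along so that downstream
    parameter-recovery analyses are well posed.
    """

    activity: np.ndarray
    table: pd.DataFrame
    candidates: np.ndarray
    sampling_rate: float
    # --- generator ground truth ---
    templates: np.ndarray | None = None  # (n_template_sets, n_words, n_active, n_win)
    active_region: np.ndarray | None = None
    window_samples: int | None = None

    @property
    def n_trials(self) -> int:
        return self.activity.shape[0]

    @property
    def n_points(self) -> int:
        return self.activity.shape[1]

    @property
    def words(self) -> np.ndarray:
        return self.table["word"].to_numpy()

    @property
    def categories(self) -> np.ndarray:
        return self.table["category"].to_numpy()

    @property
    def conditions(self) -> np.ndarray:
        return self.table["condition"].to_numpy()

    @property
    def onsets(self) -> np.ndarray:
        return self.table["onset"].to_numpy()

    def validate(self) -> None:
        words = self.words
        if self.candidates.shape != (self.n_trials, 4):
            raise ValueError("each trial must carry exactly 4 candidate words")
        if not np.all(np.any(self.candidates == words[:, None], axis=1)):
            raise ValueError("candidate sets must contain the trial's word")

    def subset(self, mask: np.ndarray) -> "TrialTensor":
        """Trial subset (e.g. one condition); ground truth is carried over."""
        idx = np.flatnonzero(mask) if mask.dtype == bool else np.asarray(mask)
        return TrialTensor(
            activity=self.activity[idx],
            table=self.table.iloc[idx].reset_index(drop=True),
            candidates=self.candidates[idx],
            sampling_rate=self.sampling_rate,
            templates=self.templates,
            active_region=self.active_region,
            window_samples=self.window_samples,
        )


def generate_trials(
    config: GeneratorConfig, grid: SourceGrid, seed: int | None = None
) -> TrialTensor:
    """Simulate one participant's trial tensor.

    Each word owns a fixed spatio-temporal template (i.i.d. standard normal
    over active grid points x window samples, drawn once per seed, scaled by
    ``pattern_gain``); both conditions share templates when
    ``shared_patterns_across_conditions`` is set, otherwise each condition
    draws its own.  I.i.d. Gaussian noise of SD ``noise_sd`` is added
    everywhere.  Candidate sets are the true word plus 3 foils drawn without
    replacement from the same category.
    """
    active, _ = config.validate_regions(grid)
    n_win = config.window_samples
    onset = int(config.word_onset)
    if onset < 0 or onset + n_win > config.n_samples:
        raise ValueError(
            f"word window [{onset}, {onset + n_win}) exceeds trial length "
            f"{config.n_samples}"
        )
    rng = np.random.default_rng(config.seed if seed is None else seed)

    words_per_cat = config.n_words // config.n_categories
    n_sets = 1 if config.shared_patterns_across_conditions else config.n_conditions
    templates = rng.standard_normal((n_sets, config.n_words, active.size, n_win))

    rows = []
    for cond in range(config.n_conditions):
        order = rng.permutation(np.repeat(np.arange(config.n_words), config.n_reps))
        for w in order:
            rows.append((int(w), int(w) // words_per_cat, cond, onset))
    table = pd.DataFrame(rows, columns=["word", "category", "condition", "onset"])
    table.insert(0, "trial", np.arange(len(table)))
    n_trials = len(table)

    candidates = np.empty((n_trials, 4), dtype=int)
    for t, (w, c) in enumerate(zip(table["word"], table["category"])):
        same_cat = np.arange(c * words_per_cat, (c + 1) * words_per_cat)
        foils = rng.choice(same_cat[same_cat != w], size=3, replace=False)
        candidates[t] = np.concatenate([[w], foils])

    activity = config.noise_sd * rng.standard_normal(
        (n_trials, grid.n_points, config.n_samples)
    )
    for t, (w, cond) in enumerate(zip(table["word"], table["condition"])):
        tmpl = templates[0 if n_sets == 1 else cond, w]
        activity[t, active[:, None], np.arange(onset, onset + n_win)[None, :]] += (
            config.pattern_gain * tmpl
        )

    trials = TrialTensor(
        activity=activity,
        table=table,
        candidates=candidates,
        sampling_rate=config.sampling_rate,
        templates=templates,
        active_region=active,
        window_samples=n_win,
    )
    trials.validate()
    return trials


def ground_truth_distance(
    config: GeneratorConfig, grid: SourceGrid, trials: TrialTensor
) -> np.ndarray:
    """Noise-free representational distance per trial in the relevant region.

    For each trial the noise-free pattern over ``relevant_region`` grid points
    is the word's template (zero at relevant points outside the active
    region).  The distance is the same statistic the decoder computes: the
    within-word correlation (exactly 1, all same-word trials being identical
    without noise) minus the mean template correlation with the trial's three
    foils.  The result is z-scored across trials so that the logistic
    intercept b0 sets mean accuracy directly.
    """
    active, relevant = config.validate_regions(grid)
    if trials.templates is None:
        raise ValueError("trials carry no generator templates")
    n_sets = trials.templates.shape[0]
    n_win = trials.templates.shape[3]

    # noise-free pattern per (template set, word) over the relevant region
    pos_in_active = {int(g): i for i, g in enumerate(active)}
    rows = [pos_in_active.get(int(g), -1) for g in relevant]
    vecs = np.zeros((n_sets, config.n_words, relevant.size, n_win))
    for j, r in enumerate(rows):
        if r >= 0:
            vecs[:, :, j, :] = trials.templates[:, :, r, :]
    flat = vecs.reshape(n_sets, config.n_words, -1)
    centred = flat - flat.mean(axis=2, keepdims=True)
    norms = np.linalg.norm(centred, axis=2)
    if np.any(norms == 0):
        raise ValueError(
            "relevant_region does not overlap the active region: "
            "noise-free patterns are constant"
        )
    unit = centred / norms[:, :, None]
    corr = np.einsum("swf,svf->swv", unit, unit)

    words = trials.words
    conds = trials.conditions
    d = np.empty(trials.n_trials)
    for t in range(trials.n_trials):
        s = 0 if n_sets == 1 else conds[t]
        foils = trials.candidates[t][trials.candidates[t] != words[t]]
        d[t] = 1.0 - corr[s, words[t], foils].mean()
    sd = d.std()
    if sd == 0:
        return np.zeros_like(d)
    return (d - d.mean()) / sd


def generate_behaviour(
    config: GeneratorConfig,
    trials: TrialTensor,
    distance_per_trial: np.ndarray,
    seed: int | None = None,
) -> pd.DataFrame:
    """Single-trial responses from a logistic link on representational distance.

    ``accuracy ~ Bernoulli(logistic(b0 + b1 * d))``; the response is the true
    word when accurate and a uniformly chosen foil otherwise.
    """
    d = np.asarray(distance_per_trial, dtype=float)
    if d.shape != (trials.n_trials,):
        raise ValueError("distance_per_trial must have one value per trial")
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    p = expit(config.behaviour_intercept + config.behaviour_slope * d)
    accuracy = (rng.random(trials.n_trials) < p).astype(int)
    words = trials.words
    response = words.copy()
    for t in np.flatnonzero(accuracy == 0):
        foils = trials.candidates[t][trials.candidates[t] != words[t]]
        response[t] = rng.choice(foils)
    return pd.DataFrame(
        {
            "trial": trials.table["trial"].to_numpy(),
            "response": response,
            "accuracy": accuracy,
        }
    )


def calibrated_intercept(
    slope: float, target_accuracy: float = 0.7, n_grid: int = 200_001
) -> float:
    """Logistic intercept b0 such that mean accuracy hits the target.

    With the standardised distance d ~ N(0, 1), solves
    ``E[logistic(b0 + slope * d)] = target_accuracy`` by bisection on a fixed
    Gauss-like grid; for slope 0 this reduces to ``logit(target)``.
    """
    if not 0 < target_accuracy < 1:
        raise ValueError("target accuracy must lie in (0, 1)")
    z = np.linspace(-8.0, 8.0, n_grid)
    w = np.exp(-0.5 * z * z)
    w /= w.sum()

    def mean_acc(b0: float) -> float:
        return float((expit(b0 + slope * z) * w).sum())

    lo, hi = -20.0, 20.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if mean_acc(mid) < target_accuracy:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@dataclass(frozen=True)
class WordInventory:
    """Phonological and semantic feature inventory for the word set."""

    phonemes: tuple[tuple[str, ...], ...]
    vectors: np.ndarray  # (n_words, n_dims), unit Euclidean norm

    @property
    def n_words(self) -> int:
        return len(self.phonemes)


def generate_word_features(
    config: GeneratorConfig, seed: int | None = None, n_dims: int = 300
) -> WordInventory:
    """Seeded phoneme strings (length 2-8) and unit-norm semantic vectors."""
    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)
    phonemes = []
    for _ in range(config.n_words):
        length = int(rng.integers(2, 9))
        phonemes.append(tuple(rng.choice(PHONEME_ALPHABET, size=length)))
    vectors = rng.standard_normal((config.n_words, n_dims))
    vectors /= np.linalg.norm(vectors, axis=1, keepdims=True)
    return WordInventory(phonemes=tuple(phonemes), vectors=vectors)


def generate_feature_driven_behaviour(
    trials: TrialTensor,
    inventory: WordInventory,
    p_correct: float = 0.7,
    feature: str = "phonological",
    temperature: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Behaviour whose confusions are biased by word-feature similarity.

    With probability ``p_correct`` the response is the target; otherwise a
    foil is drawn with probability proportional to ``exp(-distance/temperature)``
    under the chosen feature space.  Used to test that the RSA recovers the
    feature space that actually drove behaviour.
    """
    from . import rsa  # deferred: rsa does not depend on synthgen

    if feature == "phonological":
        rdm = rsa.phonological_rdm(inventory.phonemes)
    elif feature == "semantic":
        rdm = rsa.semantic_rdm(inventory.vectors)
    else:
        raise ValueError(f"unknown feature space {feature!r}")
    dist = rdm.values
    rng = np.random.default_rng(seed)
    words = trials.words
    response = words.copy()
    accuracy = np.ones(trials.n_trials, dtype=int)
    for t in range(trials.n_trials):
        if rng.random() < p_correct:
            continue
        foils = trials.candidates[t][trials.candidates[t] != words[t]]
        w = np.exp(-dist[words[t], foils] / temperature)
        response[t] = rng.choice(foils, p=w / w.sum())
        accuracy[t] = 0
    return pd.DataFrame(
        {
            "trial": trials.table["trial"].to_numpy(),
            "response": response,
            "accuracy": accuracy,
        }
    )
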