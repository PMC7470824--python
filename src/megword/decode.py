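"""Leave-one-trial-out correlation word decoding per searchlight.

The classifier is a candidate-set-restricted nearest-neighbour rule on
Pearson correlations: for a test trial, the spatio-temporal searchlight
pattern is correlated with every other trial of each of the trial's four
candidate words (same-word references exclude the test trial itself),
correlations are averaged raw within each candidate, and the trial is decoded
as the candidate with the largest mean correlation.  Chance is 25 %.

The representational distance ``d`` of a trial is the mean within-word
correlation minus the mean of the three per-foil mean correlations: the
single-trial classifier evidence that the neuro-behavioural analysis regresses
against comprehension.  Whenever a trial is decoded correctly, ``d > 0``
(its within-mean exceeds each foil mean, hence their average).

Cross-condition decoding applies the same rule with the reference set taken
from the other condition (no leave-one-out needed), probing whether two
conditions share an activity pattern, not merely a region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import FeatureTensor

__all__ = [
    "ClassificationMap",
    "DistanceTable",
    "DecodeResult",
    "classify_loo",
    "representational_distance",
    "decode_full",
    "cross_classify",
]

CHANCE_LEVEL = 0.25


@dataclass
class ClassificationMap:
    """Per-searchlight proportion correct plus per-trial decoded words."""

    performance: np.ndarray  # (n_searchlights,)
    decoded: np.ndarray  # (n_trials, n_searchlights)
    chance: float = CHANCE_LEVEL


@dataclass
class DistanceTable:
    """Per-trial, per-searchlight representational distance d in [-2, 2]."""

    d: np.ndarray  # (n_trials, n_searchlights)


@dataclass
class DecodeResult:
    classification: ClassificationMap
    distances: DistanceTable
    perm_performance: np.ndarray | None = None  # (n_perm, n_searchlights)


def _normalise_rows(x: np.ndarray, what: str) -> np.ndarray:
    centred = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centred, axis=1)
    bad = np.flatnonzero(norms == 0)
    if bad.size:
        raise ValueError(
            f"constant feature vector in {what} trial {bad[0]}: "
            "Pearson correlation undefined"
        )
    return centred / norms[:, None]


def _word_indicator(labels: np.ndarray, n_words: int) -> np.ndarray:
    m = np.zeros((labels.size, n_words))
    m[np.arange(labels.size), labels] = 1.0
    return m


def _decode_from_means(
    means: np.ndarray,
    counts_eff: np.ndarray,
    labels: np.ndarray,
    candidates: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Decoded word and distance d per trial from per-candidate mean correlations.

    Candidate columns are evaluated in ascending word order, so exact ties
    decode to the smallest word id (deterministic, seed-independent).
    """
    n = labels.size
    if candidates.ndim != 2 or candidates.shape[1] != 4:
        raise ValueError("each trial must carry exactly 4 candidate words")
    cand = np.sort(candidates, axis=1)
    rows = np.arange(n)[:, None]
    if np.any(counts_eff[rows, cand] < 1):
        t = int(np.argwhere(counts_eff[rows, cand] < 1)[0, 0])
        raise ValueError(
            f"candidate word with zero reference trials for trial {t}"
        )
    vals = means[rows, cand]
    decoded = cand[np.arange(n), np.argmax(vals, axis=1)]
    within = means[np.arange(n), labels]
    d = within - (vals.sum(axis=1) - within) / 3.0
    return decoded, d


def _performance(
    correct: np.ndarray, categories: np.ndarray | None
) -> float:
    """Proportion correct, computed per task category and then averaged."""
    if categories is None:
        return float(correct.mean())
    cats = np.unique(categories)
    return float(np.mean([correct[categories == c].mean() for c in cats]))


def decode_full(
    features: FeatureTensor,
    labels: np.ndarray,
    candidates: np.ndarray,
    categories: np.ndarray | None = None,
    permutations: np.ndarray | None = None,
) -> DecodeResult:
    """Run the leave-one-out classifier and distance in one pass.

    Parameters
    ----------
    labels, candidates, categories : per-trial word id, the four candidate
        word ids (containing the label), and the task category used for
        averaging performance.
    permutations : optional (n_perm, n_trials) trial-index shuffles.  For each
        shuffle the (label, candidate, category) annotations are permuted
        relative to the activity and the performance map is recomputed reusing
        the trial-by-trial correlation matrix — the within-participant
        permutation scheme of the group statistics.
    """
    labels = np.asarray(labels)
    candidates = np.asarray(candidates)
    n_trials = features.n_trials
    n_words = int(max(labels.max(), candidates.max())) + 1
    n_sl = features.n_searchlights

    label_sets = [(labels, candidates, categories)]
    if permutations is not None:
        for p in permutations:
            label_sets.append(
                (
                    labels[p],
                    candidates[p],
                    None if categories is None else categories[p],
                )
            )
    indicators = [
        (_word_indicator(lab, n_words), lab, cand, cat)
        for lab, cand, cat in label_sets
    ]

    performance = np.empty(n_sl)
    decoded = np.empty((n_trials, n_sl), dtype=int)
    dist = np.empty((n_trials, n_sl))
    perm_perf = (
        np.empty((len(label_sets) - 1, n_sl)) if permutations is not None else None
    )

    eye = np.arange(n_trials)
    for i in range(n_sl):
        xn = _normalise_rows(features.vectors(i), what=f"searchlight {i}")
        corr = xn @ xn.T
        diag = corr[eye, eye]
        for k, (m, lab, cand, cat) in enumerate(indicators):
            sums = corr @ m
            counts = m.sum(axis=0)
            # leave-one-out: remove each trial's self-correlation from its own word
            sums[eye, lab] -= diag
            counts_eff = counts[None, :] - m
            with np.errstate(invalid="ignore", divide="ignore"):
                means = sums / counts_eff
            dec, d = _decode_from_means(means, counts_eff, lab, cand)
            if k == 0:
                decoded[:, i] = dec
                dist[:, i] = d
                performance[i] = _performance(dec == lab, cat)
            else:
                perm_perf[k - 1, i] = _performance(dec == lab, cat)

    return DecodeResult(
        classification=ClassificationMap(performance=performance, decoded=decoded),
        distances=DistanceTable(d=dist),
        perm_performance=perm_perf,
    )


def classify_loo(
    features: FeatureTensor,
    labels: np.ndarray,
    candidates: np.ndarray,
    categories: np.ndarray | None = None,
) -> ClassificationMap:
    """Leave-one-trial-out, candidate-set-restricted correlation classification."""
    return decode_full(features, labels, candidates, categories).classification


def representational_distance(
    features: FeatureTensor,
    labels: np.ndarray,
    candidates: np.ndarray,
) -> DistanceTable:
    """Single-trial classifier evidence d per searchlight."""
    return decode_full(features, labels, candidates).distances


def cross_classify(
    features_test: FeatureTensor,
    labels_test: np.ndarray,
    candidates_test: np.ndarray,
    features_ref: FeatureTensor,
    labels_ref: np.ndarray,
    categories_test: np.ndarray | None = None,
) -> ClassificationMap:
    """Decode test-condition trials against all reference-condition trials.

    References for every candidate (including the test trial's own word) come
    exclusively from the other condition, so no leave-one-out correction is
    applied.  Every candidate word must have at least one reference trial.
    """
    labels_test = np.asarray(labels_test)
    labels_ref = np.asarray(labels_ref)
    candidates_test = np.asarray(candidates_test)
    if features_test.n_searchlights != features_ref.n_searchlights:
        raise ValueError("test and reference features use different searchlights")
    n_words = int(max(labels_test.max(), candidates_test.max(), labels_ref.max())) + 1
    m = _word_indicator(labels_ref, n_words)
    counts = m.sum(axis=0)
    n_test = features_test.n_trials
    n_sl = features_test.n_searchlights
    counts_eff = np.broadcast_to(counts, (n_test, n_words))

    performance = np.empty(n_sl)
    decoded = np.empty((n_test, n_sl), dtype=int)
    for i in range(n_sl):
        xt = _normalise_rows(features_test.vectors(i), what=f"test searchlight {i}")
        xr = _normalise_rows(features_ref.vectors(i), what=f"reference searchlight {i}")
        with np.errstate(invalid="ignore", divide="ignore"):
            means = (xt @ xr.T) @ m / counts
        dec, _ = _decode_from_means(means, counts_eff, labels_test, candidates_test)
        decoded[:, i] = dec
        performance[i] = _performance(dec == labels_test, categories_test)
    return ClassificationMap(performance=performance, decoded=decoded)
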