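"""Representational similarity analysis over word dissimilarities.

Three word-by-word representational dissimilarity matrices (RDMs) per task
category: a phonological RDM from token-level edit distance between phoneme
strings, a semantic RDM from cosine distance between length-normalised word
vectors, and a behavioural RDM from the symmetrised, opportunity-normalised
confusion counts of the 4-alternative task.  RDMs are compared by Spearman
rank correlation over the lower triangle; correlations are Fisher z-scored
and averaged across categories.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import spearmanr, wilcoxon

__all__ = [
    "RDM",
    "phonological_rdm",
    "semantic_rdm",
    "behavioural_rdm",
    "compare_rdms",
    "compare_feature_models",
    "token_levenshtein",
]


@dataclass(frozen=True)
class RDM:
    """Symmetric, zero-diagonal, non-negative dissimilarity matrix.

    Off-diagonal NaN marks a missing entry (e.g. a word pair that never
    co-occurred as target and candidate); missing entries are excluded
    pairwise from comparisons.
    """

    values: np.ndarray
    labels: tuple

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("RDM must be square")
        if len(self.labels) != v.shape[0]:
            raise ValueError("labels must match matrix size")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("RDM diagonal must be zero")
        finite = np.isfinite(v)
        if not np.array_equal(finite, finite.T) or not np.allclose(
            v[finite & finite.T], v.T[finite & finite.T]
        ):
            raise ValueError("RDM must be symmetric")
        if np.any(v[finite] < 0):
            raise ValueError("RDM entries must be non-negative")

    def lower_triangle(self) -> np.ndarray:
        i, j = np.tril_indices(self.values.shape[0], k=-1)
        return self.values[i, j]


def token_levenshtein(
    a: Sequence[str],
    b: Sequence[str],
    substitution_costs: Mapping[tuple[str, str], float] | None = None,
) -> float:
    """Levenshtein distance over phoneme tokens (unit costs by default).

    ``substitution_costs`` optionally maps unordered token pairs to a
    substitution cost, restoring feature-weighted phonological distances;
    insertions and deletions always cost 1.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("phoneme sequences must be non-empty")

    def sub_cost(x: str, y: str) -> float:
        if x == y:
            return 0.0
        if substitution_costs is None:
            return 1.0
        return substitution_costs.get((x, y), substitution_costs.get((y, x), 1.0))

    prev = np.arange(len(b) + 1, dtype=float)
    for i, x in enumerate(a, start=1):
        cur = np.empty(len(b) + 1)
        cur[0] = i
        for j, y in enumerate(b, start=1):
            cur[j] = min(
                prev[j] + 1.0, cur[j - 1] + 1.0, prev[j - 1] + sub_cost(x, y)
            )
        prev = cur
    return float(prev[-1])


def phonological_rdm(
    phonemes: Sequence[Sequence[str]],
    labels: Sequence | None = None,
    substitution_costs: Mapping[tuple[str, str], float] | None = None,
) -> RDM:
    """Pairwise token-level edit distance between phoneme strings."""
    n = len(phonemes)
    v = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            v[i, j] = v[j, i] = token_levenshtein(
                phonemes[i], phonemes[j], substitution_costs
            )
    return RDM(values=v, labels=tuple(labels) if labels is not None else tuple(range(n)))


def semantic_rdm(vectors: np.ndarray, labels: Sequence | None = None) -> RDM:
    """1 - cosine similarity of length-normalised word vectors."""
    vectors = np.asarray(vectors, dtype=float)
    norms = np.linalg.norm(vectors, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero semantic vector")
    unit = vectors / norms[:, None]
    v = 1.0 - unit @ unit.T
    v = np.clip((v + v.T) / 2.0, 0.0, None)
    np.fill_diagonal(v, 0.0)
    n = vectors.shape[0]
    return RDM(values=v, labels=tuple(labels) if labels is not None else tuple(range(n)))


def behavioural_rdm(
    words: np.ndarray,
    responses: np.ndarray,
    candidates: np.ndarray,
    labels: Sequence,
) -> RDM:
    """Symmetrised, opportunity-normalised confusion dissimilarity.

    ``C(i, j)`` counts responses j when i was presented with j among the
    candidates; with ``O(i, j)`` the number of such opportunities,
    ``dissimilarity(i, j) = 1 - (C(i,j) + C(j,i)) / (O(i,j) + O(j,i))``.
    Pairs that never co-occur are flagged NaN.  The diagonal is 0 by
    construction.
    """
    labels = list(labels)
    index = {w: k for k, w in enumerate(labels)}
    n = len(labels)
    conf = np.zeros((n, n))
    opp = np.zeros((n, n))
    for w, r, cand in zip(words, responses, candidates):
        if w not in index:
            continue
        i = index[w]
        for c in cand:
            if c != w and c in index:
                opp[i, index[c]] += 1
        if r != w and r in index:
            conf[i, index[r]] += 1
    sym_opp = opp + opp.T
    with np.errstate(invalid="ignore", divide="ignore"):
        v = 1.0 - (conf + conf.T) / sym_opp
    v[sym_opp == 0] = np.nan
    np.fill_diagonal(v, 0.0)
    return RDM(values=v, labels=tuple(labels))


def compare_rdms(rdm_a: RDM, rdm_b: RDM) -> tuple[float, float]:
    """Spearman rank correlation of two RDMs' lower triangles, plus Fisher z.

    Missing entries are excluded pairwise; at least 3 complete pairs are
    required and a constant triangle is an error (ranks undefined).
    """
    if rdm_a.labels != rdm_b.labels:
        raise ValueError("RDMs must share their labels")
    a = rdm_a.lower_triangle()
    b = rdm_b.lower_triangle()
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if a.size < 3:
        raise ValueError("need at least 3 off-diagonal pairs to compare RDMs")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant RDM triangle: rank correlation undefined")
    rho = float(spearmanr(a, b).statistic)
    z = float(np.arctanh(np.clip(rho, -1 + 1e-15, 1 - 1e-15)))
    return rho, z


def compare_feature_models(z_a: np.ndarray, z_b: np.ndarray):
    """Paired Wilcoxon signed-rank test between two per-participant z series."""
    return wilcoxon(np.asarray(z_a) - np.asarray(z_b))
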