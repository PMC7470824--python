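"""Linking single-trial classifier evidence to comprehension.

Per participant and searchlight, a ridge-penalised logistic regression
predicts single-trial accuracy from the (standardised) representational
distance d.  To avoid the class imbalance of ~70 % correct behaviour, the
model is fitted on randomly drawn balanced subsets with equal numbers of
correct and wrong trials and the d-coefficient is averaged across subsets;
computation is per task category, then averaged.  Participants at ceiling
(accuracy strictly above the threshold, default 95 %) are excluded from this
analysis only.

Group level: per-searchlight one-sample t of the betas against zero, and a
within-participant robust (Huber) regression relating each participant's
stimulus-classification map to their behavioural-weight map.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit
from scipy.stats import ttest_1samp
import statsmodels.api as sm

from .stats import BayesResult, jzs_bf_ttest

__all__ = [
    "exclude_ceiling",
    "balanced_logistic",
    "group_t_map",
    "neurobehavioural_t_maps",
    "classification_vs_relevance",
    "RobustRelation",
]


def exclude_ceiling(
    accuracy_by_participant: Mapping[object, np.ndarray], threshold: float = 0.95
) -> tuple[list, list]:
    """Split participants into (retained, excluded) by mean accuracy > threshold.

    The inequality is strict: a participant at exactly the threshold is kept.
    """
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    kept, excluded = [], []
    for pid, acc in accuracy_by_participant.items():
        (excluded if np.mean(acc) > threshold else kept).append(pid)
    return kept, excluded


def _fit_ridge_logistic(
    x: np.ndarray, y: np.ndarray, lam: float, max_iter: int = 40, tol: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Newton fit of ``logit(p) = a + b x`` with penalty ``lam/2 * b**2``.

    ``x``: (m, ...) predictor, ``y``: broadcastable 0/1 outcome.  The intercept
    is unpenalised; the quadratic penalty keeps b finite even on separable
    subsets.  Vectorised over all trailing axes; runs in x's dtype, so large
    permutation stacks can be fitted in single precision.
    """
    shape = x.shape[1:]
    dtype = x.dtype if x.dtype in (np.float32, np.float64) else np.float64
    if tol is None:
        tol = 2e-5 if dtype == np.float32 else 1e-7
    x = np.asarray(x, dtype=dtype)
    y = np.asarray(y, dtype=dtype)
    lam = dtype.type(lam) if hasattr(dtype, "type") else lam
    a = np.zeros(shape, dtype=dtype)
    b = np.zeros(shape, dtype=dtype)
    for _ in range(max_iter):
        eta = a + b * x
        p = expit(eta)
        w = p * (1.0 - p) + 1e-12
        resid = y - p
        ga = resid.sum(axis=0)
        gb = (resid * x).sum(axis=0) - lam * b
        haa = w.sum(axis=0)
        hab = (w * x).sum(axis=0)
        hbb = (w * x * x).sum(axis=0) + lam
        det = haa * hbb - hab * hab
        da = (hbb * ga - hab * gb) / det
        db = (haa * gb - hab * ga) / det
        a += da
        b += db
        if max(np.abs(da).max(), np.abs(db).max()) < tol:
            break
    return a, b


def _standardise(d: np.ndarray) -> np.ndarray:
    sd = d.std(axis=0)
    if np.any(sd == 0):
        raise ValueError(
            f"zero-variance distance at searchlight {int(np.flatnonzero(sd == 0)[0])}"
        )
    return (d - d.mean(axis=0)) / sd


def balanced_logistic(
    d: np.ndarray,
    accuracy: np.ndarray,
    categories: np.ndarray | None = None,
    n_subsets: int = 50,
    lam: float = 1.0,
    rng: np.random.Generator | int | None = None,
    subset_size: int | None = None,
) -> np.ndarray:
    """Average d-coefficient over balanced subsets, per searchlight.

    Each of ``n_subsets`` seeded draws samples ``2 * min(n_correct, n_wrong)``
    trials with equal class counts (without replacement within class) and fits
    the penalised logistic regression; betas are averaged over subsets, then
    over task categories.  d is standardised per searchlight within category.

    ``subset_size`` caps the draw at a fixed total (half per class) for the
    alternative reading in which each subset holds a fixed number of trials
    rather than the maximal balanced count.
    """
    d = np.atleast_2d(np.asarray(d, dtype=float))
    if d.shape[0] != np.size(accuracy):
        d = d.T
    accuracy = np.asarray(accuracy)
    n_trials = accuracy.size
    rng = np.random.default_rng(rng)
    n_correct = int(accuracy.sum())
    n_wrong = n_trials - n_correct
    if n_correct < 5 or n_wrong < 5:
        raise ValueError(
            f"need at least 5 correct and 5 wrong trials (got {n_correct}/{n_wrong}); "
            "near-ceiling participants should be excluded (exclude_ceiling)"
        )
    cats = np.zeros(n_trials, dtype=int) if categories is None else np.asarray(categories)

    betas = []
    for c in np.unique(cats):
        idx = np.flatnonzero(cats == c)
        dz = _standardise(d[idx])
        acc_c = accuracy[idx]
        correct = np.flatnonzero(acc_c == 1)
        wrong = np.flatnonzero(acc_c == 0)
        if correct.size == 0 or wrong.size == 0:
            raise ValueError(f"category {c} has no trials in one accuracy class")
        m = min(correct.size, wrong.size)
        if subset_size is not None:
            m = min(m, max(1, subset_size // 2))
        draws = np.empty((2 * m, n_subsets), dtype=int)
        for k in range(n_subsets):
            draws[:m, k] = rng.choice(correct, size=m, replace=False)
            draws[m:, k] = rng.choice(wrong, size=m, replace=False)
        x = dz[draws]  # (2m, n_subsets, n_searchlights)
        y = acc_c[draws][:, :, None].astype(float)
        _, b = _fit_ridge_logistic(x, y, lam=lam)
        betas.append(b.mean(axis=0))
    return np.mean(betas, axis=0)


def group_t_map(betas: np.ndarray) -> np.ndarray:
    """One-sample t of per-participant betas against zero, per searchlight."""
    betas = np.asarray(betas, dtype=float)
    n = betas.shape[0]
    if n < 2:
        raise ValueError("group t-map needs at least 2 participants")
    sd = betas.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError(
            "zero across-participant variance at searchlight "
            f"{int(np.flatnonzero(sd == 0)[0])}"
        )
    return betas.mean(axis=0) / (sd / np.sqrt(n))


def _betas_with_perms(
    d: np.ndarray,
    accuracy: np.ndarray,
    categories: np.ndarray | None,
    n_perm: int,
    n_subsets: int,
    lam: float,
    rng: np.random.Generator,
    chunk: int = 24,
) -> np.ndarray:
    """Observed plus label-shuffled balanced-logistic betas for one participant.

    Returns (n_perm + 1, S) with row 0 the observed betas.  Accuracy labels
    are shuffled within task category so balanced-subset sizes stay constant,
    which lets every permutation and subset be fitted in one vectorised
    Newton solve.
    """
    d = np.atleast_2d(np.asarray(d, dtype=float))
    if d.shape[0] != np.size(accuracy):
        d = d.T
    accuracy = np.asarray(accuracy)
    n_correct = int(accuracy.sum())
    n_wrong = accuracy.size - n_correct
    if n_correct < 5 or n_wrong < 5:
        raise ValueError(
            f"need at least 5 correct and 5 wrong trials (got {n_correct}/{n_wrong}); "
            "near-ceiling participants should be excluded (exclude_ceiling)"
        )
    cats = (
        np.zeros(accuracy.size, dtype=int) if categories is None else np.asarray(categories)
    )
    n_rows = n_perm + 1
    out = np.zeros((n_rows, d.shape[1]))
    uniq = np.unique(cats)
    for c in uniq:
        idx = np.flatnonzero(cats == c)
        # single precision: the fits are memory-bound and betas feed a t-test
        dz = _standardise(d[idx]).astype(np.float32)
        acc_c = accuracy[idx]
        correct = np.flatnonzero(acc_c == 1)
        wrong = np.flatnonzero(acc_c == 0)
        if correct.size == 0 or wrong.size == 0:
            raise ValueError(f"category {c} has no trials in one accuracy class")
        m = min(correct.size, wrong.size)
        # row 0: identity relabelling (the observed data)
        relabel = np.empty((n_rows, idx.size), dtype=int)
        relabel[0] = np.arange(idx.size)
        for p in range(1, n_rows):
            relabel[p] = rng.permutation(idx.size)
        # balanced subsets drawn in the label frame, mapped through relabel
        k = n_rows * n_subsets
        pick_c = np.argsort(rng.random((k, correct.size)), axis=1)[:, :m]
        pick_w = np.argsort(rng.random((k, wrong.size)), axis=1)[:, :m]
        base = np.concatenate(
            [correct[pick_c], wrong[pick_w]], axis=1
        ).reshape(n_rows, n_subsets, 2 * m)
        y = np.repeat([1.0, 0.0], m).astype(np.float32)[:, None, None, None]
        for lo in range(0, n_rows, chunk):
            hi = min(lo + chunk, n_rows)
            trial_idx = relabel[lo:hi, None, :].repeat(n_subsets, axis=1)
            trial_idx = np.take_along_axis(trial_idx, base[lo:hi], axis=2)
            x = np.moveaxis(dz[trial_idx], 2, 0)  # (2m, rows, n_subsets, S)
            _, b = _fit_ridge_logistic(x, y, lam=lam)
            out[lo:hi] += b.mean(axis=1)
    return out / uniq.size


def neurobehavioural_t_maps(
    distances: Sequence[np.ndarray],
    accuracies: Sequence[np.ndarray],
    categories: Sequence[np.ndarray] | None = None,
    n_perm: int = 0,
    n_subsets: int = 50,
    lam: float = 1.0,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Group t-map of neuro-behavioural betas plus a permutation surrogate.

    Permutations shuffle each participant's accuracy labels over trials
    (within task category, keeping balanced-subset sizes intact) and refit the
    balanced logistic — the within-subject trial-label shuffle of the group
    statistics.

    Returns ``(betas (n_part, S), t_obs (S,), t_perms (n_perm, S))``.
    """
    rng = np.random.default_rng(rng)
    cats = [None] * len(distances) if categories is None else categories
    all_betas = np.stack(
        [
            _betas_with_perms(d, a, c, n_perm, n_subsets, lam, rng)
            for d, a, c in zip(distances, accuracies, cats)
        ]
    )  # (n_part, n_perm + 1, S)
    t_all = np.stack([group_t_map(all_betas[:, k]) for k in range(n_perm + 1)])
    return all_betas[:, 0], t_all[0], t_all[1:]


@dataclass
class RobustRelation:
    """Per-participant robust slopes of beta on performance, plus the group test."""

    slopes: np.ndarray
    t: float
    p: float
    bf: BayesResult


def classification_vs_relevance(
    performance: np.ndarray,
    betas: np.ndarray,
    bf_scale: float = 0.707,
) -> RobustRelation:
    """Within-participant Huber regression of behavioural weight on classification.

    For each participant, an IRLS robust linear regression (Huber psi, tuning
    constant 1.345) of the beta map on the classification-performance map
    across grid points; the slopes are tested against zero with a two-sided
    one-sample t, complemented by its JZS Bayes factor.
    """
    performance = np.asarray(performance, dtype=float)
    betas = np.asarray(betas, dtype=float)
    if performance.shape != betas.shape:
        raise ValueError("performance and beta maps must share their shape")
    slopes = np.empty(performance.shape[0])
    for i, (perf, beta) in enumerate(zip(performance, betas)):
        if perf.std() == 0:
            raise ValueError(f"zero-variance predictor map for participant {i}")
        model = sm.RLM(beta, sm.add_constant(perf), M=sm.robust.norms.HuberT(t=1.345))
        slopes[i] = model.fit().params[1]
    res = ttest_1samp(slopes, 0.0)
    bf = jzs_bf_ttest(float(res.statistic), slopes.size, scale=bf_scale)
    return RobustRelation(
        slopes=slopes, t=float(res.statistic), p=float(res.pvalue), bf=bf
    )
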