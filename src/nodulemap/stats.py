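"""Statistical evaluation: ROC/AUC, DeLong's paired test, subset splits,
repetition averaging, paired t-tests across subsets, and Dice overlap."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve

__all__ = [
    "RocResult",
    "DeLongResult",
    "ComparisonMatrix",
    "SubsetSplit",
    "roc_auc",
    "delong_test",
    "pvalue_matrix",
    "partition_dataset",
    "repetition_average",
    "paired_ttest_regions",
    "dice",
]

DISPLAY_FLOOR = 1e-14


class UndefinedAUCError(ValueError):
    pass


@dataclass
class RocResult:
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    labels: np.ndarray  # retained for paired testing
    scores: np.ndarray


@dataclass
class DeLongResult:
    p_value: float
    z: float
    auc_a: float
    auc_b: float
    variance: float
    degenerate: bool = False


@dataclass
class ComparisonMatrix:
    p_values: np.ndarray  # raw values, symmetric, diagonal 1
    display_floor: float = DISPLAY_FLOOR

    @property
    def display(self) -> np.ndarray:
        return np.maximum(self.p_values, self.display_floor)


@dataclass
class SubsetSplit:
    assignments: np.ndarray  # item -> subset index in [0, k)
    sizes: np.ndarray

    @property
    def k(self) -> int:
        return len(self.sizes)

    def indices(self, subset: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == subset)


def roc_auc(labels, scores) -> RocResult:
    """ROC curve and trapezoidal AUC (equals Mann-Whitney concordance,
    ties counted half)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have the same length")
    if np.unique(labels).size < 2:
        raise UndefinedAUCError("AUC undefined with a single class")
    fpr, tpr, _ = roc_curve(labels, scores)
    return RocResult(
        auc=float(_trapezoid_auc(fpr, tpr)),
        fpr=fpr,
        tpr=tpr,
        labels=labels.copy(),
        scores=scores.copy(),
    )


# ------------------------------------------------------------------ #
# DeLong's test for two correlated AUCs (structural components)


def _midrank(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x, kind="stable")
    xs = x[order]
    n = len(x)
    mid = np.empty(n, dtype=float)
    i = 0
    while i < n:
        j = i
        while j < n and xs[j] == xs[i]:
            j += 1
        mid[i:j] = 0.5 * (i + j - 1) + 1  # 1-based midrank
        i = j
    out = np.empty(n, dtype=float)
    out[order] = mid
    return out


def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC plus per-positive and per-negative placement values."""
    m, n = len(pos), len(neg)
    tz = _midrank(np.concatenate([pos, neg]))
    tx = _midrank(pos)
    ty = _midrank(neg)
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    auc_val = (tz[:m].sum() / m - (m + 1) / 2.0) / n
    return float(auc_val), v10, v01


def delong_test(roc_a: RocResult, roc_b: RocResult) -> DeLongResult:
    """Two-sided DeLong test for a paired AUC difference.

    Both ROCs must be computed on the same cases (identical label vectors).
    A zero-variance difference (e.g. identical score vectors) yields p = 1
    with the degeneracy flag set rather than an error.
    """
    if not np.array_equal(roc_a.labels, roc_b.labels):
        raise ValueError("paired design requires identical labels")
    pos_mask = np.asarray(roc_a.labels) == np.max(roc_a.labels)
    aucs, v10s, v01s = [], [], []
    for roc in (roc_a, roc_b):
        a, v10, v01 = _placements(roc.scores[pos_mask], roc.scores[~pos_mask])
        aucs.append(a)
        v10s.append(v10)
        v01s.append(v01)
    m, n = int(pos_mask.sum()), int((~pos_mask).sum())
    diff = aucs[0] - aucs[1]
    if m < 2 or n < 2:
        # covariance of the placement values is undefined
        return DeLongResult(
            p_value=1.0, z=0.0, auc_a=aucs[0], auc_b=aucs[1],
            variance=0.0, degenerate=True,
        )
    v10s = np.asarray(v10s)
    v01s = np.asarray(v01s)
    s10 = np.cov(v10s, ddof=1)
    s01 = np.cov(v01s, ddof=1)
    s = s10 / m + s01 / n
    var = float(s[0, 0] + s[1, 1] - 2.0 * s[0, 1])
    if not np.isfinite(var) or var <= 0 or (var < 1e-300 and diff == 0):
        return DeLongResult(
            p_value=1.0, z=0.0, auc_a=aucs[0], auc_b=aucs[1],
            variance=max(var, 0.0), degenerate=True,
        )
    z = diff / np.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return DeLongResult(
        p_value=float(p), z=float(z), auc_a=aucs[0], auc_b=aucs[1], variance=var
    )


def pvalue_matrix(rocs: list[RocResult]) -> ComparisonMatrix:
    """All pairwise DeLong p-values; diagonal fixed at 1.

    Raw values are stored; sub-floor values are clamped only in ``display``.
    """
    if len(rocs) < 2:
        raise ValueError("need at least two ROC results")
    k = len(rocs)
    p = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            pij = delong_test(rocs[i], rocs[j]).p_value
            p[i, j] = p[j, i] = pij
    return ComparisonMatrix(p_values=p)


# ------------------------------------------------------------------ #


def partition_dataset(n_items, k: int = 5, seed: int = 0) -> SubsetSplit:
    """Random split into k subsets of floor(n/k) with the remainder appended
    to the final subset (e.g. 2602 -> 520, 520, 520, 520, 522)."""
    if hasattr(n_items, "__len__"):
        n = len(n_items)
    else:
        n = int(n_items)
    if n < k:
        raise ValueError(f"cannot split {n} items into {k} subsets")
    base = n // k
    sizes = np.full(k, base, dtype=np.intp)
    sizes[-1] += n - base * k
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    assignments = np.empty(n, dtype=np.intp)
    start = 0
    for subset, size in enumerate(sizes):
        assignments[perm[start : start + size]] = subset
        start += size
    return SubsetSplit(assignments=assignments, sizes=sizes)


def repetition_average(prob_table) -> np.ndarray:
    """Per-nodule mean malignancy probability over noise-position repetitions."""
    table = np.asarray(prob_table, dtype=float)
    if table.ndim != 2 or table.shape[1] < 1:
        raise ValueError("expected a (nodules x repetitions) table")
    if np.isnan(table).any():
        raise ValueError("missing repetitions in probability table")
    return table.mean(axis=1)


def paired_ttest_regions(auc_table) -> dict:
    """Paired t-tests between region columns of a (subset x region) AUC table.

    Returns means/SDs per region plus a symmetric p-value matrix (diagonal 1;
    all-zero paired differences give p = 1 with a degeneracy flag).
    """
    table = np.asarray(auc_table, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2:
        raise ValueError("need at least 2 subsets (rows)")
    n_regions = table.shape[1]
    p = np.ones((n_regions, n_regions))
    degenerate = np.zeros((n_regions, n_regions), dtype=bool)
    for i in range(n_regions):
        for j in range(i + 1, n_regions):
            diff = table[:, i] - table[:, j]
            if np.allclose(diff, diff[0]) and np.isclose(diff[0], 0.0):
                pij, degen = 1.0, True
            else:
                res = sps.ttest_rel(table[:, i], table[:, j])
                pij = float(res.pvalue)
                degen = not np.isfinite(pij)
                if degen:
                    pij = 1.0
            p[i, j] = p[j, i] = pij
            degenerate[i, j] = degenerate[j, i] = degen
    return {
        "mean": table.mean(axis=0),
        "sd": table.std(axis=0, ddof=1),
        "p_values": p,
        "degenerate": degenerate,
    }


def dice(mask_a, mask_b) -> float:
    """Dice overlap 2|A&B| / (|A|+|B|); two empty masks count as 1."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom
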