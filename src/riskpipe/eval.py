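"""Evaluation: per-user five-fold CV, ROC-AUC, table arithmetic, rank tests.

Cross-validation is per user and chronological: the normal-condition windows
are cut into five contiguous blocks; four train the one-class model and the
held-out block — joined with the user's full anomaly-condition set — tests
it.  Performance is the area under the ROC curve with *anomaly* as the
positive class.

The Wilcoxon signed-rank comparison of two classifiers over per-user AUCs is
computed with an exact two-sided p-value for up to 25 non-zero differences
(dynamic programming over the signed-rank distribution, average ranks for
ties) and a tie-corrected normal approximation beyond.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

DATASET_IDS = ("DS-1", "DS-2", "DS-3", "DS-4")


# ---------------------------------------------------------------------------
# folds


@dataclass
class FoldPlan:
    """Contiguous chronological fold boundaries over one user's normal rows."""

    n_rows: int
    k: int
    bounds: list[tuple[int, int]]  # half-open [start, stop) row ranges

    def fold_indices(self, f: int) -> np.ndarray:
        start, stop = self.bounds[f]
        return np.arange(start, stop)

    def train_indices(self, f: int) -> np.ndarray:
        start, stop = self.bounds[f]
        return np.concatenate([np.arange(0, start), np.arange(stop, self.n_rows)])


def make_folds(n_rows: int, k: int = 5) -> FoldPlan:
    """Split ``n_rows`` into ``k`` contiguous blocks, remainder to the earliest."""
    if n_rows < k:
        raise ValueError(f"cannot split {n_rows} rows into {k} folds")
    base, rem = divmod(n_rows, k)
    sizes = [base + (1 if f < rem else 0) for f in range(k)]
    bounds = []
    start = 0
    for s in sizes:
        bounds.append((start, start + s))
        start += s
    return FoldPlan(n_rows=n_rows, k=k, bounds=bounds)


def assemble_cv(ncds_matrix, acds_matrix, plan: FoldPlan):
    """Yield the five (train, test, test_labels) rotations for one user.

    ``train`` holds four normal folds; ``test`` is the held-out normal fold
    (label 0) followed by the full anomaly set (label 1).
    """
    if len(acds_matrix) == 0:
        raise ValueError("anomaly set is empty; the test folds need both classes")
    if plan.n_rows != len(ncds_matrix):
        raise ValueError("fold plan does not match the normal matrix")
    for f in range(plan.k):
        train = ncds_matrix.rows(plan.train_indices(f))
        held = ncds_matrix.rows(plan.fold_indices(f))
        test_X = np.vstack([held.X, acds_matrix.X])
        labels = np.concatenate([np.zeros(len(held), dtype=int), np.ones(len(acds_matrix), dtype=int)])
        yield train, test_X, labels


# ---------------------------------------------------------------------------
# metrics


def roc_auc(scores, labels) -> float:
    """Trapezoidal ROC-AUC, anomaly (label 1) as the positive class."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present to compute an AUC")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def summarize(per_fold: pd.DataFrame) -> pd.DataFrame:
    """AUC table from per-fold records.

    ``per_fold`` needs columns ``user_id, classifier, dataset, fold, auc``
    (AUC on the 0-1 scale).  Cells are the per-user fold means x 100 rounded
    to one decimal; an ``Average`` row holds the column means rounded to two
    decimals, mirroring how benchmark AUC tables are printed.
    """
    required = {"user_id", "classifier", "dataset", "fold", "auc"}
    if missing := required - set(per_fold.columns):
        raise ValueError(f"missing columns: {sorted(missing)}")
    if per_fold["auc"].isna().any():
        raise ValueError("missing AUC cells")
    cells = (
        per_fold.groupby(["user_id", "classifier", "dataset"])["auc"].mean().mul(100.0).round(1).unstack(["classifier", "dataset"])
    )
    cells = cells.sort_index(axis=1)
    avg = cells.mean(axis=0).round(2)
    cells.loc["Average"] = avg
    return cells


def column_averages(table: pd.DataFrame) -> pd.Series:
    """Arithmetic mean of each (classifier, dataset) column of printed cells."""
    body = table.drop(index="Average", errors="ignore")
    return body.mean(axis=0)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank


@dataclass
class WilcoxonResult:
    r_plus: float
    r_minus: float
    n_effective: int
    p_value: float
    method: str  # "exact" | "normal" | "degenerate"
    alpha: float = 0.05

    @property
    def reject(self) -> bool:
        return self.p_value < self.alpha


def _exact_signed_rank_p(ranks: np.ndarray, r_plus: float) -> float:
    """Exact two-sided p over all sign patterns of the given (tied) ranks.

    Ranks are doubled to integers so average ranks stay exact; the null
    distribution of the doubled positive-rank sum is built by dynamic
    programming (equivalent to enumerating all 2^n sign assignments).
    """
    w = np.rint(2.0 * ranks).astype(np.int64)
    total = int(w.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for wi in w:
        counts[wi:] += counts[:-wi].copy()
    t = int(np.rint(2.0 * r_plus))
    lo = min(t, total - t)
    hi = total - lo
    p = counts[: lo + 1].sum() + counts[hi:].sum()
    if lo == hi:
        p -= counts[lo]
    return min(p / 2.0 ** len(w), 1.0)


def wilcoxon_signed_rank(a, b, alpha: float = 0.05, exact_max_n: int = 25) -> WilcoxonResult:
    """Paired signed-rank test of ``a`` vs ``b`` (R+ sums ranks where a > b).

    Zero differences are dropped; tied absolute differences get average
    ranks.  The two-sided p-value is exact for up to ``exact_max_n``
    non-zero pairs and a continuity-corrected normal approximation beyond.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be one-dimensional and equally long")
    if len(a) < 5:
        raise ValueError("need at least five pairs")
    d = a - b
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return WilcoxonResult(0.0, 0.0, 0, 1.0, "degenerate", alpha)
    ranks = stats.rankdata(np.abs(d))
    r_plus = float(ranks[d > 0].sum())
    r_minus = float(ranks[d < 0].sum())
    if n <= exact_max_n:
        p = _exact_signed_rank_p(ranks, r_plus)
        method = "exact"
    else:
        mu = n * (n + 1) / 4.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_counts**3 - tie_counts).sum() / 48.0
        z = (r_plus - mu - 0.5 * np.sign(r_plus - mu)) / np.sqrt(var)
        p = float(2.0 * stats.norm.sf(abs(z)))
        method = "normal"
    return WilcoxonResult(r_plus, r_minus, n, float(p), method, alpha)


# ---------------------------------------------------------------------------
# Kruskal–Wallis


@dataclass
class KruskalResult:
    h: float
    df: int
    p_value: float


def kruskal_wallis(groups) -> KruskalResult:
    """Rank-based H test that the groups come from one population."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 1 for g in groups):
        raise ValueError("need at least two non-empty groups")
    df = len(groups) - 1
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        # all observations identical: no rank variance, H = 0 by convention
        return KruskalResult(0.0, df, 1.0)
    h, p = stats.kruskal(*groups)
    return KruskalResult(float(h), df, float(p))
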