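"""Two-phase cross-user feature selection.

Phase 1 (correlation voting): per user, greedily flag redundant features
until no pairwise ``|r| >= cutoff`` remains among the survivors; a feature is
removed from the shared schema when at least ``min_votes`` users (default
``n_users - 1``) flagged it.

Phase 2 (PCA contribution counting): on the reduced schema, per user, run a
correlation-matrix PCA (features z-scored) and keep the smallest number of
leading dimensions explaining at least ``var_target`` of the variance.  A
feature earns one count for every (user, retained dimension) where its
contribution — 100 x squared loading, normalised per dimension — exceeds the
uniform benchmark ``100 / p`` %.  Features whose total count is at most
``negligible_max`` are removed.

Both phases see *training (normal) rows only*; anomalous windows never reach
this module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)


def _as_frame(train) -> pd.DataFrame:
    """Feature columns of the training (normal) rows, as a DataFrame."""
    from .features import FeatureMatrix

    if isinstance(train, FeatureMatrix):
        if (train.df["label"] == "anomaly").any():
            train = train.normal()
            logger.warning("anomalous rows passed to feature selection were dropped")
        return train.features
    return pd.DataFrame(train)


# ---------------------------------------------------------------------------
# phase 1: correlation flags + votes


def correlation_flags(train, cutoff: float = 0.75) -> set[str]:
    """Greedy redundancy flags for one user's training matrix.

    Repeatedly take the highest-correlated remaining pair with
    ``|r| >= cutoff`` and flag the member with the larger mean absolute
    correlation against the other remaining features, until the surviving set
    has no pair at or above the cutoff.  Zero-variance columns correlate with
    nothing (treated as r = 0).
    """
    X = _as_frame(train)
    if len(X) < 2:
        raise ValueError("need at least two rows to estimate correlations")
    names = list(X.columns)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.corrcoef(X.to_numpy(dtype=float), rowvar=False)
    corr = np.atleast_2d(corr)
    if np.isnan(corr).any():
        degenerate = [names[j] for j in range(len(names)) if np.isnan(corr[j]).all()]
        if degenerate:
            logger.info("zero-variance column(s) treated as uncorrelated: %s", degenerate)
        corr = np.nan_to_num(corr, nan=0.0)
    a = np.abs(corr)
    np.fill_diagonal(a, 0.0)

    active = list(range(len(names)))
    flagged: set[str] = set()
    while len(active) > 1:
        sub = a[np.ix_(active, active)]
        i_flat = int(np.argmax(sub))
        i, j = divmod(i_flat, len(active))
        if sub[i, j] < cutoff:
            break
        gi, gj = active[i], active[j]
        mean_i = sub[i].sum() / (len(active) - 1)
        mean_j = sub[j].sum() / (len(active) - 1)
        # drop the member more entangled with everything else; ties -> first
        drop = gi if mean_i >= mean_j else gj
        flagged.add(names[drop])
        active.remove(drop)
    return flagged


def vote_removals(per_user_flags, min_votes: int) -> set[str]:
    """Features flagged by at least ``min_votes`` users."""
    if min_votes > len(per_user_flags) and per_user_flags:
        logger.debug("min_votes above user count; nothing can be removed")
    votes = feature_votes(per_user_flags)
    return {name for name, v in votes.items() if v >= min_votes}


def feature_votes(per_user_flags) -> dict[str, int]:
    votes: dict[str, int] = {}
    for flags in per_user_flags:
        for name in flags:
            votes[name] = votes.get(name, 0) + 1
    return votes


@dataclass
class CorrelationReport:
    cutoff: float
    min_votes: int
    per_user_flags: dict[str, set[str]]
    votes: dict[str, int]
    removed: set[str]


# ---------------------------------------------------------------------------
# phase 2: PCA contributions


@dataclass
class PCAReportEntry:
    """Per-user PCA summary on the post-correlation schema."""

    n_dims: int  # d: retained leading dimensions
    cum_variance: float  # cumulative explained-variance ratio at d
    contributions: pd.DataFrame  # features x dimensions, percent (columns sum to 100)


def pca_contributions(train, var_target: float = 0.60) -> PCAReportEntry:
    """Correlation-matrix PCA for one user; features are z-scored first.

    ``d`` is the smallest dimension count whose cumulative explained-variance
    ratio reaches ``var_target``; contributions are 100 x squared loadings,
    which sum to 100 % within each dimension.
    """
    X = _as_frame(train)
    names = list(X.columns)
    arr = X.to_numpy(dtype=float)
    std = arr.std(axis=0, ddof=0)
    if (std == 0).any():
        bad = [names[j] for j in np.flatnonzero(std == 0)]
        raise ValueError(f"constant column(s) cannot be standardised: {bad}")
    Z = (arr - arr.mean(axis=0)) / std
    pca = PCA(n_components=min(len(names), len(Z) - 1), svd_solver="full")
    pca.fit(Z)
    ratios = pca.explained_variance_ratio_
    cum = np.cumsum(ratios)
    d = int(np.searchsorted(cum, var_target) + 1) if var_target > 0 else 1
    d = min(d, len(ratios))
    contrib = 100.0 * pca.components_**2  # rows: dims; unit-norm loadings
    contrib_df = pd.DataFrame(
        contrib.T, index=names, columns=[f"dim{k + 1}" for k in range(contrib.shape[0])]
    )
    return PCAReportEntry(n_dims=d, cum_variance=float(cum[d - 1]), contributions=contrib_df)


def contribution_counts(reports) -> dict[str, int]:
    """Pooled counts: +1 per (user, retained dimension) where a feature's
    contribution strictly exceeds the uniform benchmark 100/p %."""
    entries = list(reports.values()) if isinstance(reports, dict) else list(reports)
    if not entries:
        return {}
    names = list(entries[0].contributions.index)
    threshold = 100.0 / len(names)
    counts = {name: 0 for name in names}
    for entry in entries:
        if list(entry.contributions.index) != names:
            raise ValueError("all PCA reports must share one schema")
        sub = entry.contributions.iloc[:, : entry.n_dims]
        above = (sub > threshold).sum(axis=1)
        for name in names:
            counts[name] += int(above[name])
    return counts


def pca_removals(counts: dict[str, int], negligible_max: int = 0) -> set[str]:
    """Features whose pooled contribution count is at most ``negligible_max``."""
    return {name for name, c in counts.items() if c <= negligible_max}


@dataclass
class PCAReport:
    var_target: float
    negligible_max: int
    entries: dict[str, PCAReportEntry]
    counts: dict[str, int]
    removed: set[str]

    @property
    def max_possible_count(self) -> int:
        """Sum over users of retained dimensions (the count ceiling)."""
        return sum(e.n_dims for e in self.entries.values())


# ---------------------------------------------------------------------------
# assembled result


@dataclass
class SelectionResult:
    removed_by_cm: set[str]
    removed_by_pca: set[str]
    retained: list[str]
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.removed_by_cm & self.removed_by_pca:
            raise ValueError("phase removal sets must be disjoint")

    @property
    def removed(self) -> set[str]:
        return self.removed_by_cm | self.removed_by_pca

    def to_dict(self) -> dict:
        return {
            "params": dict(self.params),
            "removed_by_cm": sorted(self.removed_by_cm),
            "removed_by_pca": sorted(self.removed_by_pca),
            "retained": list(self.retained),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SelectionResult":
        return cls(
            removed_by_cm=set(d["removed_by_cm"]),
            removed_by_pca=set(d["removed_by_pca"]),
            retained=list(d["retained"]),
            params=dict(d.get("params", {})),
        )


def apply_selection(matrix, result: SelectionResult, dataset_id: str | None = None):
    """Drop the removed features by name; survivor order is preserved."""
    return matrix.drop_features(result.removed, dataset_id=dataset_id)


class TwoPhaseFeatureSelector(BaseEstimator, TransformerMixin):
    """Correlation-vote + PCA-contribution feature selection across users.

    Parameters
    ----------
    cutoff : float, default 0.75
        Absolute Pearson correlation at or above which a pair is redundant.
    min_votes : int or None, default None
        Users that must flag a feature for removal; ``None`` means
        ``n_users - 1``.
    var_target : float, default 0.60
        Cumulative explained-variance ratio the retained PCA dimensions
        must reach.
    negligible_max : int, default 0
        Largest pooled contribution count still considered negligible.

    ``fit`` expects training (normal-condition) rows only; pass ``groups``
    (one user id per row) for the cross-user vote, otherwise all rows are
    treated as a single user.
    """

    def __init__(self, cutoff: float = 0.75, min_votes: int | None = None, var_target: float = 0.60, negligible_max: int = 0):
        self.cutoff = cutoff
        self.min_votes = min_votes
        self.var_target = var_target
        self.negligible_max = negligible_max

    def fit(self, X, y=None, groups=None):
        X = pd.DataFrame(X)
        names = [str(c) for c in X.columns]
        X.columns = names
        if groups is None:
            groups = np.zeros(len(X), dtype=int)
        groups = np.asarray(groups)
        if len(groups) != len(X):
            raise ValueError("groups must have one entry per row")
        users = pd.unique(groups)
        min_votes = self.min_votes if self.min_votes is not None else max(len(users) - 1, 1)

        per_user = {str(u): correlation_flags(X[groups == u], cutoff=self.cutoff) for u in users}
        votes = feature_votes(per_user.values())
        removed_cm = vote_removals(list(per_user.values()), min_votes)
        self.correlation_report_ = CorrelationReport(
            cutoff=self.cutoff, min_votes=min_votes, per_user_flags=per_user, votes=votes, removed=removed_cm
        )

        survivors = [f for f in names if f not in removed_cm]
        entries = {
            str(u): self._user_contributions(X.loc[groups == u, survivors])
            for u in users
        }
        counts = contribution_counts(entries)
        removed_pca = pca_removals(counts, negligible_max=self.negligible_max)
        self.pca_report_ = PCAReport(
            var_target=self.var_target,
            negligible_max=self.negligible_max,
            entries=entries,
            counts=counts,
            removed=removed_pca,
        )

        retained = [f for f in survivors if f not in removed_pca]
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.n_features_in_ = len(names)
        self.removed_by_cm_ = removed_cm
        self.removed_by_pca_ = removed_pca
        self.retained_ = retained
        self.selection_result_ = SelectionResult(
            removed_by_cm=removed_cm,
            removed_by_pca=removed_pca,
            retained=retained,
            params={
                "cutoff": self.cutoff,
                "min_votes": min_votes,
                "var_target": self.var_target,
                "negligible_max": self.negligible_max,
            },
        )
        return self

    def _user_contributions(self, X: pd.DataFrame) -> PCAReportEntry:
        """Per-user PCA entry; features constant for this user contribute 0 %.

        A feature with no variance in a user's training data cannot be
        standardised, but by the same token it explains none of that user's
        variability — it simply earns no contribution counts there.
        """
        std = X.to_numpy(dtype=float).std(axis=0)
        constant = [c for c, s in zip(X.columns, std) if s == 0]
        if not constant:
            return pca_contributions(X, var_target=self.var_target)
        logger.info("constant training column(s) %s contribute 0%% for this user", constant)
        entry = pca_contributions(X.drop(columns=constant), var_target=self.var_target)
        contrib = entry.contributions.reindex(X.columns, fill_value=0.0)
        return PCAReportEntry(n_dims=entry.n_dims, cum_variance=entry.cum_variance, contributions=contrib)

    def get_support(self) -> np.ndarray:
        retained = set(self.retained_)
        return np.array([f in retained for f in self.feature_names_in_])

    def transform(self, X):
        if isinstance(X, pd.DataFrame):
            return X[self.retained_]
        X = np.asarray(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count mismatch")
        return X[:, self.get_support()]


def select_features(per_user_matrices: dict, **params) -> tuple[SelectionResult, CorrelationReport, PCAReport]:
    """Run the two-phase procedure on per-user training feature matrices.

    ``per_user_matrices`` maps user id to a :class:`FeatureMatrix` (or plain
    DataFrame) of that user's normal-condition windows.
    """
    frames, groups = [], []
    for uid, mat in per_user_matrices.items():
        f = _as_frame(mat)
        frames.append(f)
        groups.extend([uid] * len(f))
    stacked = pd.concat(frames, ignore_index=True)
    sel = TwoPhaseFeatureSelector(**params).fit(stacked, groups=np.asarray(groups))
    return sel.selection_result_, sel.correlation_report_, sel.pca_report_
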