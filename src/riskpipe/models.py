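"""One-class scorers behind a common fit / anomaly_score contract.

:class:`OckraDetector` is a random-subspace k-means ensemble: each member
projects the training windows onto an independent random feature subset
(every feature kept with probability ``feature_prob``), clusters the
projection with k-means, and remembers the mean nearest-centroid distance
``delta`` of its own training rows as a similarity scale.  A test row's
member similarity is ``exp(-0.5 (d / delta)^2)`` for its distance ``d`` to
the nearest centroid; the ensemble anomaly score is one minus the mean
member similarity, hence always in ``[0, 1]`` with higher = more anomalous.

:class:`OneClassSVMDetector` adapts the RBF one-class SVM (``gamma = 0.038``,
``nu = 0.5``) to the same contract: the anomaly score is the negated signed
decision value.

Both detectors min-max scale features to ``[0, 1]`` on the training data and
freeze the scaler for scoring — distance-based scores across units as
heterogeneous as g, deg/s, bpm and degrees Celsius require a common scale.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, OutlierMixin
from sklearn.cluster import KMeans
from sklearn.metrics import pairwise_distances_argmin_min
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import OneClassSVM

logger = logging.getLogger(__name__)

DELTA_FLOOR = 1e-12  # avoids division by zero on duplicate-row clusters


def _training_array(train) -> np.ndarray:
    from .features import FeatureMatrix

    if isinstance(train, FeatureMatrix):
        if (train.labels == 1).any():
            raise ValueError("one-class training data must contain normal rows only")
        return train.X
    return np.asarray(train, dtype=float)


@dataclass
class _Member:
    feature_idx: np.ndarray
    centroids: np.ndarray
    delta: float


class OckraDetector(BaseEstimator, OutlierMixin):
    """Random-subspace k-means ensemble one-class classifier.

    Parameters
    ----------
    n_members : int, default 50
        Ensemble size.
    feature_prob : float in (0, 1], default 0.5
        Probability of including each feature in a member's projection
        (an empty draw is redrawn).
    n_clusters : int, default 10
        Centroids per member (lowered with a warning if the training set is
        smaller).
    sample_fraction : float in (0, 1], default 1.0
        Fraction of training rows each member clusters.
    max_iter, tol :
        Lloyd's-algorithm stopping rule for each member's k-means.
    scale : bool, default True
        Min-max scale features to [0, 1] on the training data.
    threshold : float, default 0.5
        Anomaly-score cut used only by :meth:`predict`.
    random_state : int or None
        Seeds the member subsets, row subsamples and k-means inits.
    """

    def __init__(
        self,
        n_members: int = 50,
        feature_prob: float = 0.5,
        n_clusters: int = 10,
        sample_fraction: float = 1.0,
        max_iter: int = 100,
        tol: float = 1e-4,
        scale: bool = True,
        threshold: float = 0.5,
        random_state=None,
    ):
        self.n_members = n_members
        self.feature_prob = feature_prob
        self.n_clusters = n_clusters
        self.sample_fraction = sample_fraction
        self.max_iter = max_iter
        self.tol = tol
        self.scale = scale
        self.threshold = threshold
        self.random_state = random_state

    def fit(self, X, y=None):
        X = _training_array(X)
        if self.n_members < 1 or self.n_clusters < 1:
            raise ValueError("n_members and n_clusters must be >= 1")
        if not 0.0 < self.feature_prob <= 1.0:
            raise ValueError("feature_prob must be in (0, 1]")
        n_rows, n_feat = X.shape
        if n_rows < 1:
            raise ValueError("empty training set")

        if self.scale:
            self.scaler_ = MinMaxScaler().fit(X)
            Xs = self.scaler_.transform(X)
        else:
            self.scaler_ = None
            Xs = X
        # canonical row order: makes the fit independent of input row order
        Xs = Xs[np.lexsort(Xs.T[::-1])]

        k = self.n_clusters
        if n_rows < k:
            warnings.warn(
                f"training set has {n_rows} rows < n_clusters={k}; lowering to {n_rows}",
                UserWarning,
                stacklevel=2,
            )
            k = n_rows

        seeds = np.random.SeedSequence(self.random_state).spawn(self.n_members)
        members: list[_Member] = []
        for ss in seeds:
            rng = np.random.default_rng(ss)
            mask = rng.random(n_feat) < self.feature_prob
            while not mask.any():
                mask = rng.random(n_feat) < self.feature_prob
            idx = np.flatnonzero(mask)
            if self.sample_fraction < 1.0:
                m = max(k, int(round(self.sample_fraction * n_rows)))
                rows = np.sort(rng.choice(n_rows, size=min(m, n_rows), replace=False))
            else:
                rows = slice(None)
            P = Xs[rows][:, idx]
            km = KMeans(
                n_clusters=min(k, len(P)),
                init="random",
                n_init=1,
                max_iter=self.max_iter,
                tol=self.tol,
                random_state=int(rng.integers(2**31 - 1)),
            ).fit(P)
            _, dists = pairwise_distances_argmin_min(P, km.cluster_centers_)
            delta = max(float(dists.mean()), DELTA_FLOOR)
            members.append(_Member(feature_idx=idx, centroids=km.cluster_centers_, delta=delta))

        self.members_ = members
        self.n_features_in_ = n_feat
        return self

    def anomaly_score(self, X) -> np.ndarray:
        """Per-row anomaly score in [0, 1]; higher = more anomalous."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape[1]} (schema mismatch)"
            )
        if self.scaler_ is not None:
            X = self.scaler_.transform(X)
        sims = np.zeros(len(X))
        for m in self.members_:
            _, d = pairwise_distances_argmin_min(X[:, m.feature_idx], m.centroids)
            sims += np.exp(-0.5 * (d / m.delta) ** 2)
        return 1.0 - sims / len(self.members_)

    def score_samples(self, X) -> np.ndarray:
        """sklearn convention: higher = more normal."""
        return -self.anomaly_score(X)

    def decision_function(self, X) -> np.ndarray:
        return self.threshold - self.anomaly_score(X)

    def predict(self, X) -> np.ndarray:
        """+1 for inliers, -1 for anomalies (sklearn outlier convention)."""
        return np.where(self.anomaly_score(X) > self.threshold, -1, 1)


class OneClassSVMDetector(BaseEstimator, OutlierMixin):
    """RBF one-class SVM behind the common anomaly-score contract.

    Defaults follow the published benchmark settings gamma = 0.038 and
    nu = 0.5.  Note gamma = 0.038 is the LibSVM default 1/n_features for a
    26-dimensional vector and is calibrated to RAW feature scales: on
    features squashed to [0, 1] the kernel becomes nearly linear and
    low-valued anomalies (for example bradycardia) are scored as more
    normal, so this adapter leaves features unscaled by default.
    ``max_train`` optionally subsamples the training rows (the kernel fit is
    quadratic in their number); ``random_state`` seeds that subsample only —
    the SVM solution itself is deterministic.
    """

    def __init__(
        self,
        gamma: float = 0.038,
        nu: float = 0.5,
        kernel: str = "rbf",
        scale: bool = False,
        max_train: int | None = None,
        random_state=None,
    ):
        self.gamma = gamma
        self.nu = nu
        self.kernel = kernel
        self.scale = scale
        self.max_train = max_train
        self.random_state = random_state

    def fit(self, X, y=None):
        X = _training_array(X)
        if len(X) < 2:
            raise ValueError("one-class SVM training needs at least two rows")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if not 0.0 < self.nu <= 1.0:
            raise ValueError("nu must be in (0, 1]")
        if self.max_train is not None and len(X) > self.max_train:
            rng = np.random.default_rng(self.random_state)
            rows = np.sort(rng.choice(len(X), size=self.max_train, replace=False))
            X = X[rows]
        if self.scale:
            self.scaler_ = MinMaxScaler().fit(X)
            Xs = self.scaler_.transform(X)
        else:
            self.scaler_ = None
            Xs = X
        self.svm_ = OneClassSVM(kernel=self.kernel, gamma=self.gamma, nu=self.nu).fit(Xs)
        self.n_features_in_ = X.shape[1]
        return self

    def anomaly_score(self, X) -> np.ndarray:
        """Negated signed decision value; higher = more anomalous."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape[1]} (schema mismatch)"
            )
        if self.scaler_ is not None:
            X = self.scaler_.transform(X)
        return -self.svm_.decision_function(X)

    def score_samples(self, X) -> np.ndarray:
        return -self.anomaly_score(X)

    def decision_function(self, X) -> np.ndarray:
        return -self.anomaly_score(X)

    def predict(self, X) -> np.ndarray:
        return np.where(self.anomaly_score(X) > 0, -1, 1)


# thin functional wrappers over the estimators


def fit_ockra(train, **params) -> OckraDetector:
    return OckraDetector(**params).fit(train)


def ockra_score(model: OckraDetector, x) -> np.ndarray:
    return model.anomaly_score(x)


def fit_ocsvm(train, **params) -> OneClassSVMDetector:
    return OneClassSVMDetector(**params).fit(train)
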