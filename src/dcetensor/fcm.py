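"""Fuzzy C-means clustering of voxel intensities.

Standard Bezdek alternating updates on scalar samples:

    centers     v_k = sum_i u_ik^m x_i / sum_i u_ik^m
    memberships u_ik = 1 / sum_j (d_ik / d_ij)^(2/(m-1))

with fuzzifier m > 1 and Euclidean distances d_ik = |x_i - v_k|.  The
iteration stops when the maximum center movement falls below ``tol``.
A sample coinciding exactly with a center receives membership 1 there
(standard singularity handling).  Clustering is intensity-only — no
spatial regularization.

The estimator follows scikit-learn conventions (``fit``/``predict``,
``get_params``/``set_params``, trailing-underscore fitted attributes) and
is used three times in the pipeline: binarization of the peak enhancement
frame, per-frame classification of the enhancement series (the
comparator), and hybrid classification of the tensor reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

from .errors import DegenerateInputError, ParameterError

__all__ = ["FuzzyCMeans", "FCMParams", "FCMResult", "fcm_cluster", "assign_tumour_cluster"]

_EPS = 1e-12


class FuzzyCMeans(ClusterMixin, BaseEstimator):
    """Fuzzy C-means on scalar intensity samples.

    Parameters
    ----------
    n_clusters : int, default 2
    m : float, default 2.0
        Fuzzifier; must exceed 1 (m -> 1+ approaches hard k-means).
    tol : float, default 1e-5
        Convergence threshold on the maximum center movement.
    max_iter : int, default 300
    init : {"quantile_centers", "random_membership"}
        Deterministic default places initial centers at evenly spaced
        sample quantiles; random initialization draws memberships from the
        seeded generator.
    random_state : int or None
        Seed for random initialization; ignored by the quantile init.

    Attributes
    ----------
    cluster_centers_ : ndarray (n_clusters,), sorted ascending.
    membership_ : ndarray (n_samples, n_clusters), rows sum to 1.
    labels_ : ndarray (n_samples,), argmax membership.
    objective_trace_ : list of float, non-increasing.
    n_iter_ : int
    """

    def __init__(
        self,
        n_clusters: int = 2,
        m: float = 2.0,
        tol: float = 1e-5,
        max_iter: int = 300,
        init: Literal["quantile_centers", "random_membership"] = "quantile_centers",
        random_state: int | None = None,
    ) -> None:
        self.n_clusters = n_clusters
        self.m = m
        self.tol = tol
        self.max_iter = max_iter
        self.init = init
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    def _validate(self, X) -> np.ndarray:
        x = np.asarray(X, dtype=float)
        if x.ndim == 2 and x.shape[1] == 1:
            x = x[:, 0]
        if x.ndim != 1:
            raise ParameterError("FuzzyCMeans expects scalar samples: shape (n,) or (n, 1)")
        if self.n_clusters < 1:
            raise ParameterError("n_clusters must be >= 1")
        if self.m <= 1:
            raise ParameterError("fuzzifier m must exceed 1")
        if self.tol <= 0:
            raise ParameterError("tol must be positive")
        if np.unique(x).size < self.n_clusters:
            raise DegenerateInputError(
                f"need >= {self.n_clusters} distinct sample values, "
                f"got {np.unique(x).size}"
            )
        return x

    def _memberships(self, x: np.ndarray, centers: np.ndarray) -> np.ndarray:
        d = np.abs(x[:, None] - centers[None, :])
        exact = d < _EPS
        d = np.maximum(d, _EPS)
        inv = d ** (-2.0 / (self.m - 1.0))
        u = inv / inv.sum(axis=1, keepdims=True)
        hit = exact.any(axis=1)
        if np.any(hit):  # sample sits on a center: full membership there
            u[hit] = 0.0
            u[hit, exact[hit].argmax(axis=1)] = 1.0
        return u

    def _objective(self, x: np.ndarray, u: np.ndarray, centers: np.ndarray) -> float:
        d2 = (x[:, None] - centers[None, :]) ** 2
        return float(np.sum(u**self.m * d2))

    # -- API ---------------------------------------------------------------

    def fit(self, X, y=None) -> "FuzzyCMeans":
        x = self._validate(X)
        c = self.n_clusters
        if self.init == "quantile_centers":
            qs = (np.arange(c) + 0.5) / c
            centers = np.quantile(x, qs)
            # separate coincident initial centers so distinct clusters exist
            for k in range(1, c):
                if centers[k] - centers[k - 1] < _EPS:
                    centers[k] = centers[k - 1] + max(np.ptp(x) * 1e-6, _EPS)
            u = self._memberships(x, centers)
        elif self.init == "random_membership":
            rng = np.random.default_rng(self.random_state)
            u = rng.random((x.size, c))
            u /= u.sum(axis=1, keepdims=True)
        else:
            raise ParameterError(f"unknown init {self.init!r}")

        trace: list[float] = []
        centers = np.empty(c)
        for it in range(1, self.max_iter + 1):
            um = u**self.m
            new_centers = um.T @ x / np.maximum(um.sum(axis=0), _EPS)
            u = self._memberships(x, new_centers)
            trace.append(self._objective(x, u, new_centers))
            moved = np.inf if it == 1 else float(np.max(np.abs(new_centers - centers)))
            centers = new_centers
            if moved < self.tol:
                break

        order = np.argsort(centers, kind="stable")
        self.cluster_centers_ = centers[order]
        self.membership_ = u[:, order]
        self.labels_ = self.membership_.argmax(axis=1)
        self.objective_trace_ = trace
        self.n_iter_ = len(trace)
        return self

    def predict(self, X) -> np.ndarray:
        x = np.asarray(X, dtype=float).ravel()
        return self._memberships(x, self.cluster_centers_).argmax(axis=1)

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_


@dataclass(frozen=True)
class FCMParams:
    """Plain-data FCM configuration (maps 1:1 onto :class:`FuzzyCMeans`)."""

    n_clusters: int = 2
    m: float = 2.0
    tol: float = 1e-5
    max_iter: int = 300
    init: str = "quantile_centers"
    seed: int | None = None

    def to_estimator(self) -> FuzzyCMeans:
        return FuzzyCMeans(
            n_clusters=self.n_clusters,
            m=self.m,
            tol=self.tol,
            max_iter=self.max_iter,
            init=self.init,  # type: ignore[arg-type]
            random_state=self.seed,
        )


@dataclass
class FCMResult:
    """Output of an FCM run on scalar samples."""

    centers: np.ndarray  # sorted ascending
    membership: np.ndarray  # (n_samples, n_clusters)
    labels: np.ndarray
    objective_trace: list[float] = field(default_factory=list)


def fcm_cluster(samples: Sequence[float] | np.ndarray, params: FCMParams) -> FCMResult:
    """Functional wrapper: cluster scalar samples with the given parameters."""
    est = params.to_estimator().fit(np.asarray(samples, dtype=float).ravel())
    return FCMResult(
        centers=est.cluster_centers_,
        membership=est.membership_,
        labels=est.labels_,
        objective_trace=est.objective_trace_,
    )


def assign_tumour_cluster(result: FCMResult, k_top: int = 1) -> set[int]:
    """Indices of the ``k_top`` clusters with the largest centers.

    Voxels of high enhancement belong to the highest-center clusters;
    ties are broken toward the lower cluster index.
    """
    c = len(result.centers)
    if not 1 <= k_top < c:
        raise ParameterError(f"k_top must satisfy 1 <= k_top < n_clusters, got {k_top} of {c}")
    order = sorted(range(c), key=lambda k: (-result.centers[k], k))
    return set(order[:k_top])
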