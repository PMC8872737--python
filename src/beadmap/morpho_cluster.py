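"""Morphological feature extraction and k-means clustering of cell images.

2D features (area, equivalent-ellipse axes, Crofton perimeter) come from the
transmission-image mask; 3D features (volume, exposed-voxel-face surface
area) from the side-scatter voxel mask.  Cells are grouped by an
unsupervised k-means written here in full (k-means++ seeding, Lloyd
iterations, multiple restarts, z-score standardisation stored with the
model) so a model fitted on one sample — e.g. a diseased stellate-cell
preparation — can be applied unchanged to predict cluster membership in a
control sample.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import measure
from sklearn.base import BaseEstimator, ClusterMixin

CORE_FEATURES = (
    "area_2d",
    "major_axis",
    "minor_axis",
    "perimeter",
    "volume_3d",
    "surface_area_3d",
)


@dataclass
class FeatureVector:
    """Per-cell morphology, in µm-based units.

    The six core features mirror the standard registration-table columns
    (2D transmission: surface area, major axis, minor axis, perimeter;
    3D SSC: volume, surface area); ``extras`` holds clearly-labelled
    optional additions, off by default.
    """

    area_2d: float = np.nan
    major_axis: float = np.nan
    minor_axis: float = np.nan
    perimeter: float = np.nan
    volume_3d: float = np.nan
    surface_area_3d: float = np.nan
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in CORE_FEATURES:
            v = getattr(self, name)
            if np.isfinite(v) and v < 0:
                raise ValueError(f"{name} must be non-negative")
        a, b = self.major_axis, self.minor_axis
        if np.isfinite(a) and np.isfinite(b) and a < b - 1e-9:
            raise ValueError("major_axis must be >= minor_axis")

    def to_series(self) -> pd.Series:
        data = {name: getattr(self, name) for name in CORE_FEATURES}
        data.update(self.extras)
        return pd.Series(data)

    def merge(self, other: "FeatureVector") -> "FeatureVector":
        """Combine 2D and 3D partial vectors into one."""
        kwargs = {}
        for name in CORE_FEATURES:
            mine, theirs = getattr(self, name), getattr(other, name)
            kwargs[name] = theirs if np.isnan(mine) else mine
        return FeatureVector(**kwargs, extras={**self.extras, **other.extras})


def features_2d(mask: np.ndarray, pixel_size: float, extras: bool = False) -> FeatureVector:
    """2D morphology of a binary mask (whole foreground as one object)."""
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise ValueError("features_2d expects a 2D mask")
    if not mask.any():
        raise ValueError("empty mask")
    region = measure.regionprops(mask.astype(np.uint8))[0]
    extra = {}
    if extras:
        extra = {
            "eccentricity_2d": float(region.eccentricity),
            "solidity_2d": float(region.solidity),
        }
    return FeatureVector(
        area_2d=float(region.area) * pixel_size**2,
        major_axis=float(region.axis_major_length) * pixel_size,
        minor_axis=float(region.axis_minor_length) * pixel_size,
        perimeter=float(region.perimeter_crofton) * pixel_size,
        extras=extra,
    )


def features_3d(voxels: np.ndarray, voxel_size: float, extras: bool = False) -> FeatureVector:
    """3D morphology of a voxel mask.

    Volume is the voxel count times the voxel volume; surface area counts
    exposed voxel faces (exact for axis-aligned shapes; biased upward ~1.5x
    on smooth shapes, see docs).
    """
    m = np.asarray(voxels, dtype=bool)
    if m.ndim != 3:
        raise ValueError("features_3d expects a 3D mask")
    n = int(m.sum())
    if n == 0:
        raise ValueError("empty mask")
    adjacencies = sum(
        int(np.logical_and(m.take(range(0, s - 1), axis=ax), m.take(range(1, s), axis=ax)).sum())
        for ax, s in enumerate(m.shape)
    )
    exposed_faces = 6 * n - 2 * adjacencies
    volume = n * voxel_size**3
    surface = exposed_faces * voxel_size**2
    extra = {}
    if extras:
        bbox_vol = float(np.prod(m.shape)) * voxel_size**3
        coords = np.argwhere(m)
        spans = coords.max(axis=0) - coords.min(axis=0) + 1
        extra = {
            "sphericity_3d": float(np.pi ** (1 / 3) * (6 * volume) ** (2 / 3) / surface),
            "extent_3d": float(volume / bbox_vol),
            "aspect_ratio_3d": float(spans.max() / spans.min()),
        }
    return FeatureVector(volume_3d=volume, surface_area_3d=surface, extras=extra)


class MorphoKMeans(ClusterMixin, BaseEstimator):
    """k-means clustering of morphology features, written from scratch.

    Lloyd's algorithm with k-means++ seeding and ``n_init`` restarts (best
    inertia kept).  Features are z-score standardised at fit time and the
    stored scaling is reapplied at predict time, so a model fitted on one
    sample transfers to another measured in the same units.  ``n_clusters``
    defaults to 2 (diseased vs normal morphology).

    Attributes (after ``fit``): ``cluster_centers_`` (standardised space),
    ``labels_``, ``inertia_``, ``inertia_history_`` (per Lloyd iteration of
    the winning restart), ``feature_means_``, ``feature_scales_``,
    ``n_iter_``, ``degenerate_``.
    """

    def __init__(
        self,
        n_clusters: int = 2,
        n_init: int = 10,
        max_iter: int = 300,
        tol: float = 1e-6,
        standardize: bool = True,
        random_state: int | None = None,
    ):
        self.n_clusters = n_clusters
        self.n_init = n_init
        self.max_iter = max_iter
        self.tol = tol
        self.standardize = standardize
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    @staticmethod
    def _sqdist(X: np.ndarray, C: np.ndarray) -> np.ndarray:
        return ((X[:, None, :] - C[None, :, :]) ** 2).sum(axis=2)

    def _kmeanspp(self, X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        n = X.shape[0]
        centers = [X[rng.integers(n)]]
        for _ in range(1, self.n_clusters):
            d2 = self._sqdist(X, np.array(centers)).min(axis=1)
            total = d2.sum()
            if total <= 0:  # all points coincide with existing centers
                centers.append(X[rng.integers(n)])
                continue
            centers.append(X[rng.choice(n, p=d2 / total)])
        return np.array(centers)

    def _lloyd(self, X: np.ndarray, centers: np.ndarray):
        history = []
        labels = None
        for it in range(1, self.max_iter + 1):
            d2 = self._sqdist(X, centers)
            labels = d2.argmin(axis=1)  # ties -> lowest index (argmin)
            inertia = float(d2[np.arange(len(X)), labels].sum())
            history.append(inertia)
            new_centers = centers.copy()
            for k in range(self.n_clusters):
                pts = X[labels == k]
                if len(pts):
                    new_centers[k] = pts.mean(axis=0)
            shift = float(np.sqrt(((new_centers - centers) ** 2).sum()))
            centers = new_centers
            if shift < self.tol:
                break
        d2 = self._sqdist(X, centers)
        labels = d2.argmin(axis=1)
        inertia = float(d2[np.arange(len(X)), labels].sum())
        history.append(inertia)
        return centers, labels, inertia, history, it

    # -- estimator API -----------------------------------------------------

    def fit(self, X, y=None) -> "MorphoKMeans":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be a 2D feature matrix")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite values")
        n, _ = X.shape
        if not 1 <= self.n_clusters <= n:
            raise ValueError(f"n_clusters must be in [1, {n}]")

        if self.standardize:
            self.feature_means_ = X.mean(axis=0)
            scales = X.std(axis=0)
            scales[scales == 0] = 1.0
            self.feature_scales_ = scales
        else:
            self.feature_means_ = np.zeros(X.shape[1])
            self.feature_scales_ = np.ones(X.shape[1])
        Z = (X - self.feature_means_) / self.feature_scales_

        self.degenerate_ = bool(np.allclose(Z, Z[0]))
        if self.degenerate_ and self.n_clusters > 1:
            warnings.warn(
                "all points identical: centroids replicated, single effective cluster",
                stacklevel=2,
            )

        rng = np.random.default_rng(self.random_state)
        best = None
        for _ in range(self.n_init):
            centers0 = self._kmeanspp(Z, rng)
            centers, labels, inertia, history, n_iter = self._lloyd(Z, centers0)
            if best is None or inertia < best[2]:
                best = (centers, labels, inertia, history, n_iter)
        self.cluster_centers_, self.labels_, self.inertia_, self.inertia_history_, self.n_iter_ = best
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "cluster_centers_"):
            raise ValueError("model is not fitted")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.cluster_centers_.shape[1]:
            raise ValueError(
                f"X must have {self.cluster_centers_.shape[1]} features, got shape {X.shape}"
            )
        Z = (X - self.feature_means_) / self.feature_scales_
        return self._sqdist(Z, self.cluster_centers_).argmin(axis=1)

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_

    # -- persistence ---------------------------------------------------------

    def to_json(self, path) -> None:
        payload = {
            "n_clusters": self.n_clusters,
            "random_state": self.random_state,
            "cluster_centers": self.cluster_centers_.tolist(),
            "feature_means": self.feature_means_.tolist(),
            "feature_scales": self.feature_scales_.tolist(),
            "inertia": self.inertia_,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "MorphoKMeans":
        with open(path) as fh:
            p = json.load(fh)
        model = cls(n_clusters=p["n_clusters"], random_state=p.get("random_state"))
        model.cluster_centers_ = np.array(p["cluster_centers"])
        model.feature_means_ = np.array(p["feature_means"])
        model.feature_scales_ = np.array(p["feature_scales"])
        model.inertia_ = p["inertia"]
        return model


def kmeans_fit(
    data: np.ndarray,
    k: int = 2,
    n_init: int = 10,
    max_iter: int = 300,
    tol: float = 1e-6,
    seed: int | None = None,
) -> MorphoKMeans:
    """Fit a from-scratch k-means model on a feature matrix."""
    return MorphoKMeans(
        n_clusters=k, n_init=n_init, max_iter=max_iter, tol=tol, random_state=seed
    ).fit(data)


def kmeans_predict(model: MorphoKMeans, data: np.ndarray) -> np.ndarray:
    """Label each point by its nearest (standardised-space) centroid."""
    return model.predict(data)
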