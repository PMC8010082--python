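"""Grid-stratified unsupervised classification ensemble.

The study area is split into equally sized grid tiles (12 in the original
design). Within each tile, 50,000 training pixels are drawn from the
six-band annual mosaic, k-means models are fitted for every cluster count
in [10, 16], and the count maximizing the Calinski-Harabasz variance
ratio is kept. Clusters are labelled oil palm / non-palm from reference
points (a stand-in for the visual very-high-resolution check), each tile's
model classifies the *entire* extent, and the twelve competing maps are
reconciled by a majority vote: a pixel is oil palm iff at least
``vote_threshold`` (default 7) of the member maps say so.

:class:`KSelectKMeans` is a plain scikit-learn clusterer on feature
matrices; :class:`GridClusterEnsemble` orchestrates the tiling, sampling,
labelling and voting on :class:`~palmage.mosaic.AnnualMosaic` inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.metrics import calinski_harabasz_score, pairwise_distances_argmin
from sklearn.utils.validation import check_is_fitted

from .grid import GridMismatchError, RasterGrid, require_same_grid
from .mosaic import AnnualMosaic
from .synthetic import ConfigurationError

__all__ = [
    "GridPartition",
    "ClusterModel",
    "KSelectKMeans",
    "GridClusterEnsemble",
    "partition_grid",
    "sample_training",
    "fit_unsupervised",
    "label_clusters",
    "predict_map",
    "majority_vote",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Tile:
    """Half-open rectangular sub-extent [r0, r1) x [c0, c1)."""

    r0: int
    r1: int
    c0: int
    c1: int

    def mask(self, grid: RasterGrid) -> np.ndarray:
        m = np.zeros(grid.shape, bool)
        m[self.r0:self.r1, self.c0:self.c1] = True
        return m

    @property
    def n_pixels(self) -> int:
        return (self.r1 - self.r0) * (self.c1 - self.c0)


@dataclass(frozen=True)
class GridPartition:
    tiles: tuple
    grid: RasterGrid

    @property
    def count(self) -> int:
        return len(self.tiles)


def _closest_factor_pair(n: int) -> tuple[int, int]:
    """(a, b) with a*b = n, a <= b and a maximal (closest to square)."""
    a = int(np.floor(np.sqrt(n)))
    while n % a:
        a -= 1
    return a, n // a


def partition_grid(grid: RasterGrid, n_tiles: int = 12) -> GridPartition:
    """Tile the extent into ``n_tiles`` near-equal rectangles.

    The tile layout is the rows x cols factorization of ``n_tiles``
    closest to square (rows factor <= cols factor); row/column boundaries
    are near-equal splits, so tiles are disjoint and cover the extent.
    """
    if n_tiles < 1:
        raise ConfigurationError("n_tiles must be >= 1")
    if n_tiles > grid.n_pixels:
        raise ConfigurationError(f"cannot cut {grid.n_pixels} pixels into {n_tiles} tiles")
    a, b = _closest_factor_pair(n_tiles)
    row_edges = np.linspace(0, grid.rows, a + 1).round().astype(int)
    col_edges = np.linspace(0, grid.cols, b + 1).round().astype(int)
    tiles = tuple(
        Tile(int(row_edges[i]), int(row_edges[i + 1]),
             int(col_edges[j]), int(col_edges[j + 1]))
        for i in range(a) for j in range(b)
    )
    return GridPartition(tiles, grid)


def sample_training(mosaic: AnnualMosaic, tile: Tile, n_train: int,
                    seed: int) -> np.ndarray:
    """Draw training feature vectors from the valid pixels of one tile.

    Uniform without replacement; if the tile holds fewer valid pixels than
    requested the sample is drawn with replacement (logged). Rows are the
    six mosaic features (3 byte bands + 3 SAVG textures).
    """
    feats = mosaic.feature_stack()
    valid = mosaic.feature_valid & tile.mask(mosaic.grid)
    idx = np.flatnonzero(valid.ravel())
    if idx.size == 0:
        raise ConfigurationError(f"tile {tile} has no valid pixels to sample")
    rng = np.random.default_rng(seed)
    if idx.size >= n_train:
        chosen = rng.choice(idx, size=n_train, replace=False)
    else:
        logger.warning("tile %s has %d valid pixels < n_train=%d; sampling "
                       "with replacement", tile, idx.size, n_train)
        chosen = rng.choice(idx, size=n_train, replace=True)
    return feats.reshape(-1, feats.shape[-1])[chosen]


class KSelectKMeans(ClusterMixin, BaseEstimator):
    """K-means with cluster-count selection on the variance-ratio criterion.

    Fits k-means for every k in [k_min, k_max] (multiple restarts, fixed
    seed) and keeps the model maximizing the Calinski-Harabasz score.
    Fully scikit-learn compatible on (n_samples, n_features) matrices.
    """

    def __init__(self, k_min: int = 10, k_max: int = 16, n_init: int = 3,
                 random_state: int | None = None):
        self.k_min = k_min
        self.k_max = k_max
        self.n_init = n_init
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, float)
        if not (1 <= self.k_min <= self.k_max):
            raise ConfigurationError("need 1 <= k_min <= k_max")
        if X.shape[0] < self.k_max:
            raise ValueError(f"need >= k_max={self.k_max} samples, got {X.shape[0]}")
        if np.unique(X, axis=0).shape[0] < self.k_min:
            raise ValueError("fewer distinct points than k_min")
        best = None
        scores = {}
        for k in range(self.k_min, self.k_max + 1):
            km = KMeans(n_clusters=k, n_init=self.n_init,
                        random_state=self.random_state).fit(X)
            scores[k] = calinski_harabasz_score(X, km.labels_)
            if best is None or scores[k] > scores[best[0]]:
                best = (k, km)
        self.k_, km = best
        self.cluster_centers_ = km.cluster_centers_
        self.labels_ = km.labels_
        self.inertia_ = km.inertia_
        self.criterion_scores_ = scores
        return self

    def predict(self, X):
        check_is_fitted(self, "cluster_centers_")
        return pairwise_distances_argmin(np.asarray(X, float), self.cluster_centers_)


@dataclass(frozen=True)
class ClusterModel:
    """One tile's fitted and (optionally) labelled cluster model.

    Centroids live in the standardized feature space; ``scaler_mean`` /
    ``scaler_scale`` map raw mosaic features into it.
    """

    k: int
    centroids: np.ndarray
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    tile_id: int
    seed: int
    criterion: str = "calinski_harabasz"
    criterion_scores: dict | None = None
    oil_palm_clusters: frozenset | None = None

    def transform(self, features: np.ndarray) -> np.ndarray:
        return (features - self.scaler_mean) / self.scaler_scale

    def assign(self, features: np.ndarray) -> np.ndarray:
        """Nearest-centroid cluster ids for raw feature rows."""
        return pairwise_distances_argmin(self.transform(features), self.centroids)


def fit_unsupervised(features: np.ndarray, k_min: int = 10, k_max: int = 16,
                     seed: int = 0, tile_id: int = 0,
                     n_init: int = 3) -> ClusterModel:
    """Standardize features, select k in [k_min, k_max], return the model."""
    features = np.asarray(features, float)
    mean = features.mean(axis=0)
    scale = features.std(axis=0)
    scale = np.where(scale > 0, scale, 1.0)
    km = KSelectKMeans(k_min, k_max, n_init=n_init, random_state=seed)
    km.fit((features - mean) / scale)
    return ClusterModel(km.k_, km.cluster_centers_, mean, scale, tile_id, seed,
                        criterion_scores=km.criterion_scores_)


def label_clusters(model: ClusterModel, ref_features: np.ndarray,
                   ref_is_palm: np.ndarray, min_ref: int = 10) -> ClusterModel:
    """Label clusters oil palm by strict reference-point majority.

    A cluster joins the oil-palm set iff >50% of its assigned reference
    points are oil palm; clusters with fewer than ``min_ref`` reference
    points are labelled non-palm with a warning.
    """
    ref_features = np.asarray(ref_features, float)
    ref_is_palm = np.asarray(ref_is_palm, bool)
    if ref_features.shape[0] == 0:
        raise ConfigurationError("no reference points supplied for labelling")
    assign = model.assign(ref_features)
    palm_ids = []
    for c in range(model.k):
        m = assign == c
        n = int(m.sum())
        if n < min_ref:
            if n:
                logger.warning("cluster %d of tile %d has only %d reference points "
                               "(min %d); labelled non-palm", c, model.tile_id, n, min_ref)
            continue
        if ref_is_palm[m].mean() > 0.5:
            palm_ids.append(c)
    return replace(model, oil_palm_clusters=frozenset(palm_ids))


def predict_map(model: ClusterModel, mosaic: AnnualMosaic
                ) -> tuple[np.ndarray, np.ndarray]:
    """Classify the whole mosaic with one tile's model.

    Returns ``(palm_map, gap_mask)``: each valid pixel goes to its nearest
    centroid (Euclidean in standardized feature space) and is 1 iff that
    cluster is labelled oil palm; invalid pixels are 0 and flagged as gaps.
    """
    if model.oil_palm_clusters is None:
        raise ValueError("cluster model has not been labelled")
    feats = mosaic.feature_stack()
    valid = mosaic.feature_valid
    flat = feats.reshape(-1, feats.shape[-1])[valid.ravel()]
    out = np.zeros(mosaic.grid.shape, np.uint8)
    if flat.shape[0]:
        assign = model.assign(flat)
        palm = np.isin(assign, sorted(model.oil_palm_clusters))
        out[valid] = palm.astype(np.uint8)
    return out, ~valid


def majority_vote(maps: list[np.ndarray], vote_threshold: int = 7,
                  gap_masks: list[np.ndarray] | None = None,
                  renormalize: bool = False) -> np.ndarray:
    """Reconcile member maps: palm iff >= ``vote_threshold`` palm votes.

    Gap pixels of a member count as 0-votes by default; with
    ``renormalize=True`` the threshold is rescaled per pixel to the number
    of non-gap votes (``ceil(threshold * n_valid / n_maps)``, palm only
    where at least one member voted validly).
    """
    if not maps:
        raise ConfigurationError("majority_vote needs at least one map")
    shape = maps[0].shape
    for m in maps:
        if m.shape != shape:
            raise GridMismatchError(f"member map shapes differ: {m.shape} vs {shape}")
    n_maps = len(maps)
    if not (1 <= vote_threshold <= n_maps):
        raise ConfigurationError(f"vote_threshold {vote_threshold} outside [1, {n_maps}]")
    stack = np.stack([np.asarray(m, np.uint8) for m in maps])
    if gap_masks is not None:
        gaps = np.stack([np.asarray(g, bool) for g in gap_masks])
        if gaps.shape != stack.shape:
            raise GridMismatchError("gap masks must match member maps")
        stack = np.where(gaps, 0, stack)
        if renormalize:
            n_valid = (~gaps).sum(axis=0)
            thr = np.ceil(vote_threshold * n_valid / n_maps)
            thr = np.maximum(thr, 1)
            return ((stack.sum(axis=0) >= thr) & (n_valid > 0)).astype(np.uint8)
    return (stack.sum(axis=0) >= vote_threshold).astype(np.uint8)


class GridClusterEnsemble(BaseEstimator):
    """The full grid-stratified unsupervised oil-palm classifier.

    Parameters mirror the published design: ``n_grids`` tiles, ``n_train``
    training points per tile, cluster counts in [k_min, k_max], and the
    7-of-12 reconciliation threshold. ``fit`` takes the annual mosaic plus
    labelled reference points; ``predict`` returns the reconciled binary
    oil-palm map for a mosaic on the same grid.
    """

    def __init__(self, n_grids: int = 12, n_train: int = 50_000,
                 k_min: int = 10, k_max: int = 16, vote_threshold: int = 7,
                 min_ref: int = 10, n_init: int = 3,
                 renormalize_votes: bool = False,
                 random_state: int | None = None):
        self.n_grids = n_grids
        self.n_train = n_train
        self.k_min = k_min
        self.k_max = k_max
        self.vote_threshold = vote_threshold
        self.min_ref = min_ref
        self.n_init = n_init
        self.renormalize_votes = renormalize_votes
        self.random_state = random_state

    def fit(self, mosaic: AnnualMosaic, reference: tuple):
        """Fit one labelled cluster model per grid tile.

        ``reference`` is ``(flat_indices, is_palm)``: raster positions (in
        row-major flat index) of labelled reference pixels and their
        oil-palm flags — the stand-in for visual high-resolution checks.
        """
        if not (1 <= self.vote_threshold <= self.n_grids):
            raise ConfigurationError(
                f"vote_threshold {self.vote_threshold} outside [1, {self.n_grids}]")
        ref_idx, ref_palm = reference
        ref_idx = np.asarray(ref_idx, np.int64)
        feats = mosaic.feature_stack().reshape(-1, 6)
        ref_feats = feats[ref_idx]
        usable = mosaic.feature_valid.ravel()[ref_idx]
        ref_feats, ref_palm = ref_feats[usable], np.asarray(ref_palm, bool)[usable]

        base = 0 if self.random_state is None else int(self.random_state)
        self.partition_ = partition_grid(mosaic.grid, self.n_grids)
        self.models_ = []
        for tid, tile in enumerate(self.partition_.tiles):
            sample = sample_training(mosaic, tile, self.n_train,
                                     seed=base * 1000 + tid)
            model = fit_unsupervised(sample, self.k_min, self.k_max,
                                     seed=base * 1000 + tid, tile_id=tid,
                                     n_init=self.n_init)
            self.models_.append(label_clusters(model, ref_feats, ref_palm,
                                               self.min_ref))
        self.selected_k_ = [m.k for m in self.models_]
        return self

    def predict_members(self, mosaic: AnnualMosaic
                        ) -> tuple[list[np.ndarray], list[np.ndarray]]:
        check_is_fitted(self, "models_")
        maps, gaps = [], []
        for model in self.models_:
            m, g = predict_map(model, mosaic)
            maps.append(m)
            gaps.append(g)
        return maps, gaps

    def predict(self, mosaic: AnnualMosaic) -> np.ndarray:
        maps, gaps = self.predict_members(mosaic)
        return majority_vote(maps, self.vote_threshold, gaps,
                             renormalize=self.renormalize_votes)
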