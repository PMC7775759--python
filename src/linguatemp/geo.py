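"""Empirical (rho, sigma, tau) estimation from geolocated binary samples.

The empirical analogue of the lattice summary statistics: rho is the
fraction of languages attesting a feature, sigma the fraction of directed
(focal, neighbor) pairs that disagree, with neighborhoods given either by
the k geographically nearest languages (great-circle / haversine distance
on a unit sphere) or, for full lattice samples, by the four von Neumann
grid bonds.  Temperatures are inferred per sample via
:func:`linguatemp.theory.temperature_from_stats`, with nonparametric
bootstrap uncertainty.

Distances are in unit-sphere radians throughout: only the ordering of
distances enters the k-NN construction, so the Earth radius is
irrelevant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _sps

from . import theory

__all__ = [
    "LanguagePoint", "FeatureSample", "EstimatorConfig", "BootstrapSummary",
    "haversine_distance", "knn_neighbors", "empirical_frequency",
    "empirical_isogloss_density", "point_estimate", "bootstrap_temperature",
    "hemisphere_split_test", "InsufficientSampleError",
]


class InsufficientSampleError(ValueError):
    """Sample too small for the requested neighborhood size."""


@dataclass(frozen=True)
class LanguagePoint:
    """One geolocated binary observation."""

    id: str
    name: str
    latitude: float
    longitude: float
    value: int

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude out of range: {self.latitude!r}")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"longitude out of range: {self.longitude!r}")
        if self.value not in (0, 1):
            raise ValueError(f"value must be binary, got {self.value!r}")


@dataclass
class FeatureSample:
    """Geolocated binary observations for one feature.

    Stored as parallel arrays for vectorized distance work.  Optional grid
    metadata (set by the synthetic-atlas generator under full sampling)
    enables exact von Neumann bond neighborhoods.
    """

    feature_id: str
    ids: np.ndarray          # object/str
    names: np.ndarray
    latitudes: np.ndarray    # degrees
    longitudes: np.ndarray   # degrees
    values: np.ndarray       # int8 in {0, 1}
    grid_shape: tuple[int, int] | None = None
    grid_index: np.ndarray | None = None   # flat row-major cell index

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        self.latitudes = np.asarray(self.latitudes, dtype=float)
        self.longitudes = np.asarray(self.longitudes, dtype=float)
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("feature values must be strictly binary")
        if np.any(np.abs(self.latitudes) > 90) or \
                np.any(np.abs(self.longitudes) > 180):
            raise ValueError("coordinates out of range")

    def __len__(self) -> int:
        return len(self.values)

    @classmethod
    def from_points(cls, feature_id: str,
                    points: list[LanguagePoint]) -> "FeatureSample":
        return cls(
            feature_id=feature_id,
            ids=np.array([p.id for p in points], dtype=object),
            names=np.array([p.name for p in points], dtype=object),
            latitudes=np.array([p.latitude for p in points]),
            longitudes=np.array([p.longitude for p in points]),
            values=np.array([p.value for p in points], dtype=np.int8),
        )

    def canonical(self) -> "FeatureSample":
        """Copy sorted by (id, original position): estimates become
        invariant under permutation of the input point order."""
        order = np.lexsort((np.arange(len(self)),
                            np.asarray(self.ids, dtype=str)))
        return self.take(order)

    def take(self, idx: np.ndarray) -> "FeatureSample":
        return FeatureSample(
            feature_id=self.feature_id,
            ids=np.asarray(self.ids)[idx], names=np.asarray(self.names)[idx],
            latitudes=self.latitudes[idx], longitudes=self.longitudes[idx],
            values=self.values[idx],
            grid_shape=self.grid_shape,
            grid_index=None if self.grid_index is None
            else np.asarray(self.grid_index)[idx],
        )

    def complemented(self) -> "FeatureSample":
        out = self.take(np.arange(len(self)))
        out.values = (1 - out.values).astype(np.int8)
        return out


@dataclass(frozen=True)
class EstimatorConfig:
    """Knobs of the empirical pipeline (defaults follow the study design)."""

    k_neighbors: int = 10
    n_bootstrap: int = 1000
    confidence_level: float = 0.95
    min_sample_size: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")
        if not 0.0 < self.confidence_level < 1.0:
            raise ValueError("confidence_level must be in (0, 1)")


@dataclass
class BootstrapSummary:
    """Per-replicate (rho, sigma, tau) triples with medians and intervals."""

    feature_id: str
    n: int
    n_bootstrap: int
    rho_b: np.ndarray
    sigma_b: np.ndarray
    tau_b: np.ndarray
    rho_median: float = field(init=False)
    sigma_median: float = field(init=False)
    tau_median: float = field(init=False)
    rho_interval: tuple[float, float] = field(init=False)
    sigma_interval: tuple[float, float] = field(init=False)
    tau_interval: tuple[float, float] = field(init=False)
    n_infinite: int = field(init=False)
    infinite_flagged: bool = field(init=False)
    ellipse_mean: np.ndarray = field(init=False)
    ellipse_cov: np.ndarray = field(init=False)
    confidence_level: float = 0.95

    def __post_init__(self) -> None:
        B = self.n_bootstrap
        a = (1.0 - self.confidence_level) / 2.0
        self.rho_median = float(np.median(self.rho_b))
        self.sigma_median = float(np.median(self.sigma_b))
        finite = np.isfinite(self.tau_b)
        self.n_infinite = int(B - finite.sum())
        self.infinite_flagged = self.n_infinite >= 0.05 * B
        # few infinities: drop from the median (robust); many: keep and flag
        tau_for_median = self.tau_b[finite] if (
            not self.infinite_flagged and finite.any()) else self.tau_b
        self.tau_median = float(_inf_safe_quantile(tau_for_median, 0.5))
        self.rho_interval = tuple(np.quantile(self.rho_b, [a, 1 - a]))
        self.sigma_interval = tuple(np.quantile(self.sigma_b, [a, 1 - a]))
        self.tau_interval = tuple(
            _inf_safe_quantile(self.tau_b, [a, 1 - a]))
        pts = np.column_stack([self.rho_b, self.sigma_b])
        self.ellipse_mean = pts.mean(axis=0)
        self.ellipse_cov = np.cov(pts, rowvar=False) if B > 1 \
            else np.zeros((2, 2))

    def ellipse_radius2(self) -> float:
        """Squared Mahalanobis radius of the normal-approximation
        confidence ellipse: the chi-square (2 dof) quantile."""
        return float(_sps.chi2.ppf(self.confidence_level, df=2))


def _inf_safe_quantile(a: np.ndarray, q) -> np.ndarray:
    """np.quantile that treats interpolation between infinite order
    statistics as infinite instead of nan."""
    with np.errstate(invalid="ignore"):
        r = np.asarray(np.quantile(a, q))
    if np.isinf(a).any():
        r = np.where(np.isnan(r), np.inf, r)
    return r


def haversine_distance(lat1, lon1, lat2, lon2) -> np.ndarray | float:
    """Great-circle distance on the unit sphere (radians), haversine form.

    Accepts scalars or broadcastable arrays of coordinates in degrees.
    """
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(lon2) - np.radians(lon1)
    h = np.sin(dphi / 2.0) ** 2 + \
        np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
    return 2.0 * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def _pairwise_haversine(lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
    return haversine_distance(lat[:, None], lon[:, None],
                              lat[None, :], lon[None, :])


def _knn_from_dist(D: np.ndarray, k: int, fast: bool = False) -> np.ndarray:
    """Indices of the k nearest columns per row, self excluded by index,
    ties broken by ascending index (stable sort).

    With ``fast=True`` the k nearest are selected by argpartition before
    the stable ordering; selection ties exactly at the k-th distance are
    then resolved arbitrarily (but deterministically) instead of by
    index.  Used inside bootstrap replicates, where boundary ties occur
    only between duplicated draws of the same point and cannot change
    the disagreement statistic.
    """
    D = D.copy()
    np.fill_diagonal(D, np.inf)
    if fast:
        part = np.argpartition(D, k, axis=1)[:, :k]
        rows = np.arange(D.shape[0])[:, None]
        sub = D[rows, part]
        inner = np.lexsort((part, sub), axis=1)
        return part[rows, inner]
    # stable argsort => equal distances keep ascending original index
    order = np.argsort(D, axis=1, kind="stable")
    return order[:, :k]


def knn_neighbors(sample: FeatureSample, k: int) -> np.ndarray:
    """(n, k) index array of each point's k nearest neighbors.

    Neighbors are the k geographically closest *other* points (self
    excluded by index, so coordinate duplicates are legitimate
    zero-distance neighbors), sorted by (distance, index).
    """
    n = len(sample)
    if n <= k:
        raise InsufficientSampleError(
            f"need more than k={k} points, got {n}")
    D = _pairwise_haversine(sample.latitudes, sample.longitudes)
    return _knn_from_dist(D, k)


def _grid_neighbor_values(sample: FeatureSample) -> np.ndarray:
    """(n, 4) von Neumann neighbor values from the periodic grid metadata."""
    if sample.grid_shape is None or sample.grid_index is None:
        raise ValueError("sample carries no grid metadata; use k-NN mode")
    rows_, cols_ = sample.grid_shape
    if len(sample) != rows_ * cols_:
        raise ValueError("grid bond mode requires full sampling (n = L^2)")
    field_flat = np.empty(rows_ * cols_, dtype=np.int8)
    field_flat[np.asarray(sample.grid_index)] = sample.values
    grid = field_flat.reshape(rows_, cols_)
    r, c = np.divmod(np.asarray(sample.grid_index), cols_)
    return np.stack([
        grid[(r + 1) % rows_, c], grid[(r - 1) % rows_, c],
        grid[r, (c + 1) % cols_], grid[r, (c - 1) % cols_],
    ], axis=1)


def empirical_frequency(sample: FeatureSample) -> float:
    """Fraction of languages attesting the feature."""
    if len(sample) == 0:
        raise ValueError("empty sample")
    return float(sample.values.mean())


def empirical_isogloss_density(sample: FeatureSample, k: int = 10,
                               neighbor_mode: str = "knn") -> float:
    """Fraction of disagreeing directed (focal, neighbor) pairs.

    Every focal language contributes exactly k pairs (its k nearest
    neighbors), so mutual pairs may count twice; the statistic is
    invariant under global complementation and input-order permutation.
    ``neighbor_mode="grid"`` uses the four periodic von Neumann bonds of
    a fully sampled lattice instead (k is ignored), reproducing the
    lattice bond density exactly.
    """
    if neighbor_mode == "grid":
        nb_values = _grid_neighbor_values(sample)
        return float((sample.values[:, None] != nb_values).mean())
    if neighbor_mode != "knn":
        raise ValueError(f"unknown neighbor_mode {neighbor_mode!r}")
    s = sample.canonical()
    nb = knn_neighbors(s, k)
    return float((s.values[:, None] != s.values[nb]).mean())


def point_estimate(sample: FeatureSample, k: int = 10,
                   neighbor_mode: str = "knn"):
    """(rho, sigma, tau) point estimates for one sample."""
    rho = empirical_frequency(sample)
    sigma = empirical_isogloss_density(sample, k, neighbor_mode)
    tau = 0.0 if sigma == 0.0 else theory.temperature_from_stats(rho, sigma)
    return rho, sigma, tau


def bootstrap_temperature(sample: FeatureSample,
                          config: EstimatorConfig = EstimatorConfig(),
                          neighbor_mode: str = "knn") -> BootstrapSummary:
    """Nonparametric bootstrap of (rho, sigma, tau) for one feature.

    Each replicate resamples the n points with replacement; duplicated
    draws are distinct points (zero distances permitted, self-pairing
    excluded by replicate index) and neighborhoods are recomputed within
    the replicate.  In grid-bond mode the focal cells are resampled while
    each keeps its von Neumann neighbor values from the full field (the
    grid adjacency is a property of the field, not of the resample).

    Replicates with sigma >= 2 rho (1-rho) have infinite temperature;
    they are kept in the replicate arrays (rank statistics see +inf) and
    excluded from the median only when they make up fewer than 5% of
    replicates, otherwise the summary is flagged.
    """
    k = config.k_neighbors
    n = len(sample)
    if neighbor_mode == "knn" and n <= k:
        raise InsufficientSampleError(
            f"need more than k={k} points, got {n}")
    s = sample.canonical()
    rng = np.random.default_rng(config.seed)
    B = config.n_bootstrap

    if neighbor_mode == "grid":
        nb_values = _grid_neighbor_values(s)
        disagree = (s.values[:, None] != nb_values).mean(axis=1)
        D = None
    else:
        D = _pairwise_haversine(s.latitudes, s.longitudes)

    rho_b = np.empty(B)
    sigma_b = np.empty(B)
    tau_b = np.empty(B)
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        vals = s.values[idx]
        rho = float(vals.mean())
        if neighbor_mode == "grid":
            sigma = float(disagree[idx].mean())
        else:
            nb = _knn_from_dist(D[np.ix_(idx, idx)], k, fast=True)
            sigma = float((vals[:, None] != vals[nb]).mean())
        rho_b[b] = rho
        sigma_b[b] = sigma
        if sigma == 0.0:
            tau_b[b] = 0.0
        else:
            tau_b[b] = theory.temperature_from_stats(rho, sigma)
    return BootstrapSummary(
        feature_id=s.feature_id, n=n, n_bootstrap=B,
        rho_b=rho_b, sigma_b=sigma_b, tau_b=tau_b,
        confidence_level=config.confidence_level)


def hemisphere_split_test(samples: list[FeatureSample],
                          config: EstimatorConfig = EstimatorConfig(),
                          boundary_west: float = -180.0,
                          boundary_east: float = -30.0):
    """Two-hemispheres robustness test.

    Each feature's temperature is estimated independently on the Western
    subset (longitude in [boundary_west, boundary_east)) and the Eastern
    subset (the remainder); the two temperature vectors are compared by
    Spearman rank correlation.  Features whose subsets do not exceed
    k_neighbors in size are dropped and reported.

    Returns
    -------
    (result, dropped) where result is a dict with keys ``feature_ids``,
    ``tau_west``, ``tau_east``, ``spearman_r``, ``p_value`` and dropped is
    the list of feature ids that failed the size precondition.
    """
    feature_ids, tau_w, tau_e, dropped = [], [], [], []
    for sample in samples:
        in_west = (sample.longitudes >= boundary_west) & \
            (sample.longitudes < boundary_east)
        west, east = sample.take(np.flatnonzero(in_west)), \
            sample.take(np.flatnonzero(~in_west))
        if len(west) <= config.k_neighbors or len(east) <= config.k_neighbors:
            dropped.append(sample.feature_id)
            continue
        _, _, tw = point_estimate(west, config.k_neighbors)
        _, _, te = point_estimate(east, config.k_neighbors)
        feature_ids.append(sample.feature_id)
        tau_w.append(tw)
        tau_e.append(te)
    if not feature_ids:
        raise InsufficientSampleError(
            "no feature has enough languages in both hemispheres")
    if len(feature_ids) < 2:
        raise ValueError("rank correlation undefined for a single feature")
    r, p = _sps.spearmanr(tau_w, tau_e)
    return {
        "feature_ids": feature_ids,
        "tau_west": np.array(tau_w),
        "tau_east": np.array(tau_e),
        "spearman_r": float(r),
        "p_value": float(p),
    }, dropped
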