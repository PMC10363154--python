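"""Geometric scaffolding: coordinate scaling, grid points, bandwidth, density.

The reference density of samples in the input space is evaluated at g grid
points. Grid points are placed with k-means on the sample coordinates (the
centroids tend to spread roughly uniformly over the occupied subspace), by
the k-means++ seeding rule alone, or supplied by the user. A Gaussian kernel
with bandwidth h — the median distance from a sample to its nearest grid
point — converts sample-to-grid distances into density contributions.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans, kmeans_plusplus

from .types import GridModel, HaystackError, SampleSpace

logger = logging.getLogger(__name__)

DEFAULT_GRID_POINTS = 100


def scale_coordinates(coords: np.ndarray) -> np.ndarray:
    """Rescale each dimension to mean 0 and standard deviation 1.

    Uses the sample standard deviation (n-1 denominator). Zero-variance
    columns are centered and left at 0 (with a warning) so column indices
    stay stable.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 1:
        coords = coords[:, None]
    if coords.shape[0] < 2:
        raise HaystackError("scaling needs at least 2 samples")
    if not np.all(np.isfinite(coords)):
        raise HaystackError("coordinates contain missing/non-finite values")
    centered = coords - coords.mean(axis=0)
    sd = coords.std(axis=0, ddof=1)
    degenerate = sd == 0
    if degenerate.any():
        logger.warning(
            "%d coordinate column(s) have zero variance; kept as zeros",
            int(degenerate.sum()),
        )
    sd = np.where(degenerate, 1.0, sd)
    return centered / sd


def scale_space(space: SampleSpace) -> SampleSpace:
    """Return a standardized copy of ``space`` (no-op if already scaled)."""
    if space.scaled:
        return space
    return SampleSpace(
        coords=scale_coordinates(space.coords),
        sample_ids=space.sample_ids,
        scaled=True,
        group=space.group,
    )


def select_grid_points(
    space: SampleSpace | np.ndarray,
    g: int = DEFAULT_GRID_POINTS,
    method: str = "kmeans",
    user_coords: np.ndarray | None = None,
    seed: int = 42,
) -> np.ndarray:
    """Choose g grid points in the sample coordinate space.

    method="kmeans" runs a single seeded k-means (Lloyd, capped at 100
    iterations) and returns the centroids; "seeding" applies only the
    k-means++ seeding rule; "user" passes ``user_coords`` through after a
    dimensionality check. If g exceeds the number of samples it is clamped
    to n with a warning.
    """
    coords = space.coords if isinstance(space, SampleSpace) else np.asarray(space, float)
    n, d = coords.shape
    if method == "user":
        if user_coords is None:
            raise HaystackError("method='user' requires user_coords")
        user_coords = np.atleast_2d(np.asarray(user_coords, dtype=float))
        if user_coords.shape[1] != d:
            raise HaystackError(
                f"user grid has {user_coords.shape[1]} columns, expected {d}"
            )
        return user_coords
    if g < 2:
        raise HaystackError("g must be at least 2")
    if g > n:
        logger.warning("g=%d exceeds n=%d samples; clamping to n", g, n)
        g = n
    if method == "kmeans":
        km = KMeans(n_clusters=g, n_init=1, max_iter=100, random_state=seed)
        km.fit(coords)
        return km.cluster_centers_.astype(float)
    if method == "seeding":
        centers, _ = kmeans_plusplus(coords, n_clusters=g, random_state=seed)
        return centers.astype(float)
    raise HaystackError(f"unknown grid method {method!r}")


def compute_bandwidth(coords: np.ndarray, grid_coords: np.ndarray) -> float:
    """Median Euclidean distance from each sample to its nearest grid point."""
    dists, _ = cKDTree(grid_coords).query(coords, k=1)
    h = float(np.median(dists))
    if h == 0:
        raise HaystackError(
            "degenerate geometry: median nearest-grid distance is 0 "
            "(most samples coincide with grid points); reduce the number of "
            "grid points or perturb the grid coordinates"
        )
    return h


def compute_density(
    coords: np.ndarray, grid_coords: np.ndarray, h: float
) -> np.ndarray:
    """Gaussian-kernel density contribution of every sample to every grid point.

    ``d[i, j] = exp(-(||s_i - grid_j|| / h)^2 / 2)``; entries lie in (0, 1],
    equal to 1 exactly when a sample sits on a grid point.
    """
    if not h > 0:
        raise HaystackError("bandwidth must be positive")
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    grid_coords = np.atleast_2d(np.asarray(grid_coords, dtype=float))
    if not (np.all(np.isfinite(coords)) and np.all(np.isfinite(grid_coords))):
        raise HaystackError("non-finite coordinates")
    sq = cdist(coords, grid_coords, metric="sqeuclidean")
    return np.exp(-sq / (2.0 * h * h))


def build_grid_model(
    space: SampleSpace,
    g: int = DEFAULT_GRID_POINTS,
    method: str = "kmeans",
    user_coords: np.ndarray | None = None,
    seed: int = 42,
) -> GridModel:
    """Grid points + bandwidth + density + reference distribution in one call."""
    from .kld import compute_Q  # local import avoids a module cycle

    grid = select_grid_points(space, g=g, method=method, user_coords=user_coords, seed=seed)
    h = compute_bandwidth(space.coords, grid)
    density = compute_density(space.coords, grid, h)
    return GridModel(grid_coords=grid, bandwidth_h=h, density=density, Q=compute_Q(density))
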