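"""Synthetic coordinate spaces and activity matrices with known ground truth.

The generator emulates the three kinds of input space the method is used on
— clustered latent embeddings (Gaussian blobs), spatial layouts (uniform
hypercube) and 1D pseudotime trajectories — together with a mixture of
planted differentially active features (a Gaussian bump of activity around a
location in the space, on top of a baseline) and null features whose
activity has the same marginal distribution but is independent of position.
Null features are exchangeable across samples by construction, which is
what makes them usable for p-value calibration checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse

from .types import ActivityMatrix, HaystackError, SampleSpace

# Default planted-effect regime: Poisson (UMI-like) noise on a baseline rate
# of 0.5 with bumps of amplitude 2 and width 1 coordinate unit.
DEFAULT_BASELINE = 0.5
DEFAULT_AMPLITUDE = 2.0
DEFAULT_WIDTH = 1.0
DEFAULT_LOGNORMAL_SIGMA = 0.4


@dataclass
class SyntheticDataset:
    """A generated space + activity matrix with per-feature truth labels."""

    space: SampleSpace
    activity: ActivityMatrix
    truth: pd.DataFrame  # index feature_id; columns label, center_*, width, amplitude
    seed: int

    @property
    def planted_mask(self) -> np.ndarray:
        return (self.truth["label"] == "planted").to_numpy()


def make_coords(
    n: int,
    d: int,
    structure: str = "blobs",
    n_blobs: int = 5,
    seed: int = 42,
) -> SampleSpace:
    """Generate n sample coordinates in d dimensions.

    structure="blobs" draws a Gaussian mixture (blob sd 0.5, centers kept at
    least 3 units apart inside [-5, 5]^d, so blobs are well separated);
    "uniform" fills the unit hypercube; "trajectory" produces sorted 1D
    pseudotime values in [0, 1] and requires d = 1. Blob membership is
    recorded in ``SampleSpace.group``.
    """
    if n < 10:
        raise HaystackError("need at least 10 samples")
    rng = np.random.default_rng(seed)
    ids = np.array([f"sample_{i}" for i in range(n)])
    if structure == "trajectory":
        if d != 1:
            raise HaystackError("trajectory structure requires d = 1")
        t = np.sort(rng.uniform(0.0, 1.0, size=n))
        return SampleSpace(coords=t[:, None], sample_ids=ids)
    if structure == "uniform":
        return SampleSpace(coords=rng.uniform(0.0, 1.0, size=(n, d)), sample_ids=ids)
    if structure == "blobs":
        centers = _separated_centers(rng, n_blobs, d, low=-5.0, high=5.0, min_dist=3.0)
        labels = rng.integers(0, n_blobs, size=n)
        coords = centers[labels] + rng.normal(0.0, 0.5, size=(n, d))
        return SampleSpace(coords=coords, sample_ids=ids, group=labels)
    raise HaystackError(f"unknown structure {structure!r}")


def _separated_centers(rng, k, d, low, high, min_dist, max_tries=10_000):
    centers = [rng.uniform(low, high, size=d)]
    tries = 0
    while len(centers) < k:
        c = rng.uniform(low, high, size=d)
        if all(np.linalg.norm(c - o) >= min_dist for o in centers):
            centers.append(c)
        tries += 1
        if tries > max_tries:  # crowded space: accept best effort
            centers.append(c)
    return np.array(centers)


def make_activity(
    space: SampleSpace,
    n_planted: int = 100,
    n_null: int = 1900,
    amplitude: float = DEFAULT_AMPLITUDE,
    width: float = DEFAULT_WIDTH,
    baseline: float = DEFAULT_BASELINE,
    noise: str = "poisson",
    seed: int = 42,
) -> SyntheticDataset:
    """Generate planted + null features over the given space.

    Planted features follow rate = baseline + amplitude * exp(-||s - c||^2 /
    (2 width^2)) with the chosen noise, centers c drawn from the sample
    coordinates themselves (so effects never land in empty space). Null
    features are built from the same recipe and then permuted across
    samples, giving the identical marginal level distribution with no
    positional association. Output is sparse (CSR).
    """
    if amplitude < 0 or width <= 0:
        raise HaystackError("amplitude must be >= 0 and width > 0")
    rng = np.random.default_rng(seed)
    coords = space.coords
    n = space.n
    f = n_planted + n_null
    rows = np.empty((f, n))
    records = []
    for i in range(f):
        planted = i < n_planted
        center = coords[rng.integers(0, n)]
        sq = np.sum((coords - center) ** 2, axis=1)
        rate = baseline + amplitude * np.exp(-sq / (2.0 * width**2))
        if not planted:
            rate = rng.permutation(rate)
        if noise == "poisson":
            y = rng.poisson(rate).astype(float)
        elif noise == "lognormal":
            y = rate * rng.lognormal(0.0, DEFAULT_LOGNORMAL_SIGMA, size=n)
        else:
            raise HaystackError(f"unknown noise model {noise!r}")
        rows[i] = y
        records.append(
            {
                "label": "planted" if planted else "null",
                **{f"center_{k}": center[k] for k in range(space.d)},
                "width": width,
                "amplitude": amplitude,
            }
        )
    feature_ids = np.array(
        [f"planted_{i}" for i in range(n_planted)]
        + [f"null_{i}" for i in range(n_null)]
    )
    truth = pd.DataFrame(records, index=pd.Index(feature_ids, name="feature_id"))
    activity = ActivityMatrix(
        values=sparse.csr_matrix(rows),
        feature_ids=feature_ids,
        sample_ids=space.sample_ids,
    )
    return SyntheticDataset(space=space, activity=activity, truth=truth, seed=seed)


def make_trajectory_patterns(
    space: SampleSpace,
    n_patterns: int = 3,
    features_per_pattern: int = 20,
    n_null: int = 200,
    amplitude: float = 4.0,
    width: float = 0.08,
    baseline: float = DEFAULT_BASELINE,
    seed: int = 42,
) -> tuple[SyntheticDataset, np.ndarray]:
    """Planted features grouped into a few shared pseudotime-localized patterns.

    All features of a pattern share one bump center (centers evenly spaced
    along the trajectory), so module clustering has a known ground truth.
    Returns the dataset and the per-feature pattern labels (-1 for null).
    """
    if space.d != 1:
        raise HaystackError("trajectory patterns require a 1D space")
    rng = np.random.default_rng(seed)
    t = space.coords[:, 0]
    centers = np.quantile(t, np.linspace(0.1, 0.9, n_patterns))
    n = space.n
    f = n_patterns * features_per_pattern + n_null
    rows = np.empty((f, n))
    labels = np.full(f, -1)
    records = []
    i = 0
    for p in range(n_patterns):
        for _ in range(features_per_pattern):
            rate = baseline + amplitude * np.exp(
                -((t - centers[p]) ** 2) / (2.0 * width**2)
            )
            rows[i] = rng.poisson(rate).astype(float)
            labels[i] = p
            records.append(
                {"label": "planted", "center_0": centers[p], "width": width,
                 "amplitude": amplitude}
            )
            i += 1
    for _ in range(n_null):
        center = t[rng.integers(0, n)]
        rate = baseline + amplitude * np.exp(-((t - center) ** 2) / (2.0 * width**2))
        rows[i] = rng.poisson(rng.permutation(rate)).astype(float)
        records.append(
            {"label": "null", "center_0": center, "width": width,
             "amplitude": amplitude}
        )
        i += 1
    feature_ids = np.array(
        [f"pattern{labels[i]}_{i}" if labels[i] >= 0 else f"null_{i}" for i in range(f)]
    )
    truth = pd.DataFrame(records, index=pd.Index(feature_ids, name="feature_id"))
    activity = ActivityMatrix(
        values=sparse.csr_matrix(rows),
        feature_ids=feature_ids,
        sample_ids=space.sample_ids,
    )
    return SyntheticDataset(space=space, activity=activity, truth=truth, seed=seed), labels
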