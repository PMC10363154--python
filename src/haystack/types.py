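"""Core in-memory containers shared across the pipeline.

The method operates on two aligned objects: a :class:`SampleSpace` holding the
coordinates of samples (cells, spots, pucks, bulk samples) in a d-dimensional
input space, and an :class:`ActivityMatrix` holding non-negative feature
activities (expression, accessibility, module scores) for those same samples.
The geometric scaffolding derived from the coordinates lives in a
:class:`GridModel`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse


class HaystackError(ValueError):
    """Base class for invalid-input and degenerate-geometry errors."""


@dataclass
class SampleSpace:
    """n samples embedded in a d-dimensional input space.

    Parameters
    ----------
    coords
        ``(n, d)`` float array; one row per sample. Dimensions may be
        pseudotime (d=1), tissue x/y(/z), or latent-space components.
    sample_ids
        Length-n identifiers, unique.
    scaled
        True once every non-degenerate column has been standardized to
        mean 0 / sd 1.
    group
        Optional generator-truth group label per sample (synthetic data only).
    """

    coords: np.ndarray
    sample_ids: np.ndarray
    scaled: bool = False
    group: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim == 1:
            self.coords = self.coords[:, None]
        self.sample_ids = np.asarray(self.sample_ids)
        if self.coords.shape[0] != self.sample_ids.shape[0]:
            raise HaystackError(
                f"coords have {self.coords.shape[0]} rows but "
                f"{self.sample_ids.shape[0]} sample ids were given"
            )
        if self.coords.shape[0] < 2:
            raise HaystackError("at least 2 samples are required")
        if not np.all(np.isfinite(self.coords)):
            raise HaystackError("coordinates contain missing/non-finite values")

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    @property
    def d(self) -> int:
        return self.coords.shape[1]


@dataclass
class ActivityMatrix:
    """features x samples non-negative activity values, sparse-capable."""

    values: sparse.spmatrix | np.ndarray
    feature_ids: np.ndarray
    sample_ids: np.ndarray

    def __post_init__(self) -> None:
        if sparse.issparse(self.values):
            self.values = self.values.tocsr()
            data = self.values.data
        else:
            self.values = np.asarray(self.values, dtype=float)
            data = self.values
        self.feature_ids = np.asarray(self.feature_ids)
        self.sample_ids = np.asarray(self.sample_ids)
        f, n = self.values.shape
        if f != len(self.feature_ids):
            raise HaystackError(
                f"matrix has {f} rows but {len(self.feature_ids)} feature ids"
            )
        if n != len(self.sample_ids):
            raise HaystackError(
                f"matrix has {n} columns but {len(self.sample_ids)} sample ids"
            )
        if data.size and not np.all(np.isfinite(data)):
            raise HaystackError("activity matrix contains non-finite values")
        if data.size and data.min() < 0:
            raise HaystackError(
                "activity values must be non-negative "
                "(use rescale_activity to min-max rescale signed inputs)"
            )

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def dense(self) -> np.ndarray:
        if sparse.issparse(self.values):
            return np.asarray(self.values.todense())
        return self.values

    def all_zero_mask(self) -> np.ndarray:
        """Boolean mask of features whose activity is zero in every sample."""
        if sparse.issparse(self.values):
            sums = np.asarray(self.values.sum(axis=1)).ravel()
            maxs = np.asarray(abs(self.values).sum(axis=1)).ravel()
            return (sums == 0) & (maxs == 0)
        return np.all(self.values == 0, axis=1)


@dataclass
class GridModel:
    """Grid points, kernel bandwidth and sample-to-grid density contributions.

    ``density[i, j] = exp(-(||s_i - grid_j|| / h)^2 / 2)`` and ``Q`` is the
    column-sum of ``density`` normalized to a probability vector — the
    reference distribution of samples over grid points.
    """

    grid_coords: np.ndarray
    bandwidth_h: float
    density: np.ndarray
    Q: np.ndarray

    def __post_init__(self) -> None:
        if self.grid_coords.shape[0] < 2:
            raise HaystackError("a grid needs at least 2 points")
        if not self.bandwidth_h > 0:
            raise HaystackError("bandwidth must be positive")

    @property
    def g(self) -> int:
        return self.grid_coords.shape[0]


@dataclass
class NullModel:
    """Permutation-null statistics and fitted spline calibration curves.

    For each of m reference features (chosen to span the CV range) the model
    stores the mean and sd of log D_KL under random permutation of the
    feature's activity across samples, plus two cross-validation-selected
    spline fits predicting those moments from log CV.
    """

    ref_feature_ids: np.ndarray
    ref_logCV: np.ndarray
    ref_mean_logDKL: np.ndarray
    ref_sd_logDKL: np.ndarray
    spline_type: str
    df_mean: int
    df_sd: int
    mean_curve: object  # callable logCV -> predicted mean of log DKL_random
    sd_curve: object  # callable logCV -> predicted sd (floored)
    n_permutations: int
    rng_seed: int
    degree_mean: int = 3
    degree_sd: int = 3

    @property
    def logcv_span(self) -> tuple[float, float]:
        return float(self.ref_logCV.min()), float(self.ref_logCV.max())


@dataclass
class HaystackResult:
    """Per-feature divergence, log10 p-values, rank and QC flag.

    ``table`` is indexed by feature id with columns ``D_KL``, ``log10_pval``,
    ``log10_pval_adj``, ``rank`` and ``flag`` (``ok`` | ``all_zero`` |
    ``zero_cv``). Ranks are 1..k over ok-flagged features (1 = most
    significant); flagged features carry NaN rank.
    """

    table: pd.DataFrame
    info: dict = field(default_factory=dict)

    def top(self, n: int = 10) -> pd.DataFrame:
        ok = self.table[self.table["flag"] == "ok"]
        return ok.sort_values("rank").head(n)

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        order = out["rank"].to_numpy(copy=True)
        order[np.isnan(order)] = np.inf
        out = out.iloc[np.argsort(order, kind="stable")]
        out.to_csv(path, sep="\t", index_label="feature_id", float_format="%.6g")
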