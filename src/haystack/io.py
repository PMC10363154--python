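"""Readers/writers, run configuration and the end-to-end pipeline driver.

Coordinates come as TSV/CSV (header required, first column sample id).
Activity matrices come as Matrix Market files with features/barcodes
sidecars (10x convention; orientation auto-detected by matching the sample
count) or as dense TSV/CSV with feature ids in the first column. An h5ad
adapter is provided as a convenience. Samples are aligned between the two
inputs by id intersection in coordinate-file order.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import io as scipy_io
from scipy import sparse

from . import coords_grid, kld, significance
from .types import ActivityMatrix, HaystackError, HaystackResult, SampleSpace

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All knobs of an end-to-end run; round-trips losslessly through YAML."""

    coords_path: str | None = None
    activity_path: str | None = None
    features_path: str | None = None
    barcodes_path: str | None = None
    output_path: str | None = None
    g: int = 100
    grid_method: str = "kmeans"
    scale_coords: bool = True
    spline_type: str = "ns"
    m_reference: int = 100
    n_permutations: int = 100
    seed: int = 42
    rescale_activity: bool = False
    verbosity: int = 1

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def _sep_for(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_coords(path) -> SampleSpace:
    """Read a coordinate table: header, first column sample id, numeric rest."""
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    coords = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(coords)):
        raise HaystackError(f"{path}: non-numeric or missing coordinate values")
    return SampleSpace(coords=coords, sample_ids=df.index.to_numpy().astype(str))


def read_activity(
    path,
    features_path=None,
    barcodes_path=None,
    n_samples_hint: int | None = None,
    rescale: bool = False,
) -> ActivityMatrix:
    """Read an activity matrix (MTX + sidecars, or dense TSV/CSV).

    For MTX, orientation is auto-detected: if the row count matches the
    barcode/sample count (and the column count does not), the matrix is
    transposed to features x samples. With ``rescale`` each feature is
    min-max rescaled to [0, 1], which is also the only way to admit signed
    inputs (e.g. module scores); negative values without the flag error.
    """
    path = str(path)
    if path.endswith(".mtx") or path.endswith(".mtx.gz"):
        if features_path is None or barcodes_path is None:
            base = Path(path).parent
            features_path = features_path or base / "features.tsv"
            barcodes_path = barcodes_path or base / "barcodes.tsv"
        mat = sparse.csr_matrix(scipy_io.mmread(path))
        features = pd.read_csv(features_path, sep="\t", header=None)[0].to_numpy(str)
        barcodes = pd.read_csv(barcodes_path, sep="\t", header=None)[0].to_numpy(str)
        nf, nb = len(features), len(barcodes)
        if mat.shape == (nf, nb):
            pass
        elif mat.shape == (nb, nf):
            mat = mat.T.tocsr()
        else:
            raise HaystackError(
                f"matrix shape {mat.shape} matches neither "
                f"(features={nf}, samples={nb}) nor its transpose"
            )
        if rescale:
            mat = _minmax_rows(np.asarray(mat.todense()))
        return ActivityMatrix(values=mat, feature_ids=features, sample_ids=barcodes)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    values = df.to_numpy(dtype=float)
    sample_ids = df.columns.to_numpy().astype(str)
    feature_ids = df.index.to_numpy().astype(str)
    if n_samples_hint is not None and values.shape[0] == n_samples_hint != values.shape[1]:
        values, sample_ids, feature_ids = values.T, feature_ids, sample_ids
    if rescale:
        values = _minmax_rows(values)
    return ActivityMatrix(
        values=values, feature_ids=feature_ids, sample_ids=sample_ids
    )


def read_h5ad(path, layer: str | None = None, obsm: str | None = None):
    """Convenience adapter: (SampleSpace | None, ActivityMatrix) from h5ad.

    The space is taken from ``obsm`` if given (e.g. "X_pca"); activity from
    ``layer`` or X, transposed to features x samples.
    """
    import anndata

    adata = anndata.read_h5ad(path)
    x = adata.layers[layer] if layer else adata.X
    if sparse.issparse(x):
        x = x.T.tocsr()
    else:
        x = np.asarray(x).T
    activity = ActivityMatrix(
        values=x,
        feature_ids=adata.var_names.to_numpy().astype(str),
        sample_ids=adata.obs_names.to_numpy().astype(str),
    )
    space = None
    if obsm is not None:
        space = SampleSpace(
            coords=np.asarray(adata.obsm[obsm], dtype=float),
            sample_ids=adata.obs_names.to_numpy().astype(str),
        )
    return space, activity


def _minmax_rows(values: np.ndarray) -> np.ndarray:
    lo = values.min(axis=1, keepdims=True)
    hi = values.max(axis=1, keepdims=True)
    span = hi - lo
    span[span == 0] = 1.0
    return (values - lo) / span


def rescale_features(activity: ActivityMatrix) -> ActivityMatrix:
    """Min-max rescale each feature to [0, 1] (densifies)."""
    return ActivityMatrix(
        values=_minmax_rows(activity.dense().copy()),
        feature_ids=activity.feature_ids,
        sample_ids=activity.sample_ids,
    )


def align_samples(
    space: SampleSpace, activity: ActivityMatrix
) -> tuple[SampleSpace, ActivityMatrix]:
    """Align the two inputs on the intersection of sample ids.

    Order follows the coordinate table; samples present on only one side
    are dropped with a warning; an empty intersection is an error.
    """
    act_pos = {str(s): i for i, s in enumerate(activity.sample_ids)}
    keep_space, keep_act = [], []
    for i, sid in enumerate(space.sample_ids):
        j = act_pos.get(str(sid))
        if j is not None:
            keep_space.append(i)
            keep_act.append(j)
    if not keep_space:
        raise HaystackError("no sample ids are shared between coordinates and matrix")
    dropped = (space.n - len(keep_space)) + (activity.n_samples - len(keep_act))
    if dropped:
        logger.warning("dropped %d unmatched sample(s) during alignment", dropped)
    new_space = SampleSpace(
        coords=space.coords[keep_space],
        sample_ids=space.sample_ids[keep_space],
        scaled=space.scaled,
        group=None if space.group is None else space.group[keep_space],
    )
    values = activity.values[:, keep_act]
    new_act = ActivityMatrix(
        values=values,
        feature_ids=activity.feature_ids,
        sample_ids=activity.sample_ids[keep_act],
    )
    return new_space, new_act


def read_inputs(config: RunConfig) -> tuple[SampleSpace, ActivityMatrix]:
    """Read and align the coordinate and activity inputs of a run."""
    space = read_coords(config.coords_path)
    activity = read_activity(
        config.activity_path,
        features_path=config.features_path,
        barcodes_path=config.barcodes_path,
        n_samples_hint=space.n,
        rescale=config.rescale_activity,
    )
    return align_samples(space, activity)


def run_haystack(
    config: RunConfig,
    space: SampleSpace | None = None,
    activity: ActivityMatrix | None = None,
) -> HaystackResult:
    """Execute the full pipeline: scale -> grid -> density -> D_KL -> p-values.

    Inputs may be passed in memory; otherwise they are read from the paths
    in ``config``. Writes the result TSV and a YAML run log (seed, g, h,
    selected spline df, flag counts) when ``config.output_path`` is set.
    """
    if space is None or activity is None:
        space, activity = read_inputs(config)
    elif config.rescale_activity:
        activity = rescale_features(activity)
    if config.scale_coords:
        space = coords_grid.scale_space(space)
    grid = coords_grid.build_grid_model(
        space, g=config.g, method=config.grid_method, seed=config.seed
    )
    dkl, _ = kld.compute_all_DKL(grid.density, activity)
    cv = significance.compute_cv(activity)
    model = significance.build_null_model(
        grid.density,
        activity,
        cv=cv,
        m=config.m_reference,
        n_perm=config.n_permutations,
        spline_type=config.spline_type,
        seed=config.seed,
    )
    result = significance.predict_pvalues(
        model, cv, dkl, feature_ids=activity.feature_ids
    )
    result.info.update(
        {
            "seed": config.seed,
            "g": grid.g,
            "bandwidth_h": float(grid.bandwidth_h),
            "n_samples": space.n,
            "n_features": activity.n_features,
        }
    )
    if config.output_path:
        out = Path(config.output_path)
        out.parent.mkdir(parents=True, exist_ok=True)
        result.to_tsv(out)
        log_path = out.with_suffix(out.suffix + ".log.yaml")
        log_path.write_text(yaml.safe_dump(result.info, sort_keys=True))
    return result


def write_grid_tsv(grid_coords: np.ndarray, path) -> None:
    pd.DataFrame(
        grid_coords,
        columns=[f"dim_{i}" for i in range(grid_coords.shape[1])],
        index=pd.Index([f"grid_{j}" for j in range(grid_coords.shape[0])], name="grid_id"),
    ).to_csv(path, sep="\t")


def plot_grid_diagnostic(space: SampleSpace, grid, path) -> None:
    """Minimal diagnostic scatter: samples + grid points sized by Q (2D)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    coords = space.coords
    fig, ax = plt.subplots(figsize=(5, 5))
    if coords.shape[1] == 1:
        ax.scatter(coords[:, 0], np.zeros(space.n), s=4, alpha=0.3, label="samples")
        ax.scatter(grid.grid_coords[:, 0], np.zeros(grid.g),
                   s=2000 * grid.Q, c="red", label="grid (size ~ Q)")
    else:
        ax.scatter(coords[:, 0], coords[:, 1], s=4, alpha=0.3, label="samples")
        ax.scatter(grid.grid_coords[:, 0], grid.grid_coords[:, 1],
                   s=2000 * grid.Q, c="red", label="grid (size ~ Q)")
    ax.legend()
    fig.savefig(path, dpi=100)
    plt.close(fig)
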