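"""Downstream summarization: gene-set module scores and feature-module clustering.

Gene-set scores turn a collection of sets (e.g. pathways) into a sets x
samples activity matrix that can be fed straight back into the divergence
engine to find sets with non-random activity over the space. The score here
is deliberately simple — the mean of each member's max-normalized activity,
min-max rescaled to [0, 1] per set — and is NOT a reimplementation of
Seurat's AddModuleScore (no expression-bin-matched control genes).

Module clustering groups the top-ranked features by the similarity of their
grid-point activity distributions P_f, either with seeded k-means or with
hierarchical clustering on correlation distance (1 - Pearson) with average
linkage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans

from .types import ActivityMatrix, HaystackError, HaystackResult

logger = logging.getLogger(__name__)

DEFAULT_MIN_SET_SIZE = 10


@dataclass
class GeneSetCollection:
    """Named sets of feature ids with a minimum-size filter."""

    sets: dict[str, list[str]]
    min_size: int = DEFAULT_MIN_SET_SIZE

    @classmethod
    def from_gmt(cls, path, min_size: int = DEFAULT_MIN_SET_SIZE) -> "GeneSetCollection":
        """Read GMT: one set per line — id, description, member ids (tab-sep)."""
        sets: dict[str, list[str]] = {}
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3:
                    continue
                sets[parts[0]] = [g for g in parts[2:] if g]
        return cls(sets=sets, min_size=min_size)

    def filtered(self, feature_ids) -> dict[str, list[str]]:
        """Members restricted to the activity matrix; small sets dropped."""
        present = set(map(str, feature_ids))
        out = {}
        for name, members in self.sets.items():
            kept = [m for m in members if m in present]
            if len(kept) >= self.min_size:
                out[name] = kept
            else:
                logger.info(
                    "gene set %s dropped: %d members present (< %d)",
                    name, len(kept), self.min_size,
                )
        return out


@dataclass
class ModuleAssignment:
    """Module labels for the clustered top features."""

    feature_ids: np.ndarray
    labels: np.ndarray
    mean_profiles: np.ndarray  # modules x g mean activity distribution
    dendrogram_order: np.ndarray | None = None
    method: str = "kmeans"
    extras: dict = field(default_factory=dict)

    @property
    def n_modules(self) -> int:
        return len(np.unique(self.labels))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"module": self.labels}, index=pd.Index(self.feature_ids, name="feature_id")
        )


def gene_set_scores(
    activity: ActivityMatrix, sets: GeneSetCollection
) -> ActivityMatrix:
    """Per-sample score of each retained gene set, as a new activity matrix.

    Each member feature's activity is divided by its maximum (so strongly
    expressed members do not dominate), members are averaged, and the
    resulting per-set vector is min-max rescaled to [0, 1] — making the
    scores directly usable as engine input.
    """
    retained = sets.filtered(activity.feature_ids)
    if not retained:
        raise HaystackError("no gene set passes the minimum-size filter")
    index = {str(fid): i for i, fid in enumerate(activity.feature_ids)}
    scores = np.zeros((len(retained), activity.n_samples))
    names = []
    for row, (name, members) in enumerate(retained.items()):
        idx = [index[m] for m in members]
        block = activity.values[idx]
        if sparse.issparse(block):
            block = np.asarray(block.todense())
        maxs = block.max(axis=1)
        maxs[maxs == 0] = 1.0
        score = (block / maxs[:, None]).mean(axis=0)
        span = score.max() - score.min()
        scores[row] = (score - score.min()) / span if span > 0 else 0.0
        names.append(name)
    return ActivityMatrix(
        values=scores, feature_ids=np.array(names), sample_ids=activity.sample_ids
    )


def compute_Pf_matrix(density: np.ndarray, activity: ActivityMatrix) -> np.ndarray:
    """Row-normalized activity-weighted density for every feature (f x g)."""
    P = np.asarray(activity.values @ density)
    totals = P.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    return P / totals


def cluster_top_features(
    result: HaystackResult | pd.DataFrame,
    Pf_matrix: np.ndarray,
    method: str = "kmeans",
    k: int = 6,
    top_n: int = 1000,
    seed: int = 42,
) -> ModuleAssignment:
    """Cluster the top_n most significant features into k modules.

    ``Pf_matrix`` rows must align with the result table. Features are taken
    in rank order; their P_f profiles are clustered — k-means on
    standardized profiles (seeded), or hierarchical clustering on
    correlation distance with average linkage, which also yields a
    dendrogram leaf order. Per-module mean (unstandardized) profiles are
    returned for visualization along the grid / pseudotime axis.
    """
    table = result.table if isinstance(result, HaystackResult) else result
    ok = table[table["flag"] == "ok"]
    if top_n > len(ok):
        raise HaystackError(f"top_n={top_n} exceeds {len(ok)} ok-flagged features")
    if k > top_n:
        raise HaystackError("k cannot exceed top_n")
    top = ok.sort_values("rank").head(top_n)
    positions = table.index.get_indexer(top.index)
    profiles = np.asarray(Pf_matrix)[positions]

    sd = profiles.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    zprof = (profiles - profiles.mean(axis=1, keepdims=True)) / sd

    order = None
    if method == "kmeans":
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        labels = km.fit_predict(zprof)
    elif method == "hclust":
        dist = pdist(profiles, metric="correlation")
        Z = hierarchy.linkage(dist, method="average")
        labels = hierarchy.fcluster(Z, t=k, criterion="maxclust") - 1
        order = np.asarray(hierarchy.leaves_list(Z))
    else:
        raise HaystackError(f"unknown clustering method {method!r}")

    mean_profiles = np.vstack(
        [profiles[labels == lab].mean(axis=0) for lab in np.unique(labels)]
    )
    return ModuleAssignment(
        feature_ids=top.index.to_numpy(),
        labels=np.asarray(labels),
        mean_profiles=mean_profiles,
        dendrogram_order=order,
        method=method,
    )
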