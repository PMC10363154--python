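"""Significance of D_KL values via a CV-stratified permutation null.

Permuting a feature's activity across samples destroys any association with
position while preserving its marginal distribution, so permuted D_KL values
sample the null. Doing this for every feature is wasteful: the null
distribution of log D_KL_random depends on the feature essentially only
through its coefficient of variation (CV = sd / mean). The engine therefore

1. selects m reference features spread evenly over the (log) CV range,
2. permutes each n_perm times and records mean/sd of log D_KL_random
   (the log values are approximately normal),
3. fits two cross-validation-selected splines predicting these moments
   from log CV, and
4. converts every feature's observed ln D_KL into an upper-tail normal
   p-value using the predicted moments at its own log CV.

All p-values are handled on the log10 scale so that values far beyond
double-precision underflow (p ~ 1e-300 and below) remain representable.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import sparse, stats

from .kld import compute_Q
from .splines import fit_spline_cv
from .types import ActivityMatrix, HaystackError, HaystackResult, NullModel

logger = logging.getLogger(__name__)

DEFAULT_REF_FEATURES = 100
DEFAULT_PERMUTATIONS = 100
SD_FLOOR = 1e-6
LN10 = np.log(10.0)
_PERM_BLOCK = 500  # permutation replicates per matmul block (memory bound)


def compute_cv(activity: ActivityMatrix) -> np.ndarray:
    """Coefficient of variation sd/mean per feature (sample sd, n-1).

    All-zero features give NaN; constant nonzero features give 0.
    """
    n = activity.n_samples
    if sparse.issparse(activity.values):
        v = activity.values
        s1 = np.asarray(v.sum(axis=1)).ravel()
        s2 = np.asarray(v.multiply(v).sum(axis=1)).ravel()
    else:
        s1 = activity.values.sum(axis=1)
        s2 = (activity.values**2).sum(axis=1)
    mean = s1 / n
    var = np.maximum(s2 - n * mean**2, 0.0) / (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.sqrt(var) / mean
    cv[mean == 0] = np.nan
    return cv


def select_reference_features(
    cv: np.ndarray, m: int = DEFAULT_REF_FEATURES, scale: str = "log"
) -> np.ndarray:
    """Indices of m features spread evenly over the CV range.

    Spacing is on the log CV scale by default (the scale the null model is
    fitted on); ``scale="linear"`` spaces on raw CV. The minimum- and
    maximum-CV features are always included; remaining target values are
    matched greedily to the nearest unused feature. Deterministic.
    """
    cv = np.asarray(cv, dtype=float)
    eligible = np.flatnonzero(np.isfinite(cv) & (cv > 0))
    if len(eligible) == 0:
        raise HaystackError("no features with positive finite CV")
    if len(eligible) <= m:
        if len(eligible) < m:
            logger.warning(
                "only %d eligible features for %d requested references; using all",
                len(eligible),
                m,
            )
        return np.sort(eligible)
    vals = np.log(cv[eligible]) if scale == "log" else cv[eligible]
    order = np.argsort(vals, kind="stable")
    eligible, vals = eligible[order], vals[order]
    chosen = [0, len(vals) - 1]  # extremes first
    used = set(chosen)
    targets = np.linspace(vals[0], vals[-1], m)[1:-1]
    for t in targets:
        dist = np.abs(vals - t)
        dist[list(used)] = np.inf
        k = int(np.argmin(dist))
        used.add(k)
        chosen.append(k)
    return np.sort(eligible[np.array(chosen)])


def randomize_DKL(
    density: np.ndarray,
    y: np.ndarray,
    n_perm: int = DEFAULT_PERMUTATIONS,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """D_KL of n_perm random permutations of y against the fixed Q.

    Permutations are drawn uniformly; replicates are computed in blocks via
    one matrix product per block.
    """
    if n_perm < 2:
        raise HaystackError("need at least 2 permutations (sd undefined)")
    y = np.asarray(y, dtype=float)
    if y.sum() <= 0:
        raise HaystackError("cannot permute a feature with zero total activity")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    density = np.asarray(density, dtype=float)
    logQ = np.log(compute_Q(density))
    out = np.empty(n_perm)
    pos = 0
    while pos < n_perm:
        b = min(_PERM_BLOCK, n_perm - pos)
        Y = rng.permuted(np.broadcast_to(y, (b, len(y))).copy(), axis=1)
        P = Y @ density
        P /= P.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(P > 0, P * (np.log(np.where(P > 0, P, 1.0)) - logQ), 0.0)
        out[pos : pos + b] = terms.sum(axis=1)
        pos += b
    return out


def fit_null_model(
    ref_logCV: np.ndarray,
    ref_replicates: np.ndarray,
    spline_type: str = "ns",
    seed: int = 42,
    ref_feature_ids: np.ndarray | None = None,
    n_permutations: int | None = None,
) -> NullModel:
    """Fit the spline null model from per-reference permutation replicates.

    ``ref_replicates`` is an (m, n_perm) array of D_KL_random values. Per
    feature the mean and sd of the log replicates are computed (non-positive
    replicates are discarded; a feature with fewer than 2 usable replicates
    is dropped with a warning). Two splines — mean ~ s(logCV) and
    sd ~ s(logCV) — are then fitted with independently cross-validated
    flexibility.
    """
    ref_logCV = np.asarray(ref_logCV, dtype=float)
    ref_replicates = np.asarray(ref_replicates, dtype=float)
    m, n_perm = ref_replicates.shape
    if len(ref_logCV) != m:
        raise HaystackError("ref_logCV / ref_replicates shape mismatch")
    if ref_feature_ids is None:
        ref_feature_ids = np.arange(m)
    means = np.full(m, np.nan)
    sds = np.full(m, np.nan)
    for i in range(m):
        reps = ref_replicates[i]
        reps = reps[reps > 0]
        if len(reps) < 2:
            continue
        lr = np.log(reps)
        means[i] = lr.mean()
        sds[i] = lr.std(ddof=1)
    keep = np.isfinite(means) & np.isfinite(sds)
    n_dropped = int(m - keep.sum())
    if n_dropped:
        logger.warning(
            "dropped %d reference feature(s) with degenerate permutation "
            "replicates",
            n_dropped,
        )
    if keep.sum() == 0:
        raise HaystackError("all reference features had degenerate replicates")
    if keep.sum() < 12:
        raise HaystackError(
            "need at least 12 usable reference features to fit the null model"
        )
    x = ref_logCV[keep]
    mean_curve = fit_spline_cv(x, means[keep], kind=spline_type, seed=seed)
    sd_curve = fit_spline_cv(x, sds[keep], kind=spline_type, seed=seed + 1)
    return NullModel(
        ref_feature_ids=np.asarray(ref_feature_ids)[keep],
        ref_logCV=x,
        ref_mean_logDKL=means[keep],
        ref_sd_logDKL=np.maximum(sds[keep], SD_FLOOR),
        spline_type=spline_type,
        df_mean=mean_curve.df,
        df_sd=sd_curve.df,
        mean_curve=mean_curve,
        sd_curve=sd_curve,
        n_permutations=n_permutations if n_permutations is not None else n_perm,
        rng_seed=seed,
        degree_mean=mean_curve.degree,
        degree_sd=sd_curve.degree,
    )


def build_null_model(
    density: np.ndarray,
    activity: ActivityMatrix,
    cv: np.ndarray | None = None,
    m: int = DEFAULT_REF_FEATURES,
    n_perm: int = DEFAULT_PERMUTATIONS,
    spline_type: str = "ns",
    seed: int = 42,
    cv_scale: str = "log",
) -> NullModel:
    """Select reference features from the data, permute them, fit the model."""
    if cv is None:
        cv = compute_cv(activity)
    ref_idx = select_reference_features(cv, m=m, scale=cv_scale)
    rng = np.random.default_rng(seed)
    dense_rows = (
        np.asarray(activity.values[ref_idx].todense())
        if sparse.issparse(activity.values)
        else activity.values[ref_idx]
    )
    reps = np.empty((len(ref_idx), n_perm))
    for r, row in enumerate(dense_rows):
        reps[r] = randomize_DKL(density, row, n_perm=n_perm, rng=rng)
    return fit_null_model(
        np.log(cv[ref_idx]),
        reps,
        spline_type=spline_type,
        seed=seed,
        ref_feature_ids=activity.feature_ids[ref_idx],
        n_permutations=n_perm,
    )


def log10_pvals_adjust(log10_p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjustment carried out entirely on the log10 scale."""
    log10_p = np.asarray(log10_p, dtype=float)
    valid = np.isfinite(log10_p)
    out = np.full_like(log10_p, np.nan)
    idx = np.flatnonzero(valid)
    if idx.size == 0:
        return out
    f = idx.size
    order = np.argsort(log10_p[idx], kind="stable")
    sorted_lp = log10_p[idx][order]
    ranks = np.arange(1, f + 1)
    adj = sorted_lp + np.log10(f / ranks)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    adj = np.minimum(adj, 0.0)
    out[idx[order]] = adj
    return out


def predict_pvalues(
    model: NullModel,
    cv: np.ndarray,
    dkl: np.ndarray,
    feature_ids: np.ndarray | None = None,
) -> HaystackResult:
    """Upper-tail log10 p-value for every feature from its CV and D_KL.

    z = (ln D_KL - mu_hat(logCV)) / sd_hat(logCV); the one-sided tail
    probability is computed in log space (scipy's ``norm.logsf``), so
    z = 40 maps to a finite log10 p near -348 rather than underflowing.
    log CV values outside the reference span are clamped to the span
    boundary. Features with undefined CV or D_KL are flagged ``all_zero``;
    features with zero CV or zero divergence are flagged ``zero_cv`` and
    assigned p = 1. Ranks (1 = most significant) cover ok features only.
    """
    if model.mean_curve is None or model.sd_curve is None:
        raise HaystackError("null model is not fitted")
    cv = np.asarray(cv, dtype=float)
    dkl = np.asarray(dkl, dtype=float)
    f = len(cv)
    if feature_ids is None:
        feature_ids = np.arange(f)
    flags = np.array(["ok"] * f, dtype=object)
    flags[~np.isfinite(cv) | ~np.isfinite(dkl)] = "all_zero"
    degenerate = (flags == "ok") & ((cv <= 0) | (dkl <= 0))
    flags[degenerate] = "zero_cv"
    ok = flags == "ok"

    log10_p = np.full(f, np.nan)
    log10_p[degenerate] = 0.0  # p = 1
    if ok.any():
        lcv = np.log(cv[ok])
        lo, hi = model.logcv_span
        n_out = int(np.sum((lcv < lo) | (lcv > hi)))
        if n_out:
            logger.warning(
                "%d feature(s) have log CV outside the reference span; clamped",
                n_out,
            )
        lcv = np.clip(lcv, lo, hi)
        mu = model.mean_curve(lcv)
        sd = np.maximum(model.sd_curve(lcv), SD_FLOOR)
        z = (np.log(dkl[ok]) - mu) / sd
        log10_p[ok] = stats.norm.logsf(z) / LN10

    log10_p_adj = log10_pvals_adjust(log10_p)
    ranks = np.full(f, np.nan)
    if ok.any():
        ok_idx = np.flatnonzero(ok)
        # ascending p; ties broken by larger divergence, then input order
        order = np.lexsort((ok_idx, -dkl[ok_idx], log10_p[ok_idx]))
        ranks[ok_idx[order]] = np.arange(1, len(ok_idx) + 1)

    table = pd.DataFrame(
        {
            "D_KL": dkl,
            "log10_pval": log10_p,
            "log10_pval_adj": log10_p_adj,
            "rank": ranks,
            "flag": flags,
        },
        index=pd.Index(feature_ids, name="feature_id"),
    )
    info = {
        "spline_type": model.spline_type,
        "df_mean": model.df_mean,
        "df_sd": model.df_sd,
        "n_permutations": model.n_permutations,
        "n_ok": int(ok.sum()),
        "n_all_zero": int(np.sum(flags == "all_zero")),
        "n_zero_cv": int(np.sum(flags == "zero_cv")),
    }
    return HaystackResult(table=table, info=info)
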