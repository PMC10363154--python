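"""Reference distribution Q, feature distributions P_f, and KL divergences.

Q_j is the total density of samples around grid point j, normalized over grid
points. P_{f,j} weights the same density contributions by the activity y_{f,i}
of feature f, again normalized. The divergence

    D_KL(f) = sum_j P_{f,j} * ln(P_{f,j} / Q_j)

is ~0 for a feature whose activity follows the sample distribution and grows
with the spatial bias of the activity. Natural log is used throughout; the
choice of base cancels in the permutation-calibrated p-values.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse

from .types import ActivityMatrix, HaystackError


def compute_Q(density: np.ndarray) -> np.ndarray:
    """Normalized total sample density per grid point (length-g, sums to 1)."""
    density = np.asarray(density, dtype=float)
    q = density.sum(axis=0)
    total = q.sum()
    if total <= 0 or np.any(q <= 0):
        raise HaystackError("reference density has an empty grid point")
    return q / total


def compute_Pf(density: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Activity-weighted density distribution of one feature over grid points."""
    y = np.asarray(y, dtype=float)
    p = y @ density
    total = p.sum()
    if total <= 0:
        raise HaystackError(
            "feature has zero total activity; its distribution is undefined"
        )
    return p / total


def compute_DKL(Pf: np.ndarray, Q: np.ndarray) -> float:
    """KL divergence of P_f from Q (natural log; 0*log(0/q) := 0)."""
    Pf = np.asarray(Pf, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if Pf.shape != Q.shape:
        raise HaystackError("Pf and Q have different lengths")
    mask = Pf > 0
    return float(np.sum(Pf[mask] * (np.log(Pf[mask]) - np.log(Q[mask]))))


def compute_all_DKL(
    density: np.ndarray, activity: ActivityMatrix
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized D_KL for every feature.

    One (sparse) matrix product ``activity @ density`` followed by row
    normalization; identical to looping compute_Pf/compute_DKL per feature.

    Returns
    -------
    dkl : (f,) array, NaN for all-zero features
    all_zero : (f,) boolean mask of skipped features
    """
    density = np.asarray(density, dtype=float)
    if activity.n_samples != density.shape[0]:
        raise HaystackError(
            f"activity has {activity.n_samples} samples but density has "
            f"{density.shape[0]} rows"
        )
    logQ = np.log(compute_Q(density))
    P = np.asarray(activity.values @ density)  # sparse @ dense -> ndarray
    totals = P.sum(axis=1)
    all_zero = totals <= 0
    safe = np.where(all_zero, 1.0, totals)
    P = P / safe[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(P > 0, P * (np.log(np.where(P > 0, P, 1.0)) - logQ), 0.0)
    dkl = terms.sum(axis=1)
    dkl[all_zero] = np.nan
    return dkl, all_zero
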