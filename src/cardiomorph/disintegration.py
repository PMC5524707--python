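"""Thin-plate-spline bending energy and the disintegration slope.

The bending-energy matrix of a reference configuration (standard TPS
setup, 3-D biharmonic kernel ``U(r) = -r``) is eigen-decomposed into
partial warps: ``k - 4`` orthonormal non-affine deformation basis vectors
with positive bending energies (affine deformations and translations span
the null space and carry zero bending energy).

For a series of shapes, the variance of each partial-warp score across
the series is regressed (log-log, ordinary least squares) on the warp's
bending energy.  The slope summarizes the *intrinsic* integration of the
series: -1 means self-similar shape variation across spatial scales,
more negative means more integrated (variation concentrated at large
scales), near 0 means disintegrated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import as_coords, DegenerateConfigurationError

__all__ = [
    "PartialWarpBasis",
    "bending_energy_basis",
    "partial_warp_scores",
    "partial_warp_variances",
    "disintegration_slope",
]

#: Warps with variance below this fraction of the largest variance are
#: excluded from the log-log regression (guards log of zero).
VARIANCE_FLOOR_RTOL = 1e-15


@dataclass
class PartialWarpBasis:
    """Eigen-decomposition of a reference's bending-energy matrix."""

    reference: np.ndarray  # (k, m)
    eigenvalues: np.ndarray  # ascending, positive
    eigenvectors: np.ndarray  # (k, k - m - 1), orthonormal columns

    @property
    def n_warps(self) -> int:
        return self.eigenvalues.size


def _tps_kernel(r: np.ndarray, m: int) -> np.ndarray:
    if m == 3:
        return -r  # 3-D biharmonic kernel
    if m == 2:
        with np.errstate(divide="ignore", invalid="ignore"):
            k = r ** 2 * np.log(r)
        return np.where(r > 0, k, 0.0)
    raise ValueError(f"unsupported dimensionality {m}")


def bending_energy_basis(reference) -> PartialWarpBasis:
    """Build the partial-warp basis of a reference configuration.

    Assembles the TPS system ``L = [[K, Q], [Q^T, 0]]`` with
    ``K_ij = U(|x_i - x_j|)`` and ``Q = [1 | X]``; the bending-energy
    matrix is the upper-left ``k x k`` block of ``L^-1``.  Its
    numerically-zero eigenvalues span the affine + translation space and
    are discarded, leaving ``k - m - 1`` positive energies in ascending
    order with orthonormal eigenvectors.
    """
    x = as_coords(reference)
    k, m = x.shape
    if k < m + 2:
        raise DegenerateConfigurationError("too few landmarks for a TPS basis")
    d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2))
    off = d[~np.eye(k, dtype=bool)]
    if np.any(off == 0):
        raise ValueError("duplicate landmarks make the TPS kernel singular")
    kmat = _tps_kernel(d, m)
    q = np.hstack([np.ones((k, 1)), x])
    L = np.zeros((k + m + 1, k + m + 1))
    L[:k, :k] = kmat
    L[:k, k:] = q
    L[k:, :k] = q.T
    be = np.linalg.inv(L)[:k, :k]
    be = 0.5 * (be + be.T)
    w, v = np.linalg.eigh(be)
    tol = max(abs(w[0]), abs(w[-1])) * k * 1e-12
    keep = w > tol
    n_null = int((~keep).sum())
    if n_null != m + 1:
        raise RuntimeError(
            f"expected {m + 1} zero bending energies, found {n_null}"
        )
    return PartialWarpBasis(reference=x, eigenvalues=w[keep],
                            eigenvectors=v[:, keep])


def partial_warp_scores(shapes, basis: PartialWarpBasis) -> np.ndarray:
    """Project shapes on the partial warps.

    ``shapes`` is (n, k, m) or a list of configurations aligned to the
    basis reference; returns (n, n_warps, m) scores.  Scores are
    translation-invariant and vanish on any affine transform of the
    reference.
    """
    arr = np.stack([as_coords(s) for s in shapes]) \
        if not isinstance(shapes, np.ndarray) else np.asarray(shapes, dtype=float)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.shape[1:] != basis.reference.shape:
        raise ValueError("shapes do not match the basis reference layout")
    return np.einsum("kw,nkm->nwm", basis.eigenvectors, arr)


def partial_warp_variances(shapes, basis: PartialWarpBasis) -> np.ndarray:
    """Per-warp variance of the scores across the shape series, summed
    over the coordinate dimensions (sample variance, ddof=1)."""
    scores = partial_warp_scores(shapes, basis)
    if scores.shape[0] < 2:
        raise ValueError("need at least 2 shapes to estimate variances")
    return scores.var(axis=0, ddof=1).sum(axis=1)


def disintegration_slope(shapes, basis: PartialWarpBasis) -> float:
    """OLS slope of log partial-warp variance against log bending energy.

    Warps whose variance falls below the positivity floor are excluded.
    A slope of -1 indicates a self-similar shape series; more negative
    values indicate stronger integration, values near 0 disintegration.
    The slope is invariant to global rescaling of the whole series.
    """
    var = partial_warp_variances(shapes, basis)
    vmax = var.max()
    if vmax <= 0:
        raise ValueError("motionless series: all partial-warp variances zero")
    use = var > VARIANCE_FLOOR_RTOL * vmax
    if use.sum() < 2:
        raise ValueError("fewer than 2 warps with positive variance")
    lx = np.log(basis.eigenvalues[use])
    ly = np.log(var[use])
    return float(np.polyfit(lx, ly, 1)[0])
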