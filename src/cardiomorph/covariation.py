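"""Two-block partial least squares (singular warps) and major-axis slopes.

The left heart is treated as two highly interacting modules, LV and LA.
Covariation between them is measured at two hierarchical levels:

* within each individual — PLS of its 16 LV shapes against its 16 LA
  shapes (both blocks from the transported deformation dataset).  The
  strength of covariation is a permutation z-score of the first singular
  pair's score correlation; the *direction* is the major-axis (MA)
  regression slope of the first LA singular-warp scores on the first LV
  singular-warp scores — a slope above 1 means the LA shape changes
  faster per unit of LV shape change than the LV itself (isometry = 1).
* across individuals — PLS between LV and LA *trajectory shapes*, one
  observation per subject, with group-level MA slopes and permutation
  tests on group differences.

PLS here treats the blocks symmetrically (no dependent/independent
attribution): it is the SVD of the cross-covariance of the column-
centered blocks, computed in the observation space so that shape blocks
with thousands of columns never materialize the full p x q matrix.  MA
regression is likewise symmetric: residuals orthogonal to the fitted
line, the slope being that of the first eigenvector of the 2 x 2
covariance of the paired scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import gpa
from .transport import TransportedSet

__all__ = [
    "PlsResult",
    "two_block_pls",
    "pls_effect_size",
    "major_axis_slope",
    "individual_covariation",
    "trajectory_covariation",
    "TrajectoryCovariationResult",
]


class IndeterminateSlopeError(ValueError):
    """Isotropic point cloud: the major axis is undefined."""


@dataclass
class PlsResult:
    singular_vectors_A: np.ndarray  # (p, r) unit columns
    singular_vectors_B: np.ndarray  # (q, r)
    singular_values: np.ndarray  # non-increasing, >= 0
    scores_A: np.ndarray  # (n, r)
    scores_B: np.ndarray
    r_pls: float  # correlation of the first paired scores
    pct_covariance: float  # squared first SV / sum of squared SVs


def _centered(block: np.ndarray, name: str) -> np.ndarray:
    x = np.asarray(block, dtype=float)
    if x.ndim != 2:
        raise ValueError(f"{name} must be 2-D")
    xc = x - x.mean(axis=0)
    if not np.any(np.abs(xc) > 0):
        raise ValueError(f"{name} has zero variance")
    return xc


def _reduced(block: np.ndarray):
    """Economy SVD of a centered block: observation-space coordinates Z
    (n x r) and the column-space basis V (p x r), block = Z @ V.T."""
    u, s, vt = np.linalg.svd(block, full_matrices=False)
    keep = s > s[0] * 1e-12
    return u[:, keep] * s[keep], vt[keep].T


def _first_pair_r(za: np.ndarray, zb: np.ndarray) -> float:
    """Correlation of the first paired PLS scores, computed entirely in
    the reduced observation space."""
    um, _, vmt = np.linalg.svd(za.T @ zb)
    sa = za @ um[:, 0]
    sb = zb @ vmt[0]
    denom = np.linalg.norm(sa - sa.mean()) * np.linalg.norm(sb - sb.mean())
    if denom == 0:
        return 0.0
    return float((sa - sa.mean()) @ (sb - sb.mean()) / denom)


def two_block_pls(block_A: np.ndarray, block_B: np.ndarray) -> PlsResult:
    """Singular-warp decomposition of the cross-covariance of two blocks.

    Returns paired unit-norm singular vectors ordered by decreasing
    singular value of ``cov(A, B)`` (divisor n-1), the per-observation
    scores (projections of the centered blocks on the vectors), the first
    paired-score correlation ``r_pls`` and the fraction of total squared
    cross-covariance carried by the first pair.

    Sign convention: within each pair, the A-vector's largest-|loading|
    entry is made positive and the B-vector flips with it, preserving
    non-negative singular values.
    """
    a = np.asarray(block_A, dtype=float)
    b = np.asarray(block_B, dtype=float)
    if a.shape[0] != b.shape[0]:
        raise ValueError("blocks must be row-matched")
    n = a.shape[0]
    if n < 3:
        raise ValueError("PLS needs at least 3 observations")
    ac = _centered(a, "block_A")
    bc = _centered(b, "block_B")
    za, va = _reduced(ac)
    zb, vb = _reduced(bc)
    um, sv, vmt = np.linalg.svd(za.T @ zb / (n - 1), full_matrices=False)
    wa = va @ um  # (p, r)
    wb = vb @ vmt.T  # (q, r)
    # deterministic signs
    for j in range(wa.shape[1]):
        i = int(np.argmax(np.abs(wa[:, j])))
        if wa[i, j] < 0:
            wa[:, j] *= -1
            wb[:, j] *= -1
    scores_a = ac @ wa
    scores_b = bc @ wb
    sa = scores_a[:, 0]
    sb = scores_b[:, 0]
    denom = np.linalg.norm(sa - sa.mean()) * np.linalg.norm(sb - sb.mean())
    r = float((sa - sa.mean()) @ (sb - sb.mean()) / denom) if denom else 0.0
    total = float(np.sum(sv ** 2))
    pct = float(sv[0] ** 2 / total) if total > 0 else 0.0
    return PlsResult(wa, wb, sv, scores_a, scores_b, r, pct)


def pls_effect_size(block_A: np.ndarray, block_B: np.ndarray,
                    n_perm: int = 999, seed: int = 0) -> float:
    """Permutation z-score of morphological-integration strength.

    Rows of ``block_B`` are permuted ``n_perm`` times; the z-score is the
    observed first-pair score correlation standardized by the mean and
    standard deviation of the permuted correlations.
    """
    a = np.asarray(block_A, dtype=float)
    b = np.asarray(block_B, dtype=float)
    if a.shape[0] != b.shape[0]:
        raise ValueError("blocks must be row-matched")
    n = a.shape[0]
    if n < 3:
        raise ValueError("PLS needs at least 3 observations")
    za, _ = _reduced(_centered(a, "block_A"))
    zb, _ = _reduced(_centered(b, "block_B"))
    obs = _first_pair_r(za, zb)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        zp = zb[rng.permutation(n)]
        null[i] = _first_pair_r(za, zp - zp.mean(axis=0))
    sd = float(null.std(ddof=1))
    if sd == 0:
        raise ValueError("degenerate permutation distribution (sd = 0)")
    return float((obs - null.mean()) / sd)


def major_axis_slope(x, y) -> float:
    """Major-axis regression slope: the slope of the first eigenvector of
    the 2 x 2 covariance matrix of (x, y).  Symmetric in the sense that
    ``slope(x, y) * slope(y, x) = 1`` for non-degenerate data."""
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape or xv.ndim != 1:
        raise ValueError("x and y must be matched 1-D arrays")
    if xv.size < 3:
        raise ValueError("need at least 3 points")
    sxx = float(np.var(xv, ddof=1))
    syy = float(np.var(yv, ddof=1))
    sxy = float(np.cov(xv, yv, ddof=1)[0, 1])
    if sxx + syy == 0:
        raise ValueError("total variance is zero")
    lam1 = 0.5 * (sxx + syy + np.sqrt((sxx - syy) ** 2 + 4 * sxy ** 2))
    if sxy == 0:
        if sxx == syy:
            raise IndeterminateSlopeError(
                "isotropic cloud: major axis undefined"
            )
        if sxx > syy:
            return 0.0
        raise IndeterminateSlopeError("vertical major axis: slope undefined")
    return float((lam1 - sxx) / sxy)


def individual_covariation(transported: TransportedSet, subject,
                           n_perm: int = 999, seed: int = 0,
                           compute_z: bool = True):
    """Within-individual LV-LA covariation strength and direction.

    PLS of one subject's 16 transported LV shapes against its 16 LA
    shapes; returns ``(z_score, ma_slope)`` where the slope is that of the
    first LA singular-warp scores (vertical axis) on the first LV scores.
    With ``compute_z=False`` the z-score is skipped (returned as nan).
    """
    if isinstance(subject, str):
        idx = transported.subject_ids.index(subject)
    else:
        idx = int(subject)
    rows = transported.residuals[idx].reshape(16, -1)
    lv = rows[:, transported.chamber_columns("LV")]
    la = rows[:, transported.chamber_columns("LA")]
    res = two_block_pls(lv, la)
    slope = major_axis_slope(res.scores_A[:, 0], res.scores_B[:, 0])
    z = pls_effect_size(lv, la, n_perm=n_perm, seed=seed) if compute_z \
        else float("nan")
    return z, slope


@dataclass
class TrajectoryCovariationResult:
    z_by_group: dict
    slope_by_group: dict
    z_difference_p: float
    slope_difference_p: float
    pct_covariance_by_group: dict


def _group_pls_stats(lv: np.ndarray, la: np.ndarray, n_perm: int, seed: int,
                     with_z: bool):
    res = two_block_pls(lv, la)
    slope = major_axis_slope(res.scores_A[:, 0], res.scores_B[:, 0])
    z = pls_effect_size(lv, la, n_perm=n_perm, seed=seed) if with_z else None
    return z, slope, res.pct_covariance


def trajectory_covariation(lv_trajectories, la_trajectories, groups,
                           n_perm: int = 999, seed: int = 0,
                           inner_perm: int = 199,
                           test_z: bool = True) -> TrajectoryCovariationResult:
    """Second-order covariation: PLS between LV and LA trajectory shapes.

    Each subject contributes one LV and one LA 16 x 3 trajectory
    configuration (each chamber run through the full transport + PCA
    pipeline separately).  Trajectory shapes are GPA-aligned per chamber;
    within each group a PLS links the two blocks.  Group differences in
    the integration z-score and in the MA slope of the first singular-warp
    pair are tested by permuting group labels (``n_perm`` label shuffles,
    z re-estimated with ``inner_perm`` inner permutations).
    """
    g = np.asarray(groups)
    levels = list(dict.fromkeys(g.tolist()))
    if len(levels) != 2:
        raise ValueError("exactly two groups required")
    if any((g == lv).sum() < 3 for lv in levels):
        raise ValueError("each group needs at least 3 subjects")
    lv_pts = [np.asarray(t.points if hasattr(t, "points") else t, dtype=float)
              for t in lv_trajectories]
    la_pts = [np.asarray(t.points if hasattr(t, "points") else t, dtype=float)
              for t in la_trajectories]
    if len(lv_pts) != len(la_pts) or len(lv_pts) != len(g):
        raise ValueError("one LV and one LA trajectory per subject required")
    lv_block = gpa(lv_pts, space="shape").aligned.reshape(len(g), -1)
    la_block = gpa(la_pts, space="shape").aligned.reshape(len(g), -1)

    rng = np.random.default_rng(seed)
    z_by, slope_by, pct_by = {}, {}, {}
    for lev in levels:
        sel = g == lev
        z, slope, pct = _group_pls_stats(
            lv_block[sel], la_block[sel], inner_perm,
            int(rng.integers(2 ** 31)), with_z=True)
        z_by[lev], slope_by[lev], pct_by[lev] = z, slope, pct

    obs_dz = abs(z_by[levels[0]] - z_by[levels[1]])
    obs_ds = abs(slope_by[levels[0]] - slope_by[levels[1]])
    count_z = 1
    count_s = 1
    for _ in range(n_perm):
        gp = rng.permutation(g)
        try:
            stats = [
                _group_pls_stats(lv_block[gp == lev], la_block[gp == lev],
                                 inner_perm, int(rng.integers(2 ** 31)),
                                 with_z=test_z)
                for lev in levels
            ]
        except (ValueError, IndeterminateSlopeError):
            continue
        ds = abs(stats[0][1] - stats[1][1])
        if ds >= obs_ds:
            count_s += 1
        if test_z:
            dz = abs(stats[0][0] - stats[1][0])
            if dz >= obs_dz:
                count_z += 1
    return TrajectoryCovariationResult(
        z_by_group=z_by,
        slope_by_group=slope_by,
        z_difference_p=count_z / (n_perm + 1) if test_z else float("nan"),
        slope_difference_p=count_s / (n_perm + 1),
        pct_covariance_by_group=pct_by,
    )
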