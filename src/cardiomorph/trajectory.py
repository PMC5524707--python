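"""Motion trajectories in the principal-component morphospace.

After linear-shift transport the 16 x n deformations live in one common
tangent plane and can be ordinated by PCA.  Each subject's motion
trajectory is the 16 x 3 configuration of its first three PC scores —
these score triplets are the "landmarks" of trajectory shape, their
homology guaranteed by the homologous times.  Trajectory attributes are:

* trajectory centroid size (how much morphospace the cycle sweeps),
* the orientation angles of the end-diastole -> end-systole chord in the
  PC1/PC2 and PC1/PC3 planes,
* trajectory shape (GPA + PCA on the 16 x 3 trajectory configurations).

Group contrasts use a permutation ANOVA (scalar attributes) / MANOVA
(shape): R^2 = between-group SS / total SS with a label-permutation null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import centroid_size, gpa, DegenerateConfigurationError
from .transport import TransportedSet

__all__ = [
    "PCAResult",
    "TrajectoryShape",
    "pca_shapes",
    "build_trajectory",
    "trajectory_angles",
    "trajectory_shape_analysis",
    "perm_anova",
]

#: Homologous-time slots used for the trajectory chord: end-diastole is
#: the R-peak slot, end-systole the LV-end-systole slot.
ED_INDEX = 0
ES_INDEX = 4


@dataclass
class PCAResult:
    scores: np.ndarray  # (n_obs, n_comp)
    loadings: np.ndarray  # (n_comp, n_var), unit rows
    explained_variance_ratio: np.ndarray
    mean: np.ndarray

    def reconstruct(self) -> np.ndarray:
        return self.scores @ self.loadings + self.mean


def _fix_signs(scores: np.ndarray, loadings: np.ndarray):
    """Deterministic PC orientation: the largest-|entry| of each loading
    vector is made positive (score signs follow)."""
    for j in range(loadings.shape[0]):
        i = int(np.argmax(np.abs(loadings[j])))
        if loadings[j, i] < 0:
            loadings[j] *= -1
            scores[:, j] *= -1
    return scores, loadings


def pca(data: np.ndarray) -> PCAResult:
    """Centered PCA via SVD with the deterministic sign convention."""
    x = np.asarray(data, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("PCA needs a 2-D array with at least 2 observations")
    mean = x.mean(axis=0)
    xc = x - mean
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    scores = u * s
    var = s ** 2
    total = var.sum()
    if total == 0:
        raise DegenerateConfigurationError("zero-variance data in PCA")
    scores, loadings = _fix_signs(scores, vt)
    return PCAResult(scores, loadings, var / total, mean)


def pca_shapes(transported: TransportedSet) -> PCAResult:
    """PCA over all 16 * n transported deformations (rows: subject-major
    time-ordered observations; columns: the 3k tangent coordinates)."""
    return pca(transported.flat_residuals())


@dataclass
class TrajectoryShape:
    """One subject's motion trajectory: 16 dominant-PC score triplets."""

    points: np.ndarray  # (16, 3)
    cs: float
    angle_12: float  # degrees in (-180, 180]
    angle_13: float
    ed_index: int = ED_INDEX
    es_index: int = ES_INDEX
    subject_id: str = ""
    group: str = ""
    degenerate: bool = False


def trajectory_angles(points: np.ndarray, ed_index: int = ED_INDEX,
                      es_index: int = ES_INDEX) -> tuple[float, float]:
    """Orientation of the end-diastole -> end-systole chord.

    ``angle_12`` is the planar angle (degrees, two-argument arctangent) of
    the (dPC1, dPC2) chord, ``angle_13`` of (dPC1, dPC3).
    """
    pts = np.asarray(points, dtype=float)
    if ed_index == es_index:
        raise ValueError("end-diastole and end-systole slots must differ")
    chord = pts[es_index] - pts[ed_index]
    if np.allclose(chord, 0):
        raise DegenerateConfigurationError("zero-length ed->es chord")
    a12 = float(np.degrees(np.arctan2(chord[1], chord[0])))
    a13 = float(np.degrees(np.arctan2(chord[2], chord[0])))
    # map -180 -> 180 so angles live in (-180, 180]
    if a12 == -180.0:
        a12 = 180.0
    if a13 == -180.0:
        a13 = 180.0
    return a12, a13


def build_trajectory(scores: np.ndarray, subject_id: str = "",
                     group: str = "") -> TrajectoryShape:
    """Assemble one subject's 16 x 3 trajectory configuration and its
    attributes from its dominant PC score triplets."""
    pts = np.asarray(scores, dtype=float)
    if pts.shape != (16, 3):
        raise ValueError(f"expected 16 x 3 scores, got {pts.shape}")
    try:
        cs = centroid_size(pts)
        degenerate = False
    except DegenerateConfigurationError:
        cs = 0.0
        degenerate = True
    if degenerate:
        a12 = a13 = float("nan")
    else:
        a12, a13 = trajectory_angles(pts)
    return TrajectoryShape(points=pts, cs=cs, angle_12=a12, angle_13=a13,
                           subject_id=subject_id, group=group,
                           degenerate=degenerate)


def trajectories_from_transport(transported: TransportedSet,
                                n_components: int = 3) -> list[TrajectoryShape]:
    """Full trajectory construction: PCA on the transported deformations,
    then one TrajectoryShape per subject from its first three PC scores."""
    res = pca_shapes(transported)
    n = transported.n_subjects
    scores = res.scores[:, :n_components].reshape(n, 16, n_components)
    return [
        build_trajectory(scores[i], transported.subject_ids[i],
                         transported.groups[i])
        for i in range(n)
    ]


def trajectory_shape_analysis(trajs: list[TrajectoryShape]):
    """Shape analysis of the trajectories themselves: shape-space GPA on
    the 16 x 3 trajectory configurations followed by PCA of the aligned
    coordinates.  Returns (consensus, PCAResult)."""
    if len(trajs) < 3:
        raise ValueError("need at least 3 trajectories")
    if any(t.degenerate for t in trajs):
        raise DegenerateConfigurationError("degenerate (motionless) trajectory")
    res = gpa([t.points for t in trajs], space="shape")
    flat = res.aligned.reshape(len(trajs), -1)
    return res.consensus, pca(flat)


def perm_anova(values, groups, n_perm: int = 9999, seed: int = 0):
    """Permutation ANOVA / MANOVA for a two-level factor.

    ``R^2`` is the between-group sum of squares over the total sum of
    squares (Euclidean, summed over columns in the multivariate case); the
    p-value is the tail probability of ``R^2`` under ``n_perm`` random
    label permutations, the observed statistic counted in the null set.
    """
    y = np.asarray(values, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    g = np.asarray(groups)
    levels = np.unique(g)
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    if any((g == lv).sum() < 2 for lv in levels):
        raise ValueError("need at least 2 observations per group")

    def r_sq(perm_g):
        grand = y.mean(axis=0)
        sst = float(np.sum((y - grand) ** 2))
        if sst == 0:
            return 0.0
        ssb = 0.0
        for lv in levels:
            sel = perm_g == lv
            ssb += sel.sum() * float(np.sum((y[sel].mean(axis=0) - grand) ** 2))
        return ssb / sst

    obs = r_sq(g)
    rng = np.random.default_rng(seed)
    count = 1  # observed statistic included in the null set
    for _ in range(n_perm):
        if r_sq(rng.permutation(g)) >= obs:
            count += 1
    return obs, count / (n_perm + 1)
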