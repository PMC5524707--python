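"""Landmark configurations and Procrustes geometry.

Implements the primitives of Kendall-type statistical shape analysis used
throughout the pipeline: centroid size, ordinary (pairwise) Procrustes
superimposition, generalized Procrustes analysis (GPA) in shape space and
in size-and-shape space, the Procrustes geodesic distance, and the
orthogonal projection onto / lifting from the tangent space at a pole
shape.

Conventions
-----------
* A configuration is a ``(k, m)`` array of landmark coordinates, ``m`` in
  {2, 3}.  Rotations are restricted to ``SO(m)``: reflections are never
  admitted, because anatomical landmark sets have a fixed chirality.
* Shape space quotients out translation, rotation and scale; size-and-shape
  space quotients out translation and rotation only.
* Pre-shapes are centered configurations of unit centroid size; the
  Procrustes (arc) distance between two shapes is the geodesic distance
  between optimally rotated pre-shapes and is bounded by pi/2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "ChamberLayout",
    "LandmarkConfiguration",
    "ShapeCycle",
    "DegenerateConfigurationError",
    "ShapeMismatchError",
    "GPAConvergenceError",
    "EVENT_NAMES",
    "centroid_size",
    "center",
    "preshape",
    "opa_align",
    "OPAResult",
    "gpa",
    "GPAResult",
    "procrustes_distance",
    "tangent_project",
    "tangent_unproject",
]

#: Electro-mechanical events annotated on every cycle, in cyclic order
#: starting from the ECG R peak (end-diastole).
EVENT_NAMES = ("R_peak", "LV_end_systole", "mitral_valve_opening", "P_peak")

#: Relative centroid-size threshold below which a configuration is treated
#: as degenerate (all landmarks effectively coincident).
DEGENERATE_RTOL = 1e-12


class DegenerateConfigurationError(ValueError):
    """All landmarks coincide (centroid size numerically zero)."""


class ShapeMismatchError(ValueError):
    """Two configurations do not share landmark count / dimensionality."""


class GPAConvergenceError(RuntimeError):
    """GPA failed to converge; carries the consensus-shift trace."""

    def __init__(self, message: str, trace: Sequence[float]):
        super().__init__(message)
        self.trace = list(trace)


@dataclass(frozen=True)
class ChamberLayout:
    """Sampling layout of one chamber surface: stacked horizontal circles
    of landmarks plus an optional apex point."""

    n_circles: int = 36
    n_per_circle: int = 36
    has_apex: bool = True

    @property
    def n_landmarks(self) -> int:
        return self.n_circles * self.n_per_circle + int(self.has_apex)


@dataclass
class LandmarkConfiguration:
    """One frame's 3D landmark cloud with per-landmark chamber labels.

    For a whole left-heart configuration the rows form two contiguous
    blocks (all LV landmarks, then all LA landmarks), 1297 each under the
    default 36x36+apex layout.
    """

    coords: np.ndarray
    chamber_labels: np.ndarray
    layout: ChamberLayout = field(default_factory=ChamberLayout)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.chamber_labels = np.asarray(self.chamber_labels)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ShapeMismatchError(
                f"coords must be (k, 3), got {self.coords.shape}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords contain non-finite values")
        if self.chamber_labels.shape != (self.coords.shape[0],):
            raise ShapeMismatchError("one chamber label per landmark required")
        bad = set(np.unique(self.chamber_labels)) - {"LV", "LA"}
        if bad:
            raise ValueError(f"unknown chamber labels: {sorted(bad)}")
        if self.n_chambers == 2:
            # two contiguous blocks, LV first
            n = self.layout.n_landmarks
            if self.coords.shape[0] != 2 * n:
                raise ShapeMismatchError(
                    f"two-chamber configuration must have {2 * n} landmarks, "
                    f"got {self.coords.shape[0]}"
                )
            if not (
                np.all(self.chamber_labels[:n] == "LV")
                and np.all(self.chamber_labels[n:] == "LA")
            ):
                raise ValueError(
                    "chamber labels must form contiguous LV then LA blocks"
                )
        else:
            if self.coords.shape[0] != self.layout.n_landmarks:
                raise ShapeMismatchError(
                    f"single-chamber configuration must have "
                    f"{self.layout.n_landmarks} landmarks, "
                    f"got {self.coords.shape[0]}"
                )

    @property
    def k(self) -> int:
        return self.coords.shape[0]

    @property
    def n_chambers(self) -> int:
        return len(np.unique(self.chamber_labels))

    def chamber(self, label: str) -> np.ndarray:
        """Coordinate rows belonging to one chamber."""
        return self.coords[self.chamber_labels == label]


@dataclass
class ShapeCycle:
    """One subject's acquired cardiac cycle.

    ``frames`` is a ``(T, k, 3)`` stack of landmark configurations at the
    acquisition frame times; ``events`` maps the four annotated
    electro-mechanical events to their occurrence time in ms.
    """

    frames: np.ndarray
    frame_times_ms: np.ndarray
    events: Mapping[str, float]
    cycle_length_ms: float
    subject_id: str
    group: str
    chamber_labels: np.ndarray
    layout: ChamberLayout = field(default_factory=ChamberLayout)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.frame_times_ms = np.asarray(self.frame_times_ms, dtype=float)
        self.chamber_labels = np.asarray(self.chamber_labels)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ShapeMismatchError("frames must be (T, k, 3)")
        if self.frames.shape[0] != self.frame_times_ms.shape[0]:
            raise ShapeMismatchError("one frame time per frame required")
        if np.any(np.diff(self.frame_times_ms) <= 0):
            raise ValueError("frame times must be strictly increasing")
        if self.group not in ("Control", "HCM"):
            raise ValueError(f"group must be Control or HCM, got {self.group!r}")
        missing = [e for e in EVENT_NAMES if e not in self.events]
        if missing:
            raise ValueError(f"missing event times: {missing}")
        L = float(self.cycle_length_ms)
        for name in EVENT_NAMES:
            t = float(self.events[name])
            if not (0.0 <= t < L):
                raise ValueError(
                    f"event {name}={t} outside [0, {L}) ms"
                )
        # cyclic ordering: unwrapped from R_peak the events must increase
        if np.any(np.diff(self.events_from_r_peak()) <= 0):
            raise ValueError(
                "events must be cyclically ordered "
                "R_peak -> LV_end_systole -> mitral_valve_opening -> P_peak"
            )

    def events_from_r_peak(self) -> np.ndarray:
        """The four event times unwrapped to an increasing sequence
        starting at the R peak (later events wrapped past the cycle end
        get ``+ cycle_length``)."""
        r = float(self.events["R_peak"])
        L = float(self.cycle_length_ms)
        out = []
        prev = r
        for name in EVENT_NAMES:
            t = float(self.events[name])
            while t < prev:
                t += L
            out.append(t)
            prev = t
        return np.array(out)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def k(self) -> int:
        return self.frames.shape[1]


# ---------------------------------------------------------------------------
# coordinate helpers
# ---------------------------------------------------------------------------

def as_coords(x) -> np.ndarray:
    """Accept a LandmarkConfiguration or a bare (k, m) array."""
    if isinstance(x, LandmarkConfiguration):
        return x.coords
    a = np.asarray(x, dtype=float)
    if a.ndim != 2:
        raise ShapeMismatchError(f"expected (k, m) array, got shape {a.shape}")
    return a


def centroid_size(config) -> float:
    """Centroid size: root summed squared distances of the landmarks from
    their centroid.  Scales linearly under uniform scaling.
    """
    x = as_coords(config)
    if x.shape[0] < 2:
        raise DegenerateConfigurationError("need at least 2 landmarks")
    c = x - x.mean(axis=0)
    cs = float(np.sqrt(np.sum(c * c)))
    scale = float(np.max(np.abs(x))) or 1.0
    if cs < DEGENERATE_RTOL * scale:
        raise DegenerateConfigurationError("all landmarks coincide (CS = 0)")
    return cs


def center(config) -> np.ndarray:
    """Translate the centroid to the origin."""
    x = as_coords(config)
    return x - x.mean(axis=0)


def preshape(config) -> np.ndarray:
    """Centered configuration scaled to unit centroid size."""
    x = center(config)
    return x / centroid_size(config)


def _check_pair(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ShapeMismatchError(
            f"configurations differ in shape: {a.shape} vs {b.shape}"
        )


def optimal_rotation(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rotation R in SO(m) minimizing || source @ R - target ||_F for
    centered configurations (Kabsch with the reflection constraint)."""
    m = source.shape[1]
    u, _, vt = np.linalg.svd(source.T @ target)
    d = np.sign(np.linalg.det(u @ vt))
    s = np.ones(m)
    s[-1] = d
    return (u * s) @ vt


@dataclass
class OPAResult:
    aligned: np.ndarray
    rotation: np.ndarray
    scale: float
    translation: np.ndarray
    residual: float


def opa_align(
    source,
    target,
    allow_scaling: bool = False,
    allow_reflection: bool = False,
) -> OPAResult:
    """Ordinary Procrustes superimposition of ``source`` onto ``target``.

    Finds translation, rotation (and optionally a positive scale) that
    minimize the summed squared landmark distances.  With
    ``allow_reflection=False`` (the default, used everywhere in the
    pipeline) the rotation is constrained to determinant +1.

    Returns the transformed source, the rotation matrix, the scale factor,
    the translation (applied after rotation/scale) and the root-summed-
    squared residual.
    """
    x = as_coords(source)
    y = as_coords(target)
    _check_pair(x, y)
    centroid_size(x), centroid_size(y)  # degenerate guard
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    m = x.shape[1]
    u, sv, vt = np.linalg.svd(xc.T @ yc)
    signs = np.ones(m)
    if not allow_reflection and np.linalg.det(u @ vt) < 0:
        signs[-1] = -1.0
    rot = (u * signs) @ vt
    if allow_scaling:
        beta = float(np.sum(sv * signs)) / float(np.sum(xc * xc))
    else:
        beta = 1.0
    aligned_c = beta * (xc @ rot)
    translation = y.mean(axis=0)
    aligned = aligned_c + translation
    residual = float(np.sqrt(np.sum((aligned_c - yc) ** 2)))
    return OPAResult(aligned, rot, beta, translation, residual)


@dataclass
class GPAResult:
    consensus: np.ndarray
    aligned: np.ndarray  # (n, k, m)
    centroid_sizes: np.ndarray  # original CS of every input
    n_iter: int


def _canonical_orientation(consensus: np.ndarray, aligned: np.ndarray):
    """Rotate the consensus into its principal-axis frame with a
    deterministic sign convention, so the GPA output does not depend on
    the input ordering (which otherwise only fixes orientation up to a
    global rotation)."""
    _, _, vt = np.linalg.svd(consensus - consensus.mean(axis=0))
    v = vt.T
    if np.linalg.det(v) < 0:
        v[:, -1] *= -1
    # sign-fix the first m-1 axes by the largest-|coordinate| landmark;
    # compensate on the last axis to stay in SO(m)
    scores = consensus @ v
    for j in range(v.shape[1] - 1):
        i = int(np.argmax(np.abs(scores[:, j])))
        if scores[i, j] < 0:
            v[:, j] *= -1
            v[:, -1] *= -1
            scores = consensus @ v
    return consensus @ v, aligned @ v


def gpa(
    configs: Iterable,
    space: str = "shape",
    tol: float = 1e-8,
    max_iter: int = 200,
    canonical: bool = True,
) -> GPAResult:
    """Generalized Procrustes analysis.

    Iteratively superimposes every configuration on the evolving mean
    until the root-mean-square displacement of the consensus falls below
    ``tol``.

    space="shape"
        every configuration is first scaled to unit centroid size and the
        consensus is re-normalized to unit CS each iteration (Kendall
        shape space: translation, rotation and size removed).
    space="size_and_shape"
        translation and rotation only; sizes are preserved.
    """
    if space not in ("shape", "size_and_shape"):
        raise ValueError(f"space must be 'shape' or 'size_and_shape': {space}")
    xs = [as_coords(c) for c in configs]
    if len(xs) < 2:
        raise ValueError("GPA needs at least 2 configurations")
    k, m = xs[0].shape
    for x in xs[1:]:
        _check_pair(xs[0], x)
    sizes = np.array([centroid_size(x) for x in xs])
    stack = np.stack([x - x.mean(axis=0) for x in xs])
    if space == "shape":
        stack = stack / np.sqrt((stack ** 2).sum(axis=(1, 2)))[:, None, None]

    consensus = stack[0].copy()
    if space == "shape":
        consensus /= np.sqrt(np.sum(consensus ** 2))
    trace = []
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        for i in range(stack.shape[0]):
            stack[i] = stack[i] @ optimal_rotation(stack[i], consensus)
        new = stack.mean(axis=0)
        if space == "shape":
            new = new / np.sqrt(np.sum(new ** 2))
        shift = float(np.sqrt(np.mean((new - consensus) ** 2)))
        trace.append(shift)
        consensus = new
        if shift < tol:
            break
    else:
        raise GPAConvergenceError(
            f"GPA did not converge in {max_iter} iterations "
            f"(last shift {trace[-1]:.3g})",
            trace,
        )
    if canonical:
        consensus, stack = _canonical_orientation(consensus, stack)
    return GPAResult(consensus, stack, sizes, n_iter)


def procrustes_distance(a, b) -> float:
    """Procrustes geodesic (arc) distance between two shapes.

    Both configurations are centered, scaled to unit centroid size and
    optimally rotated (rotations only, reflections excluded); the distance
    is ``arccos`` of the resulting shape correlation and lives in
    ``[0, pi/2]`` for configurations that can be matched, reaching its
    theoretical maximum at e.g. a planar triangle versus its mirror image.
    Invariant to similarity transforms of either argument.
    """
    x = as_coords(a)
    y = as_coords(b)
    _check_pair(x, y)
    zx = center(x)
    zx /= centroid_size(x)
    zy = center(y)
    zy /= centroid_size(y)
    u, sv, vt = np.linalg.svd(zx.T @ zy)
    if np.linalg.det(u @ vt) < 0:
        sv = sv.copy()
        sv[-1] *= -1
    c = float(np.clip(np.sum(sv), -1.0, 1.0))
    return float(np.arccos(c))


def tangent_project(config, pole) -> np.ndarray:
    """Orthogonally project a pre-aligned shape onto the tangent space of
    shape space at ``pole``.

    ``pole`` must be a non-degenerate configuration; it is internally
    reduced to its pre-shape.  ``config`` is assumed already centered,
    unit-size and rotated to the pole (as GPA output is); the projection
    removes its component along the pole: ``v = x - <x, p> p``.
    """
    p = preshape(pole)
    x = as_coords(config)
    _check_pair(x, p)
    return x - float(np.sum(x * p)) * p


def tangent_unproject(vector, pole) -> np.ndarray:
    """Inverse of :func:`tangent_project` for unit-size shapes within
    pi/2 of the pole: reconstructs the pre-shape whose projection is
    ``vector``."""
    p = preshape(pole)
    v = as_coords(vector)
    _check_pair(v, p)
    n2 = float(np.sum(v * v))
    if n2 > 1.0:
        raise ValueError("tangent vector norm exceeds 1; outside injectivity range")
    return np.sqrt(1.0 - n2) * p + v
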