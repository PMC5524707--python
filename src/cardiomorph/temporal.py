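"""Homologous-time construction and cubic-spline cycle resampling.

Every subject is acquired at a device-dependent frame rate, so shapes
cannot be compared frame-by-frame across subjects.  Instead, four strictly
homologous electro-mechanical events are annotated per cycle (R peak, LV
end-systole, mitral valve opening, P peak); between each consecutive pair
of events three additional equally spaced times are inserted, giving 16
physiologically homologous times per heartbeat.  The subject's frames are
first superimposed by GPA in size-and-shape space (size is still carried
at this stage) and each landmark coordinate is then interpolated at the
homologous times with a periodic cubic spline over one cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.interpolate import CubicSpline

from .core import (
    EVENT_NAMES,
    ChamberLayout,
    ShapeCycle,
    gpa,
)

__all__ = ["HomologousCycle", "homologous_times", "interpolate_cycle",
           "N_HOMOLOGOUS", "STRICT_INDICES"]

#: 4 strict events + 3 inserted times per inter-event gap.
N_HOMOLOGOUS = 16
#: Slots of the strict events among the 16 homologous times (R peak first).
STRICT_INDICES = (0, 4, 8, 12)


@dataclass
class HomologousCycle:
    """A subject's cycle resampled at the 16 homologous times, in
    size-and-shape alignment."""

    shapes: np.ndarray  # (16, k, 3)
    homologous_times_ms: np.ndarray  # increasing from the R peak
    strict_indices: tuple
    subject_id: str
    group: str
    chamber_labels: np.ndarray
    layout: ChamberLayout = field(default_factory=ChamberLayout)

    def __post_init__(self) -> None:
        self.shapes = np.asarray(self.shapes, dtype=float)
        self.homologous_times_ms = np.asarray(self.homologous_times_ms, dtype=float)
        if self.shapes.shape[0] != N_HOMOLOGOUS:
            raise ValueError(f"expected {N_HOMOLOGOUS} shapes, got {self.shapes.shape[0]}")
        if self.homologous_times_ms.shape != (N_HOMOLOGOUS,):
            raise ValueError("expected 16 homologous times")
        if tuple(self.strict_indices) != STRICT_INDICES:
            raise ValueError(f"strict indices must be {STRICT_INDICES}")
        if np.any(np.diff(self.homologous_times_ms) <= 0):
            raise ValueError("homologous times must be strictly increasing")

    @property
    def k(self) -> int:
        return self.shapes.shape[1]


def homologous_times(events: Mapping[str, float], cycle_length_ms: float) -> np.ndarray:
    """Build the 16 homologous times from the four annotated events.

    The output starts at the R peak and increases; between consecutive
    strict events (cyclically, the last gap wraps to the R peak of the
    next beat) three times are inserted at the 1/4, 1/2 and 3/4 points of
    the gap.  Times in wrapped gaps may exceed ``cycle_length_ms``; they
    refer to the same cycle modulo its length.
    """
    missing = [e for e in EVENT_NAMES if e not in events]
    if missing:
        raise ValueError(f"missing event times: {missing}")
    L = float(cycle_length_ms)
    # unwrap to an increasing sequence from the R peak
    strict = []
    prev = float(events["R_peak"])
    for name in EVENT_NAMES:
        t = float(events[name])
        while t < prev:
            t += L
        strict.append(t)
        prev = t
    strict.append(strict[0] + L)  # next beat's R peak closes the last gap
    strict = np.asarray(strict)
    gaps = np.diff(strict)
    if np.any(gaps <= 0):
        raise ValueError("coincident event times leave a zero-length gap")
    out = []
    for a, g in zip(strict[:-1], gaps):
        out.extend(a + g * np.array([0.0, 0.25, 0.5, 0.75]))
    times = np.asarray(out)
    assert times.shape == (N_HOMOLOGOUS,)
    return times


def interpolate_cycle(cycle: ShapeCycle, times: np.ndarray | None = None) -> HomologousCycle:
    """Resample a subject's cycle at its 16 homologous times.

    The observed frames are first aligned by GPA in size-and-shape space
    (the whole left heart taken as one shape), then one periodic cubic
    spline per landmark coordinate is fitted over the frame times and
    evaluated at the homologous times (wrapped into the observed cycle).
    """
    if cycle.n_frames < 4:
        raise ValueError("need at least 4 frames to fit a cubic spline")
    if times is None:
        times = homologous_times(cycle.events, cycle.cycle_length_ms)
    times = np.asarray(times, dtype=float)
    L = float(cycle.cycle_length_ms)
    t0 = float(cycle.frame_times_ms[0])
    span = float(cycle.frame_times_ms[-1] - t0)
    if span <= 0 or span >= L:
        raise ValueError("frame times must span less than one cycle length")

    res = gpa(list(cycle.frames), space="size_and_shape", canonical=False)
    aligned = res.aligned  # (T, k, 3)

    # periodic closure: the first frame recurs one cycle later
    t_ext = np.concatenate([cycle.frame_times_ms, [t0 + L]])
    y_ext = np.concatenate([aligned, aligned[:1]], axis=0)
    T, k, m = aligned.shape
    spline = CubicSpline(
        t_ext, y_ext.reshape(T + 1, k * m), bc_type="periodic", axis=0
    )

    t_eval = (times - t0) % L + t0
    if np.any(t_eval < t_ext[0] - 1e-9) or np.any(t_eval > t_ext[-1] + 1e-9):
        raise ValueError("requested time outside the observed cycle domain")
    shapes = spline(t_eval).reshape(len(times), k, m)
    return HomologousCycle(
        shapes=shapes,
        homologous_times_ms=times,
        strict_indices=STRICT_INDICES,
        subject_id=cycle.subject_id,
        group=cycle.group,
        chamber_labels=cycle.chamber_labels,
        layout=cycle.layout,
    )
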