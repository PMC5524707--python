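"""Synthetic 4D left-heart cohorts.

Generates beating left-heart landmark clouds with the statistical
structure the analysis pipeline assumes: two stacked quasi-ellipsoidal
chamber surfaces (LV prolate below, LA oblate dome above, sharing the
mitral-annulus circle), each sampled as 36 horizontal circles of 36
landmarks plus an apex point (1297 landmarks per chamber, 2594 per left
heart), deforming periodically over one heartbeat.

The deformation model is built from analytic displacement fields driven
by two smooth periodic activation bumps:

* a primary mode peaking at LV end-systole — LV contraction (blended
  affine squeeze and non-affine apex-weighted taper) with a matched LA
  reservoir expansion;
* a secondary mode peaking at the P wave — LV twist with an LA
  booster-pump contraction — giving elliptical rather than degenerate
  (linear) motion trajectories.

Every field is projected onto the horizontal tangent subspace of the
subject's base shape (orthogonal to translations, rotations and uniform
scaling) and normalized to unit Frobenius norm, so the planted LA:LV
shape-change rate (``covariation_slope``) survives Procrustes alignment
and is recoverable by the PLS / major-axis machinery downstream.

Between-subject variation: semiaxis jitter plus low-order harmonic
surface modulation, a random rigid device pose, beat-rate variation and
frame-time jitter; iid Gaussian landmark noise is added last.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .core import ChamberLayout, LandmarkConfiguration, ShapeCycle, centroid_size
from .disintegration import PartialWarpBasis, bending_energy_basis

__all__ = [
    "GeneratorParams",
    "CONTROL_PARAMS",
    "HCM_PARAMS",
    "generate_chamber_surface",
    "generate_left_heart",
    "generate_cycle",
    "generate_cohort",
    "generate_self_similar_series",
]


@dataclass(frozen=True)
class GeneratorParams:
    """Study-condition parameters of the synthetic cohort generator.

    Amplitudes are fractional: ``lv_amplitude`` is the peak tangent-norm
    of the LV deformation relative to the base-shape centroid size.
    ``covariation_slope`` is the planted LA:LV shape-change rate (LA
    tangent displacement per unit LV tangent displacement along the
    covarying modes); ``la_amplitude``, if set, overrides the implied
    LA amplitude ``covariation_slope * lv_amplitude``.
    """

    n_circles: int = 36
    n_per_circle: int = 36
    lv_amplitude: float = 0.12
    la_amplitude: float | None = None
    covariation_slope: float = 1.25
    mode_mix: float = 0.5  # weight of the affine component in the fields
    secondary_amplitude_frac: float = 0.35
    subject_shape_sd: float = 0.05
    landmark_noise_sd: float = 0.5  # mm
    beat_rate_mean: float = 77.0  # beats/min
    beat_rate_sd: float = 13.16
    frame_interval_ms: float = 41.6
    frame_jitter_sd_ms: float = 2.0
    event_phase_fractions: tuple = (0.0, 0.30, 0.45, 0.85)
    lv_semiaxes: tuple = (21.0, 21.0, 45.0)  # mm; prolate
    la_semiaxes: tuple = (21.0, 21.0, 18.0)  # mm; oblate dome
    activation_kappa: float = 8.0
    seed: int = 0

    def __post_init__(self):
        if self.lv_amplitude < 0 or (self.la_amplitude or 0) < 0:
            raise ValueError("amplitudes must be >= 0")
        if self.covariation_slope <= 0:
            raise ValueError("covariation_slope must be > 0")
        if self.frame_interval_ms <= 0:
            raise ValueError("frame_interval_ms must be > 0")
        f = np.asarray(self.event_phase_fractions)
        if f.shape != (4,) or np.any(np.diff(f) <= 0) or f[0] != 0.0 or f[-1] >= 1:
            raise ValueError(
                "event_phase_fractions must be 4 increasing fractions "
                "starting at 0 (R peak) and below 1"
            )

    @property
    def layout(self) -> ChamberLayout:
        return ChamberLayout(self.n_circles, self.n_per_circle, True)

    @property
    def la_scale(self) -> float:
        if self.la_amplitude is not None:
            return self.la_amplitude / self.lv_amplitude
        return self.covariation_slope


#: Group defaults: Control deforms more than HCM, planted covariation
#: slopes above/below isometry; both groups share the integration law.
CONTROL_PARAMS = GeneratorParams(lv_amplitude=0.12, covariation_slope=1.25)
HCM_PARAMS = GeneratorParams(lv_amplitude=0.08, covariation_slope=0.89)


# ---------------------------------------------------------------------------
# base geometry
# ---------------------------------------------------------------------------

def _chamber_coords(layout: ChamberLayout, a: float, b: float, c: float,
                    direction: float, radial_mod=None,
                    theta_offset: float = 0.0) -> np.ndarray:
    """Stacked-circle sampling of a half-ellipsoid.

    Circle 0 lies on the annulus plane z = 0; circles march toward the
    apex at z = direction * c (direction -1 for LV, +1 for LA).  The apex
    point is appended last.  ``radial_mod(theta, phi)`` optionally
    modulates the circle radius (subject-level surface variation).
    """
    jj = np.arange(layout.n_circles)
    phi = (np.pi / 2) * (1.0 - jj / layout.n_circles)  # pi/2 (annulus) -> ~0
    theta = 2 * np.pi * np.arange(layout.n_per_circle) / layout.n_per_circle \
        + theta_offset
    pts = np.empty((layout.n_circles, layout.n_per_circle, 3))
    for j, ph in enumerate(phi):
        r = np.sin(ph)
        if radial_mod is not None:
            rr = r * (1.0 + radial_mod(theta, ph))
        else:
            rr = np.full_like(theta, r)
        pts[j, :, 0] = a * rr * np.cos(theta)
        pts[j, :, 1] = b * rr * np.sin(theta)
        pts[j, :, 2] = direction * c * np.cos(ph)
    coords = pts.reshape(-1, 3)
    apex = np.array([[0.0, 0.0, direction * c]])
    return np.vstack([coords, apex])


def generate_chamber_surface(chamber: str = "LV",
                             params: GeneratorParams | None = None
                             ) -> LandmarkConfiguration:
    """One chamber's base surface as a LandmarkConfiguration
    (36 circles x 36 landmarks + apex = 1297 under defaults)."""
    p = params or GeneratorParams()
    if chamber == "LV":
        a, b, c = p.lv_semiaxes
        coords = _chamber_coords(p.layout, a, b, c, -1.0)
    elif chamber == "LA":
        a, b, c = p.la_semiaxes
        coords = _chamber_coords(p.layout, a, b, c, +1.0,
                                 theta_offset=np.pi / p.n_per_circle)
    else:
        raise ValueError(f"chamber must be LV or LA, got {chamber!r}")
    labels = np.full(coords.shape[0], chamber)
    return LandmarkConfiguration(coords, labels, p.layout)


def _labels(layout: ChamberLayout) -> np.ndarray:
    n = layout.n_landmarks
    return np.array(["LV"] * n + ["LA"] * n)


def generate_left_heart(params: GeneratorParams,
                        rng: np.random.Generator | None = None) -> np.ndarray:
    """Whole-LH base configuration (2k, 3): LV block then LA block,
    chambers joined at the shared annulus circle.  With an rng, subject-
    level shape variation (semiaxis jitter + harmonic surface modulation)
    is applied."""
    p = params
    lv_ax = np.array(p.lv_semiaxes, dtype=float)
    la_ax = np.array(p.la_semiaxes, dtype=float)
    mod_lv = mod_la = None
    if rng is not None and p.subject_shape_sd > 0:
        sdev = p.subject_shape_sd
        lv_ax = lv_ax * (1.0 + sdev * rng.normal(size=3))
        la_ax = la_ax * (1.0 + sdev * rng.normal(size=3))
        # keep the shared annulus circular and identical across chambers
        la_ax[:2] = lv_ax[:2]
        c_lv = sdev * rng.normal(size=3)
        c_la = sdev * rng.normal(size=3)

        def make_mod(cf):
            def mod(theta, ph):
                damp = np.cos(ph)  # vanishes at the annulus (phi = pi/2)
                return damp * (cf[0] * np.cos(theta) + cf[1] * np.sin(theta)
                               + cf[2] * np.cos(2 * theta))
            return mod
        mod_lv, mod_la = make_mod(c_lv), make_mod(c_la)
    lv = _chamber_coords(p.layout, lv_ax[0], lv_ax[1], lv_ax[2], -1.0, mod_lv)
    # half-spacing azimuthal offset: the LA annulus ring interleaves with
    # the LV ring on the shared plane (connected cloud, no coincident points)
    la = _chamber_coords(p.layout, la_ax[0], la_ax[1], la_ax[2], +1.0, mod_la,
                         theta_offset=np.pi / p.layout.n_per_circle)
    return np.vstack([lv, la])


# ---------------------------------------------------------------------------
# deformation fields
# ---------------------------------------------------------------------------

def _horizontal_project(fields: np.ndarray, base: np.ndarray,
                        rows: np.ndarray | None = None,
                        with_scaling: bool = True) -> np.ndarray:
    """Project displacement fields onto the horizontal tangent subspace
    at ``base``: orthogonal to translations, rotations about the centroid
    and uniform scaling, so planted deformations are pure shape changes
    that survive Procrustes alignment.

    With ``rows`` given, the vertical directions are restricted to those
    rows, making a chamber-supported field horizontal *within* its own
    chamber block — it then stays block-pure and alignment-invariant at
    the same time."""
    k = base.shape[0]
    bc = base - base.mean(axis=0)
    mask = np.zeros((k, 1))
    if rows is None:
        mask[:] = 1.0
    else:
        mask[rows] = 1.0
    vertical = []
    for d in range(3):  # translations
        e = np.zeros((k, 3))
        e[:, d] = 1.0
        vertical.append((e * mask).ravel())
    gens = [
        np.array([[0, -1, 0], [1, 0, 0], [0, 0, 0]], float),
        np.array([[0, 0, 1], [0, 0, 0], [-1, 0, 0]], float),
        np.array([[0, 0, 0], [0, 0, -1], [0, 1, 0]], float),
    ]
    for s in gens:  # infinitesimal rotations
        vertical.append(((bc @ s.T) * mask).ravel())
    if with_scaling:
        vertical.append((bc * mask).ravel())  # uniform scaling
    q, _ = np.linalg.qr(np.stack(vertical, axis=1))
    flat = fields.reshape(fields.shape[0], -1) if fields.ndim == 3 \
        else fields.reshape(1, -1)
    out = flat - (flat @ q) @ q.T
    return out.reshape(fields.shape)


def _unit(field: np.ndarray) -> np.ndarray:
    n = np.sqrt(np.sum(field ** 2))
    return field / n


def _set_scaling_component(field: np.ndarray, u_scale: np.ndarray,
                           beta: float) -> np.ndarray:
    """Return the unit-norm field whose component along the chamber
    scaling direction ``u_scale`` is exactly ``beta`` and whose
    orthogonal part keeps the direction of ``field``."""
    h = field - np.sum(field * u_scale) * u_scale
    h = _unit(h)
    beta = float(np.clip(beta, -0.9, 0.9))
    return np.sqrt(1.0 - beta ** 2) * h + beta * u_scale


def _deformation_fields(base: np.ndarray, params: GeneratorParams):
    """Unit-norm displacement fields for the two covarying modes, per
    chamber.  Returns (F1_lv, F1_la, F2_lv, F2_la).

    Each chamber field is supported on its own chamber block and is
    orthogonal to that block's translations and rotations.  Per-chamber
    *scaling* (volumetric) components are retained — they are genuine
    shape changes of the whole left heart — but are balanced between the
    two chambers of each mode (LV contracts while the LA fills, and vice
    versa) so that the combined field carries no global-scale component
    and therefore passes through Procrustes alignment untouched.  Mode 2
    is orthogonalized against mode 1 within each chamber so the two
    covarying pairs form matched orthonormal block bases and the planted
    LA:LV shape-change rate is exactly recoverable.
    """
    p = params
    k2 = base.shape[0]
    k = k2 // 2
    lv_rows = np.arange(k)
    la_rows = np.arange(k, k2)
    bc = base - base.mean(axis=0)
    z_lv_min = base[lv_rows, 2].min()  # LV apex level
    z_la_max = base[la_rows, 2].max()  # LA roof level
    mix = p.mode_mix
    s = p.la_scale

    # chamber-restricted unit scaling directions and their raw norms
    bc_lv = np.zeros((k2, 3))
    bc_lv[lv_rows] = bc[lv_rows]
    bc_la = np.zeros((k2, 3))
    bc_la[la_rows] = bc[la_rows]
    n_lv = np.linalg.norm(bc_lv)
    n_la = np.linalg.norm(bc_la)
    u_lv = bc_lv / n_lv
    u_la = bc_la / n_la

    def chamber_field(rows, affine, nonaffine):
        fa = np.zeros((k2, 3))
        fa[rows] = affine
        fn = np.zeros((k2, 3))
        fn[rows] = nonaffine
        f = np.zeros((k2, 3))
        if mix > 0:
            f = f + mix * _unit(fa)
        if mix < 1:
            f = f + (1 - mix) * _unit(fn)
        # remove chamber-restricted translations and rotations only
        return _unit(_horizontal_project(f, base, rows, with_scaling=False))

    xy_lv = base[lv_rows, :2]
    z_lv = base[lv_rows, 2]
    xy_la = base[la_rows, :2]
    z_la = base[la_rows, 2]

    # mode 1: LV systolic contraction / LA reservoir expansion
    aff_lv = -np.column_stack([xy_lv, 0.6 * z_lv])
    taper_lv = np.abs(z_lv) / abs(z_lv_min)  # stronger toward the apex
    na_lv = -np.column_stack([xy_lv * taper_lv[:, None], np.zeros(k)])
    f1_lv = chamber_field(lv_rows, aff_lv, na_lv)

    aff_la = np.column_stack([xy_la, 0.6 * z_la])
    taper_la = z_la / z_la_max
    na_la = np.column_stack([xy_la * taper_la[:, None], np.zeros(k)])
    f1_la = chamber_field(la_rows, aff_la, na_la)

    # mode 2: LV twist (with early-filling relaxation) / LA booster pump
    tw = (z_lv / z_lv_min)[:, None]
    twist = np.column_stack([-xy_lv[:, 1], xy_lv[:, 0], np.zeros(k)]) * tw
    shear_lv = np.column_stack([z_lv * 0.3, np.zeros(k), np.zeros(k)])
    f2_lv = chamber_field(lv_rows, shear_lv, twist)

    kick = -np.column_stack([xy_la * (0.2 + taper_la)[:, None], np.zeros(k)])
    aff_kick = -np.column_stack([xy_la, -0.3 * z_la])
    f2_la = chamber_field(la_rows, aff_kick, kick)

    # balance the volumetric components and orthogonalize the modes; the
    # two operations interact weakly, so iterate to a fixed point
    # mode 1: LA scaling compensates the LV contraction
    beta1_lv = float(np.sum(f1_lv * u_lv))
    f1_la = _set_scaling_component(f1_la, u_la,
                                   -beta1_lv * n_lv / (s * n_la))
    for _ in range(12):
        # mode-2 orthogonality to mode 1 within each chamber, then LV
        # scaling compensating the LA kick; the operations couple weakly
        f2_la = _unit(f2_la - np.sum(f2_la * f1_la) * f1_la)
        beta2_la = float(np.sum(f2_la * u_la))
        f2_lv = _set_scaling_component(f2_lv, u_lv,
                                       -s * beta2_la * n_la / n_lv)
        f2_lv = _unit(f2_lv - np.sum(f2_lv * f1_lv) * f1_lv)

    return f1_lv, f1_la, f2_lv, f2_la


def _activation(u: np.ndarray, peak: float, kappa: float) -> np.ndarray:
    """Smooth periodic activation bump on cycle fraction u in [0, 1),
    peaking at ``peak`` (von Mises shaped, ~0 far from the peak)."""
    return np.exp(kappa * (np.cos(2 * np.pi * (u - peak)) - 1.0))


def _homologous_phases(fractions) -> np.ndarray:
    """The 16 homologous cycle fractions implied by the four event phase
    fractions (3 equally spaced insertions per cyclic gap)."""
    f = list(fractions) + [fractions[0] + 1.0]
    out = []
    for a, b in zip(f[:-1], f[1:]):
        out.extend(a + (b - a) * np.array([0.0, 0.25, 0.5, 0.75]))
    return np.asarray(out) % 1.0


def _centered_activation_means(params: GeneratorParams) -> tuple[float, float]:
    """Mean activation of each mode over the 16 homologous phases.

    The deformation model subtracts these means so that the time-average
    of a cycle sits at the base geometry: the grand mean (common
    template) then coincides with the planted base shape and the tangent
    projection at it cannot leak a template-direction component into the
    planted covarying fields."""
    u = _homologous_phases(params.event_phase_fractions)
    fes = params.event_phase_fractions[1]
    fp = params.event_phase_fractions[3]
    m1 = float(_activation(u, fes, params.activation_kappa).mean())
    m2 = float(_activation(u, fp, params.activation_kappa).mean())
    return m1, m2


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, -1] *= -1
    return q


# ---------------------------------------------------------------------------
# cycles and cohorts
# ---------------------------------------------------------------------------

def generate_cycle(params: GeneratorParams, subject_seed: int,
                   subject_id: str = "S000", group: str = "Control"
                   ) -> ShapeCycle:
    """One subject's acquired cardiac cycle.

    LV contracts between the R peak and end-systole and re-expands
    through mitral-valve opening; the LA moves in anti-phase with its
    booster contraction at the P peak.  LA deformation magnitude is
    ``covariation_slope`` x the LV magnitude along the planted modes.
    Frames are sampled at the device frame interval with timing jitter;
    landmark noise is added last.  Deterministic for a given seed.
    """
    p = params
    rng = np.random.default_rng(subject_seed)
    base = generate_left_heart(p, rng)
    f1_lv, f1_la, f2_lv, f2_la = _deformation_fields(base, p)
    s = p.la_scale
    f1 = f1_lv + s * f1_la
    f2 = f2_lv + s * f2_la

    bpm = p.beat_rate_mean + p.beat_rate_sd * rng.normal()
    bpm = float(np.clip(bpm, 40.0, 140.0))
    T = 60000.0 / bpm
    fr, fes, fmvo, fp = p.event_phase_fractions
    events = {
        "R_peak": fr * T,
        "LV_end_systole": fes * T,
        "mitral_valve_opening": fmvo * T,
        "P_peak": fp * T,
    }

    n_frames = int(np.floor((T - 1e-6) / p.frame_interval_ms)) + 1
    times = np.arange(n_frames) * p.frame_interval_ms
    if p.frame_jitter_sd_ms > 0 and n_frames > 2:
        jit = p.frame_jitter_sd_ms * rng.normal(size=n_frames)
        jit[0] = 0.0
        times = times + jit
        for i in range(1, n_frames):  # keep strictly increasing
            times[i] = max(times[i], times[i - 1] + 0.5)
        times = times[times < T - 0.5]
    a1 = p.lv_amplitude * centroid_size(base)
    a2 = p.secondary_amplitude_frac * a1

    pose = _random_rotation(rng)
    shift = 50.0 * rng.normal(size=3)
    m1, m2 = _centered_activation_means(p)
    frames = np.empty((len(times), base.shape[0], 3))
    for i, t in enumerate(times):
        u = t / T
        g1 = _activation(u, fes, p.activation_kappa) - m1
        g2 = _activation(u, fp, p.activation_kappa) - m2
        x = base + a1 * g1 * f1 + a2 * g2 * f2
        frames[i] = x @ pose.T + shift
    if p.landmark_noise_sd > 0:
        frames = frames + p.landmark_noise_sd * rng.normal(size=frames.shape)
    return ShapeCycle(
        frames=frames,
        frame_times_ms=times,
        events=events,
        cycle_length_ms=T,
        subject_id=subject_id,
        group=group,
        chamber_labels=_labels(p.layout),
        layout=p.layout,
    )


def generate_cohort(
    n_control: int = 46,
    n_hcm: int = 20,
    control_params: GeneratorParams | None = None,
    hcm_params: GeneratorParams | None = None,
    seed: int = 0,
) -> tuple[list[ShapeCycle], dict]:
    """A two-group cohort of cardiac cycles plus a manifest of all
    generator parameters and per-subject seeds.  Default group contrasts:
    Control deforms more than HCM and their planted covariation slopes
    are 1.25 vs 0.89; default sizes 46 and 20."""
    cp = control_params or CONTROL_PARAMS
    hp = hcm_params or HCM_PARAMS
    ss = np.random.SeedSequence(seed)
    child = ss.spawn(n_control + n_hcm)
    cycles = []
    seeds = []
    for i in range(n_control):
        sseed = int(child[i].generate_state(1)[0] % (2 ** 31))
        seeds.append(sseed)
        cycles.append(generate_cycle(cp, sseed, f"C{i:03d}", "Control"))
    for i in range(n_hcm):
        sseed = int(child[n_control + i].generate_state(1)[0] % (2 ** 31))
        seeds.append(sseed)
        cycles.append(generate_cycle(hp, sseed, f"H{i:03d}", "HCM"))
    manifest = {
        "seed": seed,
        "n_control": n_control,
        "n_hcm": n_hcm,
        "control_params": asdict(cp),
        "hcm_params": asdict(hp),
        "subject_seeds": seeds,
        "subject_ids": [c.subject_id for c in cycles],
    }
    return cycles, manifest


def generate_self_similar_series(
    reference,
    n_shapes: int,
    law_exponent: float = -1.0,
    scale: float = 1.0,
    seed: int = 0,
    basis: PartialWarpBasis | None = None,
) -> np.ndarray:
    """Shape series with a planted partial-warp variance power law.

    Independent warp scores are drawn with total (3-D) variance
    ``scale * eigenvalue ** law_exponent``; ``law_exponent = -1`` gives a
    self-similar series (disintegration slope -1), 0 a disintegrated one.
    Returns an (n_shapes, k, 3) array.
    """
    if basis is None:
        basis = bending_energy_basis(reference)
    ref = basis.reference
    rng = np.random.default_rng(seed)
    m = ref.shape[1]
    sd = np.sqrt(scale * basis.eigenvalues ** law_exponent / m)
    scores = rng.normal(size=(n_shapes, basis.n_warps, m)) * sd[None, :, None]
    return ref[None] + np.einsum("kw,nwm->nkm", basis.eigenvectors, scores)
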