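"""Linear-shift parallel transport of within-cycle deformations.

Each subject's 16 homologous shapes are summarized by a local template
(LT, the shape-space GPA consensus of its own cycle); the whole sample is
summarized by a common template (CT, the consensus of every shape of
every subject — the grand mean of all time frames of all cycles).  The
linear shift moves each subject's deformations from its LT to the CT by
plain subtraction/addition in the Euclidean tangent plane at the CT:
starting inter-individual shape differences are removed and only the pure
within-cycle deformation survives, centered on the CT.

All transport arithmetic is performed in shape space (unit centroid
size): size is filtered out here and re-enters the analysis only through
the trajectory centroid size downstream.

Rotation management: a single rotation per subject — the one optimally
superimposing its LT on the CT — is applied to all 16 of its aligned
shapes before projection, keeping the within-subject deformation rigidly
coherent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import (
    gpa,
    optimal_rotation,
    preshape,
    tangent_project,
)
from .temporal import HomologousCycle, N_HOMOLOGOUS

__all__ = ["TransportedSet", "local_template", "linear_shift"]


@dataclass
class TransportedSet:
    """Deformation-only dataset after linear-shift transport.

    ``residuals[i, t]`` is subject *i*'s tangent-space deformation at
    homologous time *t*, expressed at the common template; the per-subject
    mean of the 16 residuals is zero by construction.
    """

    common_template: np.ndarray  # (k, 3) unit-CS consensus
    local_templates: np.ndarray  # (n, k, 3), rotated onto the CT
    residuals: np.ndarray  # (n, 16, k, 3)
    subject_ids: list
    groups: list
    chamber_labels: np.ndarray

    @property
    def n_subjects(self) -> int:
        return self.residuals.shape[0]

    @property
    def k(self) -> int:
        return self.residuals.shape[2]

    def transported_shapes(self) -> np.ndarray:
        """Transported configurations CT + residual, shape (n, 16, k, 3)."""
        return self.common_template[None, None] + self.residuals

    def flat_residuals(self) -> np.ndarray:
        """Residuals flattened to (n * 16, 3k), subject-major order."""
        n, t, k, m = self.residuals.shape
        return self.residuals.reshape(n * t, k * m)

    def chamber_columns(self, label: str) -> np.ndarray:
        """Boolean mask over the 3k flattened columns of one chamber."""
        return np.repeat(self.chamber_labels == label, 3)


def local_template(hcycle: HomologousCycle) -> np.ndarray:
    """Local template: shape-space GPA consensus of one subject's 16
    homologous shapes (unit centroid size)."""
    return gpa(list(hcycle.shapes), space="shape").consensus


def linear_shift(hcycles: Sequence[HomologousCycle]) -> TransportedSet:
    """Transport every subject's cycle deformations to the common template.

    Steps: per-subject shape-space GPA (local template = consensus); CT =
    shape-space GPA consensus of all shapes of all subjects pooled; one
    rotation per subject aligning its LT to the CT, applied to its 16
    aligned shapes; orthogonal tangent projection at the CT; per-subject
    re-centering so the local mean maps exactly to zero.
    """
    if len(hcycles) < 2:
        raise ValueError("linear shift needs at least 2 subjects")
    k = hcycles[0].k
    for h in hcycles:
        if h.shapes.shape[0] != N_HOMOLOGOUS:
            raise ValueError(
                f"subject {h.subject_id} has {h.shapes.shape[0]} shapes, "
                f"expected {N_HOMOLOGOUS}"
            )
        if h.k != k:
            raise ValueError("all subjects must share the landmark count")

    # per-subject GPA in shape space
    subject_aligned = []
    lts = []
    for h in hcycles:
        res = gpa(list(h.shapes), space="shape", canonical=False)
        subject_aligned.append(res.aligned)
        lts.append(res.consensus)

    # common template from the pooled sample of all shapes
    pool = [s for al in subject_aligned for s in al]
    ct = gpa(pool, space="shape").consensus
    p = preshape(ct)

    n = len(hcycles)
    residuals = np.empty((n, N_HOMOLOGOUS, k, 3))
    lts_rot = np.empty((n, k, 3))
    for i in range(n):
        rot = optimal_rotation(lts[i], p)
        lts_rot[i] = lts[i] @ rot
        shapes_rot = subject_aligned[i] @ rot
        proj = np.stack([tangent_project(s, p) for s in shapes_rot])
        residuals[i] = proj - proj.mean(axis=0)

    return TransportedSet(
        common_template=p,
        local_templates=lts_rot,
        residuals=residuals,
        subject_ids=[h.subject_id for h in hcycles],
        groups=[h.group for h in hcycles],
        chamber_labels=hcycles[0].chamber_labels,
    )
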