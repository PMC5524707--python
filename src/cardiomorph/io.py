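"""Dataset readers and writers.

On-disk layout of a cohort dataset:

* ``landmarks.csv`` — long form, one row per landmark per frame:
  ``subject_id, frame_index, time_ms, chamber, circle_index, point_index,
  x, y, z``; the apex is encoded ``circle_index = -1, point_index = 0``.
* ``events.json`` — list of ``{subject_id, group, cycle_length_ms,
  events: {R_peak, LV_end_systole, mitral_valve_opening, P_peak}}``.
* optionally ``manifest.json`` — generator parameters and seeds.

Floats are written with fixed ``%.6f`` formatting so output is
byte-stable; a write -> read -> write round trip reproduces the files
bit-identically.  Homologous cycles reuse the same CSV dialect with
``frame_index`` replaced by ``homologous_index`` plus a ``strict`` flag
column.  Transported datasets are stored as a compressed ``.npz`` array
container plus a JSON manifest.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ChamberLayout, EVENT_NAMES, ShapeCycle
from .temporal import HomologousCycle, STRICT_INDICES
from .transport import TransportedSet

__all__ = [
    "write_dataset",
    "read_dataset",
    "write_homologous",
    "read_homologous",
    "write_transported",
    "read_transported",
    "SchemaError",
]

LANDMARK_COLUMNS = ["subject_id", "frame_index", "time_ms", "chamber",
                    "circle_index", "point_index", "x", "y", "z"]
HOMOLOGOUS_COLUMNS = ["subject_id", "homologous_index", "time_ms", "strict",
                      "chamber", "circle_index", "point_index", "x", "y", "z"]
FLOAT_FMT = "%.6f"


class SchemaError(ValueError):
    """Dataset file violates the expected schema."""


def _layout_index(layout: ChamberLayout):
    """(circle_index, point_index) pairs in canonical row order for one
    chamber: circles base -> apexward, then the apex row (-1, 0)."""
    circ = np.repeat(np.arange(layout.n_circles), layout.n_per_circle)
    pt = np.tile(np.arange(layout.n_per_circle), layout.n_circles)
    if layout.has_apex:
        circ = np.append(circ, -1)
        pt = np.append(pt, 0)
    return circ, pt


def _cycle_frame(cycle: ShapeCycle) -> pd.DataFrame:
    layout = cycle.layout
    circ1, pt1 = _layout_index(layout)
    k = layout.n_landmarks
    circ = np.concatenate([circ1, circ1])
    pt = np.concatenate([pt1, pt1])
    rows = []
    for fi, (t, frame) in enumerate(zip(cycle.frame_times_ms, cycle.frames)):
        rows.append(pd.DataFrame({
            "subject_id": cycle.subject_id,
            "frame_index": fi,
            "time_ms": t,
            "chamber": cycle.chamber_labels,
            "circle_index": circ,
            "point_index": pt,
            "x": frame[:, 0], "y": frame[:, 1], "z": frame[:, 2],
        }))
    return pd.concat(rows, ignore_index=True)


def write_dataset(cycles, path, manifest: dict | None = None) -> dict:
    """Write a cohort to ``path``/landmarks.csv + events.json
    (+ manifest.json).  Returns the file paths written."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    df = pd.concat([_cycle_frame(c) for c in cycles], ignore_index=True)
    csv_path = path / "landmarks.csv"
    df.to_csv(csv_path, index=False, float_format=FLOAT_FMT)
    meta = [
        {
            "subject_id": c.subject_id,
            "group": c.group,
            "cycle_length_ms": round(float(c.cycle_length_ms), 6),
            "events": {k: round(float(v), 6) for k, v in c.events.items()},
        }
        for c in cycles
    ]
    events_path = path / "events.json"
    events_path.write_text(json.dumps(meta, indent=1, sort_keys=True) + "\n")
    out = {"landmarks": str(csv_path), "events": str(events_path)}
    if manifest is not None:
        man_path = path / "manifest.json"
        man_path.write_text(json.dumps(manifest, indent=1, sort_keys=True,
                                       default=str) + "\n")
        out["manifest"] = str(man_path)
    return out


def _validate_columns(df: pd.DataFrame, expected, where: str) -> None:
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise SchemaError(f"{where}: missing columns {missing}")


def _canonical_block(sub: pd.DataFrame, layout: ChamberLayout,
                     subject: str) -> np.ndarray:
    """Order one frame's rows canonically (LV block then LA block, circles
    then apex) and return the (k, 3) coordinates."""
    k = layout.n_landmarks
    parts = []
    for chamber in ("LV", "LA"):
        ch = sub[sub["chamber"] == chamber]
        if len(ch) != k:
            raise SchemaError(
                f"subject {subject}: chamber {chamber} has {len(ch)} rows, "
                f"expected {k}"
            )
        # apex (-1) sorts first; rotate it to the end
        ch = ch.sort_values(["circle_index", "point_index"], kind="mergesort")
        ch = pd.concat([ch[ch["circle_index"] >= 0], ch[ch["circle_index"] < 0]])
        parts.append(ch[["x", "y", "z"]].to_numpy(dtype=float))
    return np.vstack(parts)


def read_dataset(path, layout: ChamberLayout | None = None) -> list[ShapeCycle]:
    """Read a cohort dataset back into ShapeCycles.

    Validates the schema strictly (column names, landmark counts per
    chamber, event completeness) and normalizes arbitrary row order to
    the canonical chamber-block order.
    """
    path = Path(path)
    df = pd.read_csv(path / "landmarks.csv")
    _validate_columns(df, LANDMARK_COLUMNS, "landmarks.csv")
    meta = json.loads((path / "events.json").read_text())
    by_subject = {m["subject_id"]: m for m in meta}
    if layout is None:
        n_per_circle = int(df["point_index"].max()) + 1
        n_circles = int(df["circle_index"].max()) + 1
        layout = ChamberLayout(n_circles, n_per_circle,
                               bool((df["circle_index"] < 0).any()))
    labels = np.array(["LV"] * layout.n_landmarks + ["LA"] * layout.n_landmarks)
    cycles = []
    for subject, sdf in df.groupby("subject_id", sort=False):
        subject = str(subject)
        if subject not in by_subject:
            raise SchemaError(f"subject {subject} missing from events.json")
        m = by_subject[subject]
        events = m.get("events", {})
        missing = [e for e in EVENT_NAMES if e not in events]
        if missing:
            raise SchemaError(f"subject {subject}: missing events {missing}")
        frames = []
        times = []
        for fi, fdf in sdf.groupby("frame_index", sort=True):
            t = fdf["time_ms"].unique()
            if len(t) != 1:
                raise SchemaError(
                    f"subject {subject} frame {fi}: inconsistent time_ms")
            times.append(float(t[0]))
            frames.append(_canonical_block(fdf, layout, subject))
        cycles.append(ShapeCycle(
            frames=np.stack(frames),
            frame_times_ms=np.array(times),
            events={k: float(v) for k, v in events.items()},
            cycle_length_ms=float(m["cycle_length_ms"]),
            subject_id=subject,
            group=str(m["group"]),
            chamber_labels=labels,
            layout=layout,
        ))
    return cycles


def write_homologous(hcycles, path) -> str:
    """Write homologous cycles as CSV (same dialect as landmarks.csv with
    homologous_index 0-15 and a strict-event flag)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for h in hcycles:
        layout = h.layout
        circ1, pt1 = _layout_index(layout)
        circ = np.concatenate([circ1, circ1])
        pt = np.concatenate([pt1, pt1])
        for hi in range(h.shapes.shape[0]):
            rows.append(pd.DataFrame({
                "subject_id": h.subject_id,
                "homologous_index": hi,
                "time_ms": h.homologous_times_ms[hi],
                "strict": int(hi in STRICT_INDICES),
                "chamber": h.chamber_labels,
                "circle_index": circ,
                "point_index": pt,
                "x": h.shapes[hi, :, 0],
                "y": h.shapes[hi, :, 1],
                "z": h.shapes[hi, :, 2],
            }))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False,
                                              float_format=FLOAT_FMT)
    return str(path)


def read_homologous(path, meta: list[dict],
                    layout: ChamberLayout | None = None) -> list[HomologousCycle]:
    """Read homologous cycles written by :func:`write_homologous`;
    ``meta`` supplies subject groups (events.json content)."""
    df = pd.read_csv(path)
    _validate_columns(df, HOMOLOGOUS_COLUMNS, str(path))
    by_subject = {m["subject_id"]: m for m in meta}
    if layout is None:
        layout = ChamberLayout(int(df["circle_index"].max()) + 1,
                               int(df["point_index"].max()) + 1,
                               bool((df["circle_index"] < 0).any()))
    labels = np.array(["LV"] * layout.n_landmarks + ["LA"] * layout.n_landmarks)
    out = []
    for subject, sdf in df.groupby("subject_id", sort=False):
        subject = str(subject)
        shapes = []
        times = []
        for hi, fdf in sdf.groupby("homologous_index", sort=True):
            times.append(float(fdf["time_ms"].iloc[0]))
            shapes.append(_canonical_block(fdf, layout, subject))
        out.append(HomologousCycle(
            shapes=np.stack(shapes),
            homologous_times_ms=np.array(times),
            strict_indices=STRICT_INDICES,
            subject_id=subject,
            group=str(by_subject[subject]["group"]),
            chamber_labels=labels,
            layout=layout,
        ))
    return out


def write_transported(ts: TransportedSet, path) -> dict:
    """Store a transported dataset: arrays in ``<path>.npz``, subject
    order / groups / template checksum in ``<path>.json``."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    npz = path.with_suffix(".npz")
    np.savez_compressed(
        npz,
        common_template=ts.common_template,
        local_templates=ts.local_templates,
        residuals=ts.residuals,
        chamber_labels=ts.chamber_labels.astype(str),
    )
    checksum = hashlib.sha256(
        np.ascontiguousarray(ts.common_template).tobytes()).hexdigest()
    man = path.with_suffix(".json")
    man.write_text(json.dumps({
        "subject_ids": list(ts.subject_ids),
        "groups": list(ts.groups),
        "n_subjects": ts.n_subjects,
        "k": ts.k,
        "common_template_sha256": checksum,
    }, indent=1) + "\n")
    return {"arrays": str(npz), "manifest": str(man)}


def read_transported(path) -> TransportedSet:
    path = Path(path)
    with np.load(path.with_suffix(".npz")) as z:
        arrays = {k: z[k] for k in z.files}
    man = json.loads(path.with_suffix(".json").read_text())
    return TransportedSet(
        common_template=arrays["common_template"],
        local_templates=arrays["local_templates"],
        residuals=arrays["residuals"],
        subject_ids=man["subject_ids"],
        groups=man["groups"],
        chamber_labels=arrays["chamber_labels"],
    )
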