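"""End-to-end pipeline driver.

Runs simulate -> interpolate -> transport -> trajectory -> covary ->
disintegrate -> classify from one structured configuration, with every
stochastic stage seeded from a single master seed.  Each stage writes its
table/array outputs under the output directory and records a checksum in
the report; with ``resume: true`` stages whose outputs already exist are
loaded from disk instead of recomputed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .classification import randomized_svm_eval
from .covariation import individual_covariation, trajectory_covariation
from .disintegration import bending_energy_basis, disintegration_slope
from .synthetic import CONTROL_PARAMS, HCM_PARAMS, GeneratorParams, generate_cohort
from .temporal import interpolate_cycle
from .transport import TransportedSet, linear_shift
from .trajectory import (
    pca_shapes,
    perm_anova,
    trajectories_from_transport,
    trajectory_shape_analysis,
)

__all__ = ["run_pipeline", "default_config", "chamber_transport"]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "interpolate", "transport", "trajectory", "covary",
          "disintegrate", "classify")


def default_config() -> dict:
    return {
        "seed": 0,
        "resume": False,
        "stages": list(STAGES),
        "cohort": {
            "n_control": 46,
            "n_hcm": 20,
            "control": {},  # GeneratorParams overrides
            "hcm": {},
        },
        "analysis": {
            "n_perm_anova": 9999,
            "n_perm_pls": 999,
            "trajectory_covariation": {"n_perm": 199, "inner_perm": 99},
            "svm": {"n_train": None, "n_reps": 1000},
        },
    }


def _merged(config: dict | None) -> dict:
    base = default_config()
    if config:
        for key, val in config.items():
            if isinstance(val, dict) and isinstance(base.get(key), dict):
                for k2, v2 in val.items():
                    if isinstance(v2, dict) and isinstance(base[key].get(k2), dict):
                        base[key][k2].update(v2)
                    else:
                        base[key][k2] = v2
            else:
                base[key] = val
    return base


def _validate(cfg: dict) -> None:
    errors = []
    co = cfg["cohort"]
    if co["n_control"] < 2 or co["n_hcm"] < 2:
        errors.append("cohort: need at least 2 subjects per group")
    unknown = set(cfg["stages"]) - set(STAGES)
    if unknown:
        errors.append(f"unknown stages: {sorted(unknown)}")
    if errors:
        raise ValueError("invalid configuration: " + "; ".join(errors))


def _sha(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _params(overrides: dict, base: GeneratorParams) -> GeneratorParams:
    return replace(base, **overrides) if overrides else base


def chamber_transport(hcycles, chamber: str) -> TransportedSet:
    """Run the linear shift on a single chamber extracted from whole-LH
    homologous cycles (for per-chamber trajectory analyses)."""
    from .temporal import HomologousCycle

    singles = []
    for h in hcycles:
        sel = h.chamber_labels == chamber
        singles.append(HomologousCycle(
            shapes=h.shapes[:, sel, :],
            homologous_times_ms=h.homologous_times_ms,
            strict_indices=h.strict_indices,
            subject_id=h.subject_id,
            group=h.group,
            chamber_labels=h.chamber_labels[sel],
            layout=h.layout,
        ))
    return linear_shift(singles)


def run_pipeline(config: dict | None = None, out_dir="pipeline_out") -> dict:
    """Execute the configured stages; returns the report dictionary
    (also written as ``report.json``)."""
    cfg = _merged(config)
    _validate(cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    rng = np.random.default_rng(seed)
    stage_seeds = {s: int(rng.integers(2 ** 31)) for s in STAGES}
    resume = bool(cfg["resume"])
    stages = cfg["stages"]
    report = {"seed": seed, "config": cfg, "stages": {}, "checksums": {}}

    # --- simulate -----------------------------------------------------
    data_dir = out / "dataset"
    cycles = None
    if "simulate" in stages:
        if resume and (data_dir / "landmarks.csv").exists():
            logger.info("simulate: using cached dataset")
            cycles = cio.read_dataset(data_dir)
        else:
            co = cfg["cohort"]
            cp = _params(co.get("control", {}), CONTROL_PARAMS)
            hp = _params(co.get("hcm", {}), HCM_PARAMS)
            cycles, manifest = generate_cohort(
                co["n_control"], co["n_hcm"], cp, hp,
                seed=stage_seeds["simulate"])
            cio.write_dataset(cycles, data_dir, manifest)
        report["stages"]["simulate"] = {
            "n_subjects": len(cycles),
            "seed": stage_seeds["simulate"],
        }
        report["checksums"]["landmarks.csv"] = _sha(data_dir / "landmarks.csv")
    elif any(s in stages for s in STAGES[1:]):
        cycles = cio.read_dataset(data_dir)

    # --- interpolate --------------------------------------------------
    hpath = out / "homologous.csv"
    hcycles = None
    if "interpolate" in stages:
        if resume and hpath.exists():
            logger.info("interpolate: using cached homologous cycles")
            meta = json.loads((data_dir / "events.json").read_text())
            hcycles = cio.read_homologous(hpath, meta)
        else:
            hcycles = [interpolate_cycle(c) for c in cycles]
            cio.write_homologous(hcycles, hpath)
        report["stages"]["interpolate"] = {"n_subjects": len(hcycles)}
        report["checksums"]["homologous.csv"] = _sha(hpath)
    elif any(s in stages for s in STAGES[2:]):
        meta = json.loads((data_dir / "events.json").read_text())
        hcycles = cio.read_homologous(hpath, meta)

    # --- transport ----------------------------------------------------
    tpath = out / "transported"
    ts = None
    if "transport" in stages:
        if resume and tpath.with_suffix(".npz").exists():
            ts = cio.read_transported(tpath)
        else:
            ts = linear_shift(hcycles)
            cio.write_transported(ts, tpath)
        report["stages"]["transport"] = {"n_subjects": ts.n_subjects, "k": ts.k}
        report["checksums"]["transported"] = hashlib.sha256(
            np.ascontiguousarray(ts.residuals).tobytes()).hexdigest()
    elif any(s in stages for s in STAGES[3:]):
        ts = cio.read_transported(tpath)

    groups = None if ts is None else np.asarray(ts.groups)
    n_anova = cfg["analysis"]["n_perm_anova"]

    # --- trajectory ---------------------------------------------------
    attr_path = out / "trajectory_attributes.csv"
    trajs = None
    if "trajectory" in stages:
        pca_res = pca_shapes(ts)
        trajs = trajectories_from_transport(ts)
        consensus, traj_pca = trajectory_shape_analysis(trajs)
        n_pc = min(10, traj_pca.scores.shape[1])
        table = pd.DataFrame({
            "subject_id": ts.subject_ids,
            "group": ts.groups,
            "traj_cs": [t.cs for t in trajs],
            "angle_12": [t.angle_12 for t in trajs],
            "angle_13": [t.angle_13 for t in trajs],
        })
        for j in range(n_pc):
            table[f"traj_shape_pc{j + 1}"] = traj_pca.scores[:, j]
        table.to_csv(attr_path, index=False, float_format="%.6f")
        tests = {}
        sd = stage_seeds["trajectory"]
        for col, name in [("traj_cs", "cs"), ("angle_12", "angle_12"),
                          ("angle_13", "angle_13")]:
            r2, p = perm_anova(table[col].to_numpy(), groups, n_anova, sd)
            tests[name] = {"R_sq": r2, "p": p}
        r2, p = perm_anova(traj_pca.scores[:, :n_pc], groups, n_anova, sd)
        tests["shape_manova"] = {"R_sq": r2, "p": p}
        report["stages"]["trajectory"] = {
            "explained_variance_pc123":
                [float(v) for v in pca_res.explained_variance_ratio[:3]],
            "group_tests": tests,
            "mean_cs_by_group": {
                g: float(table.loc[table.group == g, "traj_cs"].mean())
                for g in np.unique(groups)},
        }
        report["checksums"]["trajectory_attributes.csv"] = _sha(attr_path)

    # --- covary -------------------------------------------------------
    if "covary" in stages:
        npls = cfg["analysis"]["n_perm_pls"]
        sd = stage_seeds["covary"]
        zs, slopes = [], []
        for i in range(ts.n_subjects):
            z, sl = individual_covariation(ts, i, n_perm=npls, seed=sd + i)
            zs.append(z)
            slopes.append(sl)
        cov_table = pd.DataFrame({
            "subject_id": ts.subject_ids, "group": ts.groups,
            "z_score": zs, "ma_slope": slopes,
        })
        cov_path = out / "covariation.csv"
        cov_table.to_csv(cov_path, index=False, float_format="%.6f")
        r2_z, p_z = perm_anova(np.array(zs), groups, n_anova, sd)
        r2_s, p_s = perm_anova(np.array(slopes), groups, n_anova, sd)
        # second-order level: covariation between trajectory shapes of the
        # two chambers analyzed separately
        tc_cfg = cfg["analysis"]["trajectory_covariation"]
        ts_lv = chamber_transport(hcycles, "LV")
        ts_la = chamber_transport(hcycles, "LA")
        lv_trajs = trajectories_from_transport(ts_lv)
        la_trajs = trajectories_from_transport(ts_la)
        tc = trajectory_covariation(
            lv_trajs, la_trajs, groups,
            n_perm=tc_cfg["n_perm"], inner_perm=tc_cfg["inner_perm"],
            seed=sd)
        group_report = {
            "individual": {
                "mean_z_by_group": {
                    g: float(np.mean([z for z, gg in zip(zs, groups) if gg == g]))
                    for g in np.unique(groups)},
                "mean_slope_by_group": {
                    g: float(np.mean([s for s, gg in zip(slopes, groups) if gg == g]))
                    for g in np.unique(groups)},
                "z_anova": {"R_sq": r2_z, "p": p_z},
                "slope_anova": {"R_sq": r2_s, "p": p_s},
            },
            "trajectory_level": {
                "z_by_group": {k: float(v) for k, v in tc.z_by_group.items()},
                "slope_by_group": {k: float(v) for k, v in tc.slope_by_group.items()},
                "z_difference_p": tc.z_difference_p,
                "slope_difference_p": tc.slope_difference_p,
                "pct_covariance_by_group":
                    {k: float(v) for k, v in tc.pct_covariance_by_group.items()},
            },
        }
        (out / "covariation_group.json").write_text(
            json.dumps(group_report, indent=1, sort_keys=True) + "\n")
        report["stages"]["covary"] = group_report
        report["checksums"]["covariation.csv"] = _sha(cov_path)

    # --- disintegrate -------------------------------------------------
    if "disintegrate" in stages:
        basis = bending_energy_basis(ts.common_template)
        rows = []
        for i in range(ts.n_subjects):
            shapes = ts.common_template[None] + ts.residuals[i]
            rows.append({
                "subject_id": ts.subject_ids[i],
                "group": ts.groups[i],
                "slope": disintegration_slope(shapes, basis),
            })
        dis = pd.DataFrame(rows)
        dis_path = out / "disintegration.csv"
        dis.to_csv(dis_path, index=False, float_format="%.6f")
        r2, p = perm_anova(dis["slope"].to_numpy(), groups, n_anova,
                           stage_seeds["disintegrate"])
        report["stages"]["disintegrate"] = {
            "mean_slope_by_group": {
                g: float(dis.loc[dis.group == g, "slope"].mean())
                for g in np.unique(groups)},
            "slope_anova": {"R_sq": r2, "p": p},
        }
        report["checksums"]["disintegration.csv"] = _sha(dis_path)

    # --- classify -----------------------------------------------------
    if "classify" in stages:
        svm_cfg = cfg["analysis"]["svm"]
        table = pd.read_csv(attr_path) if trajs is None else None
        attrs = pd.read_csv(attr_path)
        cov = pd.read_csv(out / "covariation.csv")
        pca_res = pca_shapes(ts)
        n = ts.n_subjects
        scores3 = pca_res.scores[:, :3].reshape(n, 16, 3)
        feature_sets = {
            "ls_pc1_all_times": scores3[:, :, 0],
            "ls_pc123_all_times": scores3.reshape(n, 48),
            "trajectory_size": attrs[["traj_cs"]].to_numpy(),
            "trajectory_angle_12": attrs[["angle_12"]].to_numpy(),
            "trajectory_angle_13": attrs[["angle_13"]].to_numpy(),
            "trajectory_shape_pcs": attrs[
                [c for c in attrs.columns if c.startswith("traj_shape_pc")]
            ].to_numpy(),
            "covariation_direction": cov[["ma_slope"]].to_numpy(),
        }
        n_train = svm_cfg.get("n_train")
        if n_train is None:
            counts = {g: int((groups == g).sum()) for g in ("Control", "HCM")}
            n_train = (max(2, int(round(0.76 * counts["Control"]))),
                       max(2, int(round(0.85 * counts["HCM"]))))
        metrics = {}
        for name, feats in feature_sets.items():
            res = randomized_svm_eval(
                feats, groups, n_train=tuple(n_train),
                n_reps=svm_cfg["n_reps"], seed=stage_seeds["classify"])
            metrics[name] = {
                "AUC": res.auc, "total_accuracy": res.total_accuracy,
                "specificity": res.specificity, "sensitivity": res.sensitivity,
            }
        (out / "classification.json").write_text(
            json.dumps(metrics, indent=1, sort_keys=True) + "\n")
        report["stages"]["classify"] = metrics

    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=1, sort_keys=True,
                                      default=str) + "\n")
    return report
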