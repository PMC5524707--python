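# cardiomorph

Geometric-morphometric analysis of time-resolved left-heart landmark
clouds: the left ventricle (LV) and left atrium (LA) acquired on the
same heartbeat, treated as one shape, and analyzed for motion-trajectory
attributes and inter-chamber covariation. The package targets
researchers working with 3D speckle-tracking echocardiography (3DSTE)
endocardial landmark exports — or any time-resolved landmark data of two
coupled anatomical modules — who want to contrast healthy and diseased
(e.g. hypertrophic cardiomyopathy, HCM) cohorts beyond scalar strain
indices.

Because patient landmark exports are rarely shareable, the package
includes a first-class synthetic cohort generator that emulates the
acquisition (two stacked quasi-ellipsoidal chamber surfaces of 36×36+1 =
1297 landmarks each, beating periodically with tunable group contrasts),
so the whole pipeline is testable and demonstrable end to end.

## Method

Input: per subject, one cardiac cycle of k = 2594 landmarks (1297 LV +
1297 LA) with frame times and four annotated electro-mechanical events
(ECG R peak, LV end-systole, mitral-valve opening, P peak).

1. **Homologous times.** Between consecutive events (cyclically) three
   equally spaced times are inserted: 16 physiologically homologous
   times per beat. Frames are superimposed by generalized Procrustes
   analysis (GPA) in size-and-shape space and each landmark coordinate
   is resampled at the 16 times with a periodic cubic spline.
2. **Linear-shift parallel transport.** Per subject, a local template
   LT (shape-space GPA consensus of its 16 shapes); for the sample, a
   common template CT (consensus of all shapes of all subjects). Each
   subject's deformations are moved from its LT to the CT by subtraction
   and addition in the tangent plane at CT — inter-individual baseline
   shape differences are filtered out, leaving pure deformation.
3. **Trajectories.** PCA over all transported deformations; each
   subject's motion trajectory is the 16×3 configuration of its first
   three PC scores, with attributes: trajectory centroid size CS,
   end-diastole→end-systole chord angles in the PC1/PC2 and PC1/PC3
   planes, and trajectory *shape* (GPA + PCA on the 16×3
   configurations). Group contrasts use permutation ANOVA/MANOVA
   (R² = SSB/SST with label shuffling).
4. **Covariation.** Per subject, two-block partial least squares (PLS)
   of its 16 LV shapes vs 16 LA shapes: the singular-warp (SW)
   decomposition of the LV–LA cross-covariance. Strength = permutation
   z-score of the first paired-score correlation; direction =
   major-axis (MA) regression slope of SW1_LA on SW1_LV (slope > 1: LA
   changes faster per unit LV shape change; 1 = isometry). A
   second-order analysis links LV and LA *trajectory shapes* across
   subjects within each group.
5. **Disintegration.** Thin-plate-spline bending-energy eigenanalysis
   of the common template (3-D kernel U(r) = −r); per subject, the OLS
   slope of log partial-warp variance on log bending energy (−1 =
   self-similar, more negative = more integrated, ≈0 = disintegrated).
6. **Classification.** Any derived feature table is evaluated by a
   randomized-split SVM (RBF kernel, C = 1): repeated stratified
   training draws, held-out evaluation, mean AUC / accuracy /
   specificity / sensitivity.

## Worked example

Run the full pipeline on a synthetic cohort of 10 Control and 8
HCM-like subjects (Control planted with larger deformation amplitude
and LA:LV covariation rate 1.25; HCM-like with 0.89):

```python
from cardiomorph.pipeline import run_pipeline

report = run_pipeline({
    "seed": 7,
    "cohort": {"n_control": 10, "n_hcm": 8},
    "analysis": {
        "n_perm_anova": 999,
        "n_perm_pls": 499,
        "trajectory_covariation": {"n_perm": 99, "inner_perm": 99},
        "svm": {"n_train": (7, 6), "n_reps": 200},
    },
}, "pipeline_out")
```

Selected output (from `report.json`):

```
trajectory.explained_variance_pc123   [0.679, 0.060, 0.006]
trajectory.mean_cs_by_group           Control 0.2455   HCM 0.1361
trajectory.group_tests.cs             R_sq 0.9998  p 0.001
covary.individual.mean_slope_by_group Control 1.2444   HCM 0.8942
covary.individual.mean_z_by_group     Control 5.77     HCM 5.08
covary.individual.slope_anova         R_sq 0.9992  p 0.001
covary.individual.z_anova             R_sq 0.5696  p 0.003
classify.ls_pc123_all_times           AUC 1.00  accuracy 1.00
```

Reading: PC1 carries ~68% of the deformation variance (the alternating
systo-diastolic axis); the Control trajectories sweep more morphospace
(larger trajectory CS); the planted covariation *direction* contrast is
recovered almost exactly (slopes 1.24 vs 0.89, strongly significant)
while the covariation *strength* z-scores are similar in magnitude for
both groups. On this noise-free-by-construction contrast the SVM
separates the groups perfectly; real cohorts are messier.

The same stages are available from the shell:

```sh
cardiomorph --seed 7 --out-dir run simulate
cardiomorph --out-dir run run-all
```

## Layout

| module | contents |
|---|---|
| `cardiomorph.core` | landmark types, centroid size, OPA/GPA, Procrustes distance, tangent maps |
| `cardiomorph.temporal` | homologous times, periodic spline resampling |
| `cardiomorph.transport` | local/common templates, linear-shift transport |
| `cardiomorph.trajectory` | PCA, trajectory attributes, permutation ANOVA |
| `cardiomorph.covariation` | two-block PLS, effect sizes, major-axis slopes |
| `cardiomorph.disintegration` | TPS bending energy, partial warps, slopes |
| `cardiomorph.classification` | randomized SVM, reproducibility utilities |
| `cardiomorph.synthetic` | 4D left-heart cohort generator |
| `cardiomorph.io` / `cli` / `pipeline` | CSV/JSON formats, CLI, pipeline driver |

See `docs/methods.md` for the modeling assumptions, parameter defaults
and known limitations.
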