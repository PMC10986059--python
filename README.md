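# chorioquant

Quantification of choroidal vascularity and choriocapillaris perfusion from
OCT/OCTA images, with a synthetic ground-truth generator and the
repeated-measures cohort statistics needed to study short-term choroidal
responses — for example to sustained near work in myopic children and
adults.

The choroid supplies the outer retina, and its vascular status is read out
at two depths:

* **Structural B-scans** — the choroid band between Bruch's membrane (BM)
  and the choroid–sclera interface is binarized with **Niblack's local
  threshold** (`T(x,y) = μ_w + k·σ_w` over a window `w`, lumen iff
  `I < T`), yielding over a 6-mm submacular region centered on the fovea:
  subfoveal choroidal thickness (SFCT), luminal / stromal / total choroidal
  areas (LA, SA, TCA = LA + SA), and the **choroidal vascularity index**
  `CVI = 100 · LA / TCA`. Vertical- and horizontal-meridian metrics are
  averaged field by field.
* **En-face OCTA** — the choriocapillaris slab (BM to 20 µm below) is
  compensated for shadow and retinal-vessel projection artifacts, and the
  **flow-deficit percentage** `CcFD = 100 · #(I < 1.5·σ_ref) / #ROI` is
  computed in a 2.5-mm foveal circle, with `σ_ref ≈ 30` gray levels from a
  normative database.

Both measurements correct ocular magnification by Bennett's abbreviated
axial-length scaling, `q ∝ (AL − 1.82 mm)`, relative to a reference eye of
24.385 mm.

Because no suitable public image sets exist, the package ships a
first-class synthetic-data module: speckled B-scans whose true lumen mask
and areas are known by construction, en-face angiograms with known deficit
fraction and optional shadow/projection artifacts, and two-cohort
longitudinal metric tables with configurable effect sizes. Every estimator
is validated against that ground truth.

## Worked example

```python
from chorioquant import (SceneParams, generate_bscan_scene, ChoroidBoundaries,
                         ScanGeometry, quantify_bscan, AngioParams,
                         generate_cc_enface, EnFaceAngio, compute_ccfd)

img, truth = generate_bscan_scene(SceneParams(target_lumen_fraction=0.62, seed=7))
bounds = ChoroidBoundaries(truth.upper_boundary_px, truth.lower_boundary_px)
geom = ScanGeometry(lateral_um_per_px=5.86, axial_um_per_px=3.9,
                    fovea_col=truth.fovea_col, al_mm=25.0)
m = quantify_bscan(img, bounds, geom)
print(f"SFCT = {m.SFCT:.1f} um")
print(f"LA   = {m.LA/1e3:.1f} x10^3 um^2")
print(f"TCA  = {m.TCA/1e3:.1f} x10^3 um^2")
print(f"CVI  = {m.CVI:.2f} %   (truth {truth.true_CVI:.2f} %)")

aimg, atruth = generate_cc_enface(AngioParams(target_fd_fraction=0.08, seed=7))
res = compute_ccfd(EnFaceAngio(aimg, 5.86), al_mm=25.0)
print(f"CcFD = {res.ccfd_pct:.2f} %  (truth {100*atruth.fd_fraction:.2f} %)")
```

prints

```
SFCT = 249.6 um
LA   = 1010.5 x10^3 um^2
TCA  = 1621.1 x10^3 um^2
CVI  = 62.33 %   (truth 62.10 %)
CcFD = 8.07 %  (truth 8.06 %)
```

The estimated CVI lands within a quarter of a percentage point of the
generator's pixel-counted truth, and the flow-deficit percentage within a
few hundredths; areas are reported on the magnification-corrected scale for
the 25.0-mm eye, which is why they sit ~2.7 % above the nominal-scale
truth values. `TCA = LA + SA` holds exactly.

The statistical layer follows the same two-object pattern as statsmodels:

```python
from chorioquant import CohortSimParams, generate_cohort, NearWorkChangeModel

cohort = generate_cohort(CohortSimParams(n_per_group=30, seed=1))
res = NearWorkChangeModel.from_dataframe(cohort, "LA").fit()
print(res.contrast)        # AL-adjusted child-minus-adult % change difference
print(res.summary())       # full coefficient table, cluster-robust SEs
```

## Command line

```bash
chorioquant run-all --seed 1 --out runs/demo          # simulate -> quantify -> analyze
chorioquant simulate --config my_config.yaml
chorioquant quantify runs/demo --out runs/demo
chorioquant analyze runs/demo/cohort.csv --out runs/demo
```

A run directory contains the images with JSON truth sidecars, a
`manifest.json` naming every file and seed, per-visit metric CSVs
(`structural_metrics.csv`, `ccfd_metrics.csv`), the cohort table, and the
statistical report (`trend_table.csv`, `time_effect.csv`,
`group_contrast.csv`, `report.txt`). One seed drives every stochastic
stage; two runs with the same config are byte-identical.

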