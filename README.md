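# petkinetics

Patlak parametric imaging and framing-protocol evaluation for dynamic
<sup>18</sup>F-FDG PET.

Long-axial-field-of-view scanners make 0–60 min whole-body dynamic FDG
imaging routine, and voxelwise Patlak analysis turns those scans into
quantitative net-influx-rate (K<sub>i</sub>) images. A practical question
for any such protocol is how coarsely the hour may be framed: sparser
framing means fewer reconstructions and less data, but it undersamples
the arterial bolus and can bias the image-derived input function (IDIF)
and hence the parametric maps. `petkinetics` implements the full workflow
needed to study this trade-off — and a synthetic dynamic phantom so the
whole pipeline is testable without patient data:

* **Framing schedules** — six preset protocols covering 3600 s with 100,
  61, 48, 29, 19 and 12 frames, plus arbitrary user schedules.
* **Rebinning** — overlap-duration-weighted rebinning of 4D dynamics or
  time–activity curves (TACs) onto any coarser protocol.
* **IDIF extraction** — cylindrical descending-aorta ROI (default 4-mm
  transversal radius) around a supplied centerline; AUC and
  cross-protocol input-function resampling.
* **Patlak analysis** — ROI fits and fully vectorized voxelwise
  K<sub>i</sub>/intercept/SSE maps.
* **Evaluation** — ROI statistics, absolute/relative differences,
  Bland–Altman limits, correlation, paired t-tests and variance F-tests,
  and a protocol-comparison report against a reference protocol.
* **Synthetic phantom** — two-tissue irreversible kinetics on a labeled
  organ map with a tri-exponential arterial bolus and count-like noise.

## The model

For an irreversibly trapped tracer, once the reversible compartments have
equilibrated (t ≥ t\*), tissue and plasma concentrations obey the Patlak
relation

```
C_T(t) / C_P(t) = Ki · (∫₀ᵗ C_P dτ) / C_P(t) + intercept
```

The slope K<sub>i</sub> (mL/min/cm³; tabulated as µL/min/cm³) is the net
influx rate — under the two-tissue irreversible model,
K<sub>i</sub> = K₁k₃/(k₂+k₃) — and the intercept mixes blood volume and
the reversible distribution volume. Because the regressor depends only on
the input function, one least-squares design is shared by every voxel and
the parametric maps are obtained in closed form.

## Worked example

Run a three-replicate protocol-comparison study on the default phantom
(32×32×48 voxels of 4×4×2.886 mm, ten kinetic regions, per-protocol IDIF,
t\* = 10 min, P-100f as reference):

```python
from petkinetics import StudyConfig, run_study

config = StudyConfig(n_replicates=3, seed=7)
report, reps = run_study(config)

print(report.ki_mean.round(1))                # uL/min/cm^3
print(report.ki_rel_diff_mean.round(2).loc[["lesion", "gray_matter", "liver"]])
print(report.auc_rel_err.round(2))            # % vs P-100f
```

which prints

```
              P-100f  P-61f  P-48f  P-29f  P-19f  P-12f
lesion          22.2   22.1   22.1   22.1   22.0   21.5
gray_matter     34.7   34.7   34.8   34.7   34.5   33.7
...
             P-100f  P-61f  P-48f  P-29f  P-19f  P-12f
lesion          0.0  -0.20  -0.16  -0.10  -0.67  -2.90
gray_matter     0.0  -0.06   0.11   0.03  -0.67  -2.89
liver           0.0  -1.15  -1.61  -0.95  -0.70  -2.96
...
        auc_rel_err_mean  auc_rel_err_sd
P-100f              0.00             0.0
P-61f               0.08             0.0
P-48f              -0.01             0.0
P-29f              -0.04             0.0
P-19f               1.03             0.0
P-12f               4.55             0.0
```

Reading the output: lesion K<sub>i</sub> sits near its configured truth
(23.5 µL/min/cm³ scaled by the 5% blood-volume fraction and the residual
reversible-compartment transient), is essentially unchanged down to 29
frames, and drops by about 3% under the 12-frame protocol — the same
protocol whose IDIF area-under-curve error (4.6%) dominates the input
side. Dense protocols agree with the reference to well under 1%.

The same pipeline is available from the shell:

```sh
petkinetics simulate  --out sim/ --seed 3
petkinetics rebin     --in sim/dyn.nii.gz --timing sim/dyn_timing.json \
                      --protocol P-29f --out p29.nii.gz
petkinetics idif      --in p29.nii.gz --timing p29_timing.json \
                      --centerline sim/centerline.csv --radius-mm 4 --out idif.csv
petkinetics patlak    --in p29.nii.gz --timing p29_timing.json --if idif.csv \
                      --tstar 10 --out-ki ki.nii.gz --out-intercept ic.nii.gz
petkinetics full-study --out study/ --seed 7 --replicates 10
```

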