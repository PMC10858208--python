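# doct — dynamic OCT analysis of tumor spheroids

`doct` is a Python library and command-line pipeline for *dynamic optical
coherence tomography* (D-OCT) analysis of tumor spheroids. D-OCT captures a
short time sequence of OCT frames at every B-scan location and converts the
temporal fluctuation of the speckle signal into label-free contrasts of
intracellular motility, which track cell viability — for example the
response of MCF-7 breast-cancer spheroids to anti-cancer drugs (tamoxifen,
paclitaxel, doxorubicin) at different concentrations and treatment times.

The package implements:

* **Scan model and I/O** — the block-repeat raster protocol (default: a
  1 × 1 mm field divided into 8 blocks × 16 B-scan locations, each location
  imaged 32 times at a 204.8 ms frame interval, i.e. 4096 frames per
  volume), with multi-page TIFF + JSON-sidecar storage.
* **Dynamics metrics** — per voxel, from the dB-scaled intensity sequence
  `I_dB(t) = 10·log10 I(t)`:
  * **LIV** (logarithmic intensity variance), the time variance
    `Var_t[I_dB]` in dB², a proxy for the *magnitude* of intracellular
    motility;
  * **OCDS_l** (late OCT correlation decay speed), the negated
    least-squares slope of the temporal autocorrelation ρ(τ) over the late
    delay window τ ∈ [204.8, 1228.8] ms, in ms⁻¹, a proxy for the *speed*
    of intracellular motility.
* **Speckle phantom simulator** — spheroids with a necrotic core, viable
  shell, sub-regions, plate reflection and shot-noise floor, whose voxel
  fields are mixtures `E(t) = √(1−m)·E_s + √m·E_d(t)` of static and
  Ornstein–Uhlenbeck dynamic circular-Gaussian components. The Siegert
  relation gives the closed-form intensity autocorrelation
  `ρ(τ) = ((1−m) + m·e^(−τ/τ_c))²`, used as an analytic oracle, and the
  fully developed speckle limit gives the closed-form LIV
  `(10/ln10)²·π²/6 ≈ 31.0 dB²`.
* **Quantification** — automated spheroid segmentation (Otsu threshold,
  per-B-scan connected regions, plate-plane removal), spheroid volume,
  in-mask mean LIV / mean OCDS_l, dead-cell ratios at the empirical
  cut-offs 3 dB² and 2 × 10⁻⁴ ms⁻¹, and Welch's t-test group comparisons
  across treatment days.
* **Visualization** — pseudo-color composites with hue ∝ metric
  (red = low, green = high), value ∝ mean OCT intensity, saturation 1;
  en face and B-scan slice extraction.
* **A study pipeline** — a deterministic, seeded end-to-end run of the
  synthetic drug-response study (10 groups × 3 replicates × 3 treatment
  days = 90 spheroids) with CSV reports, trend plots and a manifest.

## Worked example

Simulate one high-dose doxorubicin spheroid at treatment day 6, compute the
dynamics contrasts, segment it and quantify viability:

```python
from doct import MetricConfig, compute_dynamics
from doct.phantom import scenario_spec, simulate_phantom
from doct.quantify import (SegmentationConfig, ViabilityCutoffs, compute_volume,
                           dead_cell_ratio, mean_metrics, segment_spheroid)

spec = scenario_spec("DOX", 10.0, 6, replicate_seed=7)
regions, series = simulate_phantom(spec)          # ground truth + raw frames
liv, ocds = compute_dynamics(series, MetricConfig())
mask = segment_spheroid(liv.mean_intensity_db, SegmentationConfig(),
                        spec.protocol.voxel_volume_mm3)
mean_liv, mean_ocds = mean_metrics(mask, liv, ocds)
cutoffs = ViabilityCutoffs()
print(f"volume          {compute_volume(mask):.4f} mm^3")
print(f"mean LIV        {mean_liv:.2f} dB^2")
print(f"mean OCDS_l     {mean_ocds:.2e} /ms")
print(f"dead ratio LIV  {dead_cell_ratio(mask, liv, cutoffs):.3f}")
print(f"dead ratio OCDS {dead_cell_ratio(mask, ocds, cutoffs):.3f}")
```

prints

```
volume          0.0451 mm^3
mean LIV        15.61 dB^2
mean OCDS_l     1.81e-04 /ms
dead ratio LIV  0.156
dead ratio OCDS 0.551
```

i.e. a swollen day-6 spheroid (high-dose doxorubicin causes membrane damage
and swelling rather than shrinkage) whose mean motility contrasts have
dropped and whose dead-cell fractions — voxels below the LIV / OCDS_l
cut-offs — have risen, the OCDS_l-based fraction most strongly.

The same stages are available from the shell:

```bash
doct simulate --drug DOX --conc 10 --day 6 --seed 7 --out raw/
doct compute  --in raw/ --out metrics/
doct quantify --in metrics/ --out report/
doct render   --in metrics/ --metric liv --plane enface --index 20 --out liv.png
doct run-study --seed 1 --out study/          # the full 90-spheroid study
```

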