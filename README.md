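# cardiotrack

Cardiorespiratory motion estimation and geometric-fidelity analysis for
MRI-guided cardiac radioablation (STAR) on an MR-linac, in the presence
of cardiac implantable electronic devices (CIEDs).

Patients with refractory ventricular tachycardia who receive
stereotactic arrhythmia radioablation usually carry a pacemaker or ICD.
The device disturbs the static field B0, which corrupts the real-time
cine images (bSSFP banding, gradient-echo signal voids) that an MR-linac
needs for intrafraction motion monitoring, and displaces signal along
the readout axis. `cardiotrack` implements the complete validation chain
for this setting as a reusable, tested Python library:

* **`synthdata`** — generators for every input the analysis assumes:
  moving-sphere phantom cines (cos⁴ cardiac + sine respiratory motion),
  beating-left-ventricle cines with optional device artifacts, navigator
  projections, and dual-echo 3D field-map volumes with known
  off-resonance ground truth.
* **`phantom_tracking`** — circular Hough (radial gradient-vote) sphere
  detection on 5× upsampled frames, imaging-latency estimation by
  cross-correlation, and RMSE scoring against the phantom-reported
  reference.
* **`gdc`** — deformable registration minimizing the generalized
  divergence–curl functional

  L(u) = Σₓ [ −LCC(F, M∘(id+u)) + α|∇u|² + β|∇∇u|² + γ|∇×u|² ],

  with the local correlation coefficient (LCC) over a radius-3 disk as
  similarity and defaults α = β = 0.01, γ = 16; used to propagate
  myocardial landmarks through cine series.
* **`gp_predictor`** — a Gaussian-process regressor (RBF + white kernel,
  PCA-reduced navigator projections as features) trained on the first
  half of a series to predict landmark positions in real time
  (~10⁻⁴ s per frame) on the second half.
* **`b0map`** — dual-echo phase difference → off-resonance (Hz),
  quality-guided region-growing phase unwrapping, margin shells around
  the device signal void, and conversion to expected spatial distortion
  via `distortion_mm = Δf / BW × acquisition voxel` along the readout.
* **`metrics`** — point-wise deviations (PWD), RMSD, exact two-sided
  Wilcoxon signed-rank tests, and the 1.5×IQR outlier rule.
* **`experiments` / `cardiotrack` CLI** — the three end-to-end studies
  (phantom validation, landmark GDC→GP validation, B0 distortion
  analysis), reproducible from a YAML config and a seed.

## Worked example

Track the synthetic moving-sphere phantom with the coronal bSSFP
geometry (2.6 mm reconstructed pixel, 96 ms frames), with a 100 ms
injected imaging latency and SNR 20:

```python
from cardiotrack import experiments as ex
from cardiotrack.params import TrajectoryParams

cfg = ex.PhantomConfig(seed=0, n_frames=200, snr={"bSSFP": 20.0},
                       sequences=("bSSFP",), planes=("coronal",),
                       latency_ms=100.0)
report = ex.run_phantom_experiment(cfg)
cell = report["cells"]["bSSFP_coronal"]
print(f"latency {cell['latency_ms']:.1f} ms, RMSE {cell['rmse_mm']}")
```

prints

```
latency 99.9 ms, RMSE {'HF': 0.083, 'RL': 0.072, '2D': 0.110}
```

i.e. the injected 100 ms latency is recovered by cross-correlation to
0.1 ms, and the Hough-tracked centre-of-gravity trace agrees with the
generated reference to 0.11 mm in-plane RMSE — well below the
reconstructed pixel size, as sub-pixel tracking should be.

The same experiments are available from the shell:

```bash
cardiotrack run --config phantom.yaml --out results/
cardiotrack compare --a gdc.csv --b gp.csv --out report.json
```

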