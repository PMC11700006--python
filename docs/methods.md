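# Methods

This note documents the models implemented in `cardiotrack`, the
assumptions behind them, the defaults and why they were chosen, and what
the synthetic data does and does not emulate.

## Coordinate and timing conventions

Images are indexed `(row, col)`, 0-based; physical in-plane positions
are in mm relative to the grid centre. The head–feet (readout) axis is
always image axis 0; coronal planes use axes (HF, RL), sagittal
(HF, AP). Every cine frame is timestamped at its k-space centre; an
imaging latency shifts the *reported* timestamps of a series, not its
content, which is how the latency-recovery experiment injects a known
offset.

Sequence presets carry the acquisition parameters of the two cine
sequences (bSSFP: TR/TE 2.8/1.4 ms, 3.0 mm acquisition voxel, 96 ms
frames, 1884 Hz/px; T1-GRE: TR/TE 2.6/1.4 ms, 4.0 mm voxel, 97 ms
frames, 500 Hz/px) with reconstructed pixels of 2.6/2.2 mm (bSSFP
coronal/sagittal) and 3.2 mm (T1-GRE). For T1-GRE the stated FOV,
matrix and reconstructed pixel are mutually inconsistent at the source;
the reconstructed pixel is what determines tracking accuracy in mm, so
the matrix is derived as round(FOV / 3.2 mm) = 70×70 and 70×56.

## Synthetic data

**Phantom cines.** The target is the central slice of a 3 cm sphere,
rendered as a disk with an analytic one-pixel partial-volume edge, on a
static background (water-filled oval body, 10 mm-radius static insert —
deliberately outside the 12–18 mm Hough radius bracket). Its position
follows `p2p·cos⁴(π·t·f_card)` (nonnegative pulse, 70 bpm, 10 mm
peak-to-peak) plus `(p2p/2)·sin(2π·t·f_resp)` (12 bpm, 20 mm
peak-to-peak) along head–feet only; the transverse coordinate is
static. Noise is additive Gaussian on magnitude — at the SNRs used
(20 for bSSFP, 12 for T1-GRE, defined as target intensity over noise
SD) the Rician floor is negligible for a bright target.

A note on the peak-to-peak invariant: the waveforms are exposed in
closed form, and their peak-to-peak equals the parameter exactly at the
analytic extrema. A trace sampled every 10 ms misses the cos⁴ minimum
by up to 5 ms, leaving a ~10⁻⁶ mm shortfall; tests therefore check the
waveform at its extrema and the sampled trace at a grid-dependent
tolerance.

**LV cines.** The left ventricle is a myocardial annulus
(endocardial radius 20 mm, wall 9 mm) around a bright pool, contracting
radially by `contraction_p2p · cos⁴-phase(t)` (default 8 mm, inside the
0.8–16.9 mm range of typical cardiac excursions) with the epicardium
moving 0.55× the endocardial excursion (systolic wall thickening), and
translating head–feet with a respiratory sine (default 15 mm
peak-to-peak, which puts the in-plane 2D motion extents in the low
tens of mm). Contrast ordering is pool > myocardium > background for
bSSFP (1.0/0.5/0.25, noise SD 0.02) and compressed for T1-GRE
(0.55/0.42/0.25, noise SD 0.06). Ground-truth landmark tracks are the
four endocardial points at 45°/135°/225°/315°, returned alongside the
frames. The model has no papillary muscles, no through-plane motion
and no texture; consequences are discussed under Limitations.

**Device artifacts.** A device or lead is a point-like axial dipole:
`Δf(r, θ) = A·(d_ref/r)³·(3cos²θ−1)/2` with θ measured from head–feet
and r clipped at the void radius, so |Δf| decays monotonically (r⁻³)
along every ray outside the signal void. bSSFP frames are multiplied by
the banding attenuation `|cos(π·Δf·TR)|` (nulls where the per-TR phase
accrual approaches π, e.g. ~178.6 Hz at TR 2.8 ms); gradient-echo
frames get a strictly positive intravoxel-dephasing factor
`exp(−|∇Δf|·voxel·TE)` and the shared zeroed void. The dipole is a
deliberate idealization — real ICD fields are extended,
orientation-dependent sources.

**Field maps.** Dual-echo volumes store `wrap(2π·f·TE₁)` and
`wrap(2π·f·(TE₁+ΔTE))` with ΔTE = 4.6 ms (aliasing-free band
±108.7 Hz), magnitude ≈ 1 inside an ellipsoidal body, ≈ 0 in air and
zero in the void, and attach the ground-truth off-resonance for
round-trip validation.

## Phantom tracking

Frames are linearly interpolated onto a 5× grid (the working grid of
the method being validated). The circular Hough accumulator is a
radial gradient-vote: for each candidate radius (swept over the bracket
in 0.25 reconstructed-pixel steps) the inward radial component of the
image gradient is integrated along the circle, evaluated at every
centre by FFT ring correlation. Signed radial votes make straight
background edges cancel, which removed a ~0.15 mm bias that unsigned
gradient-magnitude votes exhibit near the body outline. Sub-pixel
localisation uses the accumulator centroid over a ±2-recon-pixel
window; a three-point parabola is biased by the staircase gradient of
the linear upsampling (~0.3 mm at 3.2 mm pixels), whereas the centroid
averages it out (~0.1 mm residual). Frames whose normalized peak vote
falls below a threshold (0.35 of the frame intensity span per
upsampled pixel) are flagged missing rather than guessed.

Latency is the lag maximizing the normalized cross-correlation of the
two traces on a common fine grid (quarter of the coarser sampling
interval), refined by parabolic peak interpolation; RMSE is computed
after shifting the measured trace back by the latency and linearly
resampling the reference to the corrected timestamps.

## Divergence–curl registration

The energy is implemented exactly as stated in the README formula, in
pixel units, with the similarity `D = −LCC` since the local correlation
is a similarity to be maximized. The LCC is the *squared* local Pearson
correlation over a radius-3 disk (29 pixels), bounded to [0, 1] — the
printed form of the defining equation in the source material is
garbled, and the squared correlation is the standard reading; it is
invariant under local affine intensity maps, which is the point of the
metric for bSSFP/GRE cross-contrast robustness. Neighbourhood moments
are disk-kernel convolutions with zero padding and explicit counts, so
border pixels use the clipped disk and the map agrees with a per-pixel
double loop to 1e-10. Neighbourhoods whose variance falls below
`1e-8·(intensity range)²·n` contribute 0 (flat regions carry no
information).

Gradients: the derivative of the summed squared local correlation with
respect to the warped moving image has the closed form
`∂(Σρ²)/∂W(x) = Σ_y [A(y)(F(x)−F̄(y)) − B(y)(W(x)−W̄(y))]` with
`A = 2cov/(varF·varW)`, `B = 2ρ²/varW`, assembled with four disk
convolutions and chained with the warped image's spatial gradient. The
three regularizers are quadratic forms in difference stencils
(np.gradient: central interior, one-sided boundary — exact on linear
fields, which is what makes the rotation-field curl energy match its
closed form γ·(2ω)²·N to 1e-8); their gradients use the exact discrete
adjoint of the stencil, so the only approximation in the total gradient
is the similarity term.

Optimisation is a 3-level image pyramid (a level is dropped if the
image would shrink below four LCC radii) with gradient descent: the
raw gradient is preconditioned by Gaussian smoothing (σ = 4 px — a
symmetric positive-definite operator, so descent directions remain
descent directions), normalized to a maximum update of 0.5 px, and
accepted through a backtracking line search on the true energy, which
enforces monotone decrease; coarse fields are upsampled ×2 between
levels. The preconditioner matters: image forces live on thin edges,
and unsmoothed descent takes O(distance²) iterations to diffuse
displacement into flat regions such as a blood pool.

Landmark propagation registers every frame to frame 0 (all-to-reference
avoids drift accumulation) warm-started from the previous frame's
field; a landmark's position is its frame-0 position plus the field
sampled there bilinearly, flagged invalid if displaced outside the
field of view. With γ = 16 the model assumes in-plane motion is
essentially irrotational (apparent rotation in 2D cardiac cines mostly
reflects through-plane motion); the test suite demonstrates both that
irrotational warps up to 4 px are recovered with p95 endpoint error
below 1 px and that genuinely rotational fields are recovered better
when γ is relaxed.

## Gaussian-process prediction

Features per frame are the two unit-normalized image projections
(row- and column-sums — equivalent to the central k-space lines by the
projection-slice theorem), concatenated, standardized and reduced by
PCA retaining 95% variance; scaler and PCA are fit on the training
split only. Each output coordinate gets an independent
`ConstantKernel·RBF + WhiteKernel` GP (no multi-output coupling — the
axes are reported separately anyway), hyperparameters by marginal
likelihood with three seeded restarts. The split is contiguous,
training first (50% default), matching prospective use; note that the
training half must cover the full motion range — a series shorter than
one respiratory period trains a GP that must extrapolate, and accuracy
degrades accordingly. Training on ~100 frames takes about a second and
prediction ~10⁻⁴ s per frame on one CPU, comfortably real-time.

## Field mapping and distortion

Off-resonance is `wrap(φ₂−φ₁)/(2π·ΔTE)`. Unwrapping is quality-guided
region growing: voxels are visited in descending-magnitude priority
over face-connected neighbours, each receiving the 2π multiple closest
to the mean of its already-unwrapped neighbours; the result is unique
up to a global 2π·k per connected component (disconnected components
are unwrapped independently with a warning). This is exact whenever the
true phase step between neighbouring voxels stays below π; near an
r⁻³ singularity that condition fails in the first shell around the
void regardless of algorithm, which is a physical limit of
phase-difference mapping, not an implementation one.

Shells are built by thresholding the Euclidean distance transform (in
mm, so anisotropic voxels are handled) and differencing consecutive
dilations; margins smaller than the voxel size yield empty shells on
coarse grids, so the bundled B0 experiment uses a 1 mm grid. Distortion
is `Δf/BW × acquisition in-plane voxel` along the readout (head–feet)
axis only, sign-preserving, using the acquisition voxel because the
bandwidth is specified per acquisition pixel; the "98th percentile
range" is the central 98% interval [p1, p99], computed on offsets and
converted (the map is linear, so the order is immaterial). For
identical offsets the T1-GRE/bSSFP distortion ratio is
(4.0/500)/(3.0/1884) ≈ 5.02, which is why the low-bandwidth sequence
pays for its SNR with geometric fidelity.

## Statistics

The two-sided Wilcoxon signed-rank test excludes zero differences
(a Pratt-style variant is selectable), uses mid-ranks for ties, and an
exact null distribution for up to 25 non-zero pairs built by
convolving the characteristic polynomial of the doubled ranks
(doubling keeps tied mid-ranks integral); beyond that, the
tie-corrected normal approximation. All-zero differences make the test
vacuous: p = 1, flagged. Quartiles use linear interpolation (type 7)
for the 1.5×IQR whisker rule.

## Problem sizes

Default study conditions: 200-frame phantom cines per geometry
(~19 s of imaging), ~100-frame LV cines for the GDC→GP chain, and
48³-voxel field maps at 1 mm. These sizes keep every experiment on a
single CPU core in minutes while leaving the statistical headroom the
validated properties need (e.g. the RMSE of a 200-sample trace is
estimated to ~5%).

## Limitations

* The LV model is geometric (edges, no myocardial texture); LCC-driven
  registration on real cines benefits from trabecular texture that the
  generator does not produce, so synthetic accuracies characterize the
  algorithm, not clinical performance.
* No through-plane motion, coil profiles, reconstruction artifacts or
  Rician noise floors are simulated; the banding model modulates
  magnitude only.
* The device field is a point dipole; real ICD/lead geometries produce
  extended, orientation-dependent perturbations.
* Registration is 2D; the curl penalty's irrotationality assumption is
  known not to hold for 3D cardiac twist.
* Unwrapping within one voxel shell of a steep field singularity is
  intrinsically ambiguous (phase steps exceed π).
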