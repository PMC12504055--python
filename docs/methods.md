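# Methods

This note documents the models, defaults and design choices behind
qmapkit, in the spirit of a package methods appendix: what is computed,
under which assumptions, and what the synthetic-data experiments do and
do not demonstrate.

## Signal model

The sequence model covers a 5-contrast acquisition: a steady-state PDw
SPGR readout at flip angle `pd_flip_angle` (default 1°), and a
magnetization-prepared cycle read out at `readout_flip_angle` (default
3°) containing one T2-prepared segment and three segments during
inversion recovery. All longitudinal magnetization is tracked as a
fraction of equilibrium; proton density scales the emitted signal only,
which makes every contrast exactly linear in PD.

One cycle is a chain of affine maps `mz ← a·mz + b`:

* free recovery over `Δt`: `a = e^(−Δt/T1)`, `b = 1 − a`;
* T2 preparation: the magnetization is transverse for `te_t2prep` ms
  (so it occupies wall time but sees no T1 recovery) and is attenuated
  by `e^(−te_t2prep/T2)`;
* inversion preparation: `mz ← (1 − 2·η)·mz` with efficiency
  `η ∈ [0, 1]` — `η = 1` is an ideal adiabatic inversion, `η = 0.5`
  saturation, `η = 0` disables the preparation. This parameterization
  interpolates between identity and perfect inversion so that a
  zero-efficiency configuration degenerates cleanly to an unprepared
  sequence;
* readout segment of `views_per_segment` excitations at `readout_tr`
  spacing: per excitation `mz ← cos(α)e^(−TR/T1)·mz + (1 − e^(−TR/T1))`,
  closed over the segment by a geometric sum. The recorded signal is
  `pd·sin(α)·mz` evaluated just before the central excitation
  (index `views // 2`).

The periodic steady state of the composed cycle is `mz* = b/(1 − a)`;
`|a| ≥ 1` raises a non-convergence error (it indicates a timing
misconfiguration, not a numerical problem). Fixed-point iteration is
retained only as a verification path; closed form and 50-cycle
iteration agree to better than 1e−9 relative over the entire fitting
grid (the acceptance script reports the measured maximum, ~1e−16).

Not modeled: transverse relaxation during the readout itself, B1
transmit/receive inhomogeneity (a multiplicative `flip_scale` hook
exists, default 1), slice profiles, and phase (signals are real
magnitudes).

### Timing defaults

Pulse-level timings of the clinical sequence are vendor-internal; the
defaults here were chosen once so that the five contrasts are well
conditioned over physiological T1/T2 and are recorded in every resolved
configuration: `te_t2prep` 100 ms, `acquisition_delays` (100, 1000,
1900) ms after inversion, `cycle_duration` 4000 ms, `views_per_segment`
128, `readout_tr` 3 ms, inversion efficiency 1.0. All are YAML-
overridable.

## Dictionary fitting

Atoms are simulated at `pd = 1` on a (T1, T2) grid, stored unit-ℓ2
normalized with their pre-normalization norms, ordered T1-major. The
default grids span T1 100–3000 ms and T2 5–600 ms with denser sampling
at the short end (T1 step 5 ms below 600 ms, 10 ms above; T2 step 1 ms
below 100 ms, 2 ms above). The non-uniform spacing follows the signal
geometry: at short T1/T2 the curves change fastest and a fixed step
costs the most relative accuracy — with uniform 2-ms T2 spacing, grid
quantization alone at a ~40 ms vial is ±2.5% of the value, which would
dominate a percent-bias readout.

Matching maximizes `|⟨y, d⟩|`; ties resolve to the smallest atom index.
This matched filter is algebraically identical to scanning all atoms
with per-atom least-squares scale fitting (verified exhaustively in the
tests). The signed projection divided by the atom's pre-normalization
norm is the PD-surrogate scale; negative correlations are accepted but
flagged, since they indicate sign-inverted input. Zero-norm signals
produce an unfitted sentinel (NaN parameters), never an exception in
volume mode. Voxels are processed independently, so maps are
bit-identical under any processing order or chunk size.

Two numerical details worth knowing:

* for dictionaries above 5000 atoms the argmax is computed on a float32
  copy of the correlation matrix (halving the dominant memory traffic);
  the winning atom's projection, scale and residual are recomputed in
  float64. The float32 selection could in principle flip a near-exact
  tie between adjacent atoms, which is harmless at the grid spacings
  used;
* the residual `√(1 − cos²θ)` amplifies float rounding near perfect
  matches: even an exact atom match can report a residual of order
  √(2ε) ≈ 2e−8 rather than 0.

With only one T2-weighted contrast among five, T1 and T2 errors trade
off in the joint discrete match: a noiseless off-grid tissue is
recovered within about one T1 grid step, while the T2 error can reach
two steps or ~4% of the value (worst at long T2, where the preparation
attenuation flattens, combined with off-grid T1). For the same reason
grid refinement improves recovery in aggregate (median error) but not
monotonically for every individual tissue. An optional 1-D quadratic
refinement of the correlation peak is provided but off by default, so
reported values are exact grid points.

## Synthetic data

### Digital phantom

Two 14-vial arrays (rings at one- and two-thirds volume depth) in a
filler medium, default 96³ voxels at 2 mm isotropic. The T1 reference
ladder is the manufacturer-style printed series 1741.3 … 245.8 ms
extended geometrically down to 22 ms; the T2 ladder is geometric over
493–7 ms (the manufacturer publishes only the range). Two T2 vials
(indices 1 and 5) are excluded from formal analysis by default, as on
the physical phantom. Each vial needs a full (T1, T2) pair; the
companion constant of each array is a smooth monotone function of the
reference, rounded to whole (T2) or ten (T1) milliseconds.

The repeat-scan design defaults to the benchmarking protocol: 12
sessions × 5 consecutive acquisitions, Gaussian noise with SD 0.5% of
the mean vial PDw signal, and a session-level drift factor (SD 0.2%)
applied multiplicatively to the true T1 and T2 — not to the signal
gain, which a scale-invariant matched filter would simply ignore; the
drift emulates software/B1-like day-to-day quantification changes. An
optional multiplicative bias model (e.g. +30% T1, −20% T2) emulates the
systematic offsets that phantom benchmarking is designed to detect; it
is invertible and recorded in provenance. Noise is Gaussian on
magnitude contrasts (the high-SNR limit of Rician noise, appropriate
for denoised reconstructions); a Rician option exists. All randomness
derives from one integer seed via spawned generator streams, so series
are bit-reproducible and independent across acquisitions.

### Longitudinal subject

A body ellipsoid (default 64×64×48 at 2 mm) containing a control ROI
with zero programmed effects, two lesions with per-timepoint percent
effects on T1/T2 and shrinking residual-disease (RD) extents, an
enhancing gland, and a near-zero-PD airway tube. ROI masks are identical
across timepoints (volumes are generated pre-aligned, standing in for
rigid contour propagation); the RD extent keeps the
`round(fraction·n)` voxels nearest the ROI center, so an erosion
fraction of 0.25 yields a quarter of the voxels to within one voxel.
Default effect sizes mirror reported clinical scales: +13.7%/+17.8%
(T1/T2) for the enhancing lesion and −39.5%/−32.7% for the resolving
nodal lesion at the post-treatment timepoint.

What passing tests show — and do not. The generators share the forward
signal model with the fitter, so round trips validate the fitting,
segmentation and statistics chain, not the physics fidelity of the
sequence on a scanner. Real data add coil sensitivity structure,
registration error, partial-volume mixtures, reconstruction artifacts
and Rician noise floors, none of which are in the defaults; conclusions
about absolute in vivo accuracy cannot be drawn from these simulations.

## Phantom benchmarking

Vial segmentation on the PDw volume: Otsu threshold (256 bins) with
polarity auto-detection (vials are the minority class), 26-connected
components filtered to 50–200% of nominal vial volume, centroids
matched to the layout template by least-total-squared-distance
assignment, then a 5-mm-radius spherical ROI (in mm space, voxel
included iff its center is inside — resolution independent) at each
matched centroid. Fewer matched components than template vials is an
error listing the missing indices.

Statistics use the sample (n−1) SD throughout — confirmed by exact
reproduction of the published control-tissue wCVs, which population SD
fails. Per vial: grand mean over all acquisitions, bias in ms and % of
reference, intrasession CV per session (range reported), intersession
CV over session means. Only vials whose reference lies in the
physiological window (T1 245.8–1741.3 ms, T2 42–493 ms — the outermost
analyzed vials, hence inclusive) enter the report and the unweighted
OLS regression of derived on reference. Whether the regression should
pool per-session means instead of per-vial grand means is not
determined by the published material; both modes are implemented
(`regression_mode`), grand means by default.

## Response analysis

Background is removed by Otsu thresholding of the PDw volume
(foreground strictly above threshold); the airway is the 6-connected
flood-fill component of the below-threshold region containing a seed
voxel, and a seed in foreground is rejected. ROI statistics are
computed over roi ∩ foreground ∖ exclusions with finite fitted values;
the masking order is immaterial. Skewness is the adjusted
Fisher–Pearson coefficient, defined as 0 for zero-variance ROIs.
Histograms use fixed study-wide edges (bin width 25 ms for T1, 2.5 ms
for T2) so that densities overlay across timepoints and between RD and
initial disease.

Delta analysis reports `Δms` and `Δ% = Δms/baseline·100` per ROI and
follow-up timepoint, plus median deltas where medians are available;
missing timepoints are reported absent, not raised. The within-subject
CV spans all analyzed timepoints including baseline. When per-timepoint
means must be reconstructed from published baselines and deltas, T1
uses the ms deltas and T2 the percent deltas: published T2 ms deltas
are integers on 20–40 ms baselines (far too coarse), while T1 ms deltas
carry sub-percent resolution.

Reports round half away from zero to one decimal, matching the
published table formatting. Recomputing derived cells from printed
inputs reproduces them exactly with two classes of exception, both one
final digit: cells the original analysis computed from unrounded means
(double rounding), which the tests therefore compare within one print
quantum (0.1).

## Problem sizes

The test suite and acceptance script run the phantom arm at the default
96³/2 mm geometry (fitting restricted to the vial ROIs) with the full
12×5 design for the stochastic checks and 2×1 designs for noiseless
round trips, and the subject arm at 64×64×48/2 mm with fitting
restricted to the analysis ROIs — sizes chosen to keep a full run in
minutes on one core while leaving every statistic at its design sample
size (12 sessions, 5 repeats, 3 timepoints).

## Known limitations

* Single T2-weighted contrast ⇒ T2 precision degrades at short T2
  (attenuation `e^(−100/T2)` leaves little signal) and trades off
  against T1 quantization; the published benchmarking shows the same
  pattern (largest CVs at low-T2 vials).
* No B1/coil model: the hardware-dependent variability reported when
  coils change between sessions has no synthetic counterpart.
* The bias model is a per-map global multiplier; real systematic bias
  is T1/T2-dependent (published biases range 24.9–55.6% across the T1
  ladder).
* Registration, contour propagation, white-matter segmentation and CNN
  reconstruction are out of scope; masks are inputs (or synthetic) and
  volumes are generated aligned.
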