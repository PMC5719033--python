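# Methods

## Ion-flight model

The spectrometer is idealized as a uniform acceleration gap followed by
a drift region whose energy dispersion the reflectron compensates
exactly. Ions (charge +1 throughout) are emitted at rest from height
Δh above the substrate and accelerated across the remaining gap
`h_ex − Δh` by the field `U_ex / h_ex`. The acceleration time is

    t_ac(m, Δh) = sqrt(2 h_ex² m / (U_ex e)) · sqrt((h_ex − Δh)/h_ex),

and the total flight time

    T(m, Δh) = T(m, 0) − t_ac(m, 0) · (1 − sqrt((h_ex − Δh)/h_ex)),

with the substrate-level TOF given by the quadratic mass calibration
`T(m, 0) = T_cal √(m/m_cal)` anchored at K⁺ (20.545 µs, monoisotopic
39K = 38.9637 u). No reflectron geometry, field curvature above
topographic features, angular emission, or detector dead-time is
modelled. Both `t_ac` and `T` scale as √m, so the relative shift
`T(m, Δh)/T(m, 0)` is exactly mass-independent under this model — the
property that lets a single reference peak correct the whole spectrum,
and which the test suite verifies to 1 part in 10⁹ against an
independent numerical integration of the equation of motion.

Units are SI internally; masses enter in u and are converted once at
the formula boundary (1 u = 1.66053906660×10⁻²⁷ kg,
e = 1.602176634×10⁻¹⁹ C). Two potassium masses are exposed as
constants: the monoisotopic 38.9637 u used for spectral peaks, and the
standard atomic weight 39.098 u, which is the value that reproduces the
printed ≈30.2 ns acceleration time (the monoisotopic mass gives
30.14 ns).

## Instrument parameters

| parameter | default | meaning |
|---|---|---|
| `U_ex` | 2000 V | extractor potential |
| `h_ex` | 1.5 mm | sample–extractor gap |
| `T_cal` | 20.545 µs | substrate-level K⁺ TOF (calibration anchor) |
| `m_cal` | 38.9637 u | calibration ion mass |
| `tof_bin` | 50 ps | time-to-digital bin width |
| `t_window` | 100 µs | acquisition window (⇒ 2,000,000 raw bins) |

## Synthetic scenes

The reference scene emulates a dried seedling root on a flat silica
substrate: a half-cylindrical ridge of peak height 200 µm (profile
`Δh(d) = H √(1 − (2d/w)²)`), footprint width defaulting to the
geometric rule `w = 2H / pixel_pitch`, running the length of the image.
The species palette confines Na⁺ (yield 80 counts/pixel), Mg⁺ (40), K⁺
(150), Ca⁺ (60) and three organics at 185/231/279 u (30/25/20) to the
ridge, Si⁺ (200) and Si₂⁺ (50) to the substrate, and puts Cs⁺ (300) and
Cs₂⁺ (60) everywhere, so that Cs⁺ — the sputter-gun species implanted
across the field of view — is globally the most intense peak and serves
as the correction reference. Default grid 256×256 over 500 µm (tests
and the acceptance script use 32–64 px grids of the same physical
field; the physics is per-pixel, so grid size only sets how densely the
height profile is sampled). Organic masses are spaced >1 u apart so all
peaks are resolved at the default resolving power R = m/Δm = 7000
(instrument range 5000–11000).

Three render modes:

* **stochastic** (default): per-pixel counts ~ Poisson(yield ×
  abundance) — the conventional ion-counting noise model; no
  quantitative noise model is prescribed by the source data, so shot
  noise is the stated choice. Each ion receives Gaussian arrival-time
  jitter `σ_t = T / (2 R · 2.3548)` (the time-domain image of FWHM mass
  resolution, via Δt/t = Δm/2m), then floor-quantization to the 50 ps
  grid, modelling a time-to-digital converter.
* **noiseless, delta lines**: `round(λ)` counts deposited at the
  centroid bin. Exact integer bookkeeping; every peak occupies a single
  bin, which is the worst case for centroid quantization error (±½ bin
  ≈ ±1×10⁻⁴ u at K⁺).
* **noiseless, Gaussian lines**: the expectation of the stochastic
  render — per-bin integrals of the Gaussian line shape, float counts,
  still quantized at 50 ps. This is the infinite-statistics limit and
  the right condition for accuracy statements about centroid-based
  estimators, since a real instrument's peaks span ~30 bins and
  centroiding defeats single-bin quantization. Accuracy figures quoted
  for the correction chain use this mode.

What the simulator does **not** emulate: sputter-yield matrix effects,
ion-gun tilt shading on steep features, surface charging, detector
saturation and dead-time, isotope patterns, chemical backgrounds.
Passing tests therefore demonstrate correctness of the *geometry and
timing* physics and of the data plumbing, not robustness to every
artifact of real spectra.

## Compression

Segments are found on the pixel-summed spectrum: maximal runs of
occupied bins, merged across gaps shorter than `min_gap` (40 bins =
2 ns), padded by `pad` bins each side, and retained when the integrated
count meets the threshold (default 1000 counts; on a 256×256 image that
keeps peaks down to one detected ion per ~65 pixels). The threshold is
applied to the *segment total*, the reading consistent with that
per-ion interpretation. Compression then restricts the cube to the
concatenated segments — bit-identical counts, full 50 ps resolution —
with a point-index → raw-bin → m/z map. The `pad` default is 40 bins
(2 ns): padding must cover the topographic shift scale because, for
species absent from the substrate, the corrected (substrate-level) peak
position lies *above* every observed bin and must still fall inside the
segment after correction; a pad smaller than the shift silently drops
corrected counts at segment edges. Both `min_gap` and `pad` are exposed
parameters.

Conventions: bin *i* spans `[i, i+1)·tof_bin` with centre time
`(i+0.5)·tof_bin`; point indices are 0-based; the pixel grid is
row-major with x fastest; imzML export converts to the format's 1-based
coordinates.

## Shift correction and topography

Per pixel, the reference TOF is the intensity-weighted centroid of
bin-centre times over the reference segment (sub-bin precision, needed
to approach the 5 µm height floor implied by 50 ps timing; argmax would
be quantization-limited). Pixels with fewer than `min_counts` (5)
reference counts are invalid and pass through all stages unchanged,
with the mask propagated; no spatial interpolation of D is attempted.

The substrate TOF is the maximum of the tracked field — the longest
flight comes from the lowest emission point. On noisy data the maximum
of thousands of noisy centroids is biased high by extreme-value
statistics (for 4096 pixels at centroid σ ≈ 66 ps, ≈ +0.2 ns, i.e.
≈ 10 µm of spurious height), so a quantile alternative
(`percentile < 1`) is provided; the strict maximum remains the default.
The stochastic-recovery test uses the 0.9 quantile on a scene whose
substrate occupies the top ~20% of reference TOFs, which centres the
estimate inside the substrate population.

Correction multiplies each pixel's time axis by D: every bin's support
`[t_i, t_{i+1})` maps to `[t_i D, t_{i+1} D)` and its counts are
redistributed over the output grid proportionally to overlap — a
count-conserving linear rebinning of the histogram (event lists are not
modelled, so re-timestamping is not available). Integer cubes stay
integral via largest-remainder rounding, preserving per-pixel totals
exactly; counts scaled beyond the window or outside every retained
segment are dropped and tallied. The full compressed axis of every
pixel is corrected, not just the reference-local neighbourhood.

Topography follows from the closed-form inverse of the shift law, with
`t_ac(0)` computed from the instrument geometry (it cannot be measured
directly). Negative shifts (centroid noise around the substrate level)
clamp to zero height; shifts at or beyond `t_ac(0)` are unphysical and
invalidate the pixel with a logged warning.

Accuracy under the model: in the Gaussian-line noiseless limit the
corrected K⁺ mass is restored to ~10⁻⁸ u and heights to nanometres; in
the delta-line (single-bin) limit residuals are quantization-bounded at
±½–1 bin (≈1–2×10⁻⁴ u at K⁺, ≈5 µm of height); with Poisson noise at
the default yields, height RMSE over a 200 µm scene is a few µm.
The experimentally reported residual scale (≈1.5×10⁻⁴ u) sits between
the two deterministic regimes, consistent with broadened peaks plus
counting noise.

## PCA

Deterministic full SVD (`numpy.linalg.svd`) of the pixels × points
matrix; uncentered and unwhitened by default, so explained-variance
fractions are fractions of the total sum of squares and the first
component tracks the averaged spectrum when pixel-to-pixel contrast is
low (the shared Cs⁺ background ensures this on the corrected root
cube). Centering and total-ion-count normalization exist as options,
both off by default. Sign ambiguity is fixed by making each
eigenvector's largest-magnitude element positive. Saturated (K⁺) and
source-injected (Cs⁺, Cs₂⁺) peaks are excluded before decomposition by
masking their segments' points; excluded points carry no influence.
Six components are retained by default (parameter). scikit-learn's
TruncatedSVD serves as an independent cross-check in the tests, never
as the implementation.

## Storage

HDF5 container with an embedded JSON geometry block and processing log.
Raw cubes are stored as compressed sparse rows (data/indices/indptr):
at 2,000,000 bins × 65,536 pixels a dense cube would be ~1 TB, while
the occupied bins are a few thousand per pixel; CSR is lossless and
round-trips bit-exactly. Compressed cubes store the dense matrix, both
calibration maps and the segment table. Interchange is continuous-mode
imzML (shared m/z axis; intensities float32; the raw-bin index map is
rebuilt from the inverse calibration on import since imzML carries no
time-bin provenance; 0-point spectra are written as a 1-point
placeholder axis with a warning, as the format cannot represent empty
spectra). Maps export as float32 TIFF and long-form CSV; all CSV
numerics use a fixed 9-significant-digit format so identical inputs
produce byte-identical files.

## Problem sizes

Tests and the acceptance script run the pipeline at 32×32 and 64×64
pixels over the same 500 µm field as the full-resolution instrument
grid; per-pixel physics is grid-independent, and these sizes sample the
height profile densely enough to exercise every code path (tens of
distinct heights, shift ranges of 40–80 bins).

## Known limitations

* Absolute height accuracy inherits the idealized uniform-gap model;
  field curvature over real topography is not corrected.
* Non-uniform sputtering and shading on steep features are out of
  scope, as is charge compensation.
* The correction operates on histogrammed data; sub-bin structure
  within a 50 ps bin is unrecoverable in the delta/event representation.
* Proprietary instrument file formats are not read; interchange is via
  imzML and the HDF5 container.
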