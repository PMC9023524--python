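# Methods

This note documents the models, estimators, parameter choices and known
limitations behind dyadkit's five analysis stages and the synthetic-data
generators that validate them.

## Coordinate and output conventions

All analyses use 0-based pixel indices with the physical coordinate of a
pixel center at (index + 0.5) × pixel_size. Kymographs are (space, time):
rows are positions along the scanned line, columns are scan lines.
Orientations are measured in (row = y, col = x) array coordinates as
atan2(Δrow, Δcol) reduced modulo 180°; the same convention is used for the
spectral axis estimate and for skeleton segments, so relative angles are
consistent. Floating-point outputs are written with 9 significant digits,
which makes byte-identity of repeated runs meaningful; images are 16-bit
TIFF with a JSON sidecar carrying the calibration (pixel size, line
interval, pacing times, axis order) rather than TIFF tags.

Every generator splits its seed into sub-streams in a documented order
(geometry → events → noise), so ground truth can be re-derived by
replaying a sub-stream without touching the rendering noise. Ground truth
is always computed from the generating geometry or event list, never from
rendered pixels.

## Synthetic T-tubule images

The generator emulates a membrane-dye image of a striated cardiomyocyte:
transverse tubule elements on a lattice with 2.0 µm period (the sarcomere
repeat) perpendicular to the cell long axis, which is the image x-axis by
construction; rotation is handled at analysis time. Transverse lines are
built from 1 µm elements so that `transverse_dropout` acts per unit
length, emulating patchy tubule loss. Longitudinal connectors are axial
segments of one period in length, with a Poisson-distributed count set by
`longitudinal_density` (expected longitudinal length per µm² of cell
area). The skeleton raster is blurred with a Gaussian PSF (σ 0.15 µm),
scaled so the brightest tubule pixel averages `photons_peak` counts
(default 100) over `background_photons` (default 10), and corrupted with
Poisson photon noise. Defaults give a peak signal-to-background of 10.

What this does not model: confocal sectioning beyond the Gaussian PSF,
motion, multi-cell fields, curved or branching tubule geometry beyond
right-angle crossings. Passing recovery tests therefore demonstrates that
the estimator chain is unbiased on networks of known composition at
realistic noise, not that segmentation is robust to every staining
artifact in real tissue.

## T-tubule fraction analysis

1. **Cell axis**: orientation of the dominant peak of the Hann-windowed
   2-D power spectrum, searched over periods of 1–4 µm (the physiological
   sarcomere band; outside it, low-frequency cell-shape power dominates
   disrupted images). The peak must exceed 10× the median band power,
   otherwise the image is rejected as unstructured. For a striated cell
   the peak's frequency vector points along the long axis. The same peak
   supplies the striation-period estimate.
2. **Segmentation**: white top-hat with a disk of radius 1.5× the period
   estimate (capped at half the image's smaller dimension), Otsu
   threshold, removal of components smaller than 0.2 µm². An empty mask or
   a mask covering > 60% of the image raises a QC flag instead of failing
   silently — the latter catches inverted-contrast inputs.
3. **Skeleton classification**: morphological skeleton, broken at branch
   points (pixels with > 2 neighbours); each remaining 8-connected path is
   measured as the sum of inter-pixel steps (1 or √2 pixels), **plus** one
   step per endpoint adjacent to a removed branch pixel (cutting a
   crossing costs every arm exactly one step) **plus** a half-pixel end
   cap per free endpoint (an n-pixel path spans n pixels of physical
   length, not n−1 steps). Without these two corrections, classified
   lengths under-recover the generator's bookkeeping by up to 18% for the
   shorter longitudinal segments, which biases the fraction. Segments
   shorter than 3 pixels (below PSF scale) are discarded as spurs.
   A segment is transverse when the principal axis of its pixels makes an
   angle ≥ 45° with the cell axis (ties transverse; threshold
   configurable).
4. **Fractions** are length-weighted. An empty skeleton reports (0, 0)
   with a QC flag rather than NaN.

Measured performance on synthetic data (10 seeds per condition, defaults):
mean |measured − true| transverse fraction ≤ 0.04 across true fractions
0.4–1.0, and ≤ 0.03 change under 90° rotation.

## Synthetic Ca²⁺ line scans

Defaults follow the imaging conditions the analyses are designed for:
3.78 ms/line, 0.1 µm pixels, 40 µm scan, 1 Hz field stimulation (first
stimulus at 0.5 s), dyad sites every 2 µm, baseline 100 counts.

* **Evoked release**: per site per stimulus, a Bernoulli(`p_couple`) draw.
  An active site contributes a raised-cosine spatial bump with support
  equal to the dyad spacing (neighbouring supports tile the line without
  overlap) and per-site amplitude 2× `transient_amplitude_dff`, so the
  spatial-mean ΔF/F₀ peak under full activation equals
  `transient_amplitude_dff` exactly. Temporal kernel: linear rise (15 ms)
  then exponential decay (τ = 150 ms), 5 ms latency after the stimulus.
  This shape was chosen so sites are local maxima of the evoked-average
  profile (needed for auto-detection) and the transient amplitude is
  recoverable in closed form.
* **Sparks**: per-site Poisson process; kernel = Gaussian in space
  (FWHM 2 µm) × (linear rise 8 ms, exponential decay 30 ms), peak
  amplitude equal to the configured ΔF/F₀ by construction.
* **Caffeine mode** emulates SR-content measurement with an SR-trapped
  low-affinity dye: the signal *drops* by
  `caffeine_depletion_frac × store_scale` (defaults 0.4 × 1.0) with a
  0.3 s onset and no recovery within the scan; pacing stops at the
  caffeine time, and cytosolic release signals are omitted because the
  luminal dye does not report them.
* Rendering: F = F₀·(1 + ΔF/F₀) with Poisson noise.

Not modelled: Ca²⁺ waves, dye saturation, photobleaching, motion,
two-channel crosstalk.

## Line-scan analysis

* **Baseline F₀**: per-position 10th percentile over time of the
  temporally smoothed trace (25-line moving average, ~95 ms), then
  spatial Gaussian smoothing (σ 0.3 µm), floored at 1 count. The temporal
  pre-smoothing matters: the raw 10th percentile of Poisson(100) counts
  sits ~13% below the mean, while the smoothed version recovers F₀ to
  within ~3% when active signal occupies < 5% of the record. Requires
  ≥ 100 lines.
* **Spark detection**: Gaussian smoothing (σ 0.2 µm, 4 ms), threshold at
  median + k·σ_bg with σ_bg = 1.4826 × MAD of sub-threshold pixels
  (robust to spark contamination) and k = 3.8, the classic spark-detector
  criterion; 8-connected components smaller than 0.5 µm × 10 ms are
  rejected. Lines within 150 ms after each pacing stimulus are excluded so
  evoked release is not counted as spontaneous. Overlapping events at one
  site are split at temporal local maxima with prominence > 0.5× the
  smaller peak. Amplitude is read from a lightly smoothed field (σ 1 px,
  0.5 lines) after local peak refinement — the detection field's heavier
  smoothing biases the cusp-shaped temporal peak low and late. FWHM and
  duration come from interpolated half-maximum extents at the peak.
  Measured at defaults: zero false positives on null scans (bound: ≤ 1
  per 100 µm·s), recall ≥ 0.99 and mean amplitude error ~4% at SNR 10.
* **Transients**: per stimulus, max of the spatially averaged ΔF/F₀ in a
  250 ms post-stimulus window; overlapping windows are an error.
* **Coupling fidelity**: sites are supplied or auto-detected as local
  maxima of the evoked-average spatial profile with 2 µm minimum
  separation (peak pruning at 80% of that separation, since discrete peak
  pixels jitter). A site is activated on a stimulus when the ΔF/F₀ peak
  within ±0.75 µm and 150 ms clears 0.5× the median site-stimulus peak.
  For every window of three consecutive stimuli the number of
  site–stimulus pairs without release is counted; the reported rate is
  the maximum count over windows divided by scan length per 100 µm (the
  normalization is a package convention; "max over triplets" makes the
  statistic a worst-window measure). Inconsistent sites have ≥ 1 hit and
  ≥ 1 miss. Requires ≥ 3 stimuli. On synthetic scans the recovered
  activation matrix equals the generator's Bernoulli draws exactly at
  default SNR.
* **SR content**: spatio-temporal mean before caffeine (≥ 2 s of baseline
  required) vs the extremal spatial-mean within 5 s after (minimum for
  the SR-trapped-dye convention, maximum for a cytosolic dye), both on a
  25 ms-smoothed trace; reported as |ΔF|/F_pre. Paired simulations at
  store scales 1.0 vs 0.75 recover an estimate ratio of 0.751 ± 0.002
  (20 seeds) — the computational analogue of a ~25% store reduction.

## EM dyad morphometry

Scenes are traced contours in nm: a closed T-tubule polygon, jSR
polylines, and a Z-line (point + direction). The generator places an
n-vertex polygon on an ellipse (default semi-axes 250 × 200 nm, a
realistic near-circular cross-section), offsets a contiguous arc of the
perimeter outward by the ~12 nm dyadic cleft to form the jSR, positions
the Z-line at a configured perpendicular distance from the arc midpoint,
and applies a random rigid motion so analyses cannot assume axis
alignment.

* **Circularity** 4πA/P² via the shoelace formula; polygon validity
  (simplicity, non-zero area) is checked with shapely. Unit square gives
  π/4 to 1e−12; a regular 4096-gon reaches 1 − 2·10⁻⁷.
* **Coupling ratio**: the perimeter is resampled at ≤ 1 nm arc spacing
  and each sample tested against all jSR segments (vectorised
  point-to-segment distance); the coupled fraction uses d_max = 15 nm,
  slightly above the cleft to tolerate tracing error. The geometric
  end-overshoot of the distance test (√(15² − 12²) ≈ 9 nm per arc end)
  bounds the recovery error at ~0.013 of the default perimeter; measured
  recovery of arc fractions 0–1.0 is within ±0.013.
* **Junction–Z distance**: perpendicular distance from the Z-line to the
  arc-length midpoint of the largest coupled run (circular run-finding).
  When the jSR wraps the full perimeter there is no run boundary and the
  junction falls back to the perimeter point nearest the jSR trace's own
  arc midpoint. Recovery of 0–60 nm offsets is within 0.02 nm; reported
  as missing (None) when no perimeter point is coupled.

## BioID enrichment ranking

The screen is a ratio ranking of a single pooled replicate per arm, so no
variance model is fitted. Per protein: mean of the two sensor channels
over control; proteins with control exactly 0 form the undefined-ratio
class, ranked ahead of all finite ratios (within the block: mean sensor
descending, ties by id); finite rows rank by ratio, then mean sensor,
then id. Retention is control-zero (with non-zero sensors) or ratio
strictly > 5. Rows that are zero everywhere are dropped with a QC note.
The ordering is a total order, so repeated runs are identical, and global
intensity rescaling changes nothing.

The generator models protein abundance as lognormal across proteins
(ln-sd 0.5) with independent per-column replicate noise (ln-sd 0.10,
~10% technical CV for pooled single-run label-free quantification);
enriched proteins have both sensor columns multiplied by a 10× fold, and
a subset have control set exactly to 0. The first four spiked proteins
are named for canonical dyadic markers so their recovery can be asserted.
An i.i.d.-per-column model was rejected: at these parameters it would
randomly drop ~11% of genuinely enriched proteins below the ratio-5 line,
which contradicts how cleanly such screens recover strong positives.

## Striation periodicity and colocalization

Profiles are sampled along a user-placed line by bilinear interpolation
at pixel-size steps, averaged across the sampling width. The period is
the first autocorrelation local maximum beyond 0.5 µm (excluding the
PSF shoulder) with prominence > 0.1 **and** autocorrelation ≥ 0.2 — the
height floor is required because on finite white-noise profiles chance
peaks clear the prominence bar alone at high rate, while genuine
striations correlate far above 0.2 period-to-period. Autocorrelation is
used instead of an FFT argmax because single-cell profiles are short.
Colocalization reports Pearson r of the raw profiles (no thresholding;
Manders-style coefficients are out of scope) and the lag maximising the
normalised cross-correlation within ± one period; for strongly periodic
profiles the lag is inherently ambiguous modulo the period, and exact
ties resolve to the smallest |lag|.

## Pipeline and reproducibility

`RunConfig` (JSON) rejects unknown keys and range-checks every stage's
parameters by instantiating the owning config dataclass. Each stage gets
an independent 31-bit seed derived from the run seed and stage index.
The manifest records the tool version, a canonical config hash, SHA-256
digests of every written analysis file, and per-stage timings; identical
(config, seed) reruns produce byte-identical analysis files (asserted in
tests), with the manifest's timings the only varying output.

## Problem sizes

Validation batteries use 10–20 seeds per condition, 8–16 s synthetic
scans, 40 × 20 µm images (20 × 10 µm for paired direction contrasts,
where the construction axis is supplied so the contrast isolates the
fraction readout), 100 random ranking tables, and 100 white-noise
profiles per null check — sizes at which every Monte-Carlo bound in the
test suite has comfortable margin while a full run stays within a few
minutes on one CPU.

## Known limitations

* The transverse/longitudinal classifier assumes one cell per image and a
  single global axis; strongly curved cells violate this.
* Spark FWHM/duration are read from interpolated half-maximum extents of
  a smoothed field and inherit its slight widening; amplitudes of
  overlapping events at one site share a spatial profile.
* The default 150 ms post-stimulus exclusion assumes evoked release has
  decayed by then; with slow transients (τ ≥ 150 ms) the tail past the
  window is still detected, so spontaneous spark counting should use
  unpaced recordings or a longer `exclusion_ms`.
* The coupling-fidelity threshold (0.5× median site-stimulus peak)
  presumes at least half of site–stimulus pairs release; it is not
  calibrated for coupling probabilities below ~0.5.
* The EM coupling ratio counts perimeter within a fixed distance of jSR
  traces; it does not check facing orientation, so a trace passing close
  to the far side of a tubule would be counted.
* The blind spectral axis estimate needs a detectable sarcomere-band
  peak; heavily disrupted small fields can legitimately fail it (raised
  as "no structure" rather than guessed).
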