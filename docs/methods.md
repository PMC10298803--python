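# Methods

This note records the models, conventions, numerical choices and known
limitations behind the `tonotopy` package. Coordinates are (frame, row,
col), 0-based; event start/end frames are inclusive; time is seconds from
recording start; ΔF/F is dimensionless.

## Signal conditioning (`trace`)

**ΔF/F.** Two baseline conventions are supported, matching how the two
recording types are normalized in practice: `pixel_p10` takes F₀ as the
10th percentile of each pixel's (or each grid-ROI trace's) values over the
whole recording; `roi_median` takes the median, used for hair-cell and
neuron soma ROIs. Percentiles use linear interpolation between order
statistics (the numpy default), which the test suite pins against an
independent sort-and-index oracle. A non-positive F₀ is an error that names
the offending pixel/ROI rather than propagating infinities.

**Photobleach correction** fits F(t) = a·exp(−t/τ) + c by least squares,
initialized from a log-linear regression of the offset-subtracted trace,
and subtracts only the decaying term — the offset stays, so corrected
traces keep their baseline. Non-convergence is flagged, not fatal: the
input is returned unchanged. Transients riding on the decay bias the fit
by construction; the tests bound that bias at 5 % of event amplitude for
sparse events, which is the regime the correction is used in.

**Peak detection** thresholds at median + k·SD (k = 3) of the full trace —
the SD is single-pass and includes event frames, mirroring a plain MATLAB
`std` over the recording — with a separate minimum amplitude (0.10 ΔF/F for
calcium; detector parameters take pA equivalents for electrophysiology).
Peaks are strict local maxima; a plateau counts once, at its first frame.
Peak counts are monotone non-increasing in both criteria (property-tested).

## Event segmentation (`segmentation`)

The supporting-cell region is tiled with square grid ROIs (default 10 px ≈
8.3 µm at the confocal pixel scale). Edge tiles smaller than half a square
are discarded to avoid area bias. Each ROI trace is binarized at its own
median + 3 SD with a strict inequality, so a constant (zero-variance) trace
is never active. Events are connected components of active (frame, row,
col) voxels under 26-connectivity by default (6-connectivity available);
components spanning < 3 frames or < 5 distinct ROIs are removed. Equality
with a brute-force flood fill is property-tested on random rasters, and
active-voxel counts are conserved between surviving events and filtered
components.

Merged events are split by k-means on (frame·w_t, row, col) with w_t = 1
(one frame ≡ one grid unit; there is no principled exchange rate between
frames and tiles, so the weight is exposed). The split trigger — ≥ 2 local
maxima in the event's active-ROI-count time series separated by a ≥ 30 %
trough — stands in for the by-eye confirmation such splits normally get and
is deliberately conservative and configurable. Split parts are re-checked
against the duration/size filters.

Event frequency is reported per 0.01 mm² per minute. The area normalization
is standard for this preparation; the per-minute time base is a
documented choice (configurable), since a frequency needs one.

## Per-cell analysis (`cells`)

Synchrony is the full pairwise Pearson matrix on ΔF/F traces (not
binarized rasters). The scalar summary takes each ROI's 80th-percentile
pairwise r, then averages over ROIs; the wording that definition derives
from is ambiguous between per-ROI-then-mean and a pooled percentile, so
both are implemented, with per-ROI-then-mean the default. Zero-variance
traces produce missing pairs excluded from the summary.

Hair-cell peaks are assigned to the supporting-cell event whose inclusive
[start, end] window contains them; where windows overlap, the
earliest-starting event consumes the peak. Assignment conserves peaks
(assigned + unassigned = total) and is tested against an exhaustive
double-loop oracle, including duplicate peak frames.

The K⁺ filter keeps neurons whose ΔF/F inside the wash window exceeds 0.10
strictly. Drug-wash comparisons exclude a 90 s wash-in gap after perfusion
change from both rate windows; a post window under 60 s is flagged.

## Transmitted-light analysis (`intrinsic`)

Crenations are detected on difference movies diff[n] = frame[n+lag] −
frame[n] (lag 5 s at 1 fps). Each |diff| frame is thresholded at its own
mean + 3 SD, then — following the stated, unusual, order — the *binary*
mask is Gaussian-smoothed (σ = 12 px) and re-binarized. The re-binarization
level is 0.5: half the plateau value of a 0/1 mask, so a solid patch keeps
its border (the smoothed step crosses 0.5 exactly at the edge) while
scattered supra-threshold noise pixels, whose smoothed density is far below
0.5, vanish. Detections overlapping ≥ 25 % with a region from an earlier
difference frame are merged (same physical crenation, onset = first frame);
the threshold is configurable. Areas are pixel counts × (µm/px)². For the
σ = 12 smoothing to keep area error within ~10 %, patches must be large
relative to σ; the synthetic default (≈ 100 px side at 0.5 µm/px, i.e.
2,500 µm²) is in that regime and the tests measure ≈ 5 % error from corner
rounding.

Centroid counting binarizes (Otsu unless a threshold is given), restricts
to the mask, and counts 8-connected components with ≥ 10 px (noise floor).
Touching cells merge into one count — no watershed, by design.

## Widefield mapping (`widefield`)

Spontaneous collicular events are peaks on the mean left/right ROI ΔF/F
traces at a fixed 1 % threshold and 1 % minimum amplitude; peaks on the two
sides within ±1 s merge into one bilateral event (the window is wide
relative to multi-second event half-widths, and configurable), dominance is
the larger amplitude, and half-width is the interpolated FWHM.

Line scans sample a rotated rectangle by bilinear interpolation
(`scipy.ndimage.map_coordinates`) and average across the short axis,
producing a (positions × frames) profile. Band events are 8-connected
regional maxima of that image above 2 % ΔF/F; a plateau counts once at its
centroid, and a perfectly flat field has no events. Band width normalizes
the spatial profile at the event frame to its peak and counts the
contiguous run of positions above 0.75 about the peak; for a Gaussian
profile of width σ this equals 2σ√(2·ln(4/3)) ≈ 1.517 σ, which the tests
verify to within one position. Spatial integrals use the trapezoidal rule
at unit spacing.

Tone-evoked analysis aligns −1 s…+3 s around each onset, averages repeats
per (frequency, level), and summarizes amplitude as the post-onset peak of
the mean trace minus the pre-onset baseline mean. The evoked threshold
criterion is nowhere stated for this measurement, so the ABR rule is
adopted by analogy: lowest level, linearly interpolated, whose amplitude
exceeds baseline mean + 2 SD; a never-exceeding series returns a censored
sentinel one level step above the maximum tested level. Activated area
counts pixels above 15 % ΔF/F times pixel area. Tonotopic peak positions
are per-frequency argmaxes of the line-scan profile, reported both absolute
(vs the medial end) and relative to the lowest tested frequency.

## Audiometry (`audiometry`)

ABR: peak-to-peak (max − min) per averaged waveform in a signal window; the
criterion is mean + 2 SD of the per-level *background-window* peak-to-peak
values. "Background" is not defined by the source procedure; the
pre-stimulus segment at the head of each averaged trace is the default
(trace-tail available). The threshold is the lowest level whose p2p exceeds
the criterion with all higher levels also above it (non-monotone families
use the highest crossing and carry a warning), linearly interpolated in
level–amplitude space against the next lower level, clamped when the
lowest tested level already exceeds, and censored (max level + step) when
none does.

DPOAE: F1 = 0.909·Fc, F2 = 1.09·Fc, distortion product at 2F1−F2 (11.648
kHz for Fc = 16 kHz). Per level, the DP amplitude is the spectrum at the
nearest bin and the noise criterion is mean + 2 SD of the ±10 adjacent bins
excluding a ±2-bin guard; the threshold interpolates the level where the
DP-minus-criterion margin crosses zero.

## Two-photon tuning (`tuning`)

Best frequency is the frequency of the global maximum over the (frequency ×
level) response surface; ties resolve to the lower frequency. Bandwidth
fits a·exp(−((x−b)/c)²) over x = log₂ f to the top-level amplitudes,
initialized at (max, argmax, 1 octave) with b bounded to the tested range,
and reports σ = c/√2 octaves; cells are excluded (None) on < 4 finite
points, zero curvature, or non-convergence. Responsiveness requires any
response above baseline mean + 3 baseline SD (the criterion is not
externally specified; it is configurable). PCA operates on mean-centered
raw flattened response surfaces — no z-scoring, mirroring direct PCA of
amplitudes — returning the top 3 scores.

## Synthetic data (`synth`)

The generators define the study conditions the tests run under; all draws
come from one seeded `numpy` Generator per call (no global state), and
identical configs are byte-identical.

- **Supporting-cell movies**: 2 Hz, trapezoidal events (1-frame rise at
  50 %, plateau at 100 %, 2-frame decay at 50/25 %) painted on whole grid
  tiles of an elliptical footprint inside the lower-half region; a row of
  20 oval hair-cell ROIs sits above the region border and cells under an
  event's lateral extent receive coupled transients. Events are temporally
  disjoint by construction — splitting of genuinely merged events is
  exercised on purpose-built fused fixtures instead — and event counts are
  Poisson draws at the configured rate. Defaults emulate the confocal
  condition (2 Hz, 425 µm field, ~10-min recordings); tests and the
  acceptance script run a scaled field (120×120 px, 5 min) as the
  package's standard desk-scale condition.
- **Neuron traces**: population burst events joined with probability equal
  to the burst-correlation parameter by "responsive" cells, independent
  bursts otherwise, plus a terminal high-K⁺ ramp (0.5 ΔF/F responsive,
  0.05 unresponsive, straddling the 0.10 filter).
- **Widefield movies**: two circular colliculi; each event is a Gaussian
  cross-section band (σ = 8 positions by default) across a tonotopic axis
  at the configured angle, with independent log-normal left/right
  amplitudes (dominance variability is real but unmodeled upstream, so a
  heavy-tailed amplitude law is assumed). Evoked mode places the band at a
  position linear in log₂ frequency and scales amplitude by a saturating
  growth above a planted level threshold (exactly zero below it, so
  threshold recovery is well-posed).
- **ABR families**: per level, a background-window oscillation with exact
  peak-to-peak drawn N(μ_b, s_b) and a signal-window wave whose p2p is
  μ_b + max(0, growth·(L − onset)). The ground-truth threshold is the
  closed-form crossing of that planted curve over the realized criterion
  (mean + 2 SD of the drawn background p2ps), computed analytically by the
  generator — never by running the detector — so recovery tests check the
  whole detector path (waveform p2p → criterion → monotone crossing →
  interpolation) against an independent algebraic prediction. DPOAE
  spectra are built the same way around the 2F1−F2 bin.
- **Crenation movies**: disjoint square patches darkening linearly over
  4 s; configurations that cannot pack the requested disjoint patches are
  rejected.
- **Tuning tensors**: per cell, amplitude × Gaussian(log₂ f; BF, σ) ×
  logistic(level; threshold, 8 dB slope) + Gaussian noise; BFs drawn from
  interior tested frequencies (9 half-octave steps, 4–64 kHz; levels
  30–90 dB in 20 dB steps). The two-archetype mode contrasts low-BF
  narrow/weak with high-BF broad/strong response surfaces.

**What the generators do not emulate** — and what passing tests therefore
do not show about real data: indicator kinetics and saturation, motion and
registration artifacts, spatially correlated (shot/vignetting) noise,
overlapping supporting-cell events, wave-like event propagation, neuropil
contamination structure, and any biophysics of ATP release or Cx26
genotype beyond parameter presets. Recovery results here validate the
measurement code, not the biology.

## Numerical choices and degenerate inputs

Strict inequalities at every threshold (a flat trace is never active);
first-index tie-breaks for argmax ties, flagged where the contract says so;
censored-threshold sentinel = max tested level + one step; k-means and PCA
seeded; float32 movies for memory, float64 statistics. Problem sizes in
tests and the acceptance script (120×120 px, 5-min movies; 500 oracle
rasters; 100 ABR seeds; 200 tuning cells) were chosen as the standard
desk-scale conditions for this package and complete in well under a minute
each.

## Known limitations

The split trigger for merged events is a heuristic stand-in for visual
confirmation. Photobleach correction assumes a single exponential.
Cross-frame crenation merging assumes slow, spatially stable patches.
Bilateral matching is greedy in frame order. The evoked-threshold and
responsiveness criteria are package decisions where the upstream procedure
is silent, and are exposed as parameters.
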