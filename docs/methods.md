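# Methods

## Scope and design

The package quantifies four kinds of measurement around microvascular and
wound-healing studies: (i) multi-parametric photoacoustic microscopy (PAM) of
single vessels — structure, hemoglobin oxygen saturation (sO2) and blood flow
speed, with derived volumetric flow, oxygen extraction fraction (OEF) and
relative oxygen metabolism (MRO2); (ii) ratiometric
fluorescence/phosphorescence tissue-oxygen mapping; (iii) open-wound closure
tracking; (iv) noncompartmental skin pharmacokinetics, plus a group/time
statistics helper. Because no raw in vivo data accompany such studies, every
estimator is validated against synthetic phantoms whose ground truth is known
by construction; the generators live in `mpam.synthetic` and are first-class,
tested code.

## PAM forward model and inversion

**Amplitude model.** Inside a vessel of saturation s, the expected envelope
amplitude at wavelength λ is F(λ)·[s·εHbO2(λ) + (1−s)·εHb(λ)], normalised by
εHbO2(532); outside it is zero. The fluence ratio F(532)/F(559) defaults to 1
(wavelength-dependent fluence calibration is instrument-specific) and is a
config parameter everywhere. Extinction coefficients at 532 and 559 nm are
bundled in `mpam/data/hemoglobin_extinction.csv` (approximate values from the
standard Gratzer/Kollias compilation; provenance in the file header). Both
the simulator and the unmixer read the same table, so round-trip tests do not
depend on tabulation precision. Noise is additive Gaussian post-envelope
(clipped at zero), which keeps recovery tolerances analytically predictable.

**Envelope.** `pam.envelope` is the magnitude of the analytic signal
(Hilbert transform). Tests check a pure tone (envelope = amplitude within 1%
away from the 5% edge segments) and a Gaussian-windowed tone (envelope =
window within 2% of peak).

**sO2 unmixing.** The 2×2 linear system is solved per pixel; negative
concentrations are clipped to the boundary of the non-negativity constraint
and sO2 renormalised — in two dimensions this equals the constrained
least-squares boundary solution. Pixels with 532 nm amplitude below the noise
floor are flagged invalid (NaN), never zero-filled. The estimate is invariant
to a common rescaling of both channels. Maps are 2-D en-face projections: the
projection for unmixing is the amplitude-weighted mean over depth, which for
a vessel of uniform composition equals the in-vessel amplitude.

**Flow.** The simulator advects a frozen 1-D random reflectivity pattern
along the vessel axis by v/f per repeat (f = A-line rate), shifting sub-pixel
by linear interpolation on a grid of w/10. The pattern is white noise
smoothed with a Gaussian of σ = w/2 (w = beam waist), giving autocorrelation
exp(−(Δ/w)²) and hence an inter-repeat correlation C(k) = exp(−(v·k/(f·w))²).
The estimator computes mean Pearson correlations at lags k = 1…10 over
mean-subtracted A-lines and fits the decay by regression of −ln C on k²
through the origin, weighted by C² (inverse variance of −ln C). Only the
contiguous prefix of lags with C > 0.3 enters the fit: the empirical
correlation of a single finite window carries a seed-dependent plateau of
order ±0.1 at decorrelated lags, and including plateau lags biases the speed
low. With w = 3 µm and f = 2 kHz the informative range is roughly
0.05–6 mm/s; faster flows decorrelate within one lag and report 0 with
quality 0. A zero-variance stack reports speed 0 with quality flagged
degenerate. Defaults (f = 2 kHz for the flow sequence, w = 3 µm, 100 repeats,
window 8000 samples ≈ 2.4 mm of pattern) were chosen so the correlation
decay is resolvable across 0.2–5 mm/s and the finite-window correlation
noise (∼(window/w)^−1/2) stays near 0.03.

## Vessel segmentation and metrics

Segmentation is two-stage: a multi-scale Sato tubeness filter plus hysteresis
threshold *detects* vessel-like structures, and the final mask takes pixels
above half the 99th-percentile amplitude within detected components — a
half-maximum criterion, so mask width tracks true width. The mask is
skeletonised with Lee thinning (Zhang's variant can drop half of even-width
45° bands), junction pixels (≥3 skeleton neighbours) are removed to split
branches, segments shorter than 10 px are discarded, and every mask pixel is
assigned to its nearest surviving centerline. Segmentation constants
(hysteresis fractions 0.2/0.5 of the normalised tubeness, half-max mask
fraction 0.5) are parameters.

**Diameter.** The per-segment diameter is area-based: d = (mask area − free-
end cap area) / centerline length. The centerline length is measured on a
moving-average-smoothed skeleton path (raw 8-connected step sums overestimate
oblique digital lines by up to ~8%), extended at free ends to the mask
boundary (thinning retracts ends past the rasterisation cap centres); the
caps that rasterisation adds at free ends — but not at junction-split ends —
are subtracted as half-discs of the distance-transform radius. The distance
transform along the centerline still sets that radius scale. A pure
2×mean-EDT estimator was rejected because ±0.5 px quantisation is a 25%
error on a 4 px tube; the area/length form averages the rasterisation noise
along the whole segment. At exactly 45° the rasterised band's own width
differs from the continuous diameter by up to ~12% for 4 px tubes
(lattice-plane granularity); the perpendicular-profile FWHM oracle measured
on the ground-truth mask confirms the estimator there. Synthetic vessels are
placed at generic sub-pixel offsets so axis-aligned tubes avoid the
degenerate centre-of-pixel alignment.

**Flow, OEF, MRO2.** F = v·π·d²/4, converted to µL/min (v in mm/s, d in µm:
1 m³ = 10⁹ µL). saO2 and svO2 are flow-weighted means over the arterial and
venous classes — OEF is a mass-balance quantity, so weighting by flow is the
physically consistent choice; unweighted means are a fallback when flows are
missing. Classes come from a configurable sO2 threshold (default 0.75, ties
arterial). MRO2 uses total arterial inflow (the conventional supply-side
choice). OEF with svO2 > saO2 is flagged inverted, not clipped.

## Ratiometric oxygen mapping

The forward model is single-site Stern–Volmer quenching: blue = g·B0 + bg_b,
red = g·B0/(1 + Ksv·pO2) + bg_r, with the blue fluorescence
oxygen-independent and background frames taken before nanoparticle addition.
Analysis subtracts backgrounds (floored at 0), forms the per-pixel
blue/red ratio where red exceeds a validity floor (default 3× the background
standard deviation, to avoid ratio blow-up in unlabeled regions), renders a
grayscale image by affine scaling of the ratio, and averages the gray value
over the wound-bed ROI. Gray bounds are fixed and study-wide by default —
cross-day comparability requires a common scale — with per-image min/max as
an option. Relative pO2 inverts the ratio: pO2 = (R/R0 − 1)/Ksv. The module
reports relative oxygenation only (percent of an explicit reference value);
absolute calibration in mmHg is out of scope.

## Wound closure, PK, statistics

Closure is 100 × area(day t)/area(day 0) on binary open-wound masks; values
above 100% (early swelling) are reported as-is. Masks are accepted as inputs;
a simple colour-threshold segmenter for bright-field photographs is provided
as a convenience only. PK summaries are noncompartmental: Cmax and Tmax from
the observed maximum (ties → earliest), AUC by the linear trapezoidal rule
over the sampled window with no extrapolation — the exposure endpoint of
interest is over the observed window, not to infinity. Both per-animal and
pointwise-median profile summaries are available. The statistics helper fits
a two-factor (group × time) ANOVA and Tukey-adjusted pairwise group
comparisons per timepoint (delegated to statsmodels), with stars at
0.05/0.01/0.001/0.0001; its type-I error is checked empirically on seeded
null simulations at n = 8/group, and an independent permutation test serves
as the oracle for strongly separated groups. Note the exact two-sided
permutation floor at n = 8 per group is 2/C(16,8) ≈ 1.6×10⁻⁴ — the smallest
p any permutation test can report at that sample size.

## Synthetic study conditions

The generators' defaults are the study conditions. Vessels: diameters
20–60 µm, sO2 0.4–1.0, speeds 0.2–5 mm/s, at 2 µm/pixel (configurable; PAM
lateral sampling is instrument-specific). The demo vasculature has two
arterial (sO2 0.95/0.92) and two venous (0.65/0.60) vessels. Wound series
shrink a disc radius geometrically: 5.0%/day (treated) and 2.15%/day
(vehicle), which yields day-6 open-wound fractions of 54% and 77% of the
original area. The default PK profile is a Bateman curve with ka = 0.43/h,
ke = 0.0435/h, scale = 51.83 pg/mg, peaking at 36 pg/mg near 6 h with
cumulative 0–144 h exposure ≈ 1065 pg·h/mg; the sampling design
(0,1,2,4,6,8,12,18,24,36,48,60,72,96,120,144 h) is dense around the peak and
keeps the trapezoidal panel error (ke·h)²/12 below ~2% per panel.

What the phantoms do **not** emulate: acoustic wave propagation, depth-
dependent fluence, speckle statistics beyond the frozen-pattern model,
curved/tortuous vessels, motion artifacts, nanoparticle photobleaching, or
irregular wound geometry. Passing tests therefore demonstrate correctness of
the estimators under their stated models — not robustness to every artifact
of real acquisitions.

## Numerical choices and degenerate inputs

Blank structure images segment to an empty result (not an error). A vessel
with no valid sO2 pixels reports NaN, never 0. OEF requires at least one
vessel of each class and saO2 > 0. Empty day-0 wound masks, reversed PK time
axes, ka = ke Bateman inputs, negative Ksv, and non-positive red floors are
rejected with ValueError. All generators are bit-reproducible given a seed;
pipeline stages rerun with identical config + seed produce byte-identical
outputs, and every CLI artifact carries a JSON sidecar with the config hash,
seed and package version.

## Known limitations

- Flow speeds outside the resolvable window of the chosen prf·w report 0; the
  estimator does not extrapolate beyond lag-1 decorrelation, and additive
  noise attenuates all correlations uniformly, biasing fitted speeds high
  unless an intercept is calibrated.
- The diameter estimator assumes locally straight, non-overlapping segments;
  heavily curved vessels shorter than the smoothing window fall back to chord
  length.
- The A/V classifier is a pure sO2 threshold; it cannot separate arterioles
  from well-oxygenated capillaries.
- The ANOVA helper assumes a complete, balanced-enough design with ≥2
  replicates per cell; no mixed-effects or repeated-measures modelling.
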