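# Methods

## Measurement model

The core quantity is the total fluorescence of one centriole above
background, inside a polygon contour drawn around its signal. Pixel
membership is decided by the pixel center (integer coordinates, x = column,
y = row, origin top-left): a pixel belongs to the contour when its center is
strictly inside the polygon under the even-odd rule, or exactly on the
boundary. This raster semantics is deterministic, matches common ROI
conventions, and is cross-checked in the tests against an independent
geometric oracle. Background is subtracted per pixel and clamped at zero
(`Σ max(0, I − b)`); a single clamp of the summed difference is available as
an option (`clamp="total"`). Per-pixel clamping is the default because
"intensity above background" reads most naturally per pixel; the two differ
only when the background exceeds pixel values inside the contour, i.e. for
marker-negative centrioles, where both give ≈ 0.

Measurements are taken on the contour's `z_ref` plane or (default) the
maximum-intensity z projection. Both are supported because published
contour workflows do not always state the choice; the projection default is
robust to small focus errors for diffraction-limited foci.

Background is either a fixed experimenter-chosen value or (default) the
median of an annulus obtained by dilating the contour by 2 px (inner) and
6 px (outer). The median is insensitive to tail contamination from the
neighbouring centriole. The marker-detection floor defaults to
`3 × annulus SD × √pixel_count` — the 3σ propagation of background noise
into a summed total — and decides marker-positive vs marker-negative calls.

## Age assignment and asymmetry categories

The centriole with the larger total Asl is the mother. A relative Asl
difference within `tie_tolerance` (default 5%) is declared ambiguous and
excluded from ratio statistics (counted in the QC report) — this prevents
noise-driven age flips for near-symmetric pairs.

The marker ratio r = daughter/mother is binned: transition r < 2, strong
2 ≤ r ≤ 10 (boundaries inclusive; they are measure-zero in practice),
complete r > 10 with r = +∞ when only the daughter exceeds the detection
floor. Two-centriole centrosomes with both totals below the floor are
reported as `no_marker` and excluded from ratio plots. Single-centriole
centrosomes are declared by the ROI file containing one contour and
classified by marker presence only. r < 1 (marker biased to the mother)
additionally sets the `inverted` flag; the inverted fraction is reported
over metaphase + anaphase by default, the stages where asymmetry should be
fully established.

## FRAP model

Traces are normalized to Signal/Noise,
`S/N = (centrosome − bg) / (cytoplasm − bg)`, with both numerator and
denominator background-subtracted so that acquisition gain cancels exactly
and additive offsets cancel when they are co-measured in the background
channel. Frames with cytoplasm ≤ background are undefined (NaN).

Two recovery summaries are computed:

- **Descriptive** (`recovery_metrics`): pre-bleach mean, post-bleach
  minimum, recovery fraction `(S/N − min)/(pre − min)`, and the
  first time the fraction reaches 0.5 (linear interpolation between
  frames). On a noiseless single-exponential recovery with immobile
  fraction f, this crossing sits at `ln(1/(1 − 0.5/(1 − f)))/k`, not at
  ln 2/k, because the fraction plateaus at 1 − f.
- **Model fit** (`fit_recovery`): least-squares fit of
  `S/N(t) = floor + A·(1 − e^{−kt})` to the post-bleach frames, reporting
  k, the exchange half-time ln 2/k, and the immobile fraction
  `1 − A/(pre − floor)`. The fit pools the whole trace, so its half-time is
  the estimator of choice under noise; the first-crossing metric is kept
  for descriptive plots. Parameter-recovery checks therefore assert the
  ensemble (mean/median over seeded replicates) of the fitted half-time
  against ln 2/k.

The generator produces S/N directly — flat `pre_level`, a drop to
`pre_level·(1 − depth)` at the bleach, recovery of the mobile pool
`pre_level·depth·(1 − f)·(1 − e^{−kt})` — plus Gaussian readout noise, and
embeds it into raw centrosome/cytoplasm/background channels so the analysis
path is exercised end to end. Default conditions: frame interval 30 s (the
low end of typical 30–60 s FRAP acquisition), bleach at frame 5, depth 0.8,
45 frames (≈20 min post-bleach, several recovery half-lives at
k = 0.01 s⁻¹).

## Spindle and MTOC readouts

The spindle axis is the undirected line through the two pole centroids,
defined modulo 180°. Frame-to-frame changes are unwrapped by always taking
the representative with |Δ| ≤ 90°, which assumes the spindle turns by less
than 90° between frames — safe at the ~minutes frame intervals of mitotic
movies — and makes pole-label swaps invisible. Net rotation is the
unwrapped angle difference between NEBD and anaphase; maximum rotation is
the largest excursion from the NEBD orientation inside that window. Both
are emitted because published rotation plots show both a net and a maximal
series. Division-orientation change between consecutive mitoses is the
smallest angle between two undirected axes, in [0°, 90°]; all angle
operations are invariant under global rotation and translation, and 3D tilt
is out of scope (axes are compared in the imaging plane).

MTOC phenotype: a pole is *active* when its median microtubule-intensity /
cytoplasm ratio over the interphase window reaches a threshold (default
1.5×). Apical-only activity is the wild-type asymmetry; both poles active
is a gain phenotype; no active pole or an inactive apical pole is a loss.
The original scoring is qualitative (by eye); the threshold is this
package's declared quantitative proxy.

## Synthetic data

`render_pair` draws each focus as an isotropic 2D Gaussian PSF integrated
per pixel (error-function differences, so noiseless photon mass is
conserved to border truncation), over a constant background, with Poisson
noise on the expectation and optional additive Gaussian read noise —
a standard camera model. Defaults: psf_sigma 1.5 px, background
50 AU/pixel, 64×64 frames, foci 20 px apart (well beyond the 3σ overlap
flag). Measurement contours generated for these renders are 24-gon circles
of radius 3σ, which capture ≈98.9% of the Gaussian mass; recovered totals
are therefore biased low by ≈1%, well inside the 10% recovery tolerance
used in the end-to-end checks. Study-condition totals (Asl mother
8000–15000 AU, Asl mother/daughter ratio 1.3–3, marker totals ≥ 3000 AU)
keep the peak signal-to-noise ratio above ~10.

Within-category ratio draws in `simulate_population` are log-uniform over
the category interval (the natural scale for a ratio; only the interval
boundaries are specified by the classification scheme), with the
transition interval truncated below at 0.1 and the complete interval above
at 1000 so every draw is finite and measurable.

What the generators do **not** emulate: structured-illumination
reconstruction artifacts, 3D PSFs, chromatic misalignment, photobleaching
during ordinary acquisition, cell-to-cell background variation, or
centriole movement within a frame. Passing recovery tests therefore
demonstrates correctness of the measurement and inference code under a
faithful noise model, not robustness to every property of real microscope
data.

## Statistics

Fisher exact (two-sided) follows the "sum of all tables with the observed
margins whose probability does not exceed the observed table's" definition,
with a 1 + 1e-7 relative guard against floating-point ties; a zero margin
is degenerate and returns p = 1. The implementation is delegated to
scipy.stats (whose convention is exactly this) and verified in the tests
against an exhaustive log-space enumeration oracle for every 2×2 table with
N ≤ 30. Mann–Whitney uses midranks and the exact label-enumeration null
when n + m ≤ 16 with no ties (cheap and exact), otherwise the normal
approximation with tie and continuity corrections; exactness is verified
against a full permutation oracle. Report formatting: p ≥ 1e-4 to four
decimals, smaller values in scientific notation with four significant
digits; stars at strict thresholds 0.05/0.01/0.001/0.0001. Counts are
reconstructed from reported percentages by half-to-even rounding of
percent·n/100. No multiple-testing correction is applied.

## Problem sizes

The verification suite and the acceptance script use: 200 rendered pairs
(64×64 px, 2 channels) for measurement/assignment/category recovery; an
exhaustive Fisher sweep over all 46,375 tables with N ≤ 30; 100
permutation-checked rank tests at n = m = 5; 10,000 random ratios for the
classification sweep; 100 noisy FRAP traces of 45 frames; 500 jittered
spindle tracks of 21 frames; populations of 1000–2000 records for
fraction-recovery checks. These sizes give binomial/Monte-Carlo precision
comfortably finer than the tolerances asserted while keeping the whole
suite under a minute of compute.

## Known limitations

- Contours are inputs; the package does not detect or segment centrioles.
- Overlapping centrioles are flagged and excluded, not deblended.
- The FRAP analysis is descriptive plus a single-exponential fit; it does
  not discriminate mechanistic transfer-vs-recruitment models.
- Apical/basal identity, cell-cycle stage and bleach frames are metadata,
  not inferred from images.
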