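# Methods

## The shock filter on luminance profiles

A grid image is collapsed onto its axes by row and column means. Between
lines of spots the vertical profile dips, over a line it peaks; the same
holds per spot in a line's horizontal profile. The shock filter

    u_t = −sign(G_σ ∗ u_xx) · |u_x|

evolves such a profile to a piecewise-constant steady state: where the
(Gaussian-smoothed) second derivative is positive the profile is eroded,
where negative it is dilated, so every flank steepens into a discontinuity
at the original edge position while flat and linear stretches stay put
(`sign(0) = 0`).

**Discretisation.** Explicit upwind (morphological) scheme with one-sided
differences chosen by the transport direction:
`grad_erode = max(D⁻, −D⁺, 0)` and `grad_dilate = max(D⁺, −D⁻, 0)` with
`D± ` the forward/backward differences. Per step,
`u ← u − dt·grad_erode` where the smoothed curvature is positive and
`u ← u + dt·grad_dilate` where negative. The scheme is monotone for
`dt ≤ 1`; the default `dt = 0.5` keeps a safety margin. Under this scheme
the output never exceeds the input's min/max and total variation never
increases (both are enforced as property tests).

**Boundaries.** End samples are held fixed, one-sided differences use
replicated edges, and the second derivative is defined as zero at the two
end samples (natural ends). The last choice matters: with a replicated
second-difference stencil a linear ramp has nonzero curvature at its ends,
and the Gaussian smoothing would leak that into the interior and set a
perfectly linear profile in motion.

**Smoothing.** σ (default 1 px) applies to the *sign argument only*, so
noise cannot seed spurious shocks while the transport term keeps full
resolution. The convolution is computed as an explicit loop over kernel
taps; this makes the float arithmetic reproducible sample-by-sample, which
the test suite exploits by checking bit-exact agreement with an
independently coded scalar reference implementation.

**Termination.** Iteration stops when the largest per-sample update falls
below `10⁻³` of the profile's dynamic range, or after `max_iters = 200`
steps — comfortably above the nominal 14 px spot diameter, which bounds
how far a shock must travel.

## Reading the steady state

Jumps of the filtered profile (`|Δu| ≥` 10 % of its dynamic range; runs of
same-sign differences merge into the steepest sample) are paired into
plateaus: a pair opens at an up-jump from the local base level and closes
at the down-jump that returns the profile below
`base + 0.5·(peak − base)`. The hysteresis matters because the discrete
steady state occasionally keeps a small staircase step on a bump's flank;
closing on that step would bias the plateau midpoint by several pixels.
Unpaired jumps — image margins, stray noise plateaus — are ignored.
Line and spot centres are the midpoints of a plateau's region above half
its height (the FWHM midpoint; identical to the plateau midpoint for clean
symmetric plateaus, but it stays on the spot when a weaker artefact
plateau merges into the same pair).  Plateau widths give the spot radii
directly, since the shocks form at the object edges.

On the vertical profile, plateaus whose amplitude is below half the median
line amplitude are discarded. A genuine line aggregates an entire line of
spots, so this never removes real lines, but it does remove the weak, wide
plateaus produced by rotation-fill wedges and margin noise.

## Hexagonal decomposition

A hexagonal layout interleaves two rectangular grids (uneven and even
lines, alternate lines shifted by half a pitch). Line *k*'s band runs from
the centre of line *k−1* to the centre of line *k+1* (outermost lines get
extrapolated separation lines), so it contains the full line plus the
half-spots of its vertical neighbours. Each band is padded with ⌈b/2⌉
background-valued rows (and ⌈a/2⌉ columns, so erosion windows at the
strip borders are not truncated) and opened with an elliptical
structuring element of the estimated spot radii: the half-spots cannot
contain the ellipse and vanish, full spots survive (attenuated but well
above background). The fill value is the image's first percentile rather
than its absolute minimum, which can be a single clipped pixel; all
openings use reflected borders so edge statistics match the interior.
The cleaned bands of each parity are placed back into a
background-valued frame, giving the two rectangular sub-images; their
pixel-wise maximum retains every spot of the original image, which the
acceptance suite verifies on ten random synthetic arrays.

Spot pitch comes from the highest positive local maximum of the
normalised, mean-removed profile autocorrelation. The half-width of the
first autocorrelation peak is exposed as a radius *scale* but is biased
low (≈ pitch/8 for a 50 % duty train), so the structuring-element radii
use the median shock-plateau widths instead.

If adjacent lines show no relative x-shift (cross-correlation shift below
a quarter pitch) the layout is treated as rectangular: all lines go to one
family with tight, non-overlapping bands, and the second sub-image is
empty. This keeps the tool usable on ordinary single-density arrays.

## Lattice completion and areas of interest

Weak or absent spots leave gaps in the per-line detections. Per image, an
ideal lattice `phase + k·pitch` is fitted: each detection's residual
modulo the pitch proposes a phase, the proposal with the most detections
within a quarter pitch wins, and the phase is refined by least squares
over those inliers. Both parity families sample the same lattice (one
shifted by the hexagonal offset), so *column support* is counted jointly
over all lines. The support rule is deliberately conservative, because
the top-hat passes background speckle that spot tails suppress inside the
grid but not in the margins, where surviving speckle hills can pass the
parity opening as spot-sized blobs near a phantom column one pitch
outside the grid: only detections whose plateau amplitude reaches half
their line's median may vote for a column, votes must lie within an
eighth of a pitch of the site, and a hexagonal column needs votes from
both parity families on at least three lines in total (a single family —
rectangular layout — needs two lines). Detections themselves are kept
with the quarter-pitch tolerance. Each line then reports exactly one
entry per lattice site in the accepted extent — the nearest detection
verbatim, or the site position flagged missing.

Every site receives a pitch-sized, axis-aligned area of interest *S*
(half-open, clipped at the image border), consistent with the
"cookie-cutter" quantification of commercial feature-extraction software.

## Segmentation and features

Inside *S*, Otsu's threshold proposes foreground; only the connected
component containing (or nearest to) the spot centre is kept. A
statistically flat *S* — dynamic range below three robust noise standard
deviations (1.4826 × MAD) — is declared missing with an empty foreground.
A site inserted as missing upstream is un-flagged when a component is
found, which is the recovery path for weakly expressed spots the profile
stage dropped; under noise an empty site then simply reports near-zero
intensity rather than a flag, mirroring how commercial tools quantify
every feature. Masks are computed on the log+median image: the top-hat
image is ideal for profiles (trends removed) but its residue is speckled
enough at single-spot scale to mislead a histogram threshold.

Features are measured on the rotation-corrected **raw** image so they stay
linear in physical fluorescence: background-subtracted intensity
`I = mean(fg) − mean(bg)` (negative values kept, not clipped), `R²` as the
squared Pearson correlation between the *S* pixels and a least-squares fit
of a radially symmetric Gaussian on a constant background (the one-colour
stand-in for the two-channel regression ratio of commercial software), and
`CV = std(fg − mean(bg)) / mean(fg − mean(bg))`.

Evaluation metrics: mean Euclidean centre distance and its standard
deviation over spots paired by grid index, positioning accuracy (% within
half a spot diameter), Pearson correlation and mean absolute difference of
feature vectors, and per-spot replicate MAE — the mean deviation of a
spot's replicate intensities from its replicate mean, so identical
replicates give exactly zero.

## Synthetic data

The generator emulates a one-colour hexagonal microarray scan at desk
scale: 8 lines × 20 spots, spot diameter 14 px (the nominal diameter of
production double-density arrays), pitch 28 px, hexagonal offset 14 px,
280 × 600 16-bit frame. Spots are radially symmetric Gaussian bumps
(FWHM = diameter) with amplitudes uniform in 20 000–40 000 counts; 5 % of
spots are weakly expressed (scaled to 5 % amplitude), 2 % are missing
(present in the ground truth, absent from the rendering). Additive
Gaussian noise with σ = 2 % of the maximum amplitude (800 counts) is
applied, values are clipped to [1, 2¹⁶−1] and quantised. The background
level defaults to 2000 counts, a realistic detector offset: with the 800-
count noise a near-zero background would clip a large fraction of pixels
at the floor, which no real scanner produces and which degrades
morphological background estimation. Optional global rotation and a
linear background gradient are available; `element_shape` switches the
Gaussian bumps for hard-edged disks, hexagons or annuli to emulate
scintillator screens and nanodisk arrays. Replicate sets share geometry
and amplitudes and draw independent noise from seeds `seed+1 … seed+r`.

What the generator does **not** emulate: scanner physics (comet tails,
donut spots, saturation blooming), spatially correlated background,
irregular or locally distorted lattices, and two-colour composites.
Passing tests therefore demonstrate correctness of the algorithmic chain
under controlled conditions, not robustness to every real-scan artefact.

## Preprocessing choices

The log transform `log(1+p)`, min–max stretched to [1, 2¹⁶], is the
simplest map that fills the dynamic range while compressing the 20-fold
amplitude spread enough for weak spots to register in the profiles. A
3×3 median between the log and the top-hat removes the pixel-scale
speckle the log transform makes of background noise — a white top-hat
passes structures smaller than its element, so without the median the
speckle would survive into the profiles (spots of the nominal ≥ 3 px
diameter are unaffected; `median_radius = 0` disables it). The top-hat
uses an ellipse of 1.5× the expected spot radii: just larger than a spot,
so spots pass and background trends do not. Rotation is estimated by
scanning Radon projections over ±5° in 0.05° steps for the angle with the
highest projection variance; the image (and the raw copy used for
intensity measurement) is rotated back by that angle with bilinear
interpolation, out-of-frame pixels filled with the image minimum.
Estimates below one search step are treated as zero so an already aligned
image is untouched.

## Problem sizes and defaults

The default test geometry (8 × 20 spots, 280 × 600 px) keeps a full
pipeline run around three seconds while preserving the nominal spot
diameter; the acceptance script runs the alignment study and the 20-fold
amplitude-range study at this size. All tolerances above (10 % jump
threshold, 50 % hysteresis, 50 % line-amplitude floor, quarter-pitch
inlier tolerance, 3σ flat guard) are package defaults, stated here once;
they are deliberately scale-free (fractions of local dynamic range or
pitch) so the same defaults serve full-size scans. The grid-inference
rules were hardened against a catalogue of structured failure modes
(margin-speckle phantom columns, rotation-wedge artefacts, artefact–spot
plateau merges) collected over a hundred simulated arrays spanning both
study configurations, all rotations and the rectangular degenerate case.

## Known limitations

- Skewed or locally irregular lattices are out of scope; only a global
  rotation is corrected.
- Grids with more than two interleaved line families are not supported.
- Weakly expressed spots at a few percent of the noise floor may be
  reported at their lattice position with the missing flag set when
  neither the profile stage nor the in-area threshold finds a clear
  component.
- The autocorrelation radius estimator is a biased scale proxy; radii are
  measured from shock-plateau widths.
- `R²` against a Gaussian spot model is a one-colour stand-in for the
  two-channel regression ratio of commercial software; absolute values
  agree closely on synthetic data but are not interchangeable with
  two-channel annotations on real scans.
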