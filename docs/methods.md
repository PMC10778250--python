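# Methods

## The dorsal-profile curve

A specimen is an ordered 30-point curve along the horse's dorsal outline,
tail base → facial crest end. Eight anatomical anchors are pinned at
canonical 1-based indices — 1 tail base, 5 lumbosacral junction, 8 L1,
15 T10, 27 atlantooccipital joint, 28 temporomandibular joint, 29 eye
canthus, 30 facial crest end — and runs of 3, 2, 6 and 11 intermediate
semilandmarks fill the gaps between the first five anchors. This index map
is one consistent reading of the digitisation protocol (which fixes the
insert counts but not where the later anchors fall); it reproduces the
stated region grouping exactly: hindquarter 1–8, back 9–19, head/neck
20–30.

Manual digitisation cannot be replicated in software, so intermediates are
placed by a reproducible surrogate: a chord-length-parameterised natural
cubic spline through the anchor polyline, with each run sampled at equal
arc-length fractions between its flanking anchors (dense 4001-point
sampling per segment to invert the arc length). The construction depends
on anchors only through positions and chord lengths and is therefore
exactly equivariant under rigid motions; anchors are pinned bit-exactly.
Coincident consecutive anchors are rejected.

TPS records carry `LM=30`, 30 `x y` lines with dot decimal separators, an
`ID=` code (condition letter A–D, time digit 0/1, individual 01–52),
optional `IMAGE=`/`SCALE=` and arbitrary preserved keys. `SCALE` is
ignored by the shape analysis (GPA removes scale). Coordinates are y-up in
analysis space; comma decimals are a hard parse error, as the protocol
standardises on dots.

## Superimposition and shape statistics

GPA centres every configuration, scales it to unit centroid size, and
iterates optimal proper rotation to the consensus / consensus update until
the consensus moves less than 1e-10 (root summed squared coordinates;
maximum 100 iterations — in practice 3–5). The 2-D rotation uses the
closed form θ = atan2(Σ xᵢ∧rᵢ, Σ xᵢ·rᵢ), vectorised over specimens, which
keeps thousands of replicate fits cheap. Because the consensus orientation
is otherwise arbitrary (it inherits the frame of the initialising
specimen), the fit is canonicalised by rotating the consensus so its
tail-to-face chord lies along +x; the output is then invariant under
per-specimen similarity transforms of the input to machine precision.

PCA operates on the covariance of the superimposed coordinates after
orthogonal projection into the tangent space at the consensus. The
projection removes the radial (pre-shape-sphere curvature) direction, a
second-order artifact whose spectrum otherwise contributes a spurious
57th component at ~1e-4 relative magnitude; with it, the nonzero spectrum
spans at most min(n − 1, 2k − 4) dimensions and `mean + scores·vectors`
reproduces the decomposed tangent coordinates exactly. Eigenvalues use the
n − 1 denominator; vector signs are fixed (largest-magnitude loading
positive). Three scalings of the eigenvalue-dispersion index are provided
(raw population variance, divided by squared total variance, and
additionally multiplied by the variable count); conventions differ across
morphometric software, so all three are reported rather than asserting
one.

The Procrustes ANOVA is the Goodall decomposition on flattened Procrustes
coordinates: SS_effect = Σ_g n_g‖x̄_g − x̄‖², SS_residual within groups,
dfs multiplied by m = 2k − 4. The p-value is parametric
(F with (g−1)m, (n−g)m df) by default; a label-permutation option
(10,000 permutations, fixed seed) agrees with the parametric tail within
0.02 on Gaussian synthetic data. Morphometric software packages differ on which variant they
report; parametric is the default here because it is deterministic. Group order is fixed (A<B<C<D, 0<1) for stable reports.
Centroid size uses ordinary one-way ANOVA. Confidence ellipses place the
squared Mahalanobis radius at the χ²₂ quantile of the requested
probability (0.9 by default).

## The pixel-counting protocol

Temperatures map to five 2 °C bins with half-open edges and a closed top:
[28;30), [30;32), [32;34), [34;36), [36;38]. Below 28 °C is background;
above 38 °C clamps into the top bin (the rendering scale saturates there).
Background is *exact* #000000 — a near-black pixel is surface — matching
the manual-masking convention the protocol assumes.

Thermal-camera rendering palettes are proprietary and vary by vendor;
the bundled palette
is piecewise linear in RGB within each bin's hue family (dark
purple→navy, deep→light blue, green→yellow-green, yellow→orange,
red→dark red) with a colour jump at every bin edge, and rendering clamps
each temperature into its own bin's ramp so no pixel ever blends across an
edge. This construction makes the binding round-trip property exact: for
*every* temperature, nearest-reference CIE76 classification of the
rendered 8-bit colour (references = palette at bin midpoints 29, 31, 33,
35, 37 °C; ties break to the lower bin) recovers the temperature's own
bin. A continuous ramp cannot guarantee this, because the Lab-equidistant
point between adjacent references need not sit on the bin edge after
sRGB→Lab nonlinearity and 8-bit quantisation. Alternative palettes load
from YAML config; the exactness property should be re-verified for them
(the test suite's sweep does this for the default).

Colour maths: sRGB with D65 white point and the standard 2.4-exponent
transfer function (via scikit-image), 8-bit quantisation by round-half-up;
ΔE is plain CIE76 (Euclidean distance in L\*a\*b\*). Lossy JPEG input is
accepted with a warning since quantisation can move colours across bin
boundaries; PNG/BMP are recommended and used throughout the tests.

## Group statistics

Shapiro–Wilk screens each sample (3 ≤ n ≤ 5000) and motivates the
nonparametric presentation. Kruskal–Wallis H is tie-corrected with p from
χ²(g−1); Dunn's pairwise z uses pooled midranks and the tie-corrected
variance V = N(N+1)/12 − Σ(t³−t)/(12(N−1)), two-sided normal tails,
Bonferroni-adjusted by default (statistics packages differ in their
default multiplicity correction here; `none` is available and the choice
is recorded in output metadata). Quartiles interpolate linearly
between order statistics; whiskers are the sample extremes with no outlier
trimming. Compact significance letters come from a deterministic
insert-and-absorb algorithm. Multiplicity is controlled within each
comparison family (per panel), not globally.

## Synthetic data — what it emulates and what it does not

The generator reproduces the study design: 13 horses × 4 conditions
(freely moving head, chambon, rubber band, triangle side reins) × 2 time
points = 104 occasions, 5 visible / 2 infrared frames captured and 1
selected per occasion (520/104 and 208/104). The 13-row cohort table
(sex, breed, age, BCS, height, lameness, training) ships as a fixture.

**Landmarks.** A versioned template profile (8 anchors in pixel units)
defines the species-typical shape. Per horse-condition occasion: anchor
jitter (SD 8 px per coordinate), a log-normal size factor (SD 0.05), a
spline-built 30-point base curve; the before configuration adds isotropic
landmark noise (SD 4 px), the after configuration additionally applies a
condition-specific vertical displacement field. Fields are smooth Gaussian
bumps (index SD 1.5) peaking at 2 noise-SDs: freely moving head raises
poll and tail base and lowers the mid-back; chambon is identically zero;
rubber band raises the mid-back; side reins mirror the freely-moving-head
field. Magnitudes are calibration choices: thermographic and postural field
reports identify which regions respond, not by how much. Because before and after share each
horse's base curve, the data are paired; the unpaired Goodall F is
therefore conservative on default-generator data, and the statistical
calibration simulations (type-I and power) instead use the documented
isotropic-noise-only setting (horse jitter zero), which is the stated null
model. Passing tests demonstrate correct behaviour under isotropic
Gaussian shape noise; they do not certify calibration under the
correlated, non-isotropic variation of real horses.

**Thermal scenes.** A parametric horse silhouette (trunk ellipse, neck,
head, four legs) on black background; per-scene target bin fractions by
condition and time (before: mass in the two coolest bins, none in the
hottest; after: condition-dependent shifts, strongest toward the hottest
bins under side reins), Dirichlet-jittered (concentration 300), quantised
to whole pixels by largest remainder, and laid out along a warmth score
that rises from the hindquarter toward the cranial back and ventral
neck/head with smooth spatial noise. Per-pixel temperatures are drawn
uniformly from the interior of their bin (0.02 °C margin), so the realised
fractions returned as ground truth are exact and the render→classify
round trip is pixel-perfect. The default raster is the study's 968 × 709;
tests and examples use reduced rasters (e.g. 242 × 177, 160 × 120) since
every asserted property is resolution-independent. The silhouette is a
geometric stand-in: no coat, mane, anatomy-driven vascular pattern or
ambient-condition physics.

## Numerical and design choices

- GPA tolerance 1e-10, max 100 iterations; non-convergence returns a
  flagged partial result rather than raising.
- PCA component cut-off at 1e-12 relative eigenvalue after tangent
  projection.
- Zero residual SS in either ANOVA reports a boundary (F = ∞, p = 0) with
  a warning instead of dividing by zero.
- Degenerate inputs raise: coincident landmarks (zero centroid size),
  all-identical ranks, singular score covariance, empty surfaces.
- All randomness flows from explicit `numpy` Generator seeds; reports are
  byte-reproducible for a given config + seed (fixed SVG hash salt, no
  embedded dates).
- Calibration problem sizes: 2000 null replicates (n = 104, 4 groups) for
  the Goodall F and Kruskal–Wallis type-I checks, 500 replicates
  (13 per cell) for power — the documented study-condition sizes.

## Known limitations

- No sliding of semilandmarks (bending-energy or Procrustes-distance);
  the equal-arc-length placement is fixed.
- 2-D landmarks only; no allometry regression or asymmetry decomposition.
- The PCP is purely colourimetric: no radiometric calibration, emissivity
  or reflected-temperature correction, and no decoding of proprietary
  radiometric file formats.
- Repeated measures are not modelled (no mixed effects); the nonparametric
  tests treat observations as independent, as the original presentation
  does.
- The synthetic generator's effect sizes and silhouette are surrogates;
  quantitative agreement with real thermograms or digitised photographs is
  out of scope.
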