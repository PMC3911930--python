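# Methods

This note records the model, the defaults and the numerical choices
behind `streetstat`, and what its synthetic fixtures do and do not
demonstrate.

## Preprocessing

Color images are collapsed to luminance by the unweighted mean of the
R, G, B channels (the minimal reading of "collapsing" channels);
Rec. 601 luma weights are available via the `weights` argument.
Decimation by an integer factor uses an eighth-order Chebyshev Type I
low-pass with 0.05 dB passband ripple and normalized cutoff
`0.8/factor` of Nyquist — the classic anti-aliased decimation design —
applied forward and backward along each axis. Both cutoff and ripple
are configurable. Edge transients use Gustafsson's minimal-transient
method rather than signal-extension padding: Gustafsson's method is
exactly invariant to time reversal, so an even-symmetric input
produces an exactly symmetric output, which is the defining property
of a zero-phase filter (reflect-padded forward-backward filtering
violates it near the boundaries by whole luminance levels).
Subsampling keeps every `factor`-th sample and crops to
`floor(dim/factor)`, so a 4288×2848 capture decimated by 2 is
2144×1424. Quantization maps the source bit-depth range linearly to
[0, 255], rounds half-to-even and clips, making outputs bit-exact
across platforms.

Viewing-geometry helpers convert pixel counts to visual angle with
the full-angle formula `2·atan(extent/2/distance)`; they exist so
spatial frequencies can be reported in cycles/degree for a given
display and viewing distance.

## IC filter bank

Filters are learned with FastICA (hyperbolic-tangent working
nonlinearity, 200 iterations, global whitening, no dimension
reduction) on patches sampled without overlap from a corpus of
textured images; 16×16 patches yield 256 components. Patches are not
per-patch mean-centered (only the feature-wise global mean is
removed inside the ICA stage), so a mean-luminance direction remains
representable. The component whose amplitude spectrum is most
concentrated at zero frequency is flagged as the DC component; its
response downstream is pinned to a constant `c` (default 0 — any
constant only shifts one sample of the response distribution, and 0
is the least informative choice). Each filter is normalized to unit
Euclidean norm and sign-fixed so the carrier phase at the patch
center is nonnegative; response kurtosis is invariant to both
choices. With this learning recipe the non-DC unmixing filters are
only approximately zero-mean (weight sums around 1e-3, versus ~0.3
for the DC-flagged filter): whitening suppresses but does not
annihilate the mean direction in the remaining rows.

Each non-DC filter is characterized by a least-squares 2-D Gabor fit
initialized from its spectral peak and moment envelope. The
preferred frequency and orientation come from the fitted carrier; the
half-amplitude spatial-frequency bandwidth in octaves is
`log2(f_hi/f_lo)` with `f_{hi,lo} = f ± sqrt(ln2/2)/(π·σ_x)`, the
closed form for a Gaussian-envelope Gabor; the bandwidth diverges
when the envelope's spectrum reaches DC. Fits are reported with a
relative residual norm; a filter is treated as "localized and
oriented" when that residual is below 0.8 (i.e. the Gabor explains at
least ~36% of the filter's energy — a deliberately lenient bound that
still excludes noise-like components).

## Contrast and kurtosis maps

Neighborhoods are vectorized column-major. The contrast map is the
population standard deviation per window, computed by accumulating
shifted slices after subtracting the global image mean (keeping the
`E[x²]−E[x]²` form conditioned to better than 1e-9 against
per-window brute force). The kurtosis map log-transforms each
window, projects it onto the bank, pins the DC response, and takes
the Pearson (non-excess) kurtosis of the responses with population
moments. Windows whose response variance falls below 1e-12 are
masked and excluded from downstream statistics (the excluded fraction
is logged). Both maps cover the valid region only; stride is
configurable (default 1, with coarser strides for speed — all tests
state theirs) and the dense implementation is contractually equal to
per-neighborhood brute force.

The kurtosis map responds to low-frequency *structure*: windows
containing luminance steps or coarse gratings drive a few filters
strongly (sparse responses, kurtosis ≫ 3), while fine texture drives
many (kurtosis ≈ 3). Featureless windows — pure flat regions —
carry responses at the weight-sum residue level and land slightly
below the texture baseline rather than above it; the high-kurtosis
signal of a "smooth" image region comes from its coarse internal
transitions and boundaries, not from flatness itself.

## The measure

All four summary statistics use population moments; kurtosis is
non-excess, so K_K ≥ 1 and the denominator of
`M = μ_C·σ_C·S_K/K_K` never vanishes. M carries the sign of S_K.
The combination is isolated in one function (`complexity_measure`) so
an alternative algebraic form is a one-line change. Degenerate maps
(fewer than 4 defined entries, or zero variance) raise rather than
return a silent value.

## Baselines

* **Perimeter length**: nonzero pixels of a Canny edge map, Gaussian
  σ = 1.0, hysteresis thresholds at 10%/20% of the peak
  smoothed-gradient magnitude. Peak-relative thresholds are
  contrast-scale invariant and behave additively for disjoint
  structures; gradient-quantile thresholds were tried first and
  collapse on images dominated by flat background or sensor noise.
  All parameters configurable. Note that on pixel-aligned step edges
  the non-maximum suppression can keep two-pixel-wide ridges (the
  true edge falls exactly between samples); faint noise breaks the
  tie.
* **JPEG size**: byte length of a grayscale JPEG encode at quality 75
  (configurable), no metadata, so the count is deterministic.
* **Subband entropy**: mean base-2 Shannon entropy of 255-bin
  histograms of each subband of a 3-level `db4` (orthogonal wavelet)
  decomposition of the luminance channel — a documented
  simplification of the steerable-pyramid construction it
  approximates. Bands whose spread is at the float-residue level of
  the decomposition contribute 0 bits.
* **Näsänen's measure**: effective area × median radial frequency of
  the DC-excluded Fourier amplitude spectrum. Effective area is
  interpreted as the product of 4·std of the marginal spatial
  distributions of `|I − mean(I)|` along x and y (a second-moment
  spread); the median frequency is the smallest radius at which
  cumulative amplitude mass reaches half the total, which makes it
  exactly the carrier frequency for a pure grating and invariant to
  contrast scaling.
* **Feature congestion** is deliberately not implemented (it is a
  separate method with its own color/orientation covariance
  machinery); report schemas reserve a column for it.

## Ranking aggregation

A participant's session partitions the items into simple / ordinary /
complex groups, ordered within groups; the two group boundaries are
rankable "division" items, so n items produce n + 2 positions (76 for
74). Item rank across participants is treated as a random variable;
the aggregate rank sorts items (divisions included) by the mean of
that distribution, with ties broken by item identifier, and the
division means induce the final three-way classification. How
division markers should interact with exactly tied image means is
undefined in the protocol; the deterministic identifier tie-break
makes the choice reproducible. Correlation reports use Pearson's R
with the two-sided t-test p-value (n − 2 df) and a first-order
least-squares fit; the significance criterion defaults to p < 0.001.
Rank files use a one-row-per-subject CSV dialect with `|` tokens at
the two divisions.

## Synthetic fixtures and what they show

The generator's defaults define the study conditions used throughout
the tests.

* **Edges / gratings**: 16×16 two-level edges (upper half brighter by
  Δ, centered in [0,255], RMS contrast exactly Δ/2) and 16×16
  two-dimensional cosine gratings with equal horizontal and vertical
  frequency components (45° orientation), scaled to [0,255].
* **Texture corpus**: dead-leaves occlusion images — disks and
  oriented bars with power-law sizes (density ∝ r⁻³, radii 2–60 px)
  — under 0.7 px optical blur and σ = 1.5 sensor noise, with a
  per-image exposure spread (gain 0.35–1.0, offset 0–40) emulating
  day/night luminance diversity. This reproduces what ICA needs from
  photographs: ~1/f amplitude spectra (radial log-amplitude slope
  ≈ −1.3), sparse edge-dominated statistics at all orientations, and
  structured energy up to Nyquist. Earlier Gaussian-noise corpora
  (pink/band-pass mixtures) were abandoned: ICA on Gaussian data has
  no identifiable structure and returns noise filters.
* **Surrogate scenes**: mid-gray canvas with band-pass texture
  (default 0.3 cycles/pixel), smooth low-frequency blob regions over
  a controllable area fraction, and a controllable count of
  high-contrast rectangles; the construction complexity parameter is
  `n_objects + 10·smooth_fraction`. Object count drives μ_C; smooth
  area drives S_K in the dilute regime (the skewness of a mixture
  rises while the high-kurtosis component is a minority and falls
  once it dominates, so S_K checks use modest smooth fractions).
* **Participants**: Gaussian rank jitter around a known true order,
  split 12/47/15 (the observed group proportions of a 74-item
  session) at the default quantiles; 40 subjects, noise σ = 2
  positions.

Limits of the emulation: the corpus has no perspective, shading
gradients, or photometric calibration, and the learned filters are
more spatially localized than photograph-trained ones — their
half-amplitude bandwidth histogram peaks at ~0.8–0.9 octaves instead
of the 0.3–0.5 reported for a photographic corpus. Corpora low-passed
like camera images reproduce the photographic bandwidth mode but
lose top-octave coverage and with it the strict decrease of grating
kurtosis with frequency, which is the mechanism the measure rests
on; full-band coverage was chosen. Passing tests therefore establish
the machinery and its qualitative behavior, not quantitative
agreement with photograph-trained banks.

## Problem sizes

The test suite learns its shared 16×16 bank from 8,000 patches (40
corpus images) and evaluates maps at strides 4–8 on 48–256 px
images; brute-force oracle comparisons run at 64×64 and stride 1.
The acceptance script uses 50,000 patches from ~206 corpus images.
Map values are independent of stride and image size by the
brute-force equivalence contract, and bank structure (256 components,
one DC) is independent of patch count; patch count mainly sharpens
individual filters.
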