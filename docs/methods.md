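# Methods

## The decomposition

The fusion rules need a transform that is (i) multiscale, (ii)
multidirectional, (iii) fully shift-invariant, (iv) exactly invertible,
and (v) keeps every subband at the input resolution so that positions
correspond across subbands. The classical nonsubsampled contourlet
transform has these properties, but published descriptions leave the
exact filter coefficients unspecified. `nsctfuse` therefore uses an
explicit construction with the same contract:

* **Pyramid stage.** An additive à-trous pyramid. The level-`j` lowpass
  is the separable binomial kernel `[1,4,6,4,1]/16` with `2^(j-1) - 1`
  zeros inserted between taps, applied as circular (FFT) convolution; the
  detail band is the residual. Because each level is a plain
  lowpass/residual split, `low + sum(details)` reproduces the input to
  machine precision by construction.
* **Directional stage.** Frequency-domain angular wedge windows.
  Orientation is taken modulo pi (so masks are symmetric under frequency
  negation and real images give real subbands) and divided into `2^l`
  equal sectors with raised-cosine transitions of half-width a quarter
  sector. Adjacent windows sum to one across each transition, so the
  wedges form an exact partition of unity and the directional bands of a
  detail band sum back to it. Direction index increases counter-clockwise
  from the horizontal frequency axis; scales are stored coarsest first,
  matching the default direction list `(2, 2, 3, 3)`.

Circular convolution makes shift invariance *exact* for circular shifts
(measured residuals ~1e-15), at the price of wrap-around rather than
mirrored boundaries in the transform stage; window-based fusion
operations use symmetric padding instead. Numerical equality with any
specific published contourlet filter set is not claimed — every property
the fusion method relies on is tested directly instead.

Reconstruction is the plain sum of all bands. The decomposition of a
256x256 image at the defaults produces 1 + 4 + 4 + 8 + 8 = 25 bands of
256x256 doubles (~13 MB), which bounds practical image sizes well above
anything this method targets.

## The coefficient model

Directional subband histograms are sharply peaked at zero with heavy
tails; the zero-mean generalized Gaussian density captures this family
with two parameters (scale `alpha`, shape `beta`; `beta = 2` is Gaussian,
`beta = 1` Laplacian). Maximum-likelihood fitting reduces to a
one-dimensional root-find for `beta` (the scale then has a closed form).
The score equation is solved by Newton–Raphson with an analytic
derivative, safeguarded by bisection inside the bracket `[0.1, 10]`,
started from a moment estimate (inverting the ratio
`E|x| / sqrt(E x^2)`), with tolerance 1e-8 on the score and at most 100
iterations. Two non-root cases are handled deliberately:

* No sign change on the bracket: the data are lighter-tailed than
  `beta = 10` admits (common for near-sinusoidal ripples in smooth
  regions). The clipped moment estimate is used; this is an expected
  boundary condition and logs at DEBUG only.
* Non-convergence within the iteration budget: moment fallback with a
  WARNING.

Exact zeros are clamped at `|x| >= 1e-12` inside the likelihood terms so
`log|x|` stays finite. Fits require at least 32 samples and a
non-constant sample; constant tiles fall back to `(alpha=1e-12, beta=2)`.
On 1e5 samples the fit recovers both parameters within ~2% across
`alpha in {0.5, 1, 2} x beta in {0.7, 1, 1.5, 2}`.

## Divergences

The Kullback–Leibler divergence between two GGDs has a closed form; it is
cross-checked against adaptive quadrature of the defining integral.  Two
numerical points matter and are easy to get wrong:

* The quadrature evaluates `log q` analytically from the GGD parameters,
  not as `log(pdf + tiny)`: in double precision the density underflows in
  the far tail while `p * log q` still contributes O(1e-4) and more, and
  a clamped logarithm silently truncates it. (For arbitrary callable
  densities the clamped form is all that is possible, and is used.)
* The adaptive integrator receives breakpoints at both scale parameters
  and both effective support half-widths; without them, a heavy-tailed
  partner stretches the interval by orders of magnitude and the
  subdivision can step over a narrow peak.

With both, closed form and quadrature agree to ~1e-9.

The Jensen–Shannon divergence `0.5*(KL(P||M) + KL(Q||M))`,
`M = (P+Q)/2`, is used as the similarity measure between fitted subband
models because it is symmetric, finite and bounded by `ln 2` (all
divergences are in nats). `M` is a mixture, not a GGD, so the closed form
does not apply; both terms are integrated by trapezoid on a shared grid
that clusters points quadratically around the peak and covers 1.5x both
supports (2049 points per density by default). This grid evaluation
agrees with the adaptive-quadrature route to ~1e-5 while being an order
of magnitude faster — the pipeline evaluates tens of thousands of tile
pairs per fusion, and results are memoized on the (symmetric,
canonically ordered) parameter pairs.

## Fusion rules

**Low frequency.** Regional standard deviation (uniform 3x3 window,
same-window mean, symmetric padding) and a normalized entropy of squared
window coefficients (in [0, 1] by dividing by `log W^2`) are combined
into convex pixel weights `(delta + xi)/2`. Where an activity denominator
falls below `eps = 1e-12` both sources weigh 0.5. The halving restores
convexity — without it the combined weights sum to 2 and the fused
approximation would double in intensity; convexity also gives the
identity `fuse(X, X) = X` and pointwise bounds
`min(A,B) <= F <= max(A,B)`.

**High frequency.** JSDs need distributions, not single coefficients, so
GGDs are fitted on non-overlapping 32x32 blocks (auto-halved down to 8
when a subband holds fewer than 4 blocks per dimension; a short trailing
tile merges into its neighbour) and dependency values broadcast
tile-wise. Since all subbands share the image size, tiles align across
scales and directions. The per-subband horizontal (same-scale siblings)
and vertical (all subbands at the adjacent coarser + finer scale;
missing neighbours contribute nothing) dependency sums are normalized to
`h + v = 1` (both zero where no information exists), and coefficients are
emphasized by `1 + h^2 + v^2`, a multiplier in `[1, 2]`.

The emphasized coefficients feed the saliency comparison only: saliency
is their absolute value smoothed by a normalized Gaussian (radius 5,
sigma 5, i.e. 11x11), binary weight maps pick the larger saliency
pixelwise (ties go to the first image), and the *original* coefficient of
the winner is selected. Selecting originals rather than emphasized
coefficients keeps reconstruction faithful — fusing an image with itself
is then exact (~1e-15) instead of detail-amplified — while the dependency
model still decides *who wins* each pixel. Both the tie rule and the
choice to compute saliency on emphasized coefficients are configurable
conventions.

**Color.** For grayscale + RGB fusion the color image is converted to
YCbCr, its luminance (rescaled from [16, 235] to [0, 1]) fused with the
grayscale image, and the chrominance reattached unchanged.

## Metrics

EN, MI and SF quantize images to 256 levels by min-max scaling (the
community default; the method is histogram-based, so any monotone
rescaling of intensities is irrelevant) and use base-2 logarithms. MI is
the summed form `MI(A,F) + MI(B,F)`. Q^AB/F uses Sobel gradients,
orientation differences folded modulo pi into `[0, pi/2]`, and the
standard sigmoid constants (0.9994, -15, 0.5) / (0.9879, -22, 0.8);
gradient-strength weighting. Note the sigmoids cap the score below 1:
even a perfect fusion (`F = A = B`) scores about 0.975. The UID metric is
not implemented and is reported as `null` in metric reports.

## Synthetic phantoms

`make_phantom_pair` emulates the *complementarity* of a CT/MRI pair, not
anatomy: the CT-like image has a bright outer ring and high-contrast
piecewise-constant blobs on a dark background; the MRI-like image has
smooth sinusoidal tissue gradients and a fine 30-degree texture disk.
Named masks record the ring (only in A) and texture disk (only in B), and
the generator guarantees the masked regions truly differ (mean |A-B| >
0.2). Both images get additive Gaussian noise of sigma 0.01 and are
clipped to [0, 1]; geometry, contrasts and noise level are fixed
constants chosen to resemble the dynamic range of windowed clinical
images. `make_functional_phantom` renders a few broad Gaussian activity
blobs through a hot-metal palette for the color path. What passing tests
show is that the *rules* behave as specified (features survive, entropy
does not drop, edges transfer); they do not certify clinical image
quality, registration robustness, or behaviour under modality-specific
artifacts (bias fields, metal streaks, Poisson noise).

## Problem sizes and determinism

The test suite exercises fusion at 128x128 and the acceptance script adds
a full 256x256 fusion — the size typical of registered clinical fusion
benchmarks; both finish in seconds to tens of seconds. The pipeline
itself contains no randomness: fusion output is a deterministic function
of the two images and the configuration. All synthetic data flow from
explicit seeds.

## Known limitations

* 2-D single-pair fusion only; no registration, no 3-D volumes.
* The transform matches the nonsubsampled contourlet *contract*, not any
  specific published filter coefficients, so numbers computed on clinical
  images elsewhere are not bit-reproducible here.
* Block-constant dependency maps introduce tile boundaries in the weight
  fields; with binary selection this is invisible in practice but a
  smooth interpolation of tile parameters would be the natural extension.
* The JSD grid quadrature is tuned for parameter ratios up to a few
  orders of magnitude (always the case for fitted subband tiles); for
  pathological ratios beyond ~1e3 the bounded result saturates at `ln 2`.
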