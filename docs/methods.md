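# Methods

This note records the models the package implements, the numerical
choices behind them, and what the synthetic validation does and does not
establish.

## Spectral slope estimation

A patch is mean-centred, tapered, transformed, and radially averaged.
Choices that the standard verbal description leaves open, and how they
were resolved here:

- **Window.** The Kaiser–Bessel taper is built as a *radially symmetric*
  2-D function (weight depends only on distance from the patch centre,
  zero outside the inscribed disc), not as a separable outer product,
  because the downstream analysis is isotropic. The shape parameter
  defaults to α = 2; α = 0 degenerates to a flat disc.
- **Mean subtraction.** The *window-weighted* mean is subtracted before
  tapering, so the DC coefficient vanishes exactly and Parseval's
  identity is assertable in tests. Overall brightness therefore cannot
  leak into the lowest frequency bins.
- **Radial average.** Each non-DC cell at signed integer frequencies
  (u, v) is assigned to the annulus `round(sqrt(u² + v²))`. Radii run to
  the grid corners (`⌊√2·side/2⌋`), so a 200-px patch covers the default
  10–110 cycles/image band even past the axial Nyquist of 100.
- **Binning.** 20 bins, logarithmically spaced over 10–110 cycles/image.
  The bin *value* is the mean of log10 power over the bin's radii and the
  bin *centre* is the mean of log10 frequency over the same radii — not
  the log of the mean, and not the edge midpoint. With this pairing the
  estimator is exact on pure power laws (`P = c·f^β` gives bin value
  `β·centre + log10 c` identically), which the test suite asserts at
  1e-9. Low-frequency bins narrower than one integer radius are dropped
  with a warning.
- **Regression.** Unweighted OLS of bin log power on bin log frequency.
  Binning, not weighting, is what equalizes the influence of the
  frequency decades.
- **Per-fish slope.** When one value per fish is needed, it is the mean
  of that fish's (default 2) patch slopes; the per-fish spectrum is the
  per-bin mean of its patch spectra, which commutes with the regression.
- **Deviation.** The fish-to-habitat deviation is the mean squared
  difference between fish bin values and the habitat-class reference
  (per-bin mean over all patches of the class), computed on *raw* log
  power. A `shape_only` flag removes each side's mean log power first
  (comparing spectral shape only); it is off by default, so differences
  in overall contrast count as mismatch.

## Synthetic images

Prescribed-slope images use random-phase Fourier filtering: a seeded
white Gaussian field is transformed, amplitudes scaled by `f^(β/2)` with
the DC term zeroed, inverted, standardized, scaled to a mean level of 0.5
and an RMS contrast of 0.2 of the mean, and clipped to [0, 1]. At that
contrast, ±3σ stays inside the unit interval, so clipping is rare and the
realized exponent is essentially unbiased (measured |bias| of the mean
over 50 images ≈ 0.013 across β ∈ [−3, 0]).

Two caveats tests inherit from this construction. First, the fields are
circularly periodic, so a full-field transform has *no* edge
discontinuity; the edge-leakage advantage of the taper only shows on
patches cropped out of larger fields, and the windowing test crops
accordingly. Second, the generator produces isotropic Gaussian textures —
it emulates the second-order spectral statistics of natural scenes, not
their phase structure (edges, objects, horizons), occlusions, lighting,
or anisotropy. Passing recovery tests therefore validates the estimator
chain, not any claim about real photographs.

Habitat images in the synthetic pipeline are square (600 px by default);
resizing machinery for arbitrary camera aspect ratios
(`imaging.resize_block_mean`, `imaging.downsample_half`) is exercised on
the empirical path. Box-size robustness is checked with the analysis band
held fixed in cycles/pixel, since a band defined in cycles/image is not
attainable by a box smaller than its upper edge.

## Receiver color space

The camera-to-receiver mapping regresses each cone quantum catch on all
10 monomials of total degree ≤ 2 in the three camera catches (intercept
included). Curves are resampled to a common wavelength grid by linear
interpolation and catches are trapezoid-rule inner products. At least 10
training spectra spanning the basis are required; rank deficiency is an
error, not a silent pseudo-inverse. Negative cone predictions are clamped
to zero (the alternative, renormalization, is not applied). Sensitivity
curves in the synthetic layer are Gaussians in wavelength — a generic
smooth unimodal template chosen because only the mapping machinery, not
any specific photoreceptor nomogram, is under test. The default dichromat
peaks are 525 and 603 nm, and luminance is the sum of the two cone
channels. Half-size reduction is exact 2×2 block averaging (trailing odd
row/column dropped).

## Study simulator

Per fish: `slope = b0 + b·slope_hab(species) + u_species + u_site +
sex_effect·I(female) + e`, with `u_species ~ MVN(0, σ²_p C)` (C in
correlation form), `u_site` and `e` iid normal, sexes alternating within
site. Defaults mirror the scale of published darter work: five habitat
classes with true slopes averaging −2.35 (underwater scenes are steeper
than the ~−2 typical of terrestrial ones; the generator uses plain
power-law noise rather than modeling the aquatic blur mechanism),
`b0 = −2.5`, `b = 0.262`, `sex_effect = −0.166`, and σ_p, σ_s, σ_e of
0.15 / 0.05 / 0.25 so the total fish SD is ≈ 0.3. The default ten-species
tree is a synthetic ultrametric tree of depth 1 whose clades group
species by habitat, reproducing the habitat–phylogeny confounding real
communities show.

## The phylogenetic mixed model

A Gibbs sampler alternates a joint multivariate-normal draw of all
location effects with conjugate inverse-gamma draws of the variances.
Numerical conventions:

- The scalar inverse-Wishart prior IW(V, ν) is the inverse-gamma
  (ν/2, νV/2); defaults V = 1, ν = 0.02 for every variance component.
  Fixed effects get independent N(0, 10¹⁰) priors (the convention of the
  mixed-model software this follows), configurable.
- The phylogenetic covariance is scaled to unit diagonal so σ²_p is
  comparable across trees; this requires an ultrametric tree and raises a
  clear error otherwise (`scale_phylo=False` uses raw shared branch
  lengths).
- The species effect is *either* tree-structured (`"phylo"`) or
  unstructured (`"species"`); both can be included if a model with a
  separate iid species term is wanted.
- pMCMC = 2·min(P(draw > 0), P(draw < 0)), with zeros split evenly
  between signs and a floor of 2/n_draws. HPD intervals are the narrowest
  contiguous window containing ⌈0.95·n⌉ sorted draws.
- DIC uses the conditional Gaussian deviance (conditioning on the drawn
  location effects), with the plug-in deviance evaluated at the posterior
  means of the effects and of σ²_e. The "without phylogeny" comparison
  model drops the species term entirely and keeps site.
- Production chain defaults are 1,000,000 iterations, 10,000 burn-in,
  thinning 50. The pipeline and test harness run 20,000 / 2,000 / 10 —
  on the simulated studies used here the chains mix essentially
  immediately (split-half stationarity is tested), so longer chains only
  sharpen the pMCMC floor.
- The per-fish habitat predictor is the measured mean patch slope of the
  fish's habitat class — the only class-level scalar available once the
  class is fixed.
- Each fish contributes one observation (the mean of its two patches),
  so model n counts individuals, not patches.

## Pipeline determinism

One global seed is split into fixed, named substreams (study simulation
and the three chains); per-image seeds — both for generation and for
patch placement — derive from a CRC32 hash of the image's source
identifier combined with the global seed. Generated images are quantized
to the 16-bit grid before analysis. Together these make the in-memory
synthetic path and the on-disk empirical path of the same study produce
byte-identical tables, which the test suite asserts, and make every
deterministic stage reproducible by checksum (recorded in the run
manifest).

## Known limitations

- Only luminance (achromatic) spectra; no chromatic or
  orientation-resolved analysis.
- The Gaussian-texture generator cannot probe estimator behavior on
  structured scenes (horizons, specularities, focus gradients).
- The mixed model is Gaussian single-response only; no alternative
  samplers. With 10 species, a species-level fixed effect is weakly
  identified against the phylogenetic term, so single-study posterior
  means of b wobble by ~±0.07 even at near-zero simulated noise;
  calibration tests therefore average over replicate studies.
- DIC is reported with the conditional (effect-level) focus; model
  comparisons with other focuses are out of scope.
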