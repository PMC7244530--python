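# patternspectra

Tools for asking whether animal color patterns spectrally match the
habitats they are displayed in. The package measures the **Fourier slope**
of luminance images — the slope of log10 power against log10 spatial
frequency in the radially averaged 2-D power spectrum — for both animal
patterns (e.g. the flank patterns of darters, *Etheostoma* spp.) and
underwater habitat photographs, and then fits a Bayesian phylogenetic
mixed model relating the two across species. It is aimed at researchers
in visual ecology and sensory drive who want a reproducible,
synthetically validated version of this analysis chain.

## What it computes

For a square luminance patch `I`, the spectral workflow is:

1. taper with a radially symmetric Kaiser–Bessel window (α = 2),
2. 2-D FFT, power = |F|²,
3. radial average over integer-frequency annuli (cycles/image),
4. mean log10 power in 20 log-spaced bins over 10–110 cycles/image,
5. OLS slope of bin log power on bin log frequency → the Fourier slope β.

Pattern–habitat matching is quantified two ways: per-species, by the mixed
model

    slope_fish = b0 + b · slope_habitat + u_species + u_site + ε,

with `u_species ~ N(0, σ²_p C)` for the Brownian-motion phylogenetic
covariance `C`, `u_site ~ N(0, σ²_s I)` for capture site nested in
species, fitted by a conjugate Gibbs sampler with inverse-Wishart
(V = 1, ν = 0.02) variance priors; and per-fish, by the **deviation**
statistic (mean squared difference between a fish's spectrum bins and its
habitat-class reference), modeled as a function of sex with the same
random effects. Posteriors are summarized by mean, 95% HPD interval,
pMCMC, and DIC.

Because studies of this kind rest on field photographs, the `synth`
module generates every input with known ground truth: power-law noise
images with prescribed spectral exponents, receptor sensitivity curves,
and hierarchical study tables — so each stage of the pipeline is testable
against the parameters that generated its data.

## Worked example

```python
import numpy as np
from patternspectra import synth, spectra

# an image whose power spectrum follows f^-2.35 (a typical aquatic habitat)
img = synth.generate_spectral_noise_image(
    synth.SpectralNoiseConfig(side_px=200, beta=-2.35, seed=7)
)
est = spectra.patch_slope(img.pixels)
print(f"slope = {est.slope:.3f}, r^2 = {est.r_squared:.3f}")
```

prints

```
slope = -2.391, r^2 = 0.998
```

i.e. the estimator recovers the generating exponent −2.35 to within the
single-image sampling noise (the mean over 50 seeds is within ±0.015),
and the binned spectrum is almost perfectly log-log linear.

A full synthetic study — habitat and fish images, slopes, deviations,
ANOVAs, t test, and all three mixed models — runs with:

```python
from patternspectra import pipeline
bundle, manifest = pipeline.run_synthetic_study(
    pipeline.RunConfig(seed=1, out_dir="out")
)
```

which writes `study_table.csv`, `habitat_patches.csv`,
`stats_summary.csv`, `model_summaries.csv` and a human-readable
`report.md`, all byte-reproducible under a fixed seed. The same analysis
can start from images on disk via `pipeline.run_empirical` or the
`patternspectra` command-line interface (`synth`, `slopes`, `deviation`,
`fit`, `run`, `report` subcommands).

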