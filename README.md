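# msrelevance

Multiscale Relevance (MSR) analysis of grayscale images: an
information-theoretic, model-agnostic way to ask *how much structure an
image carries across all spatial scales*, and to pick the segmentation
levels that carry the most of it.

## The idea

An image `h(r)` on an `N = N_X × N_Y` lattice is a sample of N unique
(position, intensity) points. Compress it in two steps: binarise at a
quantile threshold `a` (exactly `round(a·N)` darkest pixels become
black), then replace each pixel coordinate by the index of its cell on a
grid of step `ℓ`. The compressed sample's multiplicity structure —
`k_s` pixels in each (cell, color) state, `m_k` states with multiplicity
`k` — defines two entropies in bits:

    Ĥ[s] = − Σ_s (k_s/N) log₂(k_s/N)        (resolution)
    Ĥ[k] = − Σ_k (k·m_k/N) log₂(k·m_k/N)    (relevance)

Resolution is the coding cost of state labels; relevance is the
information in the histogram heights once labels are dropped. Sweeping
`ℓ` traces a relevance-vs-resolution curve, and its area on axes
normalized by `log₂ N`,

    MSR = ∫ Ĥ[k] dĤ[s]  ∈ [0, 1],

scores the robustness of the image's informational content to
compression. Scanning the threshold gives the profile `MSR(a)`, whose
local maxima `a_c` are the most informative segmentations. For synthetic
`1/f^α` Gaussian textures of Hurst roughness `H = α − 1`, anticorrelated
fields (H < 0) have two maxima symmetric about `a = 0.5` that merge near
the critical roughness `H ≈ 0`; near-critical textures behave much like
natural images.

The package also provides the supporting tool chain: a spectral
`1/f^α` texture generator, derivative-of-Gaussian gradient-magnitude
fields, PSNR/SSIM reference metrics, and two MSR-calibrated processing
tasks (Boltzmann stochastic color mapping and ROF total-variation
denoising).

## Worked example

```python
from msrelevance import FieldSpec, generate_field, msr_profile

field = generate_field(FieldSpec(H=-0.8, size=(256, 256), seed=3))
profile = msr_profile(field.values, tie_seed=3)
print("critical thresholds:", profile.maxima)
print("MSR at a=0.50:", round(float(profile.msr_values[profile.a_grid == 0.5][0]), 4))
```

prints

```
critical thresholds: [0.36, 0.62]
MSR at a=0.50: 0.2275
```

The strongly anticorrelated texture (H = −0.8) is *more* informative
when segmented off-center: the profile peaks at `a ≈ 0.36` and `0.62`
(MSR ≈ 0.247 at both) rather than at the symmetric threshold 0.5
(MSR ≈ 0.228). Picking a "background canvas" fraction reveals more
multiscale structure. Comparing roughness values at `a = 0.5` with a
shared noise seed reproduces the characteristic ordering

```
MSR(H=+0.5) = 0.1900  <  MSR(H=-0.5) = 0.2446  <  MSR(H=0) = 0.2496
```

— near-critical (H = 0) textures carry the most scale-spanning
information.

## Command line

```sh
msr texture --H -0.8 --size 512 --seed 3 --out field.tiff
msr profile --image field.tiff --a-step 0.02 --scales geometric --seed 7 --out profile.csv
msr gradient --image field.tiff --j 0 --out grad.tiff
msr compare --ref a.png --test b.png --metrics psnr,ssim,msr,msr_grad
msr calibrate --image a.png --task colormap --grid 0:0.5:0.02 --metrics psnr,ssim --out cal.json
```

Curves/profiles are CSV with documented headers; calibrations and specs
are JSON; every output records its configuration and seeds.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from freshly generated 256² textures: the mean offset of the
two MSR(a) maxima at H = −0.8, the location of the upper maximum for
strongly anticorrelated fields (H ∈ {−0.9, −0.7}), the roughness at
which the two maxima merge into one (scan H = −0.6…0.4), and the
PSNR-optimal Boltzmann color-mapping temperature. Results are written as
JSON, one entry per quantity, each produced by running the full pipeline
at the given seed.

See `docs/methods.md` for the model details, parameter defaults, and
known limitations (including two documented tensions between this
implementation's measured thresholds and idealized reference values).
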