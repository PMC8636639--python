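# iccs — spatial image cross-correlation spectroscopy

`iccs` quantifies how much of the signal in one fluorescence channel is
colocalized with a second channel, at densities where individual molecules
cannot be resolved. It is aimed at quantitative microscopists comparing
antibody staining patterns — for example deciding whether an apparent
membrane stain truly overlaps a reference marker or merely shares the same
neighborhood — using spatial fluctuation analysis rather than pixel
thresholding.

## The estimator

Within a rectangular region of interest (ROI), intensity fluctuations in
channel *a* are δI_a(x, y) = I_a(x, y) − ⟨I⟩_a. The normalized spatial
correlation of channels *a* and *b* at pixel lags (ξ, η) is

    r(ξ, η)_ab = ⟨δI_a(x, y) · δI_b(x + ξ, y + η)⟩ / (⟨I⟩_a ⟨I⟩_b)

computed with FFTs over periodic shifts. Its zero-lag amplitude is the
inverse of the mean number of (co-)fluctuating particles per beam focal
area: ⟨N⟩ = 1 / r(0, 0). Because uncorrelated detector noise contributes
only to the exact (0, 0) sample, the amplitude is estimated by fitting a
2D Gaussian

    r(ξ, η) = r(0,0) · exp(−[(ξ − u)² + (η − v)²] / ω₀²) + r_∞

to the central part of the surface, optionally excluding the zero-lag
sample, where ω₀ is the e⁻² beam radius and r_∞ absorbs long-range
correlations. The three fitted amplitudes (two autocorrelations, one
cross-correlation) give the colocalized fractions

    M1 = r(0,0)_ab / r(0,0)_bb     M2 = r(0,0)_ab / r(0,0)_aa
    f_ICCS = (M1 + M2) / 2

M1 is the fraction of channel-a particles carrying both labels, M2 the
converse. Being amplitude ratios, the fractions are invariant to channel
gain and — unlike the pixelwise Pearson coefficient — remain accurate when
the two channels have very different particle densities.

A synthetic-data module generates two-channel fields of Gaussian-PSF point
emitters with a known shared fraction φ, background and noise, so every
stage of the pipeline is testable against ground truth.

## Worked example

Simulate two conditions (true colocalized fractions 0.2 and 0.8, six
replicate fields each) and analyze them:

```
iccs simulate --phi 0.2 --phi 0.8 --replicates 6 --seed 11 --out sim
iccs analyze --manifest sim/manifest.csv --out results
```

prints

```
wrote 12 images and sim/manifest.csv
phi=0.2: f_ICCS = 0.164 +/- 0.039 (n = 6)
phi=0.8: f_ICCS = 0.794 +/- 0.019 (n = 6)
welch-t phi=0.2 vs phi=0.8: p = 2.55e-09
```

Each line is the per-group mean ± SD of f_ICCS over accepted ROIs — the
recovered fractions track the simulated truths (0.2, 0.8) within sampling
error — followed by the two-group Welch t-test. `results/` contains the
per-ROI table (`roi_results.csv`, one row per ROI with M1, M2, f_ICCS,
particle numbers, fit parameters and quality flags), `group_summary.csv`,
and `run_metadata.json` with the full configuration for reproducibility.

The same analysis is available as a library:

```python
from iccs import SyntheticSpec, generate_image, analyze_roi, ROI

image, truth = generate_image(SyntheticSpec(phi=0.8, seed=11))
result = analyze_roi(image, ROI(0, 0, 64, 64))
print(result.f_iccs, result.m1, result.m2, result.accepted)
```

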