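# Methods

## Model and assumptions

Image cross-correlation spectroscopy (ICCS) treats each detection channel
as a stationary random field of unresolved particles convolved with a
Gaussian point-spread function. For a single species at area density *d*
(particles per pixel²) imaged with an e⁻² beam radius ω₀ (pixels), the
normalized zero-lag autocorrelation amplitude equals the inverse mean
occupancy of a beam focal area:

    r(0,0) = 1 / ⟨N⟩,   ⟨N⟩ = d · π · ω₀²

The cross-correlation amplitude of two channels counts only particles
carrying both labels, so the amplitude ratios M1 = r_ab/r_bb and
M2 = r_ab/r_aa are the colocalized fractions of channels a and b, and
f_ICCS = (M1 + M2)/2 is the per-ROI summary. The estimator assumes:

- spatial stationarity within the ROI (the spatial mean is the ensemble
  mean); slowly varying structure is absorbed by the fit offset r_∞;
- channels are co-registered (no alignment is attempted);
- detector noise is white: uncorrelated between pixels and between
  channels.

## Pipeline and numerical choices

1. **Background.** Per ROI and channel, the background is the mean of the
   lowest 10% of pixel values (configurable), which is robust to sparse
   bright emitters. Subtraction clips negatives at zero and logs the
   clipped fraction. Note the estimator converges to the lower-tail
   conditional mean of the noise (≈1.755σ below the mean for Gaussian
   noise of width σ), not the noise mean; because the colocalized
   fractions are amplitude ratios, a residual common-mode background
   cancels to first order when channels are comparably bright, but very
   dim channels over strong backgrounds will bias ⟨I⟩ and deflate
   amplitudes. A reference-region or user-supplied background can be
   passed instead.
2. **Correlation.** FFT-based, periodic (circular) shifts; the surface is
   trimmed to the largest symmetric lag window. The brute-force oracle in
   the test suite uses the identical periodic convention, so agreement is
   exact (1e−10).
3. **Cropping.** Fits use |lag| ≤ 16 for 64×64 ROIs (a quarter of the ROI;
   configurable), which both limits random long-range correlations and
   keeps wrap-around bias from non-periodic emitter fields negligible.
4. **Gaussian fit.** Five parameters (amplitude, ω₀, peak u, v, offset) by
   bounded least squares (`scipy.optimize.curve_fit`, xtol 1e−10,
   ftol 1e−12), initialized from the surface itself: offset ← edge median,
   amplitude ← mean of the four |lag| = 1 samples minus the edge median,
   ω₀ ← 3 px, (u, v) ← (0, 0) bounded to ±2 px; up to 5 restarts with
   jittered initials. The amplitude standard error comes from the fit
   covariance.
5. **Zero-lag handling.** The (0, 0) sample is excluded from
   autocorrelation fits (white/shot noise lives entirely on that sample)
   and retained in cross-correlation fits (noise is uncorrelated across
   channels). On synthetic fields with σ = 25% of peak signal, the
   excluded-sample fit amplitude moves by less than half its 95% CI while
   the raw r(0,0) sample inflates by σ²/⟨I⟩², matching theory to four
   digits.
6. **Peak position.** Autocorrelation fits keep (u, v) free within ±2 px;
   fits near the bound are flagged `displaced-peak`. The cross-correlation
   fit pins (u, v) = (0, 0) by default (`fix_peak_cross`): with a free
   peak, fits to independent-channel surfaces latch onto random off-center
   blobs (at true φ = 0, 90% of free fits hit the bound), inflating the
   apparent colocalization at independence; since channels are assumed
   registered, the colocalization amplitude is by definition the value at
   zero lag. Both modes are available and the choice is recorded in run
   metadata.
7. **SNR gate.** A fit is accepted when amplitude > 0,
   amplitude ≥ 2 × its standard error, and amplitude ≥ |offset| (both
   thresholds configurable). ROI acceptance follows the two
   autocorrelation gates — a channel too dim to autocorrelate precludes
   ICCS — while a cross fit failing its gate reports zero colocalization
   (flagged `low-snr-cross`) rather than discarding the ROI, so the
   independence limit remains measurable. Fractions above 1 are reported
   raw with a `clamped-range` flag; negative cross amplitudes map to zero
   fractions with a `negative-cross` flag.
8. **Group statistics.** Per-group mean ± SD of f_ICCS over accepted ROIs;
   Welch's two-sided t-test for two groups, one-way ANOVA plus
   Bonferroni-corrected pairwise Welch tests for more. Failed ROIs stay in
   the per-ROI table with flags so acceptance rates are auditable.

## Synthetic data: what it emulates and what it does not

`generate_image` renders point emitters at continuous subpixel positions
with the PSF profile exp(−2d²/ω₀²) — the generator's ω₀ is the same e⁻²
radius the correlation fit estimates, so recovery comparisons need no
conversion factor. A fraction φ of emitters (rounded share of the smaller
channel count) is placed at identical positions in both channels; an
optional jitter (default 0) can displace the shared positions. Constant
background plus Gaussian white noise (or Poisson resampling) completes the
model; negatives are clipped at zero.

Default template: 64×64 px, 40 emitters per channel (density ≈ 0.0098/px,
⟨N⟩ ≈ 0.28 per beam area), ω₀ = 3 px, peak intensity 100, background 10,
σ = 5 — bright, well-separated staining with per-pixel SNR ≈ 20, the
regime where ICS estimators are well conditioned.

Deliberate simplifications: emitters straddling image edges are truncated
(no periodic wrapping), so total flux falls ~3% short of the ideal
n·I·πω₀²/2 budget on a 64×64 field (<2% at 256×256, where the flux
invariant is tested); there is no cellular geometry, no 3D PSF, no
detector gain model, and shared emitters are perfectly coincident by
default. Consequently, passing recovery tests demonstrate estimator
correctness under the stated statistical model, not robustness to
structured biological backgrounds, chromatic misregistration, or
binding-site displacement.

## Simulation sizes

Recovery checks use 50 replicates per condition (standard error of the
mean f_ICCS ≈ 0.007 at the default template); the null-calibration of the
two-group comparison uses 200 simulated experiments with 8 ROIs per group.
Welch's t-test is noticeably conservative below ~6 samples per group,
which is why the calibration uses 8.

## Known limitations

- Fractions are unreliable when either channel fails its autocorrelation
  SNR gate; such ROIs are excluded from summaries by design.
- The white-noise correction assumes the noise is uncorrelated between
  pixels; correlated noise (e.g. detector smear) leaks into nonzero lags
  and inflates amplitudes.
- Background estimation from the ROI's low percentile assumes emitter-free
  pixels exist within the ROI; dense fields violate this and call for a
  reference region.
- Very low particle numbers per ROI (≲10 emitters) make the fluctuation
  statistics noisy; single-ROI fractions then scatter widely even though
  replicate means remain accurate.
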