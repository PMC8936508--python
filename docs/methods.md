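# Methods

## The separation problem

Neurophysiological signals (EEG, LFP, MEG) mix a broadband scale-free
("fractal", 1/f) background with narrow-band oscillations such as the alpha
rhythm. For a *pair* of channels the same mixture appears in the cross-power
spectrum: genuine long-range coupling produces a power-law cross-spectrum
`|S_xy(f)| ∝ f**(-beta_xy)` on which coherent oscillatory peaks ride. The
cross-spectral exponent `beta_xy` relates to the bivariate Hurst exponent as
`beta_xy = 2*H_xy - 1`, and for the process class used here
`H_xy = (H_x + H_y)/2`.

The separation exploits the self-affinity of the fractal component:
fractionally resampling both signals by `h > 1` rescales the fractal
cross-spectrum by `h**(H_x+H_y)` but *relocates* any oscillatory peak (to
`f0/h` after upsampling, `f0*h` after downsampling). The geometric mean of
the cross-spectral magnitudes of the `h`- and `1/h`-resampled pair therefore
cancels the fractal rescaling exactly while a peak contaminates each `h` at
different frequencies; the frequency-wise median over a grid of `h` values
then rejects those contaminated bins as outliers. With identical inputs
(`y = x`) the procedure reduces to the univariate IRASA separation.

## Algorithm

Given a pair of length `N` at rate `fs` and a configuration
(`MrcsaConfig`):

1. **Segmentation.** `n_segments = 15` partially overlapping segments of
   length `floor(0.9*N)`, start indices evenly spaced over `[0, N - L]`
   (real-valued positions rounded to the nearest sample, half-sample ties
   toward zero).
2. **Transform sizing.** `nfft = 2 * nextpow2_exceeding(L)`, so the grid
   outnumbers the samples of every resampled version (`h < 2`).
3. **Native spectrum.** Hann-tapered, zero-padded FFT of each channel;
   mixed cross-spectral magnitude `|F_x(f) * conj(F_y(f))|`.
4. **Resampling.** For each `h` in `{1.10, 1.15, ..., 1.90}` both channels
   are resampled by `h` and `1/h` with cubic splines (not-a-knot ends; the
   output grid starts at t = 0 and is clamped to the last native sample).
   Before downsampling, a transform-domain brick-wall low-pass at
   `fs / (2*ceil(h_max))` prevents aliasing; `h_max` is the grid's largest
   factor so all `h` share one filter.
5. **Grid alignment.** All resampled cross-spectra use the *same* `nfft`
   and frequency labelling as the native segment (zero-padding as needed),
   so bins align exactly.
6. **Fusion.** Per `h`: geometric mean of the up- and down-sampled
   magnitudes. Per segment: frequency-wise median over the `h` grid (even
   counts: midpoint of the two central order statistics, the numpy
   convention). Finally both the mixed and the fractal spectra are averaged
   (arithmetic mean of magnitudes) across segments.

Magnitude (not complex) averaging is used across segments for both spectra;
any fixed taper-normalization constant cancels in every reported quantity
(slopes, fractions, peak ratios), so the raw tapered FFT is kept.

### Variance control (design choice)

The cancellation argument above treats spectra as noise-free. Estimated
single-taper cross-periodogram magnitudes, however, fluctuate with ~100%
relative variance per bin, and the median of `sqrt(X*Y)` of independent
fluctuations is *multiplicatively* biased low (≈ 0.62 for exponential
fluctuations) — enough to destroy the fractal-fraction statistic entirely
(≈ 65% instead of ≈ 100% on purely fractal input). All magnitude spectra
are therefore smoothed with a variable-width Daniell (running-mean) kernel
of full width `max(smooth_rel_bw * f, smooth_min_bins * fs/L)` before the
geometric-mean and median steps, with defaults `smooth_rel_bw = 0.05`
(±2.5%, which preserves power laws up to a frequency-independent constant
and keeps a 10 Hz peak out of its 8–9 / 11–12 Hz flanking bands) and
`smooth_min_bins = 10` native bins (≥ 10 independent bins per window keeps
the Jensen bias of the square root below ~2.5%). The identical kernel is
applied to the native mixed spectrum so that ratios are unaffected. With
the defaults the fractal fraction of purely fractal pairs comes out at
≈ 96–98% rather than the theoretical 100%; disabling the smoother
(`smooth_min_bins = 0, smooth_rel_bw = 0`) reproduces the heavily biased
estimator.

## Slope and fraction estimation

`fit_spectral_slope` log10-transforms frequency and power inside the fit
band (DC and Nyquist always excluded), linearly interpolates log-power onto
an evenly spaced log-frequency grid (as many points as native bins in band,
capped at 1000 — a uniform grid would over-weight high frequencies), and
fits by ordinary least squares. The reported `beta` is the negated slope,
so a steeper 1/f decay is a larger positive number. Non-positive power
bins are dropped with a warning; at least 10 usable bins are required.
`r_squared` is reported but never used as a gate.

`fractal_fraction` is `100 * sum(fractal) / sum(mixed)` over the band bins,
deliberately not clipped at 100 (the fractal estimate may exceed the mixed
spectrum bin-wise; values slightly above 100 are meaningful diagnostics).

The default fit band is 0.5–30 Hz, the usual EEG range below beta-band
artifacts; the simulation experiments use 0.5–100 Hz. The band's upper
edge must stay below `fs / (2*ceil(h_max))` (125 Hz at `fs = 500`), the
spectral range unaffected by the anti-alias filter.

## Simulation framework

`simulate_mc_arfima` draws a mixed-correlated ARFIMA(0,d,0) pair: four
fractionally integrated streams `p_i` with weights
`psi_n(d) = Gamma(n+d)/(Gamma(n+1)Gamma(d))` (computed by the recurrence
`psi_n = psi_{n-1}(n-1+d)/n`, truncated at `n_weights = 100` taps with the
first 100 samples discarded as burn-in) driven by jointly Gaussian
innovations with correlation `rho`; then `u = w1*p1 + w2*p2`,
`v = w3*p3 + w4*p4`, each standardized. The printed closed form with a
leading factor `d` would make the `d = 0` stream vanish instead of reducing
to white noise, so the standard convention with `psi_0 = 1` is used; the
overall constant is irrelevant after standardization. The defaults
`w = (0.1, 1, 1, 0.1)`, `d = (0.4, 0.3, 0.2, 0.3)`, unit variances and
`rho_23 = 0.9` give a theoretical `beta_uv = d2 + d3 = 0.5`.

Oscillations are injected by adding the *same* unit-variance sinusoid to
both channels (fully correlated coupling; one uniform-random phase per
frequency), scaled to variance `rel_variance * f**(-beta_uv)` with `f` in
Hz, so the peak keeps a fixed proportion to the fractal cross-power at its
frequency. White measurement noise is independent per channel with
`var(noise) = var(channel) * 100 / snr_percent`; `snr_percent = 0` is the
noise-free control. The noise-robustness experiment uses the mild-noise
regime `snr_percent = 1000` (noise variance one tenth of signal variance),
pairs parameterized for `beta_uv = 0.8` (`d2 = d3 = 0.4`) and one 10 Hz
oscillation at `rel_variance = 0.64`, the geometric middle of the dyadic
0.16–5.12 amplitude sweep.

`synthesize_powerlaw_pair` is the exact oracle: inverse-FFT synthesis with
amplitudes `f**(-beta/2)` per channel and one shared phase sequence, so the
cross-spectral magnitude is exactly `f**(-(beta_x+beta_y)/2)` and coherence
is 1 at every bin. It anchors the slope-recovery, rescaling and
peak-removal tests with known ground truth.

### What the generator does and does not emulate

It reproduces the statistical skeleton of coupled neurophysiological
recordings — long-range temporal correlation, genuine cross-correlation
with a tunable exponent, coherent narrow-band rhythms, additive sensor
noise — under stationarity and Gaussianity. It does not emulate
non-stationarity (drifts, state switches), amplitude-modulated or
non-sinusoidal rhythms, volume conduction, or heavy-tailed artifacts.
Passing tests therefore validate the estimator under the model's
assumptions; on real data the usual preprocessing (filtering, artifact
rejection) remains the user's responsibility.

## Connectivity analysis

`pairwise_mrcsa` runs the separation for every unordered channel pair and
every trial, fits slope and fraction per trial, and averages the matrices
across trials (fitting per trial and averaging estimates, not fitting on
averaged spectra). The diagonal holds univariate auto-spectral exponents.
Node degree is the per-channel sum of off-diagonal exponents (the auto term
is not a connection; an `include_diagonal` option exists). Failed pairs
are recorded as NaN with a warning rather than aborting the matrix.

`compare_conditions` compares two conditions edge-wise on paired subject
averages: a Lilliefors test (Kolmogorov–Smirnov against a normal with
estimated moments, via statsmodels) on the paired differences at
`alpha = 0.05` selects a paired t-test (normal) or a paired Wilcoxon
signed-rank test (otherwise; zero differences dropped, ties mid-ranked).
Multiplicity is corrected over the `n*(n-1)/2` edge family with Bonferroni
or Benjamini–Hochberg FDR; the diagonal of auto exponents forms its own
`n`-sized family. An edge is flagged significant when its adjusted p-value
is strictly below `alpha`.

## Numerical choices and degenerate inputs

- Signals shorter than 64 samples, non-finite values, mismatched lengths
  and non-positive sampling rates are rejected up front.
- Resampling grids never extrapolate: the final up-sampled grid points
  (at most a fraction of one sample past the end) are clamped to the last
  native sample.
- `h` grids must be strictly increasing; the median fusion itself is
  permutation-invariant.
- A constant (zero-variance) channel yields zero added noise in
  `add_white_noise` and an all-zero spectrum error in slope fitting.
- All randomness flows through `numpy` Generators; every public simulation
  entry point takes a seed or Generator, and multi-run experiments derive
  per-run streams from `SeedSequence((seed, stream))` so adding runs never
  perturbs existing ones. The separation itself is deterministic.

## Problem sizes in the shipped experiments

The packaged experiments use 10,000-sample pairs at 500 Hz; seeded medians
use 20 realizations (5 in `reproduce --quick`), and the oscillation
slope-error comparison uses 6–10 realizations, which is ample for the
order-of-magnitude contrast it demonstrates.

## Known limitations

- The oscillatory cross-spectrum itself is *not* recovered; the mixed
  minus fractal difference contains irreducible fractal–oscillatory
  interaction terms, so only the fractal part and the fraction bound are
  reported.
- Spectrum-domain exponent estimators of this family carry a small
  finite-sample bias even without oscillations; validation therefore
  compares against estimates from uncontaminated realizations rather than
  the asymptotic theoretical exponent where the distinction matters.
- One scaling range is assumed (no breakpoint detection, no multifractal
  description, no sliding-window time–frequency mode).
- The Daniell smoother trades a small controlled bias near sharp spectral
  edges for a large variance reduction; analyses that require raw
  periodogram resolution should disable it and work with band-integrated
  quantities only.
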