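# mrcsa

Separation of the scale-free (fractal) component of the **cross-power
spectrum** of two coupled time series from narrow-band oscillatory
components, by multiple fractional resampling — the bivariate counterpart
of IRASA — together with a mixed-correlated ARFIMA simulator with known
cross-spectral exponents and fractal-connectivity statistics for
multichannel recordings.

## Who this is for

Researchers quantifying *fractal (scale-free) functional connectivity* in
EEG/MEG/LFP-style data: the cross-spectrum between two channels mixes a
broadband `1/f` background, whose log-log slope `beta_xy` indexes long-range
coupling, with coherent oscillations (e.g., the alpha peak) that bias any
naive slope fit. This package separates the two contributions and estimates

- the **fractal cross-spectrum** `SF_xy(f)` and the mixed spectrum
  `|SS_xy(f)|`,
- the **cross-spectral exponent** `beta_xy` (`|SS_xy(f)| ∝ f**(-beta_xy)`,
  reported with positive sign for 1/f decay; `beta_xy = 2*H_xy - 1` with
  `H_xy` the bivariate Hurst exponent),
- the **fractal power fraction** `%Fractal = 100 * Σ SF_xy / Σ |SS_xy|`, an
  upper bound on the non-oscillatory share of cross-spectral power.

The method: for each resampling factor `h` in `{1.10, ..., 1.90}` the
cross-spectra of the pair resampled by `h` and `1/h` are combined by a
geometric mean (the fractal rescaling factors `h**(H_x+H_y)` cancel), and
the frequency-wise median over the `h` grid discards relocated oscillatory
peaks; spectra are estimated per overlapping Hann-tapered segment and
averaged. See `docs/methods.md` for the full algorithm and the estimator
variance-control choices.

## Worked example

```python
from mrcsa import (McArfimaParams, OscillationSpec, MrcsaConfig,
                   simulate_mc_arfima, inject_oscillations, mrcsa,
                   fit_spectral_slope, fractal_fraction)

params = McArfimaParams()                      # coupled pair, beta_uv = 0.5
pair = simulate_mc_arfima(params, 10_000, 500.0, seed=0)
pair = inject_oscillations(pair, [OscillationSpec(freq=10.0, rel_variance=0.64)],
                           params.beta_theoretical, seed=1)

config = MrcsaConfig(fit_band=(0.5, 100.0))
spec = mrcsa(pair, config)                     # mixed + fractal spectra

fit = fit_spectral_slope(spec, config.fit_band)
frac = fractal_fraction(spec, config.fit_band)
print(f"beta_xy  = {fit.beta:.3f}")
print(f"%Fractal = {frac.percent:.1f}")

fit_mixed = fit_spectral_slope(spec, config.fit_band, which="mixed")
print(f"beta from mixed spectrum = {fit_mixed.beta:.3f}")
```

Output:

```
beta_xy  = 0.536
%Fractal = 66.6
beta from mixed spectrum = 0.530
```

The pair was built with a theoretical cross-spectral exponent of 0.5 and a
strongly coherent 10 Hz oscillation. The separated fractal spectrum yields
`beta_xy ≈ 0.54` (spectrum-domain estimators scatter by about ±0.05 on
single 10,000-sample realizations), and `%Fractal ≈ 67` reports that about
a third of the cross-power in 0.5–100 Hz is oscillatory — without the
oscillation the same pipeline returns values close to 100. With only one
peak the mixed-spectrum slope happens to remain usable; the fraction is
what exposes the oscillatory contamination, and with larger or multiple
peaks the mixed slope degrades while the separated one does not.

The same analysis runs from the shell:

```sh
mrcsa simulate arfima_osc10 --seed 1 --out fixture
mrcsa analyze fixture/pair.csv --fs 500 --band 0.5 100 --out results
mrcsa reproduce --quick --seed 7      # scaled-down validation table
```

For multichannel data, `mrcsa.pairwise_mrcsa` fills channels × channels
exponent and `%Fractal` matrices (per-trial fits averaged across trials),
`node_degree` sums each channel's off-diagonal exponents, and
`compare_conditions` runs Lilliefors-gated paired t / Wilcoxon tests with
Bonferroni or FDR correction across the edge family — the standard
two-condition (e.g., rest vs task) comparison.

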