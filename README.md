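# specoct

Adaptive spectroscopic visible-light OCT oximetry: per-vessel retinal oxygen
saturation (sO₂) from raw spectral-domain interferograms, together with a
forward phantom simulator for end-to-end validation.

## The problem and who this is for

Visible-light OCT can measure retinal sO₂ because oxygenated and
deoxygenated hemoglobin absorb green light differently, but the
oxygen-dependent spectrum of blood is buried under *spectral contaminants*:
tissue reflections above the vessel, spectrally dependent roll-off and
background bias of the instrument, and chromatic aberration. This package
implements, in scientific Python, an adaptive processing chain that isolates
the blood signal vessel by vessel, and a physics-based simulator that
generates raw scans with known ground truth so every stage can be tested
quantitatively. It is aimed at researchers developing or evaluating
spectroscopic OCT oximetry algorithms.

## The method in brief

A 2048-sample fringe (508–614 nm) is resampled uniform in wavenumber and
multiplied by 21 Gaussian windows (528–588 nm, equidistant in k, 11 nm FWHM
at 558 nm), giving 21 spectrally dependent A-lines with ≈9 µm axial
resolution in tissue. Inside a vessel each band decays as
exp(−μ_t(λ)(z − z_d)) with

    μ_t(λ) = C_HbO₂ (μ_a,HbO₂ + SSF·μ_s,HbO₂) + C_Hb (μ_a,Hb + SSF·μ_s,Hb),

where SSF ∈ [0.02, 0.10] scales the Mie-theory scattering coefficient.
Normalizing each band at the decay onset z_d cancels multiplicative
contaminants from everything above the blood; the log spectrum,
depth-averaged over the window that a spectral-stability criterion selects,
is fitted by non-negative least squares and

    sO₂ = C_HbO₂ / (C_HbO₂ + C_Hb).

The whole chain is repeated over small variations of SSF, z_d and the
background amplitude S; filtered by fit quality; and the median surviving
estimate is reported with its R² and SSF. A non-adaptive single-pass
baseline (fixed anchor, fixed window, fixed SSF — the "FA" method) is
included for comparison. Details, parameter defaults and limitations are in
`docs/methods.md`.

## Worked example

```bash
python examples/02_recover_so2.py
```

simulates a 16 B-scan × 192 A-line scan of a 120 µm vessel at 60%
saturation — with spectral background, chromatic aberration, roll-off,
axial motion, dispersion and shot noise — and recovers:

```
true sO2      : 60.0%
recovered sO2 : 56.6%  (R^2 = 0.984, SSF = 0.08)
depth window  : z0 = 6 px, dz = 34 px below the detected decay onset
profiles used : 144 of 144 (16 B-scans x 9 sub-segmentations, after quality control)
```

The recovered saturation is the median surviving cell of the (SSF, z_d, S)
iteration; the window is where the band spectrum is most stable against
depth shifts. The other examples show the simulator's ground truth (01),
the stability-matrix window selection (03), and the adaptive-versus-fixed
spread under fully developed speckle (04).

There is also a thin command-line interface:

```bash
specoct simulate --so2 0.6 --seed 1 -o scan.h5
specoct process scan.h5 --vessels scan.vessels.json -o out/
specoct report out/results.csv --split-diameter 100
```

## Layout

- `src/specoct/` — the library: `stft` (windows/transform), `blood`
  (coefficients and digitization), `contaminants` (roll-off, background,
  chromatic aberration), `phantom` (forward simulator), `preprocess`
  (background removal, registration, segmentation, QC), `depth` (onset,
  normalization, window selection), `oxifit` (non-negative fit),
  `adaptive` (iteration, filtering, aggregation), `pipeline`, `container`,
  `cli`, `config`.
- `tests/` — unit and property tests plus the acceptance suite.
- `examples/` — four short narrative scripts.
- `docs/methods.md` — the model, defaults and known limitations.
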