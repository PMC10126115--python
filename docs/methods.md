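# Methods

`specoct` measures the oxygen saturation (sO₂) of a retinal blood vessel
from visible-light spectral-domain OCT interferograms. This note documents
the model, the numerical choices, the synthetic-data generator, and the
limits of what the tests show.

## Signal model

A spectrometer fringe (2048 samples, 508–614 nm) is resampled onto a
12288-point grid uniform in wavenumber k = 2π/λ and multiplied by 21
Gaussian windows with centers equidistant in k from 528 to 588 nm and a
common k-width equal to 11 nm at 558 nm. The inverse transform of each
windowed fringe is one spectrally dependent A-line (SDA-line): the depth
profile of backscattered amplitude in that band, with an axial resolution of
about 9 µm in tissue (n = 1.35) and a depth pixel of π/K ≈ 1.47 µm optical
(1.09 µm in tissue), where K is the sampled wavenumber span. The 1.09 µm
pixel follows from the stated 508–614 nm calibration; all depth grids step
by one pixel.

Inside a vessel the band amplitude follows Beer–Lambert decay with the
whole-blood attenuation coefficient

    μ_t(λ) = C_HbO₂ (μ_a,HbO₂ + SSF·μ_s,HbO₂) + C_Hb (μ_a,Hb + SSF·μ_s,Hb),

where SSF ∈ [0.02, 0.10] scales the Mie-theory scattering coefficient down
to what OCT detects. Dividing each band by its value at the decay onset z_d
cancels every multiplicative contaminant accumulated above the blood
(vessel wall, nerve fiber layer, spectral roll-off), and the log of the
normalized profile is linear in μ_t(λ)·(z − z_d) up to the depth-averaged
chromatic-aberration residual LCA_avg(λ). The per-vessel estimate is

    sO₂ = C_HbO₂ / (C_HbO₂ + C_Hb),

from a non-negative least-squares fit (free intercept; C's constrained ≥ 0,
which confines sO₂ to [0, 1]) of the depth-averaged log spectrum.

## Pipeline

1. **Band decomposition.** DC removal and source normalization (smoothed
   blocked-sample background subtracted, then divided out), cubic
   resampling to the k grid, Gaussian windowing, inverse transform.
2. **Background template and removal.** The additive spectrally-dependent
   background B(λ, z) is estimated from the blocked-sample calibration
   fringe as the rank-1 (separable) factorization of its band × depth
   amplitude, depth factor lightly smoothed, scaled by √(4/π) — the
   Rayleigh factor relating one realization's magnitude to the RMS
   envelope. Background and shot-noise floor are incoherent with the sample
   field, so they are removed in the intensity domain:
   amp′ = √(max(amp² − S²B² − n², 0)). The amplitude scale S is iterated.
3. **Averaging and registration.** Per B-scan, the central 36/40/42% of the
   vessel's A-lines at −4/0/+4% lateral shifts give nine sub-segmentations,
   each averaged in the intensity domain (RMS — the unbiased envelope
   estimator for speckle). Rigid axial motion per B-scan and residual
   per-band shifts (dispersion, chromatic aberration) are tracked on a
   bright fiducial reflection above the vessel and removed with spline
   interpolation; whole-profile correlation is the fallback when no
   prominent fiducial exists.
4. **Quality control.** Profiles more than 2 robust SDs worse than the
   stack in in-vessel SNR or in spectral smoothness at z_d are dropped
   (≥ 3 must survive); survivors are RMS-averaged.
5. **Decay onset.** z_d is the knee of the full-band log decay: the last
   prominent intensity maximum followed by a sustained decay, advanced to
   where the local decay rate reaches 85% of the established deep rate, so
   the anchor and the windows sit in the Beer–Lambert regime rather than in
   the onset region smeared by the axial point-spread function. The blood
   onset itself is estimated as the peak minus σ·x*, where x* solves
   φ(x*)/Φ(x*) = μσ (the analytic peak displacement of a smeared decay).
6. **Window selection.** Candidate windows start z0 ∈ {0…9} px below z_d
   and extend dz ∈ {16…35} px (≈17–38 µm), a 10 × 20 grid. Each window's
   mean spectrum is 0–1 normalized; a cell's score is the summed 21-band
   MSE against its 8 neighbors; the interior argmin (ties to the smallest
   window) fixes (z0, dz).
7. **Fit.** The measured spectrum, minus LCA_avg for a candidate focal
   shift (±100 µm in 50 µm steps; the best-R² shift wins), is regressed on
   the band-digitized blood coefficients scaled by the pathlength
   (z0 + dz/2). R² is computed against the full model prediction.
8. **Adaptive iteration.** Steps 2–7 are repeated over SSF (0.02–0.10 step
   0.01), z_d offsets (±2 px) and S (0.8–1.2 step 0.1). Cells are filtered
   (keep the top half by R², floor 0.5; drop estimates pinned at 0/1 when
   interior cells exceed 20%; drop failed fits), and the surviving cell
   holding the median sO₂ is reported with its R² and SSF.
9. **Baseline.** The fixed-attenuation method runs one pass with a fixed
   anchor (the segmented vessel's anterior signal plus one resolution
   element), a fixed window (z0 = 0, dz ≈ 29 µm), SSF = 0.06, S = 1, no
   QC, no window optimization and no iteration.

### Band digitization and in-band spectral reshaping

Blood is a dense scattering medium, so its spectral field components
decorrelate and the speckle-averaged band *intensity* responds to μ_t with
the squared window as spectral weights; the reference spectra are therefore
digitized with normalized w² weights (the literal amplitude window is kept
as an option). Because the band-averaged decay is −ln⟨e^(−μ_t(k)·z)⟩ rather
than −⟨μ_t⟩·z, the effective band attenuation drifts with depth toward each
window's weakly-absorbing side. For a fixed mixture this reshaped response
is still linear in the concentrations, so the fit re-digitizes the pure
regressors with attenuation-reweighted windows, w²·e^(−2μ_mix·z̄), at the
window's mean depth below the estimated onset, and repeats the non-negative
regression to self-consistency (3 passes; results cached on a quantized
key). On noiseless contaminant-free phantoms this refinement reduces the
maximum recovery error from ≈6% to ≈0.6% absolute.

## Reference spectra

The package ships a synthetic whole-blood coefficient table
(`data/whole_blood_coefficients_synthetic.csv`, generated by
`scripts/make_blood_table.py`): monotone-segment interpolants through
landmark knots reproducing the canonical structure of compiled
oxy/deoxyhemoglobin data at 45% hematocrit — Q-band peaks at 542/577 nm
(HbO₂) and 555 nm (Hb), isosbestic crossings within 2 nm of 548, 570 and
586 nm, magnitudes from molar extinction (ln 10 · ε · 150 g/L ÷ 64500
g/mol, ≈28 mm⁻¹ at the peaks) with red-cell pigment-packing flattening —
plus smooth Mie-scale scattering (≈70 mm⁻¹, slowly declining). The
green-range crossing knots are placed, within the ±2 nm constraint, so that
the band-digitized oxy and deoxy coefficients agree at the nearest band.
The 586 nm crossing does not survive 11-nm band averaging (the window
overlaps the 577 nm peak and the red cliff — true of any tabulation); the
band-level isosbestic property therefore holds at the 548- and 570-adjacent
bands. It is not a published measurement, and no claim of numeric agreement
with any published table is made.

## Synthetic-data generator

Each A-line is a coherent sum of discrete scatterers (1.2 µm spacing — the
dense regime whole blood occupies) with spectral amplitudes carrying
backscattering, layer transmissions, oxygen-dependent Beer–Lambert decay
inside a cylindrical vessel, spectral roll-off F(λ, z) and the confocal
factor √A(λ, z). Defaults: a 50 µm high-backscatter surface layer and a
470 µm inner layer from 80 µm depth; a bright specular surface reflection;
a 120 µm vessel with its lumen at 180 µm, a 12 µm scattering wall whose
specular outer interface sits one wall thickness above the blood onset;
SSF 0.06. Contaminants: roll-off 0.15 mm⁻¹ (±30% across the band — the
normalized ratio stays within 1% over 40 µm windows, justifying its
neglect after normalization); additive background at 8% of the blood
signal at z_d, with a −40%/band-span spectral slope and a 250 µm depth
constant, whose phase pattern is redrawn per exposure while the amplitude
envelope is fixed (the blocked-sample calibration stores one realization);
chromatic focal shift 50 µm across the band with a 180 µm confocal width
(0.05 numerical aperture scale); ±2 µm per-B-scan axial motion; a 2 px
dispersion-like spread of band positions; shot noise at 35 dB in-band SNR
at z_d. Scan geometry: 16 B-scans × 256 A-lines at 0.8 µm pitch, mirroring
a dense arc scan at reduced A-line count.

Speckle is fully developed (circular-Gaussian scatterer weights, fresh per
B-scan and A-line, as for flowing blood). A speckle-free validation mode
replaces the weights with a phase family orthogonal across B-scans
(φ_jb = 2πjb/B, reflectors offset by B/2), so the B-scan-averaged intensity
equals the incoherent Beer–Lambert envelope exactly; its members are only
meaningful jointly, so quality control is configured to keep all of them
(it requires B·spacing ≳ 18 µm, enforced at simulation time).

**What the phantoms do not emulate:** lateral beam-width speckle
correlation, flow and orientation-dependent red-cell scattering, eye bulk
motion beyond rigid axial jitter, depth-dependent dispersion, multiple
scattering, and anatomical variety (one vessel in two flat layers).
Passing tests therefore demonstrate contaminant removal and model fidelity
under controlled conditions, not clinical performance.

## Accuracy and noise, as measured here

* Noiseless, contaminant-free phantoms: recovery within ±0.7% absolute at
  0/25/50/75/100% saturation (worst at the 0% boundary, where
  non-negativity makes the residual one-sided); this is the second-order
  floor of the linearized band model.
* The 17-level saturation sweep (contaminants, shot noise, motion,
  speckle-free limit) recovers sO₂ with a mean absolute error of ≈1–2
  points, limited by the fidelity of the single-realization background
  calibration at high saturation.
* With fully developed speckle at this scan size (≈150 in-vessel A-lines ×
  16 B-scans), the single-pixel normalization anchor alone carries ≈1.6%
  amplitude uncertainty after all lateral averaging, which bounds
  per-measurement sO₂ noise at several points; it scales as 1/√N with the
  A-line count. The adaptive estimate remains tighter than the fixed
  baseline under these conditions (paired-seed comparison).

## Numerical choices and degenerate inputs

* Log floor: amplitudes are clipped per band at the 0.1-percentile positive
  value before the log (per-band, so per-band rescalings cancel exactly in
  the normalization); the valid depth range ends at the first clip.
* SSM ties break to the smallest z0, then dz, with a small relative
  tolerance so exactly-stable grids resolve deterministically; degenerate
  (flat) window spectra are excluded as centers and neighbors.
* Saturated fringes are flagged per A-line and excluded.
* Vessels deeper than 700 µm, narrower than 4 annotated A-lines, without a
  sustained decay, or with fewer than 3 surviving QC profiles are rejected
  with a reason.
* All randomness is seeded; processing is deterministic given a container,
  annotations and a configuration. Simulated containers are byte-identical
  for a fixed seed.

## Open design points resolved here

* The decay-onset detector works on the full-band (band-summed) profile.
* The regression includes a free intercept: the normalized depth-averaged
  spectrum carries an arbitrary additive constant (and the band-common part
  of the confocal residual), which belongs to no physical regressor.
* The window grid uses 10 × 20 cells (start offsets 0–9 px, extents from
  ≈17 µm), stepping by the actual depth pixel.
* Iteration grids (SSF step 0.01, z_d ±2 px, S 0.8–1.2 step 0.1, focal
  shifts ±100 µm step 50) and the filter rules reconstruct steps whose
  published description is not specific; all are configuration-exposed.
* Problem sizes used in tests and in the reproduction script (16 × 256
  scans, 17 levels, 20-seed comparisons) are the package's validation
  scale; larger scans only improve the statistics.
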