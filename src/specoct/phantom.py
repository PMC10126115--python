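"""Forward-model phantom simulator with known oximetry ground truth.

A layered digital retina with an embedded cylindrical blood vessel is
rendered into raw spectrometer fringes.  Each A-line is a coherent sum of
discrete scatterers: ``fringe(k) = Re sum_j w_j a_j(lambda) exp(i 2 k n z_j)``
with complex speckle weights ``w_j``, spectral amplitudes ``a_j`` carrying
backscattering, cumulative attenuation (oxygen-dependent inside the vessel),
interface transmissions, spectral roll-off ``F`` and the confocal/chromatic
factor ``sqrt(A)``.  The simulator also injects the additive spectrally-
dependent background (as a deterministic fixed-pattern fringe whose band
amplitude follows the model template), per-B-scan axial motion, a
dispersion-like per-band axial shift, and white shot noise.

All depths are physical tissue depths (um) from the zero-delay position;
optical path uses n = 1.35.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .blood import BloodSpectra, digitize_reference, load_reference_table
from .container import RawScan, VesselAnnotation
from .contaminants import ContaminantModel, lca_transfer, sdbg_shape, sdr_factor
from .errors import ValidationError
from .stft import TISSUE_INDEX, WindowBank, build_windows, resample_to_k

MIN_DIAMETER_UM = 35.0
MAX_VESSEL_DEPTH_UM = 700.0

_BG_PHASE_SEED = 20200508  # fixed-pattern background is instrument-like, not seeded


@dataclass(frozen=True)
class Layer:
    """One tissue slab: thickness, backscattering, attenuation, interface T."""
    thickness_um: float
    mu_b_per_mm: float
    mu_t_per_mm: float
    transmission: float = 1.0

    def __post_init__(self):
        if not 0.0 < self.transmission <= 1.0:
            raise ValidationError("interface transmission must be in (0, 1]")


def default_layers():
    return [
        Layer(thickness_um=50.0, mu_b_per_mm=2.0, mu_t_per_mm=1.5, transmission=0.95),
        Layer(thickness_um=470.0, mu_b_per_mm=0.6, mu_t_per_mm=0.8),
    ]


@dataclass(frozen=True)
class VesselSpec:
    """Cylindrical vessel: geometry, oxygenation and wall optics.

    ``anterior_depth_um`` is the top of the blood column (the lumen); the
    vessel wall is a thin scattering slab above and below the lumen, with a
    specular reflection at its outer surface — so the blood decay onset sits
    about one wall thickness below the bright anterior-wall interface, as in
    real vessels.
    """
    anterior_depth_um: float = 180.0
    diameter_um: float = 120.0
    so2_true: float = 0.6
    ssf_true: float = 0.06
    wall_thickness_um: float = 12.0
    wall_mu_b_per_mm: float = 1.5       # wall slab backscattering
    wall_reflectivity: float = 1.2      # outer-interface reflector vs blood amplitude
    wall_transmission: float = 0.90
    backscatter_frac: float = 0.08      # mu_b_blood = frac * mu_s_blood
    attenuation_scale: float = 1.0      # 0 disables blood attenuation

    def __post_init__(self):
        if self.diameter_um < MIN_DIAMETER_UM:
            raise ValidationError(f"vessel diameter below {MIN_DIAMETER_UM:.0f} um")
        if self.anterior_depth_um + self.diameter_um >= MAX_VESSEL_DEPTH_UM:
            raise ValidationError("vessel extends beyond 700 um from zero delay")
        if not 0.0 <= self.so2_true <= 1.0:
            raise ValidationError("so2_true must lie in [0, 1]")
        if not 0.02 <= self.ssf_true <= 0.10:
            raise ValidationError("ssf_true must lie in [0.02, 0.10]")


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic scan."""
    vessel: VesselSpec = field(default_factory=VesselSpec)
    layers: tuple = None
    contaminants: ContaminantModel = field(default_factory=ContaminantModel)
    contaminants_on: bool = True
    sdbg_scale_true: float = 1.0      # true S multiplying the background template
    noise_snr_db: float = 35.0        # in-band SNR at z_d; None/inf disables
    speckle: bool = True
    n_bscans: int = 16
    n_alines: int = 256
    lateral_pixel_um: float = 0.8
    bscan_jitter_um: float = 2.0      # SD of per-B-scan axial motion
    band_shift_spread_px: float = 2.0  # dispersion-like axial spread across bands
    surface_depth_um: float = 80.0
    scatterer_spacing_um: float = 1.2
    seed: int = 0

    def __post_init__(self):
        if self.layers is None:
            object.__setattr__(self, "layers", tuple(default_layers()))

    def with_(self, **kw) -> "PhantomSpec":
        return replace(self, **kw)

    def clean(self, **kw) -> "PhantomSpec":
        """A noiseless, contaminant-free, speckle-free copy (for validation)."""
        return self.with_(contaminants_on=False, noise_snr_db=None, speckle=False,
                          bscan_jitter_um=0.0, band_shift_spread_px=0.0, **kw)


@dataclass
class GroundTruth:
    """What the pipeline should recover, in pipeline coordinates."""
    so2_true: float
    ssf_true: float
    zd_true_px: int                 # depth pixel of blood-decay onset
    vessel_alines: tuple            # (left, right) inclusive A-line bounds
    anterior_depth_um: float
    diameter_um: float
    mu_t_blood_band: np.ndarray     # (21,) true per-band attenuation, mm^-1
    band_shift_px: np.ndarray       # injected per-band axial shifts
    bscan_jitter_px: np.ndarray     # injected per-B-scan axial motion
    sdbg_scale_true: float = 1.0


def _blood_mu(table, wavelength_nm, vessel: VesselSpec):
    """(mu_b, mu_t) of blood on the wavelength grid for the true sO2/SSF."""
    lam = table.wavelength_nm
    s = vessel.so2_true
    mu_a = s * np.interp(wavelength_nm, lam, table.mu_a_hbo2) + \
        (1 - s) * np.interp(wavelength_nm, lam, table.mu_a_hb)
    mu_s = s * np.interp(wavelength_nm, lam, table.mu_s_hbo2) + \
        (1 - s) * np.interp(wavelength_nm, lam, table.mu_s_hb)
    mu_t = vessel.attenuation_scale * (mu_a + vessel.ssf_true * mu_s)
    mu_b = vessel.backscatter_frac * mu_s
    return mu_b, mu_t


class _Scene:
    """Precomputed spectral amplitude columns for every A-line type."""

    def __init__(self, spec: PhantomSpec, wavelength_nm: np.ndarray,
                 table, windows: WindowBank):
        self.spec = spec
        self.lam = wavelength_nm
        self.k = 2.0 * np.pi / wavelength_nm          # rad/nm, descending
        self.env = np.exp(-0.5 * ((wavelength_nm - 561.0) / 28.0) ** 2) ** 2
        self.windows = windows

        v = spec.vessel
        self.mu_b_blood, self.mu_t_blood = _blood_mu(table, wavelength_nm, v)

        # scatterer depth grid (physical um)
        z_top = spec.surface_depth_um
        z_bot = z_top + sum(l.thickness_um for l in spec.layers)
        self.z = np.arange(z_top, z_bot, spec.scatterer_spacing_um)
        self.ds_mm = spec.scatterer_spacing_um * 1e-3

        # per-scatterer layer properties (wavelength-flat)
        edges = np.cumsum([z_top] + [l.thickness_um for l in spec.layers])
        idx = np.searchsorted(edges, self.z, side="right") - 1
        idx = np.clip(idx, 0, len(spec.layers) - 1)
        self.mu_b_layer = np.array([spec.layers[i].mu_b_per_mm for i in idx])
        self.mu_t_layer = np.array([spec.layers[i].mu_t_per_mm for i in idx])
        trans = np.ones(self.z.size)
        for i, e in enumerate(edges[:-1]):
            t = spec.layers[i].transmission
            trans[self.z >= e] *= np.sqrt(t)
        self.t_above = trans

        # vessel chord geometry per A-line
        r = v.diameter_um / 2.0
        x = (np.arange(spec.n_alines) - spec.n_alines / 2.0) * spec.lateral_pixel_um
        self.half_chord = np.where(np.abs(x) < r, np.sqrt(np.maximum(r * r - x * x, 0.0)), 0.0)
        self.z_center = v.anterior_depth_um + r
        self.in_vessel = self.half_chord > 0.5 * spec.scatterer_spacing_um

        # phase factors exp(i 2 k n z) for scatterers and singleton reflectors
        self.phase = np.exp(1j * 2.0 * self.k[None, :] * TISSUE_INDEX
                            * (self.z[:, None] * 1e3))  # um -> nm
        # contaminant fields on the scatterer grid
        if spec.contaminants_on:
            cm = spec.contaminants
            f_sdr = sdr_factor(cm, self.z[:, None], self.lam[None, :])
            a_lca = lca_transfer(cm, self.z[:, None], self.lam[None, :])
            self.inst = f_sdr * np.sqrt(a_lca)
        else:
            self.inst = np.ones((self.z.size, self.lam.size))

    def _reflector(self, z_um, amplitude_lam):
        """Spectral row and phase for a discrete reflector."""
        ph = np.exp(1j * 2.0 * self.k * TISSUE_INDEX * z_um * 1e3)
        return amplitude_lam * ph

    def column(self, aline: int):
        """Complex (J+extras, n_samples) matrix ``a_j(lambda) * phase_j`` for
        one A-line (rows: scatterers then discrete reflectors), plus the
        physical depth of every row (used to build orthogonal phase
        families in the speckle-free mode)."""
        spec = self.spec
        v = spec.vessel
        hc = self.half_chord[aline]
        z = self.z

        mu_b = self.mu_b_layer[:, None] * np.ones_like(self.lam)[None, :]
        # cumulative attenuation of the layer stack above each scatterer
        cum_t = np.cumsum(self.mu_t_layer) * self.ds_mm
        atten = np.exp(-cum_t[:, None] * np.ones_like(self.lam)[None, :])
        trans = self.t_above[:, None].copy()

        rows_extra = []
        z_extra = []
        if hc > 0:
            z_t, z_b = self.z_center - hc, self.z_center + hc
            wt = v.wall_thickness_um
            inside = (z >= z_t) & (z < z_b)
            in_wall = ((z >= z_t - wt) & (z < z_t)) | ((z >= z_b) & (z < z_b + wt))
            below_wall_top = z >= z_t - wt
            mu_b = np.where(inside[:, None], self.mu_b_blood[None, :], mu_b)
            mu_b = np.where(in_wall[:, None], v.wall_mu_b_per_mm, mu_b)
            # blood displaces the host layer: its attenuation replaces the
            # layer's over the chord path
            path_mm = np.clip(z - z_t, 0.0, 2.0 * hc)[:, None] * 1e-3
            i_host = int(np.searchsorted(z, self.z_center))
            mu_host = self.mu_t_layer[min(i_host, z.size - 1)]
            atten = atten * np.exp(-(self.mu_t_blood[None, :] - mu_host) * path_mm)
            trans = trans * np.where(below_wall_top[:, None],
                                     np.sqrt(v.wall_transmission), 1.0)
            # specular reflection at the outer anterior-wall surface,
            # spectrally flat, one wall thickness above the blood onset
            z_awi = z_t - wt
            i_wall = min(int(np.searchsorted(z, z_awi)), z.size - 1)
            wall_amp = (v.wall_reflectivity
                        * np.sqrt(self.mu_b_blood * self.ds_mm) * self.env
                        * self.t_above[i_wall] * np.exp(-cum_t[i_wall]))
            if spec.contaminants_on:
                cm = spec.contaminants
                wall_amp = wall_amp * sdr_factor(cm, z_awi, self.lam) * \
                    np.sqrt(lca_transfer(cm, z_awi, self.lam))
            rows_extra.append(self._reflector(z_awi, wall_amp))
            z_extra.append(z_awi)

        a = self.env[None, :] * np.sqrt(mu_b * self.ds_mm) * atten * trans * self.inst
        rows = a * self.phase
        # bright specular surface reflection (inner limiting membrane
        # analogue); amplitude independent of the scatterer grid
        surf_amp = 0.4 * self.env
        rows_extra.append(self._reflector(self.spec.surface_depth_um - 1.0, surf_amp))
        z_extra.append(self.spec.surface_depth_um - 1.0)
        row_z = np.concatenate([z, np.asarray(z_extra)])
        self.n_scatterer_rows = z.size
        return np.vstack([rows] + rows_extra), row_z


def _band_probe(windows: WindowBank, wavelength_nm, fringes, band: int = 10):
    """Band amplitude image of raw (already DC-free) fringes; (depth, n)."""
    on_k = resample_to_k(np.atleast_2d(fringes), wavelength_nm, windows.k_grid)
    spec = np.fft.rfft(on_k * windows.weights[band][None, :], axis=1)
    return np.abs(spec[:, :windows.n_depth]).T


def _background_pattern(spec: PhantomSpec, wavelength_nm, windows: WindowBank,
                        signal_scale: float, rng=None, n_realizations: int = 1):
    """Additive background fringes whose band amplitude follows the SDBG
    template, scaled to ``sdbg_rel_amp`` of the blood signal at z_d.

    The amplitude envelope B(lambda, z) is fixed (instrument-like), but the
    phases of the underlying pattern fluctuate between acquisitions; with
    ``rng=None`` a fixed internal seed is used (the blocked-sample
    calibration), otherwise one realization per B-scan is drawn.
    Returns an (n_realizations, n_samples) array.
    """
    cm = spec.contaminants
    if rng is None:
        rng = np.random.default_rng(_BG_PHASE_SEED)
    z_m = np.arange(30.0, 690.0, 5.0)
    c = sdbg_shape(cm, z_m[:, None], wavelength_nm[None, :])
    k = 2.0 * np.pi / wavelength_nm
    carrier = np.exp(1j * 2.0 * k[None, :] * TISSUE_INDEX * z_m[:, None] * 1e3)
    psi = rng.uniform(0, 2 * np.pi, (n_realizations, z_m.size))
    patterns = np.real(np.exp(1j * psi) @ (c * carrier))
    # normalize: band amplitude at the vessel's z_d depth -> rel_amp * signal
    zd_px = int(round(spec.vessel.anterior_depth_um / windows.axial_px_um))
    probe = _band_probe(windows, wavelength_nm, patterns)
    lo, hi = max(zd_px - 5, 0), zd_px + 6
    current = float(np.sqrt(np.mean(probe[lo:hi] ** 2)))
    if current <= 0:
        return np.zeros_like(patterns)
    return patterns * (cm.sdbg_rel_amp * signal_scale / current)


def simulate_scan(spec: PhantomSpec, table=None, windows: WindowBank = None):
    """Render a phantom into a raw scan; returns ``(RawScan, GroundTruth)``.

    Deterministic for a fixed spec (the seed drives speckle, motion and
    noise); two runs with the same spec produce identical fringes.
    """
    if table is None:
        table = load_reference_table()
    wavelength = np.linspace(508.0, 614.0, 2048)
    if windows is None:
        windows = build_windows(wavelength)
    rng = np.random.default_rng(spec.seed)
    if not spec.speckle:
        # the orthogonal-phase family cancels cross terms only if scatterers
        # sharing a phase (B apart) are well separated compared to the PSF
        sep_opt_um = spec.n_bscans * spec.scatterer_spacing_um * 1.35
        if sep_opt_um < 24.0:
            raise ValidationError(
                "speckle-free mode needs n_bscans * scatterer_spacing >= "
                f"{24.0 / 1.35:.0f} um (got {sep_opt_um / 1.35:.1f}); "
                "use more B-scans or a coarser scatterer grid")
    scene = _Scene(spec, wavelength, table, windows)
    v = spec.vessel

    B, A, S = spec.n_bscans, spec.n_alines, wavelength.size
    fringes = np.empty((B, A, S))

    # per-B-scan axial motion and dispersion-like per-band shift phases
    jitter_um = rng.normal(0.0, spec.bscan_jitter_um, B) if spec.bscan_jitter_um > 0 \
        else np.zeros(B)
    k = scene.k
    ph_jit = np.exp(1j * 2.0 * k[None, :] * TISSUE_INDEX * jitter_um[:, None] * 1e3)
    k_mid = 0.5 * (windows.center_k[0] + windows.center_k[-1])
    if spec.band_shift_spread_px != 0.0:
        dz_opt_nm = windows.axial_px_optical_um * 1e3
        beta = (spec.band_shift_spread_px * dz_opt_nm
                / (windows.center_k[-1] - windows.center_k[0]))
        ph_disp = np.exp(1j * beta * (k - k_mid) ** 2)
        band_shift_px = beta * (windows.center_k - k_mid) / dz_opt_nm
    else:
        ph_disp = np.ones_like(k)
        band_shift_px = np.zeros(windows.n_bands)

    def weights(n_rows, count, n_scat):
        # diffuse scatterers get circular-Gaussian speckle weights; the
        # discrete reflectors are specular (deterministic phase)
        w = np.ones((count, n_rows), dtype=complex)
        if spec.speckle:
            w[:, :n_scat] = (rng.standard_normal((count, n_scat))
                             + 1j * rng.standard_normal((count, n_scat))) / np.sqrt(2.0)
        return w

    out_cols = np.nonzero(~scene.in_vessel)[0]
    ves_cols = np.nonzero(scene.in_vessel)[0]

    if spec.speckle:
        m_out = scene.column(int(out_cols[0]))[0] if out_cols.size else None
        if m_out is not None:
            w = weights(m_out.shape[0], B * out_cols.size, scene.n_scatterer_rows)
            block = (w @ m_out).reshape(B, out_cols.size, S)
            fringes[:, out_cols, :] = np.real(
                block * (ph_jit[:, None, :] * ph_disp[None, None, :]))
        for x in ves_cols:
            m_x = scene.column(int(x))[0]
            w = weights(m_x.shape[0], B, scene.n_scatterer_rows)
            block = w @ m_x
            fringes[:, x, :] = np.real(block * ph_jit * ph_disp[None, :])
    else:
        # speckle-free limit: scatterer phases form a DFT-orthogonal family
        # across B-scans (phi_jb = 2 pi j b / B), so the B-scan-averaged
        # *intensity* equals the incoherent Beer-Lambert envelope exactly
        # (cross terms cancel; scatterers B steps apart are far outside one
        # resolution cell).  The pipeline averages profiles as RMS.
        bb = max(B, 2)

        def ortho(row_z):
            # scatterers keep their grid index; reflectors get an index
            # offset by B/2 from the scatterer at their own depth, so the
            # reflector-scatterer cross term also cancels within a
            # resolution cell
            n_scat = scene.z.size
            fam = np.arange(row_z.size, dtype=float)
            for r in range(n_scat, row_z.size):
                near = int(np.argmin(np.abs(scene.z - row_z[r])))
                fam[r] = near + bb // 2
            b = np.arange(B)
            return np.exp(2j * np.pi * np.outer(b, fam) / bb)

        if out_cols.size:
            m_out, z_out = scene.column(int(out_cols[0]))
            block = ortho(z_out) @ m_out          # (B, S)
            fringes[:, out_cols, :] = np.real(
                (block * ph_jit * ph_disp[None, :])[:, None, :])
        for x in ves_cols:
            m_x, z_x = scene.column(int(x))
            block = ortho(z_x) @ m_x
            fringes[:, x, :] = np.real(block * ph_jit * ph_disp[None, :])

    # reference blood signal amplitude at z_d (RMS over a few B-scans of the
    # vessel core, band 10) used to scale the background and the shot noise
    zd_um = scene.z_center - scene.half_chord.max()
    zd_px = int(round(zd_um / windows.axial_px_um))
    core = ves_cols[np.abs(ves_cols - A // 2) <= max(2, ves_cols.size // 8)] \
        if ves_cols.size else out_cols[:3]
    nb = min(B, 6)
    probe = np.sqrt(np.mean([
        _band_probe(windows, wavelength, fringes[b, core, :]) ** 2
        for b in range(nb)], axis=0))
    signal_scale = float(np.mean(probe[max(zd_px - 2, 0):zd_px + 6, :]))

    # additive background (SDBG) and DC terms; the background's phase
    # pattern fluctuates between exposures (A-line rate), its amplitude
    # envelope does not; the blocked-sample calibration is one realization
    dc = 2000.0 * scene.env + 20.0
    bg_cal = np.zeros(S)
    if spec.contaminants_on and spec.contaminants.sdbg_rel_amp > 0:
        bg_cal = _background_pattern(spec, wavelength, windows, signal_scale)[0]
        bg_scan = _background_pattern(spec, wavelength, windows, signal_scale,
                                      rng=rng, n_realizations=B * A)
        fringes += spec.sdbg_scale_true * bg_scan.reshape(B, A, S)
    fringes += dc[None, None, :]
    background = dc + bg_cal

    # shot noise, calibrated to the requested in-band SNR at z_d
    if spec.noise_snr_db is not None and np.isfinite(spec.noise_snr_db):
        probe_rng = np.random.default_rng(977)
        unit = probe_rng.standard_normal((32, S)) * np.sqrt(dc / dc.max())[None, :]
        gain = float(np.mean(_band_probe(windows, wavelength, unit)[100:900, :]))
        target = signal_scale * 10.0 ** (-spec.noise_snr_db / 20.0)
        sigma0 = target / gain
        fringes += sigma0 * rng.standard_normal(fringes.shape) * \
            np.sqrt(dc / dc.max())[None, None, :]

    scan = RawScan(
        fringes=fringes,
        wavelength_nm=wavelength,
        background_fringe=background,
        axial_pixel_um=windows.axial_px_um,
        lateral_pixel_um=spec.lateral_pixel_um,
        scan_type="raster",
    )
    spectra = digitize_reference(table, windows)
    mu_t_band = v.attenuation_scale * (
        v.so2_true * (spectra.mu_a_hbo2_band + v.ssf_true * spectra.mu_s_hbo2_band)
        + (1 - v.so2_true) * (spectra.mu_a_hb_band + v.ssf_true * spectra.mu_s_hb_band))
    truth = GroundTruth(
        so2_true=v.so2_true,
        ssf_true=v.ssf_true,
        zd_true_px=zd_px,
        vessel_alines=(int(ves_cols[0]), int(ves_cols[-1])) if ves_cols.size else (0, 0),
        anterior_depth_um=v.anterior_depth_um,
        diameter_um=v.diameter_um,
        mu_t_blood_band=mu_t_band,
        band_shift_px=band_shift_px,
        bscan_jitter_px=jitter_um / windows.axial_px_um,
        sdbg_scale_true=spec.sdbg_scale_true,
    )
    return scan, truth


def single_reflector_fringe(depth_optical_um: float = 150.0,
                            wavelength_nm=None, amplitude: float = 1.0):
    """Noiseless fringe of one ideal reflector at a given optical depth.

    Returns ``(fringe, background, wavelength_nm)``: the fringe carries the
    source envelope and DC terms; the background is the DC alone.  Used for
    point-spread-function and resolution measurements.
    """
    if wavelength_nm is None:
        wavelength_nm = np.linspace(508.0, 614.0, 2048)
    lam = np.asarray(wavelength_nm, dtype=float)
    k = 2.0 * np.pi / lam
    env = np.exp(-0.5 * ((lam - 561.0) / 28.0) ** 2) ** 2
    dc = 2000.0 * env + 20.0
    fringe = amplitude * env * np.cos(2.0 * k * depth_optical_um * 1e3) + dc
    return fringe, dc, lam


def default_annotation(spec: PhantomSpec, truth: GroundTruth,
                       vessel_id: str = "V1") -> VesselAnnotation:
    """Annotation matching the simulated vessel's lateral bounds."""
    left, right = truth.vessel_alines
    return VesselAnnotation(vessel_id=vessel_id, a_line_left=left,
                            a_line_right=right, vessel_type="vein")


def make_series(so2_levels, spec: PhantomSpec, seed: int):
    """One phantom per sO2 level, child seeds derived from a master seed."""
    levels = list(so2_levels)
    children = np.random.SeedSequence(seed).spawn(len(levels))
    out = []
    for lvl, child in zip(levels, children):
        sub_seed = int(child.generate_state(1)[0] % (2 ** 31))
        sub = spec.with_(vessel=replace(spec.vessel, so2_true=float(lvl)),
                         seed=sub_seed)
        out.append(simulate_scan(sub))
    return out
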