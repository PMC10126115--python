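"""System-dependent spectral contaminant models: SDR, SDBG and LCA.

Three instrument effects bias depth-resolved band spectra:

* spectrally-dependent roll-off (SDR), a multiplicative, band-dependent
  sensitivity decay with depth, ``F(lambda, z)``;
* spectrally-dependent background (SDBG), an additive band/depth bias
  ``B(lambda, z)`` with an amplitude scale ``S``;
* longitudinal chromatic aberration (LCA), a band-dependent confocal axial
  profile ``A(lambda, z)`` whose focal plane shifts with wavelength.

The same model objects drive the phantom simulator (forward direction) and
the oximetry fit (the depth-averaged log-residual of ``A``, which enters the
regression as a known offset per candidate focal shift).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ValidationError

LCA_SHIFT_LIMIT_UM = 100.0
_REF_NM = 558.0
_BAND_HALF_SPAN_NM = 30.0  # 528..588 spans +-30 nm about 558


@dataclass(frozen=True)
class ContaminantModel:
    """Parameterization of the three system contaminants.

    Depths are physical tissue depths in micrometers from the zero-delay
    position; rates are per millimeter of physical depth.
    """

    sdr_decay_per_mm: float = 0.15    # amplitude decay rate of F at 558 nm
    sdr_slope: float = 0.3            # fractional change of the rate per +30 nm
    sdbg_rel_amp: float = 0.08        # SDBG amplitude relative to blood signal at z_d
    sdbg_lambda_slope: float = -0.4   # fractional change of B per +30 nm
    sdbg_depth_const_um: float = 250.0
    lca_focal_center_um: float = 220.0
    lca_focal_shift_um: float = 50.0  # chromatic focal shift across 528->588 nm
    lca_sigma_um: float = 180.0       # Gaussian confocal axial width

    def __post_init__(self):
        if abs(self.lca_focal_shift_um) > LCA_SHIFT_LIMIT_UM:
            raise ValidationError(
                f"|LCA focal shift| must be <= {LCA_SHIFT_LIMIT_UM:.0f} um")
        if self.sdbg_rel_amp < 0 or self.sdbg_depth_const_um <= 0:
            raise ValidationError("SDBG parameters out of range")
        if self.sdr_decay_per_mm < 0 or self.lca_sigma_um <= 0:
            raise ValidationError("SDR/LCA parameters out of range")

    def with_(self, **kw) -> "ContaminantModel":
        return replace(self, **kw)


def sdr_factor(model: ContaminantModel, depth_um, wavelength_nm) -> np.ndarray:
    """Roll-off factor F(lambda, z); F(., 0) = 1, monotone non-increasing in z.

    Broadcasts over both arguments.
    """
    z = np.asarray(depth_um, dtype=float)
    lam = np.asarray(wavelength_nm, dtype=float)
    rate = model.sdr_decay_per_mm * (
        1.0 + model.sdr_slope * (lam - _REF_NM) / _BAND_HALF_SPAN_NM)
    rate = np.maximum(rate, 0.0)
    return np.exp(-rate * z * 1e-3)


def lca_transfer(model: ContaminantModel, depth_um, wavelength_nm,
                 focal_shift_um: float = None) -> np.ndarray:
    """Confocal transfer A(lambda, z): Gaussian in depth, chromatic focus.

    The focal plane moves linearly with wavelength; ``focal_shift_um`` is the
    total shift across the 528-588 nm band (default: the model's own value).
    A zero shift makes A identical across bands.
    """
    shift = model.lca_focal_shift_um if focal_shift_um is None else float(focal_shift_um)
    if abs(shift) > LCA_SHIFT_LIMIT_UM:
        raise ValidationError(
            f"|LCA focal shift| must be <= {LCA_SHIFT_LIMIT_UM:.0f} um")
    z = np.asarray(depth_um, dtype=float)
    lam = np.asarray(wavelength_nm, dtype=float)
    z_f = model.lca_focal_center_um + shift * (lam - _REF_NM) / (2 * _BAND_HALF_SPAN_NM)
    return np.exp(-0.5 * ((z - z_f) / model.lca_sigma_um) ** 2)


def lca_avg(model: ContaminantModel, band_centers_nm, zd_px: int,
            z0_px: int, dz_px: int, axial_px_um: float,
            focal_shift_um: float = None) -> np.ndarray:
    """Depth-averaged residual LCA over the window [z_d+z0, z_d+z0+dz].

    Returns, per band, ``0.5 * < ln A(lambda, z) - ln A(lambda, z_d) >_z``
    (the window includes both endpoints) with the band mean removed — the
    additive regressor the oximetry fit subtracts from the measured
    spectrum.  Only the spectral shape matters: the band-common part of the
    confocal profile is indistinguishable from the fit's free intercept, so
    a zero focal shift gives an identically zero regressor.
    """
    if z0_px < 0 or dz_px <= 0:
        raise ValidationError("window offsets must be non-negative, extent positive")
    z_px = zd_px + z0_px + np.arange(dz_px + 1)
    z_um = z_px * axial_px_um
    lam = np.asarray(band_centers_nm, dtype=float)
    ln_a = np.log(lca_transfer(model, z_um[:, None], lam[None, :], focal_shift_um))
    ln_a_zd = np.log(lca_transfer(model, zd_px * axial_px_um, lam, focal_shift_um))
    out = 0.5 * (ln_a.mean(axis=0) - ln_a_zd)
    return out - out.mean()


def sdbg_shape(model: ContaminantModel, depth_um, wavelength_nm) -> np.ndarray:
    """Unit-amplitude SDBG shape B(lambda, z)/B0: separable band x depth decay."""
    z = np.asarray(depth_um, dtype=float)
    lam = np.asarray(wavelength_nm, dtype=float)
    spectral = np.maximum(
        1.0 + model.sdbg_lambda_slope * (lam - _REF_NM) / _BAND_HALF_SPAN_NM, 0.0)
    return spectral * np.exp(-z / model.sdbg_depth_const_um)


def sdbg_template_from_background(background_fringe, wavelength_nm, windows,
                                  depth_px: int = 1024,
                                  artifact_px: int = 20) -> np.ndarray:
    """Estimate the additive band/depth background template from a background
    fringe (sample arm blocked), processed through the same STFT.

    The background bias is separable (a band shape times a depth profile),
    but a single calibration fringe carries speckle-like ripple; the
    template is therefore the rank-1 factorization of the band x depth
    amplitude image, which averages the ripple over both axes.  Returns a
    (depth, band) amplitude array to be scaled by the iterated amplitude
    factor S and subtracted.
    """
    from .stft import stft_alines  # local import to avoid a cycle

    sda = stft_alines(background_fringe[None, :], wavelength_nm, windows,
                      background=background_fringe, dc_mode="background",
                      depth_px=depth_px)
    raw = sda.amplitude[:, :, 0].astype(float)
    # exclude the zero-delay artifact from the factorization
    body = raw[artifact_px:]
    u, sv, vt = np.linalg.svd(body, full_matrices=False)
    # the true depth factor is smooth (it decays over hundreds of pixels);
    # smoothing removes the single-realization speckle ripple of the
    # calibration fringe without distorting the profile
    from scipy.ndimage import gaussian_filter1d
    depth_factor = gaussian_filter1d(np.abs(u[:, 0]), 10.0, mode="nearest")
    rank1 = sv[0] * np.outer(depth_factor, np.abs(vt[0]))
    # |X| of one circular-Gaussian realization estimates sqrt(pi/4) of the
    # RMS envelope; rescale so the template matches the intensity-domain
    # (RMS) background it is subtracted from
    rank1 *= np.sqrt(4.0 / np.pi)
    out = np.zeros_like(raw)
    out[artifact_px:] = rank1
    out[:artifact_px] = raw[:artifact_px]
    return out
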