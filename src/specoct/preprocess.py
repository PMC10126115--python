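"""SDBG removal, axial registration, vessel segmentation and B-scan QC.

Registration aligns per-B-scan depth profiles by cross-correlation (parabolic
sub-pixel refinement) and removes residual per-band misalignment against a
reference band.  Vessel segmentation refines an annotated lateral span using
the vessel's attenuation shadow and emits nine central sub-segmentations
(central 36/40/42% of A-lines, each at -4/0/+4% lateral shift), which the
pipeline treats as separate B-scans.  Quality control drops outlier B-scans
by robust thresholds on in-vessel SNR and spectral smoothness at z_d.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d, shift as nd_shift
from scipy.signal import correlate

from .errors import InsufficientData, ValidationError, VesselRejected

MAX_VESSEL_DEPTH_UM = 700.0
SEGMENT_FRACTIONS = (0.36, 0.40, 0.42)
SEGMENT_SHIFTS = (-0.04, 0.0, 0.04)


def remove_sdbg(amplitude: np.ndarray, template: np.ndarray, s: float,
                noise_floor=None, domain: str = "intensity") -> np.ndarray:
    """Remove the scaled additive background (and optionally the noise floor).

    The background and shot noise are incoherent with the sample field, so
    under intensity (RMS) averaging they add in quadrature; the default
    removes them in the intensity domain,
    ``sqrt(max(amp^2 - (S B)^2 - n^2, 0))``.  ``domain="amplitude"`` applies
    the literal amplitude subtraction ``max(amp - S B, 0)`` instead.
    """
    amp = np.asarray(amplitude, dtype=float)
    tpl = np.asarray(template, dtype=float)
    if tpl.shape != amp.shape[: tpl.ndim] and tpl.shape != amp.shape:
        raise ValidationError(
            f"SDBG template shape {tpl.shape} does not match data {amp.shape}")
    if domain == "amplitude":
        if s == 0.0:
            return amp.copy()
        return np.maximum(amp - s * tpl, 0.0)
    if domain != "intensity":
        raise ValidationError(f"unknown SDBG removal domain {domain!r}")
    power = amp ** 2 - (s * tpl) ** 2
    if noise_floor is not None:
        power = power - np.asarray(noise_floor, dtype=float)[None, :] ** 2
    return np.sqrt(np.maximum(power, 0.0))


def _xcorr_shift(profile, reference, max_lag: int = 40):
    """Lag that best aligns ``profile`` to ``reference`` (sub-pixel).

    Returns (shift, peak_corr) where applying ``shift`` to ``profile`` aligns
    it with the reference; ``peak_corr`` is the normalized correlation peak.
    """
    p = np.asarray(profile, float) - np.mean(profile)
    r = np.asarray(reference, float) - np.mean(reference)
    denom = np.linalg.norm(p) * np.linalg.norm(r)
    if denom == 0:
        return 0.0, 0.0
    c = correlate(r, p, mode="full") / denom
    center = p.size - 1
    lo, hi = center - max_lag, center + max_lag + 1
    seg = c[lo:hi]
    i = int(np.argmax(seg))
    lag = i - max_lag
    # parabolic sub-pixel refinement; integer fallback at flat/edge peaks
    if 0 < i < seg.size - 1:
        y0, y1, y2 = seg[i - 1], seg[i], seg[i + 1]
        denom2 = (y0 - 2 * y1 + y2)
        if denom2 < -1e-12:
            lag = lag + 0.5 * (y0 - y2) / denom2
    return float(lag), float(seg[i])


def _subpixel_peak(profile, idx: int) -> float:
    """Parabolic sub-pixel refinement of a local maximum position."""
    if not 0 < idx < profile.size - 1:
        return float(idx)
    y0, y1, y2 = profile[idx - 1], profile[idx], profile[idx + 1]
    denom = y0 - 2 * y1 + y2
    if denom >= -1e-18:
        return float(idx)
    return float(idx + 0.5 * (y0 - y2) / denom)


def _peak_offset(reference, profile, around_px: int, half_width: int = 15) -> float:
    """Sub-pixel displacement of ``profile``'s peak from ``reference``'s,
    both located within a window around ``around_px``.

    Returns the shift to apply to ``profile`` so its peak aligns with the
    reference's (positive = profile peak is shallower than the reference's).
    """
    lo = max(around_px - half_width, 0)
    hi = min(around_px + half_width + 1, len(reference))
    r = np.asarray(reference, float)[lo:hi]
    p = np.asarray(profile, float)[lo:hi]
    pr = _subpixel_peak(r, int(np.argmax(r)))
    pp = _subpixel_peak(p, int(np.argmax(p)))
    return pr - pp


@dataclass
class RegisteredStack:
    """Axially co-registered per-B-scan band profiles."""

    profiles: np.ndarray            # (n_bscans, depth, band)
    bscan_shifts_px: np.ndarray     # shift applied per B-scan
    band_shifts_px: np.ndarray      # residual shift applied per band
    registered_ok: np.ndarray       # bool per B-scan (correlation above floor)


def register_stack(profiles, reference_band: int = 10,
                   corr_floor: float = 0.2, fiducial=None) -> RegisteredStack:
    """Register per-B-scan (depth x band) profiles axially.

    Per-B-scan shifts come from cross-correlating full-band (band-summed)
    intensity against the first B-scan.  Per-band residual shifts (from
    dispersion and chromatic aberration) are measured as the displacement of
    a bright fiducial reflection between each band and the reference band;
    ``fiducial=(lo, hi)`` restricts the fiducial search to a depth range
    *above* the vessel, because attenuation inside blood moves each band's
    apparent peak by a different amount — a spectral feature that must not
    be registered away.  Shifts are applied with cubic spline interpolation.
    """
    prof = np.asarray(profiles, dtype=float)
    if prof.ndim != 3 or prof.shape[0] < 2:
        raise ValidationError("need >= 2 B-scan profiles of shape (depth, band)")
    n_b = prof.shape[0]

    full = prof.sum(axis=2)  # (n_bscans, depth)
    ref = full[0]
    if fiducial is None:
        lo_f, hi_f = 0, ref.size
    else:
        lo_f = int(np.clip(fiducial[0], 0, ref.size - 2))
        hi_f = int(np.clip(fiducial[1], lo_f + 2, ref.size))
    fid_ref = ref[lo_f:hi_f]
    spike = int(np.argmax(fid_ref))
    # a sharp bright reflection (e.g. the inner surface) tracks rigid motion
    # far better under speckle than whole-profile correlation; fall back to
    # correlation when the fiducial region has no prominent feature
    prominence = float(fid_ref[spike]) / max(float(np.median(fid_ref)), 1e-12)
    use_spike = prominence > 2.0

    shifts = np.zeros(n_b)
    ok = np.ones(n_b, dtype=bool)
    for b in range(1, n_b):
        if use_spike:
            lag = _peak_offset(fid_ref, full[b, lo_f:hi_f], spike, half_width=12)
            shifts[b] = float(np.clip(lag, -12.0, 12.0))
        else:
            lag, peak = _xcorr_shift(full[b], ref)
            if peak < corr_floor:
                ok[b] = False
                lag = 0.0
            shifts[b] = lag
    out = prof.copy()
    for b in range(n_b):
        if shifts[b] != 0.0:
            out[b] = nd_shift(out[b], (shifts[b], 0.0), order=3, mode="nearest")

    mean_prof = out[ok].mean(axis=0)
    band_ref = mean_prof[lo_f:hi_f, reference_band]
    spike_b = int(np.argmax(band_ref))
    band_shifts = np.zeros(prof.shape[2])
    for k in range(prof.shape[2]):
        if use_spike:
            lag = _peak_offset(band_ref, mean_prof[lo_f:hi_f, k], spike_b,
                               half_width=10)
        else:
            lag, peak = _xcorr_shift(mean_prof[lo_f:hi_f, k], band_ref, max_lag=8)
            if peak < corr_floor:
                lag = 0.0
        band_shifts[k] = float(np.clip(lag, -5.0, 5.0))
    for k in range(prof.shape[2]):
        if band_shifts[k] != 0.0:
            out[:, :, k] = nd_shift(out[:, :, k], (0.0, band_shifts[k]),
                                    order=3, mode="nearest")

    return RegisteredStack(profiles=out, bscan_shifts_px=shifts,
                           band_shifts_px=band_shifts, registered_ok=ok)


@dataclass
class VesselROI:
    """Refined lateral vessel bounds plus the nine sub-segmentations."""

    a_line_left: int
    a_line_right: int               # inclusive
    center: float
    segmentations: list             # nine (left, right) inclusive intervals
    diameter_um: float
    anterior_depth_px: int
    anterior_depth_um: float
    shadow_contrast: float
    refined: bool = True


def segment_vessel(intensity, annotation, lateral_pixel_um: float,
                   axial_px_um: float, contrast_floor: float = 0.05,
                   min_depth_px: int = 20, col_offset: int = 0) -> VesselROI:
    """Refine a vessel annotation on a full-band (depth x a_line) image.

    The vessel's anterior depth is the peak of the in-vessel minus flanking
    depth profile (robust against bright common layers); the vessel center
    is the minimum of the depth-integrated intensity below the vessel (its
    attenuation shadow); the nine segmentations are the central 36/40/42% of
    A-lines at -4/0/+4% lateral shifts of the center.  Vessels whose
    anterior signal sits deeper than 700 um are rejected.

    ``col_offset`` is the absolute A-line index of the image's first column
    (the image may be an ROI crop); all reported bounds are absolute.
    """
    img = np.asarray(intensity, dtype=float)
    left, right = int(annotation.a_line_left), int(annotation.a_line_right)
    left = max(left, col_offset)
    right = min(right, col_offset + img.shape[1] - 1)
    width = right - left + 1
    if width < 4:
        raise VesselRejected("annotated vessel narrower than 4 A-lines")
    li, ri = left - col_offset, right - col_offset

    col_profile = gaussian_filter1d(img[:, li:ri + 1].mean(axis=1), 2.0)
    flank_cols = np.r_[0:li, ri + 1:img.shape[1]]
    if flank_cols.size >= 4:
        flank = gaussian_filter1d(img[:, flank_cols].mean(axis=1), 2.0)
        seek = col_profile - flank
    else:
        seek = col_profile
    anterior_px = min_depth_px + int(np.argmax(seek[min_depth_px:]))
    anterior_um = anterior_px * axial_px_um
    if anterior_um > MAX_VESSEL_DEPTH_UM:
        raise VesselRejected(
            f"vessel at {anterior_um:.0f} um exceeds the 700 um depth limit")

    diameter_um = width * lateral_pixel_um
    depth_px_diam = max(int(round(diameter_um / axial_px_um)), 4)
    lo = min(anterior_px + depth_px_diam, img.shape[0] - 8)
    hi = min(lo + int(150.0 / axial_px_um), img.shape[0])
    shadow = gaussian_filter1d(img[lo:hi, li:ri + 1].sum(axis=0), 2.0)
    contrast = float((shadow.max() - shadow.min()) / max(shadow.max(), 1e-12))
    if contrast >= contrast_floor:
        center = left + float(np.argmin(shadow))
        refined = True
    else:
        center = 0.5 * (left + right)
        refined = False

    segs = []
    for frac in SEGMENT_FRACTIONS:
        n = max(int(round(frac * width)), 2)
        for sh in SEGMENT_SHIFTS:
            c = center + sh * width
            s_left = int(round(c - n / 2.0))
            s_right = s_left + n - 1
            s_left = max(s_left, left)
            s_right = min(s_right, right)
            segs.append((s_left, s_right))

    return VesselROI(a_line_left=left, a_line_right=right, center=center,
                     segmentations=segs, diameter_um=diameter_um,
                     anterior_depth_px=anterior_px, anterior_depth_um=anterior_um,
                     shadow_contrast=contrast, refined=refined)


@dataclass
class QCReport:
    snr_db: np.ndarray
    spectral_mse: np.ndarray
    kept: np.ndarray
    reasons: list = field(default_factory=list)


def _robust_bounds(x, n_sd: float):
    med = np.median(x)
    sd = 1.4826 * np.median(np.abs(x - med))
    return med, max(sd, 1e-12)


def qc_filter(profiles, zd_px: int, n_sd: float = 2.0,
              min_keep: int = 3, signal_px: int = 20):
    """Drop outlier B-scan profiles and average the survivors.

    Metrics per profile: in-vessel SNR in dB (mean full-band amplitude over
    [z_d, z_d+signal_px] against the deep noise floor) and the MSE of the
    0-1-normalized band spectrum at z_d against the stack median spectrum.
    Profiles beyond ``n_sd`` robust SDs are dropped (low side for SNR, high
    side for MSE).  Raises if fewer than ``min_keep`` survive.
    Returns ``(mean_profile, QCReport)``.
    """
    prof = np.asarray(profiles, dtype=float)
    n, depth, n_bands = prof.shape
    full = prof.sum(axis=2)
    noise_lo = int(depth * 0.85)
    sig = full[:, zd_px:min(zd_px + signal_px, depth)].mean(axis=1)
    floor = np.median(full[:, noise_lo:], axis=1)
    snr_db = 20.0 * np.log10(np.maximum(sig, 1e-12) / np.maximum(floor, 1e-12))

    spec = prof[:, zd_px, :]
    rng_ = spec.max(axis=1) - spec.min(axis=1)
    spec01 = (spec - spec.min(axis=1, keepdims=True)) / \
        np.maximum(rng_, 1e-12)[:, None]
    med_spec = np.median(spec01, axis=0)
    mse = np.mean((spec01 - med_spec[None, :]) ** 2, axis=1)

    snr_med, snr_sd = _robust_bounds(snr_db, n_sd)
    mse_med, mse_sd = _robust_bounds(mse, n_sd)
    kept = (snr_db >= snr_med - n_sd * snr_sd) & (mse <= mse_med + n_sd * mse_sd)

    reasons = []
    for i in range(n):
        if kept[i]:
            continue
        why = []
        if snr_db[i] < snr_med - n_sd * snr_sd:
            why.append("low_snr")
        if mse[i] > mse_med + n_sd * mse_sd:
            why.append("unstable_spectrum")
        reasons.append((i, "+".join(why)))

    if kept.sum() < min_keep:
        raise InsufficientData(
            f"only {int(kept.sum())} B-scan profiles survive QC (need {min_keep})")
    report = QCReport(snr_db=snr_db, spectral_mse=mse, kept=kept, reasons=reasons)
    # intensity-domain (RMS) average: for speckle, E[amp^2] tracks the
    # squared envelope, so the RMS is an unbiased envelope estimate
    return np.sqrt((prof[kept] ** 2).mean(axis=0)), report
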