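"""Background removal, registration, segmentation and quality control."""

import numpy as np
import pytest
from scipy.ndimage import shift as nd_shift

import specoct as sp
from specoct.errors import InsufficientData, ValidationError, VesselRejected
from specoct.preprocess import qc_filter, register_stack, remove_sdbg, segment_vessel


def test_remove_sdbg_identity_and_exact_zero():
    amp = np.abs(np.random.default_rng(0).normal(1.0, 0.1, (40, 21)))
    tpl = 0.3 * np.ones((40, 21))
    np.testing.assert_array_equal(remove_sdbg(amp, tpl, 0.0), amp)
    # input exactly equal to the scaled background -> all-zero output
    np.testing.assert_allclose(remove_sdbg(1.3 * tpl, tpl, 1.3), 0.0, atol=1e-12)
    np.testing.assert_allclose(
        remove_sdbg(1.3 * tpl, tpl, 1.3, domain="amplitude"), 0.0, atol=1e-12)


def test_remove_sdbg_never_negative_and_shape_checked():
    rng = np.random.default_rng(1)
    amp = np.abs(rng.normal(0.3, 0.2, (60, 21)))
    tpl = np.abs(rng.normal(0.3, 0.2, (60, 21)))
    for domain in ("intensity", "amplitude"):
        out = remove_sdbg(amp, tpl, 1.1, domain=domain)
        assert np.all(out >= 0)
    with pytest.raises(ValidationError):
        remove_sdbg(amp, tpl[:, :5], 1.0)


def test_remove_sdbg_quadrature_recovers_signal():
    # incoherent background adds in intensity; the intensity-domain removal
    # recovers the signal envelope where the amplitude-domain one cannot
    s = np.linspace(1.0, 0.1, 50)[:, None] * np.ones((1, 21))
    b = 0.2 * np.ones_like(s)
    measured = np.sqrt(s ** 2 + b ** 2)
    rec = remove_sdbg(measured, b, 1.0)
    np.testing.assert_allclose(rec, s, rtol=1e-10)


def test_residual_background_small_when_scale_matches(windows):
    """On phantoms with injected background (no shot noise), removal at the
    true scale strongly suppresses the background in signal-free depths; the
    residual reflects the single-realization calibration statistics."""
    spec = sp.PhantomSpec(vessel=sp.VesselSpec(so2_true=0.6, diameter_um=70.0),
                          n_bscans=16, n_alines=64, seed=8, noise_snr_db=None)
    scan, truth = sp.simulate_scan(spec)
    tpl = sp.sdbg_template_from_background(scan.background_fringe,
                                           scan.wavelength_nm, windows,
                                           depth_px=700)
    cubes = [sp.stft_alines(scan.fringes[b, :16, :], scan.wavelength_nm,
                            windows, background=scan.background_fringe,
                            depth_px=700).amplitude.astype(float) ** 2
             for b in range(16)]
    amp = np.sqrt(np.mean(cubes, axis=(0, 3)))
    # signal-free depths below the tissue: only the background lives there
    sl = slice(600, 660)
    before = amp[sl].mean()
    after = remove_sdbg(amp, tpl, truth.sdbg_scale_true)[sl].mean()
    assert after < 0.7 * before  # suppression limited by the single
    #                                 calibration realization's statistics


def _profile_stack(shifts, n_bands=21, depth=300, seed=0):
    rng = np.random.default_rng(seed)
    z = np.arange(depth)
    base = 5 * np.exp(-0.5 * ((z - 60) / 1.8) ** 2) + \
        np.exp(-0.5 * ((z - 170) / 35.0) ** 2)
    prof0 = base[:, None] * np.ones((1, n_bands))
    prof0 = prof0 * (1 + 0.02 * rng.standard_normal(prof0.shape))
    return np.asarray([nd_shift(prof0, (s, 0.0), order=3, mode="nearest")
                       for s in shifts])


def test_register_recovers_constructed_shift():
    stack = _profile_stack([0.0, 3.0])
    reg = register_stack(stack, fiducial=(20, 120))
    assert reg.bscan_shifts_px[1] == pytest.approx(-3.0, abs=0.1)
    np.testing.assert_allclose(reg.profiles[1][80:250], stack[0][80:250],
                               rtol=0.05, atol=0.02)


def test_register_identical_profiles_zero_shift():
    stack = _profile_stack([0.0, 0.0, 0.0])
    reg = register_stack(stack, fiducial=(20, 120))
    np.testing.assert_allclose(reg.bscan_shifts_px, 0.0, atol=1e-9)
    # per-band shifts see each band's independent fixture noise: sub-pixel
    np.testing.assert_allclose(reg.band_shifts_px, 0.0, atol=0.2)


def test_register_inverse_consistent():
    a = _profile_stack([0.0, 2.4])
    fwd = register_stack(a, fiducial=(20, 120)).bscan_shifts_px[1]
    bwd = register_stack(a[::-1], fiducial=(20, 120)).bscan_shifts_px[1]
    assert fwd + bwd == pytest.approx(0.0, abs=0.5)


def test_register_recovers_injected_motion_and_dispersion(noisy_phantom, windows):
    """On the default phantom, B-scan motion and per-band dispersion shifts
    are recovered within +-0.5 px of the injected values."""
    spec, scan, truth = noisy_phantom
    lo, hi = 20, spec.n_alines - 20
    cubes = [sp.stft_alines(scan.fringes[b, lo:hi, :], scan.wavelength_nm,
                            windows, background=scan.background_fringe,
                            depth_px=700).amplitude.astype(float)
             for b in range(spec.n_bscans)]
    profiles = np.asarray([np.sqrt((c ** 2).mean(axis=2)) for c in cubes])
    reg = register_stack(profiles, fiducial=(20, 130))
    exp_b = -(truth.bscan_jitter_px - truth.bscan_jitter_px[0])
    assert np.max(np.abs(reg.bscan_shifts_px - exp_b)) < 0.5
    exp_band = -(truth.band_shift_px - truth.band_shift_px[10])
    assert np.max(np.abs(reg.band_shifts_px - exp_band)) < 0.5


def _vessel_image(width=100, n_alines=200, depth=400, anterior=150):
    img = np.full((depth, n_alines), 0.2)
    img[60:62, :] = 3.0                     # bright surface
    left = (n_alines - width) // 2
    img[anterior:anterior + 3, left:left + width] = 1.5
    # attenuation shadow below the vessel, deepest at its center
    x = np.arange(n_alines)
    shadow = np.exp(-0.5 * ((x - (left + width / 2)) / (width / 3)) ** 2)
    img[anterior + 100:, :] *= (1 - 0.8 * shadow)[None, :]
    return img, left, width


def test_segmentation_fractions_and_shifts():
    img, left, width = _vessel_image()
    ann = sp.VesselAnnotation("V", left, left + width - 1)
    roi = segment_vessel(img, ann, lateral_pixel_um=1.0, axial_px_um=1.09)
    assert len(roi.segmentations) == 9
    widths = sorted({hi - lo + 1 for lo, hi in roi.segmentations})
    assert widths == [36, 40, 42]
    # the three 36% segmentations are displaced by 4% of the vessel width
    segs36 = sorted([s for s in roi.segmentations if s[1] - s[0] + 1 == 36])
    assert segs36[1][0] - segs36[0][0] == 4
    assert segs36[2][0] - segs36[1][0] == 4
    assert roi.diameter_um == pytest.approx(width, abs=1)
    assert abs(roi.center - (left + width / 2)) < 3
    assert roi.refined


def test_segmentation_falls_back_without_shadow():
    img, left, width = _vessel_image()
    img[250:, :] = 0.2  # erase the shadow
    ann = sp.VesselAnnotation("V", left, left + width - 1)
    roi = segment_vessel(img, ann, 1.0, 1.09)
    assert not roi.refined
    assert roi.center == pytest.approx(left + (width - 1) / 2, abs=1)


def test_deep_vessel_rejected():
    img, left, width = _vessel_image(anterior=380)
    img[60:62, :] = 0.2   # no bright shallow structure
    ann = sp.VesselAnnotation("V", left, left + width - 1)
    with pytest.raises(VesselRejected):
        segment_vessel(img, ann, 1.0, 2.0)  # 380 px * 2 um = 760 um > 700


def _qc_profiles(n=16, depth=300, seed=3, corrupt=None, noise=0.0):
    rng = np.random.default_rng(seed)
    z = np.arange(depth)
    base = np.exp(-(z - 100) * 0.03) * (z > 100) + 0.01
    prof = base[:, None] * np.ones((1, 21))
    stack = np.repeat(prof[None], n, axis=0)
    if noise:
        stack = stack * (1 + noise * rng.standard_normal(stack.shape))
    if corrupt is not None:
        stack[corrupt] = base[:, None] * (
            1 + 3 * max(noise, 0.2) * rng.standard_normal((depth, 21)))
    return np.abs(stack)


def test_qc_keeps_identical_profiles():
    stack = _qc_profiles(16)
    mean, report = qc_filter(stack, zd_px=100)
    assert report.kept.all()
    np.testing.assert_allclose(mean, stack[0], rtol=1e-12)


def test_qc_drops_exactly_the_corrupted_profile():
    # fifteen identical profiles plus one with tripled noise injected
    stack = _qc_profiles(16, corrupt=5)
    _, report = qc_filter(stack, zd_px=100)
    assert not report.kept[5]
    assert report.kept.sum() == 15


def test_qc_keeps_most_profiles_at_default_noise(noisy_phantom):
    spec, scan, truth = noisy_phantom
    case = sp.build_vessel_case(scan, sp.default_annotation(spec, truth))
    assert case.n_profiles_kept >= 0.8 * 9 * spec.n_bscans


def test_qc_insufficient_survivors_raises():
    stack = _qc_profiles(3, corrupt=1)
    with pytest.raises(InsufficientData):
        qc_filter(stack, zd_px=100, min_keep=3)
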