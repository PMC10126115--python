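"""Blood coefficient table, band digitization and the attenuation model."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import specoct as sp
from specoct.blood import ReferenceSpectrumTable, digitize_reference
from specoct.errors import CoverageError, ValidationError

ISOSBESTIC_NOMINAL_NM = (548.0, 570.0, 586.0)


def _crossings(table):
    d = table.mu_a_hbo2 - table.mu_a_hb
    lam = table.wavelength_nm
    sel = (lam > 520) & (lam < 600)
    idx = np.nonzero(np.diff(np.sign(d[sel])))[0]
    lam_sel, d_sel = lam[sel], d[sel]
    out = []
    for i in idx:
        x0, x1 = lam_sel[i], lam_sel[i + 1]
        y0, y1 = d_sel[i], d_sel[i + 1]
        out.append(x0 - y0 * (x1 - x0) / (y1 - y0))
    return np.array(out)


def test_table_structure(table):
    for name in ("mu_a_hbo2", "mu_a_hb", "mu_s_hbo2", "mu_s_hb"):
        assert np.all(getattr(table, name) >= 0)
    assert table.wavelength_nm.min() <= 508
    assert table.wavelength_nm.max() >= 614
    # oxy double peak (542/577) and deoxy single peak (555), green range
    lam = table.wavelength_nm
    green = (lam >= 520) & (lam <= 600)
    pk_deoxy = lam[green][np.argmax(table.mu_a_hb[green])]
    assert abs(pk_deoxy - 555) < 4


def test_isosbestic_crossings_near_nominal(table):
    crossings = _crossings(table)
    for nominal in ISOSBESTIC_NOMINAL_NM:
        assert np.min(np.abs(crossings - nominal)) <= 2.0, nominal


def test_digitize_constant_spectrum_is_constant(windows):
    lam = np.arange(450.0, 651.0)
    c = 7.25
    t = ReferenceSpectrumTable(
        wavelength_nm=lam, mu_a_hbo2=np.full(lam.size, c),
        mu_a_hb=np.full(lam.size, c), mu_s_hbo2=np.full(lam.size, c),
        mu_s_hb=np.full(lam.size, c))
    out = digitize_reference(t, windows)
    for arr in (out.mu_a_hbo2_band, out.mu_a_hb_band):
        np.testing.assert_allclose(arr, c, rtol=1e-12)


def test_digitize_linear_in_k_hits_weight_centroid(windows):
    # a spectrum linear in k reduces to the weight centroid exactly; the
    # oracle is dense quadrature with the same normalized weights
    lam = np.arange(450.0, 651.0, 0.5)
    k = 2 * np.pi / lam
    a, b = 3.0, 4000.0
    vals = a + b * k
    t = ReferenceSpectrumTable(wavelength_nm=lam, mu_a_hbo2=vals,
                               mu_a_hb=vals, mu_s_hbo2=vals, mu_s_hb=vals)
    out = digitize_reference(t, windows)
    w2 = windows.weights ** 2
    w2 /= w2.sum(axis=1, keepdims=True)
    oracle = w2 @ (a + b * windows.k_grid)
    np.testing.assert_allclose(out.mu_a_hbo2_band, oracle, rtol=1e-3)


def test_band_grid_shape_and_span(spectra):
    assert spectra.n_bands == 21
    assert spectra.band_centers_nm[0] == pytest.approx(528.0, abs=0.01)
    assert spectra.band_centers_nm[-1] == pytest.approx(588.0, abs=0.01)
    for arr in (spectra.mu_a_hbo2_band, spectra.mu_a_hb_band,
                spectra.mu_s_hbo2_band, spectra.mu_s_hb_band):
        assert arr.shape == (21,)


def test_band_values_within_source_range(table, windows, spectra):
    lam = table.wavelength_nm
    sel = (lam >= 508) & (lam <= 614)
    assert spectra.mu_a_hbo2_band.min() >= table.mu_a_hbo2[sel].min() - 1e-9
    assert spectra.mu_a_hbo2_band.max() <= table.mu_a_hbo2[sel].max() + 1e-9


@settings(max_examples=20, deadline=None, derandomize=True)
@given(scale=st.floats(min_value=0.01, max_value=50.0))
def test_digitize_commutes_with_positive_scaling(scale):
    windows = sp.build_windows(np.linspace(508, 614, 2048))
    lam = np.arange(500.0, 625.0)
    base = 5.0 + np.sin(lam / 7.0) ** 2
    def make(v):
        return ReferenceSpectrumTable(wavelength_nm=lam, mu_a_hbo2=v,
                                      mu_a_hb=v, mu_s_hbo2=v, mu_s_hb=v)
    a = digitize_reference(make(base), windows).mu_a_hbo2_band
    b = digitize_reference(make(scale * base), windows).mu_a_hbo2_band
    np.testing.assert_allclose(b, scale * a, rtol=1e-10)


def test_table_not_covering_windows_raises(windows):
    lam = np.arange(530.0, 580.0)
    t_kwargs = dict(wavelength_nm=lam, mu_a_hbo2=np.ones(lam.size),
                    mu_a_hb=np.ones(lam.size), mu_s_hbo2=np.ones(lam.size),
                    mu_s_hb=np.ones(lam.size))
    with pytest.raises(CoverageError):
        ReferenceSpectrumTable(**t_kwargs)


def test_attenuation_linearity_and_domain(spectra):
    a1 = sp.blood_attenuation(spectra, 1.0, 0.0, 0.0)
    np.testing.assert_allclose(a1, spectra.mu_a_hbo2_band, rtol=1e-12)
    np.testing.assert_allclose(sp.blood_attenuation(spectra, 0.0, 0.0, 0.07), 0.0)
    # linear in concentrations and in SSF
    mix = sp.blood_attenuation(spectra, 0.3, 0.7, 0.05)
    parts = (0.3 * sp.blood_attenuation(spectra, 1, 0, 0.05)
             + 0.7 * sp.blood_attenuation(spectra, 0, 1, 0.05))
    np.testing.assert_allclose(mix, parts, rtol=1e-12)
    s_lin = (sp.blood_attenuation(spectra, 1, 1, 0.08)
             - sp.blood_attenuation(spectra, 1, 1, 0.0))
    np.testing.assert_allclose(
        s_lin, 0.08 * (spectra.mu_s_hbo2_band + spectra.mu_s_hb_band), rtol=1e-12)
    with pytest.raises(ValidationError):
        sp.blood_attenuation(spectra, -0.1, 0.5, 0.05)


def test_isosbestic_band_split_independence(spectra):
    """At bands centered on the interior isosbestic crossings, attenuation
    with SSF = 0 and fixed total hemoglobin is independent of the oxy/deoxy
    split to within the band-averaging error."""
    for nominal in (548.0, 570.0):
        band = int(np.argmin(np.abs(spectra.band_centers_nm - nominal)))
        vals = [sp.blood_attenuation(spectra, f, 1.0 - f, 0.0)[band]
                for f in (0.0, 0.25, 0.5, 0.75, 1.0)]
        spread = (max(vals) - min(vals)) / np.mean(vals)
        assert spread < 0.02, (nominal, spread)


def test_so2_ratio_stays_in_unit_interval(spectra):
    for c1, c2 in ((0.0, 1.0), (0.5, 0.5), (2.3, 0.1)):
        mu = sp.blood_attenuation(spectra, c1, c2, 0.06)
        assert np.all(mu >= 0)
        so2 = c1 / (c1 + c2)
        assert 0.0 <= so2 <= 1.0
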