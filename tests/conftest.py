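"""Shared fixtures: window bank, blood spectra, and small phantoms.

Session-scoped fixtures hold the expensive objects (simulated scans) so the
suite stays fast; phantoms are generated in memory, never stored on disk.
"""

import numpy as np
import pytest

import specoct as sp


@pytest.fixture(scope="session")
def wavelength():
    return np.linspace(508.0, 614.0, 2048)


@pytest.fixture(scope="session")
def windows(wavelength):
    return sp.build_windows(wavelength)


@pytest.fixture(scope="session")
def table():
    return sp.load_reference_table()


@pytest.fixture(scope="session")
def spectra(table, windows):
    return sp.digitize_reference(table, windows)


@pytest.fixture(scope="session")
def bank(table, windows):
    from specoct.blood import RegressorBank
    return RegressorBank.from_table(table, windows)


@pytest.fixture(scope="session")
def clean_phantom():
    """Speckle-free, noiseless, contaminant-free phantom (sO2 = 0.6)."""
    spec = sp.PhantomSpec(vessel=sp.VesselSpec(so2_true=0.6),
                          n_bscans=16, n_alines=192, seed=5).clean()
    scan, truth = sp.simulate_scan(spec)
    return spec, scan, truth


@pytest.fixture(scope="session")
def noisy_phantom():
    """Default-conditions phantom: speckle, shot noise, contaminants."""
    spec = sp.PhantomSpec(vessel=sp.VesselSpec(so2_true=0.6),
                          n_bscans=16, n_alines=192, seed=2)
    scan, truth = sp.simulate_scan(spec)
    return spec, scan, truth


@pytest.fixture(scope="session")
def clean_case(clean_phantom):
    """Assembled vessel case for the clean phantom."""
    from specoct.blood import RegressorBank
    spec, scan, truth = clean_phantom
    windows = sp.build_windows(scan.wavelength_nm)
    bank = RegressorBank.from_table(sp.load_reference_table(), windows)
    cfg = sp.PipelineConfig(qc_n_sd=float("inf"))
    case = sp.build_vessel_case(scan, sp.default_annotation(spec, truth),
                                cfg, windows=windows, regressor_bank=bank)
    return case, truth
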