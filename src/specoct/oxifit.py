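"""Non-negative least-squares oximetry fit of a depth-averaged band spectrum.

The measured spectrum (natural-log, normalized at z_d and depth-averaged) is
modeled as

    S(lambda) = LCA_avg(lambda)
                - [C_HbO2 (mu_a_HbO2 + SSF mu_s_HbO2)
                 + C_Hb   (mu_a_Hb   + SSF mu_s_Hb)] * L + b,

with L the window pathlength (z0 + dz/2, in mm), C_HbO2, C_Hb >= 0 the
effective (concentration x pathlength) regression weights, and b a free
intercept absorbing the constant offset of the normalized spectrum.  Oxygen
saturation is the ratio sO2 = C_HbO2 / (C_HbO2 + C_Hb), constrained to
[0, 1] by the non-negativity of the regression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import lsq_linear

from .blood import BloodSpectra
from .errors import ValidationError

SSF_MIN = 0.02
SSF_MAX = 0.10


def build_design(spectra: BloodSpectra, ssf: float,
                 pathlength_mm: float) -> np.ndarray:
    """Design matrix: [-(mu_a+SSF mu_s)_oxy * L, -(...)_deoxy * L, 1]."""
    if not SSF_MIN <= ssf <= SSF_MAX:
        raise ValidationError(f"SSF must lie in [{SSF_MIN}, {SSF_MAX}]")
    if not pathlength_mm > 0:
        raise ValidationError("pathlength must be positive")
    reg_oxy = -(spectra.mu_a_hbo2_band + ssf * spectra.mu_s_hbo2_band) * pathlength_mm
    reg_deoxy = -(spectra.mu_a_hb_band + ssf * spectra.mu_s_hb_band) * pathlength_mm
    return np.column_stack([reg_oxy, reg_deoxy, np.ones(spectra.n_bands)])


@dataclass
class FitResult:
    c_hbo2: float
    c_hb: float
    intercept: float
    so2_fraction: float          # NaN when both weights are zero
    r_squared: float
    ssf_used: float
    lca_shift_um: float
    residuals: np.ndarray
    valid: bool = True


def fit_so2(measured, spectra: BloodSpectra, ssf: float, pathlength_mm: float,
            lca_avg=None, lca_shift_um: float = 0.0, regressor_bank=None,
            tilt_depth_mm: float = None, n_refine: int = 3) -> FitResult:
    """Fit the measured 21-band spectrum; returns sO2, R^2 and diagnostics.

    ``lca_avg`` (per-band, precomputed for the chosen window and candidate
    focal shift) is subtracted as a known offset before the regression.
    R^2 compares the full model prediction (including the LCA offset) with
    the measured spectrum; it may be negative for pathological fits.

    When a ``regressor_bank`` (RegressorBank) and ``tilt_depth_mm`` are
    given, the regressors are re-digitized with attenuation-reweighted
    windows at the fitted mixture (in-band spectral reshaping) and the
    non-negative regression is repeated ``n_refine`` times to
    self-consistency; ``spectra`` then only seeds the first pass.
    """
    if regressor_bank is not None and tilt_depth_mm is not None:
        fit = _fit_once(measured, spectra, ssf, pathlength_mm,
                        lca_avg, lca_shift_um)
        for _ in range(max(n_refine, 0)):
            if not np.isfinite(fit.so2_fraction):
                break
            tilted = regressor_bank.tilted(fit.so2_fraction, ssf, tilt_depth_mm)
            fit = _fit_once(measured, tilted, ssf, pathlength_mm,
                            lca_avg, lca_shift_um)
        return fit
    return _fit_once(measured, spectra, ssf, pathlength_mm, lca_avg, lca_shift_um)


def _fit_once(measured, spectra: BloodSpectra, ssf: float, pathlength_mm: float,
              lca_avg=None, lca_shift_um: float = 0.0) -> FitResult:
    y_meas = np.asarray(measured, dtype=float)
    if y_meas.ndim != 1 or y_meas.size != spectra.n_bands:
        raise ValidationError("measured spectrum must have one value per band")
    if not np.all(np.isfinite(y_meas)):
        raise ValidationError("measured spectrum contains non-finite values")
    offset = np.zeros_like(y_meas) if lca_avg is None else np.asarray(lca_avg, float)

    design = build_design(spectra, ssf, pathlength_mm)
    if not np.any(design[:, :2]):
        raise ValidationError("singular design: attenuation regressors are zero")
    y = y_meas - offset
    sol = lsq_linear(design, y, bounds=([0.0, 0.0, -np.inf],
                                        [np.inf, np.inf, np.inf]),
                     method="bvls")
    c1, c2, b = sol.x
    y_pred = design @ sol.x + offset
    resid = y_meas - y_pred
    ss_tot = float(np.sum((y_meas - y_meas.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else np.nan

    total = c1 + c2
    so2 = c1 / total if total > 0 else np.nan
    return FitResult(c_hbo2=float(c1), c_hb=float(c2), intercept=float(b),
                     so2_fraction=float(so2), r_squared=float(r2),
                     ssf_used=float(ssf), lca_shift_um=float(lca_shift_um),
                     residuals=resid, valid=bool(total > 0 and np.isfinite(r2)))
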