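"""Adaptive parameter iteration, iteration filtering and result aggregation.

The contaminant-removal steps depend on three parameters that cannot be
known exactly for a given vessel: the scattering scaling factor SSF, the
decay-onset depth z_d, and the background amplitude scale S.  The adaptive
controller re-runs normalization, window selection and the fit over a small
grid of all three (iterating the LCA focal shift inside the fit), filters
the resulting sO2/R^2 cube, and reports the surviving cell holding the
median sO2 — together with its R^2 and SSF.  A non-adaptive single-pass
baseline (the fixed-attenuation method) is provided for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .blood import BloodSpectra
from .contaminants import ContaminantModel, lca_avg
from .depth import normalize_log, stability_matrix, depth_average
from .errors import NormalizationError, ValidationError, VesselRejected
from .oxifit import fit_so2
from .preprocess import VesselROI, remove_sdbg


@dataclass(frozen=True)
class IterationGrid:
    """Parameter grid for the adaptive iteration."""
    ssf_values: tuple = tuple(np.round(np.arange(0.02, 0.101, 0.01), 3))
    zd_offsets_px: tuple = (-2, -1, 0, 1, 2)
    s_values: tuple = (0.8, 0.9, 1.0, 1.1, 1.2)
    lca_shifts_um: tuple = (-100.0, -50.0, 0.0, 50.0, 100.0)

    def __post_init__(self):
        if min(self.ssf_values) < 0.02 or max(self.ssf_values) > 0.10:
            raise ValidationError("SSF grid outside [0.02, 0.10]")
        if max(abs(s) for s in self.lca_shifts_um) > 100.0:
            raise ValidationError("LCA shift grid outside +-100 um")


@dataclass(frozen=True)
class FilterRules:
    """Step-11 style filtering of the iteration cube."""
    r2_keep_quantile: float = 0.5    # keep the top half by R^2 ...
    r2_floor: float = 0.5            # ... but never below this R^2
    pinned_interior_frac: float = 0.2  # drop sO2 pinned at 0/1 if interior cells
    #                                    exceed this fraction


@dataclass
class VesselCase:
    """Everything the controller needs for one vessel."""
    mean_amplitude: np.ndarray       # (depth, band) QC-averaged, SDBG kept in
    all_mean_amplitude: np.ndarray   # (depth, band) average over all profiles
    sdbg_template: np.ndarray        # (depth, band)
    zd_base_px: int
    axial_px_um: float
    band_centers_nm: np.ndarray
    contaminants: ContaminantModel
    roi: VesselROI = None
    n_profiles_kept: int = 0
    qc_report: object = None
    vessel_id: str = "V?"
    zt_est_px: int = None            # estimated blood onset (for reshaping depth)
    regressor_bank: object = None    # RegressorBank for tilt-refined fits
    noise_floor_band: np.ndarray = None  # per-band noise-floor amplitude


@dataclass
class OximetryResult:
    so2_fraction: float
    r_squared: float
    ssf: float
    window_z0_px: int
    window_dz_px: int
    zd_px: int
    s_scale: float
    lca_shift_um: float
    method_tag: str
    viable: bool
    reason: str = ""
    cube_so2: np.ndarray = None      # (ssf, zd, S)
    cube_r2: np.ndarray = None
    cube_mask: np.ndarray = None
    diagnostics: dict = field(default_factory=dict)


def _fit_cell(case: VesselCase, spectra: BloodSpectra, ssf: float,
              zd_px: int, s: float, lca_shifts, amplitude=None):
    """Steps 2-9 for one parameter cell; best fit over candidate LCA shifts."""
    amp = case.mean_amplitude if amplitude is None else amplitude
    corrected = remove_sdbg(amp, case.sdbg_template, s,
                            noise_floor=case.noise_floor_band)
    nl = normalize_log(corrected, zd_px, case.axial_px_um)
    ssm = stability_matrix(nl)
    z0, dz = ssm.best_window_px
    spectrum = depth_average(nl, z0, dz)
    pathlength_mm = (z0 + dz / 2.0) * case.axial_px_um * 1e-3

    # mean depth below the blood onset governing in-band spectral reshaping:
    # halfway between the normalization anchor and the window midpoint
    tilt_depth_mm = None
    if case.regressor_bank is not None and case.zt_est_px is not None:
        anchor_mm = max(zd_px - case.zt_est_px, 0) * case.axial_px_um * 1e-3
        tilt_depth_mm = anchor_mm + 0.5 * pathlength_mm

    best = None
    for shift in lca_shifts:
        offs = lca_avg(case.contaminants, case.band_centers_nm, zd_px,
                       z0, dz, case.axial_px_um, focal_shift_um=shift)
        fit = fit_so2(spectrum, spectra, ssf, pathlength_mm,
                      lca_avg=offs, lca_shift_um=shift,
                      regressor_bank=case.regressor_bank,
                      tilt_depth_mm=tilt_depth_mm)
        if best is None or (fit.valid and fit.r_squared > best.r_squared):
            best = fit
    return best, (z0, dz)


def filter_iterations(cube_so2, cube_r2, cube_valid,
                      rules: FilterRules = FilterRules()) -> np.ndarray:
    """Boolean mask of iteration cells kept for the median selection."""
    so2 = np.asarray(cube_so2, float)
    r2 = np.asarray(cube_r2, float)
    mask = np.asarray(cube_valid, bool) & np.isfinite(so2) & np.isfinite(r2)
    if not mask.any():
        return mask
    thr = max(float(np.quantile(r2[mask], rules.r2_keep_quantile)), rules.r2_floor)
    keep = mask & (r2 >= thr)
    if not keep.any():  # never drop everything on the R^2 rule alone
        keep = mask & (r2 >= np.max(r2[mask]))
    pinned = (so2 <= 0.0) | (so2 >= 1.0)
    interior_frac = float((keep & ~pinned).sum()) / max(int(keep.sum()), 1)
    if interior_frac > rules.pinned_interior_frac and (keep & ~pinned).any():
        keep &= ~pinned
    return keep


def _median_cell(cube_so2, cube_r2, mask):
    """Index of the surviving cell whose sO2 is the median (ties: higher R^2)."""
    idx = np.argwhere(mask)
    vals = cube_so2[mask]
    med = float(np.median(vals))
    dist = np.abs(vals - med)
    near = dist <= dist.min() + 1e-12
    cand = idx[near]
    r2s = cube_r2[mask][near]
    pick = cand[int(np.argmax(r2s))]
    return tuple(pick)


def run_adaptive(case: VesselCase, spectra: BloodSpectra,
                 grid: IterationGrid = IterationGrid(),
                 rules: FilterRules = FilterRules()) -> OximetryResult:
    """Iterate (SSF, z_d offset, S), filter, and report the median-sO2 cell."""
    n_ssf, n_zd, n_s = len(grid.ssf_values), len(grid.zd_offsets_px), len(grid.s_values)
    so2 = np.full((n_ssf, n_zd, n_s), np.nan)
    r2 = np.full_like(so2, np.nan)
    valid = np.zeros(so2.shape, dtype=bool)
    windows = {}
    fits = {}

    for j, dzd in enumerate(grid.zd_offsets_px):
        zd = case.zd_base_px + int(dzd)
        for kk, s in enumerate(grid.s_values):
            for i, ssf in enumerate(grid.ssf_values):
                try:
                    fit, win = _fit_cell(case, spectra, float(ssf), zd,
                                         float(s), grid.lca_shifts_um)
                except (NormalizationError, ValidationError):
                    continue
                so2[i, j, kk] = fit.so2_fraction
                r2[i, j, kk] = fit.r_squared
                valid[i, j, kk] = fit.valid
                windows[(i, j, kk)] = win
                fits[(i, j, kk)] = fit

    mask = filter_iterations(so2, r2, valid, rules)
    if not mask.any():
        return OximetryResult(
            so2_fraction=np.nan, r_squared=np.nan, ssf=np.nan,
            window_z0_px=-1, window_dz_px=-1, zd_px=case.zd_base_px,
            s_scale=np.nan, lca_shift_um=np.nan, method_tag="ADS",
            viable=False, reason="all iteration cells filtered out",
            cube_so2=so2, cube_r2=r2, cube_mask=mask)

    i, j, kk = _median_cell(so2, r2, mask)
    fit = fits[(i, j, kk)]
    z0, dz = windows[(i, j, kk)]
    return OximetryResult(
        so2_fraction=float(so2[i, j, kk]), r_squared=float(r2[i, j, kk]),
        ssf=float(grid.ssf_values[i]), window_z0_px=z0, window_dz_px=dz,
        zd_px=case.zd_base_px + int(grid.zd_offsets_px[j]),
        s_scale=float(grid.s_values[kk]), lca_shift_um=fit.lca_shift_um,
        method_tag="ADS", viable=True,
        cube_so2=so2, cube_r2=r2, cube_mask=mask,
        diagnostics={"n_cells_kept": int(mask.sum()),
                     "n_cells_total": int(valid.sum())})


def run_fixed(case: VesselCase, spectra: BloodSpectra, *, ssf: float = 0.06,
              s_scale: float = 1.0, zd_px: int = None,
              window_px: tuple = None) -> OximetryResult:
    """Non-adaptive single-pass baseline (fixed-attenuation method).

    Uses a crude fixed anchor (the brightest full-band pixel in the ROI
    plus 2 px unless ``zd_px`` is given), a fixed pre-defined window
    (z0 = 0, dz ~ 29 um), the nominal SSF, no QC averaging, no window
    optimization, no parameter iteration and no LCA candidates.
    """
    amp = case.all_mean_amplitude
    if zd_px is None:
        # fixed anchor rule: the segmented vessel's anterior signal plus one
        # axial resolution element (no adaptive decay detection)
        res_px = int(round(9.0 / case.axial_px_um))
        if case.roi is not None:
            zd_px = int(case.roi.anterior_depth_px) + res_px
        else:
            full = amp.sum(axis=1)
            limit = int(min(full.size, 700.0 / case.axial_px_um))
            zd_px = 20 + int(np.argmax(full[20:limit])) + res_px
    if window_px is None:
        dz = int(round(29.0 / case.axial_px_um))
        window_px = (0, dz)
    z0, dz = window_px

    try:
        corrected = remove_sdbg(amp, case.sdbg_template, s_scale,
                                noise_floor=case.noise_floor_band)
        nl = normalize_log(corrected, zd_px, case.axial_px_um)
        spectrum = depth_average(nl, z0, dz)
        pathlength_mm = (z0 + dz / 2.0) * case.axial_px_um * 1e-3
        tilt_depth_mm = None
        if case.regressor_bank is not None and case.zt_est_px is not None:
            anchor_mm = max(zd_px - case.zt_est_px, 0) * case.axial_px_um * 1e-3
            tilt_depth_mm = anchor_mm + 0.5 * pathlength_mm
        fit = fit_so2(spectrum, spectra, ssf, pathlength_mm, lca_avg=None,
                      regressor_bank=case.regressor_bank,
                      tilt_depth_mm=tilt_depth_mm)
        viable = fit.valid and np.isfinite(fit.so2_fraction) \
            and 0.0 <= fit.so2_fraction <= 1.0
    except (NormalizationError, ValidationError) as e:
        return OximetryResult(
            so2_fraction=np.nan, r_squared=np.nan, ssf=ssf,
            window_z0_px=z0, window_dz_px=dz, zd_px=zd_px, s_scale=s_scale,
            lca_shift_um=0.0, method_tag="FA", viable=False, reason=str(e))
    return OximetryResult(
        so2_fraction=fit.so2_fraction, r_squared=fit.r_squared, ssf=ssf,
        window_z0_px=z0, window_dz_px=dz, zd_px=zd_px, s_scale=s_scale,
        lca_shift_um=0.0, method_tag="FA", viable=viable)


def success_rate(results) -> float:
    """Percent of physiologically viable measurements (sO2 in [0,1], fit ok)."""
    results = list(results)
    if not results:
        return np.nan
    ok = sum(1 for r in results if r.viable
             and np.isfinite(r.so2_fraction) and 0.0 <= r.so2_fraction <= 1.0)
    return 100.0 * ok / len(results)


def aggregate_vessels(records, split_diameter_um: float = 100.0):
    """Summarize result records.

    Repeated vessels are de-duplicated by keeping the highest-R^2 record;
    group means +- SD are computed by vessel type and caliber (major/minor at
    the diameter split); per-vessel repeatability SD uses vessels with >= 2
    records.  Returns a dict of DataFrames: ``unique``, ``groups``,
    ``repeatability``.
    """
    from .container import results_frame
    df = results_frame(list(records))
    if df.empty:
        return {"unique": df, "groups": pd.DataFrame(), "repeatability": pd.DataFrame()}

    unique = (df.sort_values("r_squared", ascending=False)
                .groupby(["vessel_id", "method_tag"], as_index=False).first())
    unique["caliber"] = np.where(unique["diameter_um"] >= split_diameter_um,
                                 "major", "small")
    groups = (unique.groupby(["method_tag", "caliber"])
              .agg(n=("so2_fraction", "size"),
                   mean_so2=("so2_fraction", "mean"),
                   sd_so2=("so2_fraction", "std"),
                   mean_r2=("r_squared", "mean"))
              .reset_index())

    rep_rows = []
    for (vid, tag), g in df.groupby(["vessel_id", "method_tag"]):
        if len(g) >= 2:
            rep_rows.append({"vessel_id": vid, "method_tag": tag,
                             "n": len(g), "sd_so2": g["so2_fraction"].std(ddof=1)})
    rep = pd.DataFrame(rep_rows)
    return {"unique": unique, "groups": groups, "repeatability": rep}
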