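"""Ready-made 3 T and 7 T scenario presets.

The presets are *calibrated*: each fan class's angular T1 law is solved so
that the exact measurement operators of the analysis (4.5-degree binning
at the fan angles, two-anchor baseline, first-minus-last bin difference,
selection mean) reproduce the target statistics listed below on noise-free
data.  The targets are the reference statistics the phantom is designed
to reproduce; because the baseline operator shrinks a Gaussian peak
slightly, the injected ``peak_amp`` is a few percent larger than the
measured peak delta it produces.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq

from . import anisotropy
from .anisotropy import SelectionRule
from .dti import fa as fa_of_evals
from .phantom import AngularT1Law, ScenarioConfig, TissueClass, fan_angles
from .watson import cos2_moment

__all__ = [
    "WM_RULE",
    "SELECTION_RULES",
    "PEAK_ANGLE",
    "scenario_3t",
    "scenario_7t",
    "get_preset",
    "PRESETS",
]

# analysis selections (index windows); FA uses the fitted map, the others
# ground-truth maps
WM_RULE = SelectionRule("FA", 0.45, 0.9)
SELECTION_RULES = {
    "FA": SelectionRule("FA", 0.70, 0.90),
    "ODI": SelectionRule("ODI", 0.0, 0.20),
    "F1": SelectionRule("F1", 0.45, 0.80),
    "F2": SelectionRule("F2", 0.20, 0.50),
    "F3": SelectionRule("F3", 0.05, 0.45),
}
PEAK_ANGLE = {3.0: 54.0, 7.0: 40.0}

# selection-level calibration targets: (selection mean T1, peak delta at
# the field's peak angle, first-minus-last-bin delta), all ms.  The FA
# selection sees only the coherent high-FA fan; the ODI selection sees the
# high-FA and mid-FA low-dispersion fans in equal parts; the whole-WM FA
# 0.45-0.9 selection additionally sees the dispersed fan.
CALIBRATION = {
    3.0: {"fa_row": (817.6, 38.7, 0.0), "odi_row": (817.8, 59.4, 0.0), "wm_mean": 829.3},
    7.0: {"fa_row": (905.0, 22.4, 47.2), "odi_row": (907.1, 37.0, 75.6), "wm_mean": 917.8},
}
ACQUISITION = {
    3.0: {"bvals": (1500.0, 3000.0), "tis": (200.0, 300.0, 600.0, 900.0, 1200.0, 1500.0),
          "voxel_size": 1.5},
    7.0: {"bvals": (1000.0, 2000.0), "tis": (300.0, 600.0, 1000.0, 1500.0, 2000.0, 3000.0),
          "voxel_size": 1.05},
}
GM_T1 = {3.0: 1300.0, 7.0: 1900.0}


def _measured_statistics(values: np.ndarray, peak_angle: float):
    """Apply the analysis measurement operators to one idealised profile
    vector (one value per fan angle / angular bin)."""
    return np.array([
        float(np.mean(values)),
        anisotropy.delta_from_profile(values, peak_angle),
        anisotropy.d090_from_profile(values),
    ])


def solve_law(
    mean_t1: float,
    delta_peak: float,
    delta_090: float,
    theta_peak: float,
    sigma_peak: float = 12.0,
) -> AngularT1Law:
    """Invert the measurement operators for (t1_base, peak_amp, grad_amp).

    The three measured statistics are linear in the three law parameters,
    so a single 3x3 solve yields the law whose noise-free measurement
    equals the requested values exactly.
    """
    angles = fan_angles()
    basis = [
        np.ones_like(angles),
        np.exp(-((angles - theta_peak) ** 2) / (2.0 * sigma_peak ** 2)),
        1.0 - angles / 90.0,
    ]
    M = np.column_stack([_measured_statistics(b, theta_peak) for b in basis])
    base, amp, grad = np.linalg.solve(M, [mean_t1, delta_peak, delta_090])
    return AngularT1Law(
        t1_base=float(base),
        peak_amp=float(amp),
        theta_peak=theta_peak,
        sigma_peak=sigma_peak,
        grad_amp=float(grad),
    )


def dispersed_evals(lambda_par: float, lambda_perp: float, kappa: float) -> np.ndarray:
    """Eigenvalues of the Watson-averaged single-fibre tensor."""
    t = cos2_moment(kappa)
    delta = lambda_par - lambda_perp
    return np.array([
        lambda_perp + delta * t,
        lambda_perp + delta * 0.5 * (1.0 - t),
        lambda_perp + delta * 0.5 * (1.0 - t),
    ])


def solve_lambda_perp(lambda_par: float, kappa: float, fa_target: float) -> float:
    """Radial diffusivity giving a requested FA for a pure dispersed fibre.

    FA decreases monotonically in lambda_perp, so this is a bracketed
    root find; raises if the target exceeds the dispersion-limited maximum.
    """
    def gap(lp):
        return fa_of_evals(dispersed_evals(lambda_par, lp, kappa)) - fa_target

    lo = 1e-7
    if gap(lo) < 0:
        raise ValueError(
            f"FA {fa_target} unreachable at kappa={kappa} (dispersion-limited)"
        )
    return float(brentq(gap, lo, lambda_par * (1 - 1e-9), xtol=1e-12))


def _build_scenario(field: float, seed, n_subjects, grid_shape, n_dirs_per_shell,
                    n_b0, snr_b0, snr_ir, sigma_peak, subject_t1_sd,
                    subject_amp_cv, s0_slope, name) -> ScenarioConfig:
    cal = CALIBRATION[field]
    acq = ACQUISITION[field]
    peak = PEAK_ANGLE[field]

    fa_mean, fa_dp, fa_d090 = cal["fa_row"]
    odi_mean, odi_dp, odi_d090 = cal["odi_row"]
    # the ODI selection averages the coherent and mid fans equally
    mid_mean = 2.0 * odi_mean - fa_mean
    mid_dp = 2.0 * odi_dp - fa_dp
    mid_d090 = 2.0 * odi_d090 - fa_d090
    # the whole-WM mean averages all three fans equally
    disp_mean = 3.0 * cal["wm_mean"] - mid_mean - fa_mean

    kappa_coherent = 12.706204736174698  # ODI = 0.05 exactly
    classes = [
        TissueClass(
            name="wm_mid_fan",
            kappa=kappa_coherent,
            lambda_par=1.7e-3,
            lambda_perp=solve_lambda_perp(1.7e-3, kappa_coherent, 0.60),
            t1_law=solve_law(mid_mean, mid_dp, mid_d090, peak, sigma_peak),
            fan=True,
        ),
        TissueClass(
            name="wm_coherent_fan",
            kappa=kappa_coherent,
            lambda_par=1.7e-3,
            lambda_perp=solve_lambda_perp(1.7e-3, kappa_coherent, 0.725),
            t1_law=solve_law(fa_mean, fa_dp, fa_d090, peak, sigma_peak),
            fan=True,
        ),
        TissueClass(
            name="wm_dispersed_fan",
            kappa=3.0,
            lambda_par=1.7e-3,
            lambda_perp=solve_lambda_perp(1.7e-3, 3.0, 0.52),
            t1_law=AngularT1Law(t1_base=disp_mean, theta_peak=peak, sigma_peak=sigma_peak),
            fan=True,
        ),
        TissueClass(
            name="wm_crossing",
            fibre_axes=((0.0, 0.0, 1.0), (1.0, 0.0, 0.0)),
            volume_fractions=(0.45, 0.35, 0.0),
            kappa=8.0,
            lambda_par=1.7e-3,
            lambda_perp=0.2e-3,
            d_iso=0.9e-3,
            t1_law=AngularT1Law(t1_base=cal["wm_mean"], theta_peak=peak, sigma_peak=sigma_peak),
        ),
        TissueClass(
            name="gm",
            volume_fractions=(0.7, 0.0, 0.0),
            kappa=0.5,
            lambda_par=1.0e-3,
            lambda_perp=0.7e-3,
            d_iso=0.9e-3,
            t1_law=AngularT1Law(t1_base=GM_T1[field], theta_peak=peak, sigma_peak=sigma_peak),
            in_wm=False,
        ),
        TissueClass(name="background", background=True, in_wm=False, s0_base=0.0),
    ]
    return ScenarioConfig(
        field_strength=field,
        classes=classes,
        bvals=acq["bvals"],
        tis=acq["tis"],
        grid_shape=grid_shape,
        n_dirs_per_shell=n_dirs_per_shell,
        n_b0=n_b0,
        snr_b0=snr_b0,
        snr_ir=snr_ir,
        n_subjects=n_subjects,
        seed=seed,
        subject_t1_sd=subject_t1_sd,
        subject_amp_cv=subject_amp_cv,
        s0_slope=s0_slope,
        voxel_size=acq["voxel_size"],
        name=name,
    )


def scenario_3t(seed: int = 1, n_subjects: int = 11, grid_shape=(40, 40, 20),
                n_dirs_per_shell: int = 64, n_b0: int = 6, snr_b0: float = 40.0,
                snr_ir: float = 80.0, sigma_peak: float = 12.0,
                subject_t1_sd: float = 10.0, subject_amp_cv: float = 0.12,
                s0_slope: float = 0.0) -> ScenarioConfig:
    """Eleven-subject 3 T study preset (peak at 54 degrees, no 0-90 gradient)."""
    return _build_scenario(3.0, seed, n_subjects, grid_shape, n_dirs_per_shell,
                           n_b0, snr_b0, snr_ir, sigma_peak, subject_t1_sd,
                           subject_amp_cv, s0_slope, "scenario_3T")


def scenario_7t(seed: int = 1, n_subjects: int = 6, grid_shape=(40, 40, 20),
                n_dirs_per_shell: int = 64, n_b0: int = 6, snr_b0: float = 40.0,
                snr_ir: float = 80.0, sigma_peak: float = 12.0,
                subject_t1_sd: float = 10.0, subject_amp_cv: float = 0.12,
                s0_slope: float = 0.0) -> ScenarioConfig:
    """Six-subject 7 T study preset (peak at 40 degrees plus a 0-90 gradient)."""
    return _build_scenario(7.0, seed, n_subjects, grid_shape, n_dirs_per_shell,
                           n_b0, snr_b0, snr_ir, sigma_peak, subject_t1_sd,
                           subject_amp_cv, s0_slope, "scenario_7T")


PRESETS = {"scenario_3T": scenario_3t, "scenario_7T": scenario_7t}


def get_preset(name: str, **overrides) -> ScenarioConfig:
    try:
        factory = PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None
    return factory(**overrides)
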