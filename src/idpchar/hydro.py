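"""Hydrodynamic arithmetic and conformational-state classification.

Covers the quantities a SEC + analytical-ultracentrifugation study of a
candidate IDP produces:

* SEC calibration: gel-phase distribution coefficient
  ``Kav = (Ve - V0)/(Vt - V0)`` and the standard-protein power law
  ``log10(Rs) = -0.204 + 0.357 log10(MM[Da])`` (globular/native track),
* sphere volume and apparent density from a Stokes radius,
* state-specific ``Rs(MM)`` power laws (native, molten globule,
  pre-molten globule, unfolded, plus coil-like and PMG-like IDP tracks)
  and nearest-state classification in log space,
* ``Rg/Rs`` shape bands (sphere / oblate / prolate),
* frictional-ratio classification against interpolated reference tracks,
* Svedberg-relation derivations (friction coefficient, ``f/f0``, Rs)
  from a sedimentation coefficient.

Units are fixed package-wide: radii in Angstrom, volumes in Angstrom^3,
masses in Da or kDa as stated per argument, sedimentation coefficients in
Svedberg (1e-13 s), viscosity in cP, density in g/ml.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from . import constants as C

__all__ = [
    "SECCalibration",
    "StateClassification",
    "kav",
    "rs_native_from_mm",
    "calibrate_sec",
    "rs_from_elution",
    "sphere_volume",
    "apparent_density",
    "state_rs",
    "classify_state",
    "rg_rs_classify",
    "frictional_ratio_classify",
    "auc_derive",
    "s20w_standardize",
]


# --- SEC ----------------------------------------------------------------

def kav(ve: float, v0: float, vt: float) -> float:
    """Gel-phase distribution coefficient (Ve - V0) / (Vt - V0)."""
    if vt <= v0:
        raise ValueError("total volume must exceed void volume")
    k = (ve - v0) / (vt - v0)
    if not (v0 <= ve <= vt):
        warnings.warn(f"elution volume {ve} outside [{v0}, {vt}]; Kav={k:.3f}")
    return k


def rs_native_from_mm(mm_da: float) -> float:
    """Stokes radius (A) of a globular protein from its mass in daltons.

    Power law log10(Rs) = -0.204 + 0.357 log10(MM); the argument is in Da
    (the law reproduces the standard-protein radii only with dalton input).
    """
    if mm_da <= 0:
        raise ValueError("molecular mass must be positive")
    return C.rs_power_law(mm_da)


@dataclass(frozen=True)
class SECCalibration:
    """Least-squares line log10(Rs) = intercept + slope * Kav."""

    standards: tuple  # of (name, mm_da, rs_A, ve_ml)
    v0: float
    vt: float
    intercept: float
    slope: float
    r_squared: float
    residual_rms: float
    kav_range: tuple[float, float]


def calibrate_sec(
    standards: Sequence[tuple[str, float, float, float]],
    v0: float,
    vt: float,
) -> SECCalibration:
    """Fit log10(Rs) vs Kav for >= 3 standards (name, MM Da, Rs A, Ve ml)."""
    if len(standards) < 3:
        raise ValueError("need at least 3 calibration standards")
    if vt <= v0:
        raise ValueError("total volume must exceed void volume")
    ks = np.array([kav(ve, v0, vt) for (_, _, _, ve) in standards])
    logrs = np.log10([rs for (_, _, rs, _) in standards])
    slope, intercept = np.polyfit(ks, logrs, 1)
    pred = intercept + slope * ks
    resid = logrs - pred
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((logrs - logrs.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return SECCalibration(
        standards=tuple(tuple(s) for s in standards),
        v0=v0, vt=vt,
        intercept=float(intercept), slope=float(slope),
        r_squared=r2,
        residual_rms=float(np.sqrt(ss_res / len(standards))),
        kav_range=(float(ks.min()), float(ks.max())),
    )


def rs_from_elution(cal: SECCalibration, ve: float) -> float:
    """Stokes radius (A) of a sample from its elution volume."""
    k = kav(ve, cal.v0, cal.vt)
    lo, hi = cal.kav_range
    if not (lo <= k <= hi):
        warnings.warn(
            f"Kav {k:.3f} outside calibrated range [{lo:.3f}, {hi:.3f}]; "
            "extrapolating"
        )
    return 10.0 ** (cal.intercept + cal.slope * k)


# --- volume / density ---------------------------------------------------

def sphere_volume(rs: float) -> float:
    """Volume (A^3) of the equivalent sphere of radius ``rs`` (A)."""
    if rs <= 0:
        raise ValueError("radius must be positive")
    return 4.0 / 3.0 * math.pi * rs**3


def apparent_density(mm_kda: float, vs: float) -> float:
    """Apparent density (kDa/A^3) of mass ``mm_kda`` in volume ``vs`` (A^3)."""
    if vs <= 0:
        raise ValueError("volume must be positive")
    return mm_kda / vs


# --- conformational-state laws ------------------------------------------

@dataclass(frozen=True)
class StateClassification:
    predicted_rs: Mapping[str, float]  # state -> Rs (A)
    rs_exp: float
    verdict: str
    log_distance: float


def state_rs(mm_kda: float, state: str, config: Mapping | None = None) -> float:
    """Predicted Stokes radius (A) for a conformational state at mass MM (kDa)."""
    if mm_kda <= 0:
        raise ValueError("molecular mass must be positive")
    laws = (config["hydro"]["state_laws"] if config is not None else C.STATE_LAWS)
    if state not in laws:
        raise KeyError(f"no Rs(MM) coefficients for state {state!r}")
    a, b = laws[state]
    return C.rs_power_law(mm_kda * 1000.0, a, b)


def classify_state(
    mm_kda: float, rs_exp: float, config: Mapping | None = None
) -> StateClassification:
    """Nearest conformational state by |log10 Rs_exp - log10 Rs_state|."""
    if rs_exp <= 0:
        raise ValueError("experimental Rs must be positive")
    laws = (config["hydro"]["state_laws"] if config is not None else C.STATE_LAWS)
    predicted = {}
    for state in laws:
        try:
            predicted[state] = state_rs(mm_kda, state, config)
        except (KeyError, TypeError):
            warnings.warn(f"missing coefficients for state {state!r}; skipped")
    dists = {s: abs(math.log10(rs_exp) - math.log10(r)) for s, r in predicted.items()}
    verdict = min(dists, key=dists.get)
    return StateClassification(predicted, rs_exp, verdict, dists[verdict])


# --- shape classifiers --------------------------------------------------

def rg_rs_classify(rg: float, rs: float, config: Mapping | None = None) -> dict:
    """Shape verdict from the Rg/Rs ratio.

    0.778 (within tolerance) for a hard sphere, 0.875-0.987 oblate,
    1.36-2.24 prolate; anything between bands is indeterminate.
    """
    if rg <= 0 or rs <= 0:
        raise ValueError("Rg and Rs must be positive")
    if config is not None:
        bands = config["hydro"]["rg_rs"]
        sphere, tol = bands["sphere"], bands["sphere_tol"]
        oblate, prolate = tuple(bands["oblate"]), tuple(bands["prolate"])
    else:
        sphere, tol = C.RG_RS_SPHERE, C.RG_RS_SPHERE_TOL
        oblate, prolate = C.RG_RS_OBLATE, C.RG_RS_PROLATE
    ratio = rg / rs
    if abs(ratio - sphere) <= tol:
        verdict = "sphere"
    elif oblate[0] <= ratio <= oblate[1]:
        verdict = "oblate"
    elif prolate[0] <= ratio <= prolate[1]:
        verdict = "prolate"
    else:
        verdict = "indeterminate"
    return {"ratio": ratio, "verdict": verdict}


def _track_ff0(track: Sequence[Sequence[float]], mm_kda: float) -> float:
    """Log-linear interpolation of an f/f0 reference track in MM."""
    (m1, f1), (m2, f2) = track
    t = (math.log10(mm_kda) - math.log10(m1)) / (math.log10(m2) - math.log10(m1))
    return f1 + t * (f2 - f1)


def frictional_ratio_classify(
    f_over_f0: float, mm_kda: float, config: Mapping | None = None
) -> dict:
    """Classify f/f0 against globular / PMG-like / coil-like IDP tracks.

    The reference tracks interpolate the published anchor values
    log-linearly in MM; the operational "elongated if f/f0 > 1.8" rule is
    exposed as a separate flag.
    """
    if f_over_f0 < 1.0:
        raise ValueError("f/f0 < 1 is unphysical (sphere is the friction minimum)")
    if config is not None:
        tracks = config["hydro"]["ff0_tracks"]
        threshold = config["hydro"]["ff0_elongated_threshold"]
    else:
        tracks = C.FF0_TRACKS
        threshold = C.FF0_ELONGATED_THRESHOLD
    expected = {name: _track_ff0(track, mm_kda) for name, track in tracks.items()}
    dists = {name: abs(f_over_f0 - v) for name, v in expected.items()}
    verdict = min(dists, key=dists.get)
    return {
        "verdict": verdict,
        "expected": expected,
        "elongated": f_over_f0 > threshold,
    }


# --- AUC (Svedberg relations) -------------------------------------------

def auc_derive(
    s_svedberg: float,
    mm_kda: float,
    vbar_ml_g: float,
    rho_g_ml: float,
    eta_cp: float,
) -> dict:
    """Friction coefficient, f/f0, and Stokes radius from a sedimentation
    coefficient via the Svedberg relation.

    f  = MM (1 - vbar rho) / (N_A s)          [g/s, CGS]
    f0 = 6 pi eta (3 MM vbar / (4 pi N_A))^(1/3)
    Rs = f / (6 pi eta)

    Unit handling: MM kDa -> g/mol (*1000); s Svedberg -> s (*1e-13);
    eta cP -> poise (*0.01); vbar ml/g and rho g/ml are already CGS.
    Radius is returned in Angstrom (cm * 1e8).
    """
    for name, val in [("s", s_svedberg), ("MM", mm_kda), ("vbar", vbar_ml_g),
                      ("rho", rho_g_ml), ("eta", eta_cp)]:
        if val <= 0:
            raise ValueError(f"{name} must be positive")
    buoyancy = 1.0 - vbar_ml_g * rho_g_ml
    if buoyancy <= 0:
        raise ValueError("buoyancy term 1 - vbar*rho <= 0 (floating particle)")
    mm_g_mol = mm_kda * 1000.0
    s_sec = s_svedberg * C.SVEDBERG
    eta_poise = eta_cp * 0.01
    f = mm_g_mol * buoyancy / (C.AVOGADRO * s_sec)
    f0 = 6.0 * math.pi * eta_poise * (
        3.0 * mm_g_mol * vbar_ml_g / (4.0 * math.pi * C.AVOGADRO)
    ) ** (1.0 / 3.0)
    rs_cm = f / (6.0 * math.pi * eta_poise)
    return {
        "f": f,
        "f0": f0,
        "f_over_f0": f / f0,
        "rs": rs_cm * 1e8,
    }


def s20w_standardize(
    s_svedberg: float,
    eta_buffer_cp: float,
    rho_buffer_g_ml: float,
    vbar_ml_g: float,
    eta_water_cp: float = C.WATER_VISCOSITY_20C,
    rho_water_g_ml: float = C.WATER_DENSITY_20C,
) -> float:
    """Standardize s to water at 20 degC (viscosity/buoyancy correction)."""
    denom = 1.0 - vbar_ml_g * rho_buffer_g_ml
    if denom <= 0:
        raise ValueError("buoyancy term 1 - vbar*rho <= 0 in buffer")
    return s_svedberg * (eta_buffer_cp / eta_water_cp) * (
        (1.0 - vbar_ml_g * rho_water_g_ml) / denom
    )
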