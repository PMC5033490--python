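"""Synthetic-data generators and the fixture registry.

Every analysis stage in the package can be exercised without downloads:
the generators here produce (data, truth) pairs with the statistical
structure the analyses assume -- Debye/sphere scattering with
beamline-shaped noise, convex mixtures of CD basis bands, log-linear SEC
calibration behaviour, and sequences with controllable order/disorder
composition bias.  ``FIXTURES`` collects the experimental constants the
analyses are validated against, each with a provenance location string.
"""

from __future__ import annotations

import math
import types
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from . import constants as C
from .cdspec import CDSpectrum
from .ensemble import generate_pool
from .hydro import SECCalibration, rs_native_from_mm
from .saxs import SAXSCurve
from .seqdis import SequenceRecord

__all__ = [
    "SyntheticConfig",
    "FIXTURES",
    "synth_saxs",
    "synth_cd",
    "synth_sec",
    "synth_sequence",
    "reference_cd_basis",
    "debye_function",
    "sphere_intensity",
]


# --- fixture registry ---------------------------------------------------

@dataclass(frozen=True)
class Fixture:
    value: object
    units: str
    location: str


FIXTURES = types.MappingProxyType({
    # SEC characterization block for the MetC reference construct
    "metc_mm_kda": Fixture(23.40, "kDa", "published SEC table: theoretical MM"),
    "metc_mm_da": Fixture(23396.0, "Da", "sequence-derived (ProtParam) MM"),
    "metc_mm_esi_da": Fixture(23394.0, "Da", "ESI-MS measured MM"),
    "metc_rs_theor": Fixture(22.7, "A", "published SEC table: Rs if globular"),
    "metc_rs_sec": Fixture(36.0, "A", "published SEC table: measured Rs, +/- 2.0"),
    "metc_vs_theor": Fixture(49.0e3, "A^3", "published SEC table: theor. volume"),
    "metc_vs_exp": Fixture(195.4e3, "A^3", "published SEC table: exp. volume"),
    "metc_density_theor": Fixture(0.48e-3, "kDa/A^3",
                                  "published SEC table: theor. density"),
    "metc_density_exp": Fixture(0.12e-3, "kDa/A^3",
                                "published SEC table: exp. density"),
    "metc_mm_sec_kda": Fixture(74.6, "kDa", "SEC-derived apparent MM, +/- 3.0"),
    "sec_standards": Fixture(
        (("apoferritin", 443000.0, 64.8),
         ("beta-amylase", 200000.0, 48.8),
         ("alcohol dehydrogenase", 150000.0, 44.0),
         ("albumin", 66000.0, 32.9),
         ("carbonic anhydrase", 29000.0, 24.5)),
        "(name, Da, A)", "published SEC calibration standards"),
    "sec_v0_ml": Fixture(8.18, "ml", "published column void volume"),
    "sec_vt_ml": Fixture(24.0, "ml", "published column total volume"),
    # sedimentation-velocity characterization (main peak, per concentration)
    "auc_rows": Fixture(
        ((0.08, 0.00457, 1.88, 1.392, 1.342, 88.9, 33.2, 19.0),
         (0.17, 0.00582, 1.84, 1.382, 1.332, 89.7, 32.0, 18.2),
         (0.30, 0.00663, 1.91, 1.383, 1.330, 90.5, 33.8, 19.2)),
        "(mg/ml, rmsd, f/f0, s20w S, s S, %, Rs A, MM kDa)",
        "published sedimentation-velocity table, main peak"),
    # state-law predictions at 23.4 kDa (config-validation fixtures)
    "metc_rs_pmg_idp": Fixture(33.6, "A",
                               "published PMG-like-state prediction, +/- 0.4"),
    "metc_rs_coil_idp": Fixture(38.7, "A",
                                "published U-like-state prediction, +/- 0.4"),
    # CD extrema; the source prints the exponent as 10^-3, physically 10^+3
    "metc_mre_200": Fixture(-13700.0, "deg cm^2 dmol^-1",
                            "published CD minimum near 200 nm (printed as "
                            "-13.7x10^-3; the exponent sign is a typographic "
                            "error, stored here as x10^3)"),
    "metc_mre_222": Fixture(-3500.0, "deg cm^2 dmol^-1",
                            "published CD shoulder near 222 nm "
                            "(printed -3.5x10^-3)"),
    "cd_conc_molar": Fixture(18e-6, "M", "published CD conditions: 18 uM"),
    "cd_pathlength_cm": Fixture(0.2, "cm", "published CD conditions: 2 mm cell"),
    # SAXS
    "metc_rg_guinier": Fixture(51.0, "A", "published Guinier Rg"),
    "metc_rg_pr": Fixture(56.0, "A", "published p(r)-moment Rg"),
    "metc_dmax": Fixture(220.0, "A", "published Dmax"),
    "metc_rg_rs_ratio": Fixture(1.62, "-", "published Rg/Rs ratio"),
    "flory_rg_n218": Fixture(42.22, "A", "published Flory-law Rg at N=218"),
    "metc_n_residues": Fixture(218, "count",
                               "Flory chain length reproducing the published "
                               "42.22 A (the construct 509-716 plus 9-residue "
                               "tag remnant gives 217)"),
    "metc_n_residues_construct": Fixture(217, "count",
                                         "MetC 509-716 plus GSGGIEGRH tag remnant"),
    "saxs_s_range": Fixture((0.0025, 0.441), "A^-1", "published measured s range"),
    # ensemble optimization
    "eom_pool_size": Fixture(10000, "count", "published random-conformer pool size"),
    "eom_chi2": Fixture(0.981, "-", "published sub-ensemble fit chi^2"),
    "eom_contribution_range": Fixture((3.0, 25.0), "%",
                                      "published per-model contribution range"),
})


# --- configuration ------------------------------------------------------

@dataclass
class SyntheticConfig:
    """Knobs for the generators; the defaults are the study conditions."""

    seed: int
    curve_model: str = "gaussian_chain"  # | sphere | ensemble_average
    rg: float = 51.0          # A; gaussian_chain target Rg
    radius: float = 30.0      # A; sphere radius
    i0: float = 1.0
    s_min: float = C.S_GRID_MIN
    s_max: float = C.S_GRID_MAX
    n_s: int = C.S_GRID_N
    rel_floor: float = 0.01       # relative-noise floor
    counting_scale: float = 0.0   # counting-noise scale (sqrt(I) term)
    noise: bool = True
    # ensemble_average model
    n_residues: int = 218
    n_conf: int = 100
    # CD
    cd_weights: Sequence[float] = (1.0,)
    cd_noise_rel: float = 0.0
    ht_ramp_below_nm: float | None = None
    # SEC
    sec_ve_noise_ml: float = 0.0
    # sequence
    length: int = 217
    composition: Mapping[str, float] | None = None

    def s_grid(self) -> np.ndarray:
        return np.geomspace(self.s_min, self.s_max, self.n_s)


# --- analytic curve models ----------------------------------------------

def debye_function(s: np.ndarray, rg: float, i0: float = 1.0) -> np.ndarray:
    """Gaussian-chain (Debye) intensity: I = I0 * 2(e^-x - 1 + x)/x^2, x=(sRg)^2."""
    x = (np.asarray(s, dtype=float) * rg) ** 2
    out = np.empty_like(x)
    small = x < 1e-6  # series branch avoids catastrophic cancellation
    out[small] = 1.0 - x[small] / 3.0
    xb = x[~small]
    out[~small] = 2.0 * (np.exp(-xb) - 1.0 + xb) / xb**2
    return i0 * out


def sphere_intensity(s: np.ndarray, radius: float, i0: float = 1.0) -> np.ndarray:
    """Homogeneous-sphere form factor squared."""
    x = np.asarray(s, dtype=float) * radius
    out = np.ones_like(x)
    nz = x != 0
    out[nz] = (3.0 * (np.sin(x[nz]) - x[nz] * np.cos(x[nz])) / x[nz] ** 3) ** 2
    return i0 * out


def sphere_pr(r: np.ndarray, radius: float) -> np.ndarray:
    """Closed-form p(r) of a homogeneous sphere, p(r) ~ r^2(1 - 3r/4R + r^3/16R^3)."""
    r = np.asarray(r, dtype=float)
    x = r / radius
    p = r**2 * (1.0 - 0.75 * x + x**3 / 16.0)
    return np.where(r <= 2.0 * radius, np.clip(p, 0.0, None), 0.0)


# --- generators ---------------------------------------------------------

def synth_saxs(config: SyntheticConfig) -> tuple[SAXSCurve, dict]:
    """Synthetic scattering curve plus its ground-truth record."""
    rng = np.random.default_rng(config.seed)
    s = config.s_grid()
    truth: dict = {"model": config.curve_model, "seed": config.seed}
    if config.curve_model == "gaussian_chain":
        i = debye_function(s, config.rg, config.i0)
        truth.update(rg=config.rg, i0=config.i0)
    elif config.curve_model == "sphere":
        i = sphere_intensity(s, config.radius, config.i0)
        truth.update(radius=config.radius, dmax=2.0 * config.radius,
                     rg=math.sqrt(3.0 / 5.0) * config.radius, i0=config.i0)
    elif config.curve_model == "ensemble_average":
        pool = generate_pool(config.n_residues, config.n_conf, config.seed,
                             s_grid=s)
        i = pool.intensities.mean(axis=0) * (config.i0 / config.n_residues**2)
        truth.update(rg=float(np.sqrt(np.mean(pool.rgs**2))),
                     n_residues=config.n_residues, n_conf=config.n_conf,
                     i0=config.i0)
    else:
        raise ValueError(f"unknown curve model {config.curve_model!r}")
    sigma = np.maximum(config.rel_floor * np.abs(i),
                       config.counting_scale * np.sqrt(np.abs(i)))
    sigma = np.clip(sigma, 1e-12 * max(config.i0, 1.0), None)
    if config.noise:
        i = i + rng.normal(0.0, sigma)
    return SAXSCurve(s=s, intensity=i, sigma=sigma, label="synthetic"), truth


def reference_cd_basis(wavelength_nm: np.ndarray | None = None) -> list[CDSpectrum]:
    """Synthetic helix/strand/coil reference CD shapes (MRE units).

    Gaussian-band parameterizations of the canonical far-UV features:
    helix (negative 222/208, positive 193), strand (negative 218,
    positive 196), unordered coil (deep negative 198, slight positive
    above 215).  Intended for testing the deconvolution machinery, not as
    measured reference spectra.
    """
    if wavelength_nm is None:
        wavelength_nm = np.arange(190.0, 261.0, 1.0)
    wl = np.asarray(wavelength_nm, dtype=float)

    def band(center, width, amp):
        return amp * np.exp(-0.5 * ((wl - center) / width) ** 2)

    helix = band(222, 6, -33000) + band(208, 6, -30000) + band(193, 5, 60000)
    strand = band(218, 7, -18000) + band(196, 5, 30000)
    coil = band(198, 7, -40000) + band(220, 10, 3000)
    turns = band(205, 8, -8000) + band(190, 5, 12000)
    return [
        CDSpectrum(wl, helix, units="mre", label="helix"),
        CDSpectrum(wl, strand, units="mre", label="strand"),
        CDSpectrum(wl, turns, units="mre", label="turns"),
        CDSpectrum(wl, coil, units="mre", label="unordered"),
    ]


def synth_cd(
    config: SyntheticConfig, basis: Sequence[CDSpectrum] | None = None
) -> tuple[CDSpectrum, dict]:
    """Convex mixture of basis spectra with optional noise and HT ramp."""
    if basis is None:
        basis = reference_cd_basis()
    w = np.asarray(config.cd_weights, dtype=float)
    if w.size != len(basis):
        raise ValueError("cd_weights length must match basis size")
    if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("cd_weights must lie in the simplex")
    rng = np.random.default_rng(config.seed)
    wl = basis[0].wavelength_nm
    signal = sum(wi * b.signal for wi, b in zip(w, basis))
    if config.cd_noise_rel > 0:
        scale = config.cd_noise_rel * float(np.max(np.abs(signal)))
        signal = signal + rng.normal(0.0, scale, size=signal.shape)
    ht = np.full(wl.shape, 400.0)
    if config.ht_ramp_below_nm is not None:
        low = wl < config.ht_ramp_below_nm
        ht[low] = 800.0 + 10.0 * (config.ht_ramp_below_nm - wl[low])
    truth = {"weights": {b.label: float(wi) for wi, b in zip(w, basis)},
             "seed": config.seed}
    return CDSpectrum(wl, signal, units="mre", ht_volts=ht,
                      label="synthetic"), truth


# truth line for the synthetic SEC column: log10(Rs) = a + b * Kav
_SEC_TRUTH_INTERCEPT = 1.95
_SEC_TRUTH_SLOPE = -0.75


def synth_sec(
    config: SyntheticConfig,
    standards: Sequence[tuple[str, float, float]] | None = None,
    sample_rs: Sequence[float] = (),
) -> tuple[dict, dict]:
    """Synthetic SEC calibration table plus sample elution volumes.

    Standards default to the five reference proteins (mass, Stokes
    radius); elution volumes are generated from a log-linear
    Kav line (the truth record carries its coefficients) with optional
    Gaussian Ve noise.
    """
    if standards is None:
        standards = FIXTURES["sec_standards"].value
    if len(standards) < 3:
        raise ValueError("need at least 3 standards")
    rng = np.random.default_rng(config.seed)
    v0 = FIXTURES["sec_v0_ml"].value
    vt = FIXTURES["sec_vt_ml"].value

    def ve_from_rs(rs: float) -> float:
        k = (math.log10(rs) - _SEC_TRUTH_INTERCEPT) / _SEC_TRUTH_SLOPE
        return v0 + k * (vt - v0)

    table = []
    for name, mm_da, rs in standards:
        ve = ve_from_rs(rs)
        if config.sec_ve_noise_ml > 0:
            ve += rng.normal(0.0, config.sec_ve_noise_ml)
        table.append((name, float(mm_da), float(rs), float(ve)))
    samples = []
    for rs in sample_rs:
        ve = ve_from_rs(rs)
        if config.sec_ve_noise_ml > 0:
            ve += rng.normal(0.0, config.sec_ve_noise_ml)
        samples.append({"rs_true": float(rs), "ve": float(ve)})
    truth = {"intercept": _SEC_TRUTH_INTERCEPT, "slope": _SEC_TRUTH_SLOPE,
             "v0": v0, "vt": vt, "seed": config.seed}
    return {"standards": table, "v0": v0, "vt": vt, "samples": samples}, truth


# composition bias emulating a disorder-promoting sequence: Q/S/P/E/K-rich,
# W/F/Y/I/N-poor
DISORDER_BIASED_COMPOSITION = {
    "A": 0.06, "R": 0.05, "N": 0.02, "D": 0.03, "C": 0.01,
    "Q": 0.14, "E": 0.07, "G": 0.06, "H": 0.02, "I": 0.02,
    "L": 0.06, "K": 0.06, "M": 0.02, "F": 0.01, "P": 0.10,
    "S": 0.16, "T": 0.05, "W": 0.005, "Y": 0.015, "V": 0.04,
}
assert abs(sum(DISORDER_BIASED_COMPOSITION.values()) - 1.0) < 1e-9


def synth_sequence(config: SyntheticConfig) -> tuple[SequenceRecord, dict]:
    """I.i.d. random sequence under a stated composition distribution."""
    comp = dict(config.composition or DISORDER_BIASED_COMPOSITION)
    aas = sorted(comp)
    probs = np.array([comp[a] for a in aas], dtype=float)
    if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("composition must be a probability distribution")
    rng = np.random.default_rng(config.seed)
    letters = rng.choice(np.array(aas), size=config.length, p=probs)
    seq = "".join(letters.tolist())
    truth = {"composition": comp, "length": config.length, "seed": config.seed}
    return SequenceRecord(id=f"synthetic-{config.seed}", residues=seq), truth


def synthetic_metc_like_sequence(seed: int = 20160922) -> SequenceRecord:
    """A synthetic stand-in for the MetC construct sequence.

    The published sequence figure is an image and is not transcribable
    from text, so this 217-residue surrogate reproduces only its stated
    composition character (rich in Q, S and P; poor in W, F, Y, I and N);
    it is synthetic and carries no real MetC residues.
    """
    cfg = SyntheticConfig(seed=seed, length=217)
    record, _ = synth_sequence(cfg)
    return SequenceRecord(id="synthetic-metc-like", residues=record.residues)
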