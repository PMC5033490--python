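"""Physical constants, amino-acid scales and default classification tables.

Every table here is a *default*: the config layer (:mod:`idpchar.config`)
can override any of them from YAML, so classification boundaries are data,
not code.
"""

from __future__ import annotations

import math

# --- physical constants -------------------------------------------------

AVOGADRO = 6.02214076e23          # mol^-1
SVEDBERG = 1.0e-13                # s; 1 S = 1e-13 s
WATER_VISCOSITY_20C = 1.002       # cP, pure water at 20 degC
WATER_DENSITY_20C = 0.99823       # g/ml, pure water at 20 degC

CANONICAL_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

# --- Kyte-Doolittle hydropathy ------------------------------------------

KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}


def normalized_kd(residue: str) -> float:
    """Kyte-Doolittle hydropathy mapped onto [0, 1] via (KD + 4.5) / 9."""
    return (KYTE_DOOLITTLE[residue] + 4.5) / 9.0


# net charge at pH 7: K,R = +1; D,E = -1; H treated as neutral
RESIDUE_CHARGE = {"K": 1, "R": 1, "D": -1, "E": -1}

# charge-hydropathy boundary <R> = CH_SLOPE*<H> + CH_INTERCEPT
# (constants of the Uversky-plot construction; points above the line are
# predicted disordered)
CH_SLOPE = 2.785
CH_INTERCEPT = -1.151
CH_BOUNDARY_EPS = 0.005
CH_WINDOW = 5

# residue classes by disorder-promoting propensity
DISORDER_PROMOTING = frozenset("ARGQSEKP")
ORDER_PROMOTING = frozenset("WCFIYVLN")
DISORDER_NEUTRAL = frozenset("HMTD")

# --- hydrodynamic state laws --------------------------------------------
# log10(Rs[A]) = A + B * log10(MM[Da]) per conformational state.
# Globular tracks (native, molten globule, pre-molten globule,
# GdmCl-unfolded) follow the published compilation; the native track is
# the same power law used for SEC-standard radii.  The two IDP tracks keep
# the published scaling exponents with intercepts anchored to the
# validated 23.4 kDa predictions (33.6 A PMG-like, 38.7 A coil-like).
STATE_LAWS = {
    "native": (-0.204, 0.357),
    "molten_globule": (-0.053, 0.334),
    "pre_molten_globule": (-0.21, 0.392),
    "unfolded": (-0.723, 0.543),
    "pmg_idp": (-0.2344, 0.403),
    "coil_idp": (-0.5663, 0.493),
}

# order used by the monotonicity invariant for globular states
GLOBULAR_STATE_ORDER = ("native", "molten_globule", "pre_molten_globule", "unfolded")

# --- frictional-ratio reference tracks ----------------------------------
# anchor points (MM kDa, f/f0); interpolated log-linearly in MM
FF0_TRACKS = {
    "globular": ((20.0, 1.19), (200.0, 1.25)),
    "pmg_idp": ((20.0, 1.75), (200.0, 2.05)),
    "coil_idp": ((20.0, 2.1), (200.0, 3.0)),
}
FF0_ELONGATED_THRESHOLD = 1.8

# --- Rg/Rs shape bands --------------------------------------------------

RG_RS_SPHERE = 0.778
RG_RS_SPHERE_TOL = 0.01
RG_RS_OBLATE = (0.875, 0.987)
RG_RS_PROLATE = (1.36, 2.24)

# --- Flory scaling for disordered chains --------------------------------

FLORY_PREFACTOR = 2.54   # A
FLORY_EXPONENT = 0.522

# --- CD double-wavelength regions ---------------------------------------
# rectangles in ([theta]_200, [theta]_222) MRE space, deg cm^2 dmol^-1,
# approximating the published coil-like and PMG-like IDP clusters
CD_REGIONS = {
    "coil": {"theta200": (-21600.0, -16600.0), "theta222": (-2400.0, -1000.0)},
    "pmg": {"theta200": (-13200.0, -8800.0), "theta222": (-5900.0, -3300.0)},
}
CD_HT_MAX = 750.0  # volts

# --- SAXS ---------------------------------------------------------------

GUINIER_SRG_MAX = 1.3

# default experimental s grid: 200 log-spaced points over the measured range
S_GRID_MIN = 0.0025   # A^-1
S_GRID_MAX = 0.441    # A^-1
S_GRID_N = 200

# --- coarse-grained chain model -----------------------------------------

CA_BOND = 3.8           # A, virtual Calpha-Calpha bond
CA_CLASH_RADIUS = 4.0   # A, for residue pairs |i-j| >= 3
CA_ANGLE_RANGE = (75.0, 150.0)   # degrees, pseudo-bond-angle

TWO_POINT_RG = CA_BOND / 2.0  # Rg of a 2-residue chain


def rs_power_law(mm_da: float, intercept: float = -0.204, slope: float = 0.357) -> float:
    """Evaluate log-linear Stokes-radius law Rs = 10**(a + b*log10(MM))."""
    return 10.0 ** (intercept + slope * math.log10(mm_da))
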