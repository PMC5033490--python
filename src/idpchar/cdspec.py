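"""Circular-dichroism spectrum handling.

Far-UV CD distinguishes disordered chains (deep negative band near
200 nm, weak signal at 222 nm) from helical/strand-rich folds.  This
module converts raw ellipticity to mean-residue ellipticity (MRE),
filters wavelengths by the detector high-tension (HT) channel, places a
spectrum on the double-wavelength ([theta]_200, [theta]_222) coil-like vs
PMG-like diagnostic plane, and estimates secondary-structure fractions by
simplex-constrained basis-set deconvolution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "CDSpectrum",
    "SecondaryStructureFractions",
    "to_mre",
    "from_mre",
    "ht_filter",
    "double_wavelength_classify",
    "deconvolve",
]

from . import constants as C


@dataclass(frozen=True)
class CDSpectrum:
    """Ellipticity vs wavelength, optionally with the HT channel.

    ``units`` is ``"mdeg"`` (raw machine units) or ``"mre"``
    (deg cm^2 dmol^-1).  MRE conversion requires concentration (molar),
    pathlength (cm) and residue count in ``meta``.
    """

    wavelength_nm: np.ndarray
    signal: np.ndarray
    units: str = "mdeg"
    ht_volts: np.ndarray | None = None
    meta: Mapping | None = None
    label: str = ""

    def __post_init__(self):
        wl = np.asarray(self.wavelength_nm, dtype=float)
        sig = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "wavelength_nm", wl)
        object.__setattr__(self, "signal", sig)
        if wl.shape != sig.shape:
            raise ValueError("wavelength and signal shapes differ")
        if wl.size and not (np.all(np.diff(wl) > 0) or np.all(np.diff(wl) < 0)):
            raise ValueError("wavelengths must be strictly monotone")
        if self.ht_volts is not None:
            ht = np.asarray(self.ht_volts, dtype=float)
            if ht.shape != wl.shape:
                raise ValueError("HT channel shape differs from wavelength grid")
            object.__setattr__(self, "ht_volts", ht)
        if self.units not in ("mdeg", "mre"):
            raise ValueError(f"unknown units {self.units!r}")

    def value_at(self, wl: float) -> float:
        """Signal interpolated at a wavelength (grid sorted ascending first)."""
        order = np.argsort(self.wavelength_nm)
        return float(np.interp(wl, self.wavelength_nm[order], self.signal[order]))


@dataclass(frozen=True)
class SecondaryStructureFractions:
    helix: float
    strand: float
    turns: float
    unordered: float
    residual_norm: float = 0.0
    weights: Mapping[str, float] | None = None

    def __post_init__(self):
        vals = (self.helix, self.strand, self.turns, self.unordered)
        if any(v < -1e-9 for v in vals):
            raise ValueError("negative secondary-structure fraction")
        if abs(sum(vals) - 1.0) > 0.02:
            raise ValueError(f"fractions sum to {sum(vals):.4f}, not 1 +/- 0.02")


def to_mre(
    spectrum: CDSpectrum,
    conc_molar: float | None = None,
    pathlength_cm: float | None = None,
    n_residues: int | None = None,
) -> CDSpectrum:
    """Convert raw ellipticity (mdeg) to mean-residue ellipticity.

    MRE(lambda) = theta_mdeg / (10 * c * l * n_res) with molar protein
    concentration c, pathlength l in cm, and the residue count -- i.e. the
    denominator is the mean-residue molar concentration times 10*l (a
    common pitfall is using pathlength in mm, which is off by 10x).
    """
    meta = dict(spectrum.meta or {})
    conc = conc_molar if conc_molar is not None else meta.get("conc_molar")
    path = pathlength_cm if pathlength_cm is not None else meta.get("pathlength_cm")
    nres = n_residues if n_residues is not None else meta.get("n_residues")
    if spectrum.units == "mre":
        return spectrum
    if not all(x is not None and x > 0 for x in (conc, path, nres)):
        raise ValueError("MRE conversion needs conc_molar, pathlength_cm and "
                         "n_residues, all positive")
    factor = 10.0 * conc * path * nres
    meta.update(conc_molar=conc, pathlength_cm=path, n_residues=nres)
    return replace(spectrum, signal=spectrum.signal / factor, units="mre",
                   meta=meta)


def from_mre(spectrum: CDSpectrum) -> CDSpectrum:
    """Exact inverse of :func:`to_mre` (back to machine mdeg units)."""
    if spectrum.units == "mdeg":
        return spectrum
    meta = dict(spectrum.meta or {})
    try:
        factor = 10.0 * meta["conc_molar"] * meta["pathlength_cm"] * meta["n_residues"]
    except KeyError as exc:
        raise ValueError("metadata needed to invert MRE conversion") from exc
    return replace(spectrum, signal=spectrum.signal * factor, units="mdeg")


def ht_filter(spectrum: CDSpectrum, ht_max: float = C.CD_HT_MAX) -> CDSpectrum:
    """Drop wavelengths whose HT is at or above ``ht_max`` (keep HT < ht_max).

    High detector voltage means the sample/buffer absorbs nearly all light
    and the ellipticity there is noise; the conventional cutoff keeps only
    points with HT strictly under 750 V.
    """
    if spectrum.ht_volts is None:
        warnings.warn("no HT channel; spectrum passed through unfiltered")
        return spectrum
    keep = spectrum.ht_volts < ht_max
    if not np.any(keep):
        raise ValueError(f"all points have HT >= {ht_max} V; nothing retained")
    return replace(
        spectrum,
        wavelength_nm=spectrum.wavelength_nm[keep],
        signal=spectrum.signal[keep],
        ht_volts=spectrum.ht_volts[keep],
    )


def _in_rect(x: float, y: float, rect: Mapping) -> bool:
    (x0, x1), (y0, y1) = sorted(rect["theta200"]), sorted(rect["theta222"])
    return x0 <= x <= x1 and y0 <= y <= y1


def _rect_center(rect: Mapping) -> tuple[float, float]:
    return (sum(rect["theta200"]) / 2.0, sum(rect["theta222"]) / 2.0)


def double_wavelength_classify(
    mre_200: float, mre_222: float, config: Mapping | None = None
) -> dict:
    """Coil-like vs PMG-like IDP verdict from ([theta]_200, [theta]_222).

    The two groups occupy distinct regions of the double-wavelength plane
    (coil-like IDPs: deep 200 nm band, nearly no 222 nm signal; PMG-like:
    shallower 200 nm band with residual 222 nm structure).  Points inside
    a region get that label; points in neither region but within the
    convex hull of both get "between" plus the nearer group; anything
    else is "outside".
    """
    regions = (config["cdspec"]["regions"] if config is not None else C.CD_REGIONS)
    point = np.array([mre_200, mre_222])
    for name, rect in regions.items():
        if _in_rect(mre_200, mre_222, rect):
            nearer = "coil-like" if name == "coil" else "PMG-like"
            return {"verdict": nearer, "nearer": nearer}
    # convex hull of both rectangles = bounding box over all corners
    xs = [x for r in regions.values() for x in r["theta200"]]
    ys = [y for r in regions.values() for y in r["theta222"]]
    centers = {name: _rect_center(r) for name, r in regions.items()}
    dists = {name: float(np.hypot(*(point - np.array(c))))
             for name, c in centers.items()}
    nearer = min(dists, key=dists.get)
    nearer_label = "coil-like" if nearer == "coil" else "PMG-like"
    if min(xs) <= mre_200 <= max(xs) and min(ys) <= mre_222 <= max(ys):
        return {"verdict": "between", "nearer": nearer_label}
    return {"verdict": "outside", "nearer": nearer_label}


def _kkt_solve(A: np.ndarray, y: np.ndarray, support: np.ndarray):
    """Equality-constrained LS on a support: min ||A_S w - y||, sum w = 1."""
    As = A[:, support]
    m = As.shape[1]
    kkt = np.zeros((m + 1, m + 1))
    kkt[:m, :m] = 2.0 * As.T @ As
    kkt[:m, m] = 1.0
    kkt[m, :m] = 1.0
    rhs = np.concatenate([2.0 * As.T @ y, [1.0]])
    sol = np.linalg.lstsq(kkt, rhs, rcond=None)[0]
    return sol[:m], float(sol[m])


def _simplex_lstsq(A: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Minimize ||A w - y||^2 subject to w >= 0, sum(w) = 1.

    Exact active-set method: solve the equality-constrained KKT system on
    the current support, drop the most negative weight while any is
    negative, then re-admit zeroed variables whose KKT multiplier is
    negative (they would reduce the residual).  Deterministic, and exact
    on noiseless mixtures.
    """
    scale = max(float(np.max(np.abs(y))), 1e-30)
    A = A / scale
    y = y / scale
    k = A.shape[1]
    support = np.ones(k, dtype=bool)
    for _outer in range(4 * k + 8):
        w_s, lam = _kkt_solve(A, y, support)
        while np.any(w_s < -1e-12):
            idx = np.nonzero(support)[0]
            if idx.size == 1:
                break
            support[idx[np.argmin(w_s)]] = False
            w_s, lam = _kkt_solve(A, y, support)
        w = np.zeros(k)
        w[support] = np.clip(w_s, 0.0, None)
        # optimality of excluded variables: reduced gradient must be >= 0
        grad = 2.0 * A.T @ (A @ w - y) + lam
        violating = (~support) & (grad < -1e-10)
        if not np.any(violating):
            break
        support[int(np.argmin(np.where(violating, grad, np.inf)))] = True
    total = w.sum()
    if total <= 0:
        raise RuntimeError("deconvolution failed: degenerate weights")
    return w / total


def deconvolve(
    spectrum: CDSpectrum,
    basis: Sequence[CDSpectrum],
    labels: Sequence[str] | None = None,
) -> SecondaryStructureFractions:
    """Secondary-structure fractions by constrained basis-set deconvolution.

    Solves a non-negative, sum-to-one least-squares fit of the sample
    spectrum as a convex mixture of reference spectra, then aggregates
    weights by each basis member's structure label (``helix``, ``strand``,
    ``turns`` or ``unordered``, from ``labels`` or each spectrum's
    ``label``).  Deterministic.
    """
    if len(basis) < 2:
        raise ValueError("need at least 2 basis spectra")
    if labels is None:
        labels = [b.label for b in basis]
    if len(labels) != len(basis):
        raise ValueError("labels length mismatch")
    allowed = {"helix", "strand", "turns", "unordered"}
    if not set(labels) <= allowed:
        raise ValueError(f"labels must be in {sorted(allowed)}")

    wl = spectrum.wavelength_nm
    cols = []
    for b in basis:
        if b.wavelength_nm.shape == wl.shape and np.allclose(b.wavelength_nm, wl):
            cols.append(b.signal)
        else:
            if wl.min() < b.wavelength_nm.min() or wl.max() > b.wavelength_nm.max():
                raise ValueError("basis grid does not cover the sample's range")
            warnings.warn("basis grid mismatch; resampling basis onto sample grid")
            order = np.argsort(b.wavelength_nm)
            cols.append(np.interp(wl, b.wavelength_nm[order], b.signal[order]))
    A = np.column_stack(cols)
    if np.linalg.matrix_rank(A) < A.shape[1]:
        raise ValueError("singular basis: reference spectra are linearly dependent")

    w = _simplex_lstsq(A, spectrum.signal)
    residual = float(np.linalg.norm(A @ w - spectrum.signal))
    agg = {"helix": 0.0, "strand": 0.0, "turns": 0.0, "unordered": 0.0}
    for wi, lab in zip(w, labels):
        agg[lab] += float(wi)
    return SecondaryStructureFractions(
        helix=agg["helix"], strand=agg["strand"], turns=agg["turns"],
        unordered=agg["unordered"], residual_norm=residual,
        weights={f"{lab}:{i}": float(wi) for i, (wi, lab) in enumerate(zip(w, labels))},
    )
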