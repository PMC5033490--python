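"""Sequence-level disorder diagnostics.

Intrinsically disordered proteins (IDPs) have a biased amino-acid
composition: depleted in bulky hydrophobic, order-promoting residues
(W, F, Y, I, ...) and enriched in polar/charged disorder-promoting ones
(Q, S, P, E, K, ...).  This module provides the classic sequence-only
diagnostics built on that observation:

* composition fractions and enrichment relative to a reference
  distribution (with bootstrap confidence intervals),
* the disorder/order/neutral residue census,
* the charge-hydropathy (Uversky) classifier: mean normalized
  Kyte-Doolittle hydropathy ``<H>`` against absolute mean net charge
  ``<R>``, with the linear boundary ``<R> = 2.785 <H> - 1.151``,
* a windowed foldability index ``FI = 2.785 <H>_w - |<R>_w| - 1.151``
  whose negative stretches mark predicted-unfolded segments.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from . import constants as C

__all__ = [
    "SequenceRecord",
    "CompositionProfile",
    "EnrichmentResult",
    "ChargeHydropathyPoint",
    "composition_fractions",
    "enrichment",
    "disorder_promoting_fraction",
    "charge_hydropathy",
    "fold_index_profile",
]


@dataclass(frozen=True)
class SequenceRecord:
    """A validated protein sequence of canonical one-letter residues."""

    id: str
    residues: str

    def __post_init__(self):
        seq = self.residues.upper().replace("\n", "").replace(" ", "")
        object.__setattr__(self, "residues", seq)
        if len(seq) < 1:
            raise ValueError("empty sequence")
        bad = set(seq) - set(C.CANONICAL_RESIDUES)
        if bad:
            raise ValueError(
                f"non-canonical residue(s) {sorted(bad)} in sequence {self.id!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class CompositionProfile:
    """Per-residue fractions over the 20 canonical amino acids.

    ``n_residues`` records the sequence length behind a sample profile;
    it is required for the bootstrap in :func:`enrichment`.
    """

    fractions: Mapping[str, float]
    source: str = "sample"
    n_residues: int | None = None

    def __post_init__(self):
        fr = {aa: float(self.fractions.get(aa, 0.0)) for aa in C.CANONICAL_RESIDUES}
        if any(v < 0 for v in fr.values()):
            raise ValueError("negative composition fraction")
        total = sum(fr.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"composition fractions sum to {total}, not 1")
        object.__setattr__(self, "fractions", fr)

    def as_array(self) -> np.ndarray:
        return np.array([self.fractions[aa] for aa in C.CANONICAL_RESIDUES])


@dataclass(frozen=True)
class EnrichmentResult:
    """Relative enrichment e_x = (f_sample - f_ref)/f_ref per residue."""

    enrichment: Mapping[str, float]
    ci_low: Mapping[str, float]
    ci_high: Mapping[str, float]
    significant: Mapping[str, bool]
    n_boot: int
    seed: int


@dataclass(frozen=True)
class ChargeHydropathyPoint:
    mean_hydropathy: float
    mean_net_charge: float
    verdict: str  # ordered | disordered | boundary
    boundary_distance: float = 0.0


def composition_fractions(seq: SequenceRecord) -> CompositionProfile:
    """Fraction of each canonical residue (0 for absent residues)."""
    n = len(seq)
    counts = {aa: 0 for aa in C.CANONICAL_RESIDUES}
    for r in seq.residues:
        counts[r] += 1
    return CompositionProfile(
        fractions={aa: counts[aa] / n for aa in counts},
        source="sample",
        n_residues=n,
    )


def enrichment(
    sample: CompositionProfile,
    reference: CompositionProfile,
    n_boot: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> EnrichmentResult:
    """Per-residue relative enrichment of ``sample`` against ``reference``.

    Confidence intervals come from resampling sequences of the sample's
    length from its own composition (multinomial bootstrap) and taking
    percentile bounds on the resampled enrichment.  A residue is flagged
    significant when its CI excludes zero.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if seed is None:
        raise ValueError("seed is mandatory for the bootstrap")
    n = sample.n_residues
    if n is None:
        raise ValueError("sample profile lacks n_residues; build it with "
                         "composition_fractions() or set n_residues")

    fs = sample.as_array()
    fr = reference.as_array()
    aas = list(C.CANONICAL_RESIDUES)

    point = np.empty(20)
    for i in range(20):
        if fr[i] > 0:
            point[i] = (fs[i] - fr[i]) / fr[i]
        elif fs[i] > 0:
            warnings.warn(
                f"reference fraction 0 for {aas[i]} with nonzero sample "
                "fraction; enrichment reported as +inf"
            )
            point[i] = math.inf
        else:
            point[i] = 0.0

    rng = np.random.default_rng(seed)
    boot_counts = rng.multinomial(n, fs, size=n_boot)  # (n_boot, 20)
    boot_frac = boot_counts / n
    with np.errstate(divide="ignore", invalid="ignore"):
        boot_e = np.where(fr > 0, (boot_frac - fr) / fr, np.inf)
        boot_e = np.where((fr == 0) & (boot_frac == 0), 0.0, boot_e)
    lo = np.percentile(boot_e, 100 * alpha / 2, axis=0)
    hi = np.percentile(boot_e, 100 * (1 - alpha / 2), axis=0)
    # percentile CI must bracket the point estimate
    lo = np.minimum(lo, point)
    hi = np.maximum(hi, point)
    sig = (lo > 0) | (hi < 0)

    return EnrichmentResult(
        enrichment=dict(zip(aas, point.tolist())),
        ci_low=dict(zip(aas, lo.tolist())),
        ci_high=dict(zip(aas, hi.tolist())),
        significant=dict(zip(aas, sig.tolist())),
        n_boot=n_boot,
        seed=seed,
    )


def disorder_promoting_fraction(
    seq: SequenceRecord, config: Mapping | None = None
) -> dict[str, float]:
    """Fractions of disorder-promoting, order-promoting and neutral residues."""
    if config is not None:
        classes = config["seqdis"]["classes"]
        dis = set(classes["disorder_promoting"])
        orde = set(classes["order_promoting"])
        neu = set(classes["neutral"])
    else:
        dis, orde, neu = C.DISORDER_PROMOTING, C.ORDER_PROMOTING, C.DISORDER_NEUTRAL
    n = len(seq)
    nd = sum(1 for r in seq.residues if r in dis)
    no = sum(1 for r in seq.residues if r in orde)
    nn = sum(1 for r in seq.residues if r in neu)
    return {
        "disorder_promoting": nd / n,
        "order_promoting": no / n,
        "neutral": nn / n,
    }


def _windowed_hydropathy(seq: SequenceRecord, window: int) -> np.ndarray:
    h = np.array([C.normalized_kd(r) for r in seq.residues])
    if window <= 1:
        return h
    kernel = np.ones(window) / window
    return np.convolve(h, kernel, mode="valid")


def mean_net_charge(residues: str) -> float:
    """Absolute mean net charge |#(K,R) - #(D,E)| / N at pH 7."""
    q = sum(C.RESIDUE_CHARGE.get(r, 0) for r in residues)
    return abs(q) / len(residues)


def charge_hydropathy(
    seq: SequenceRecord,
    window: int = C.CH_WINDOW,
    config: Mapping | None = None,
) -> ChargeHydropathyPoint:
    """Place a sequence on the charge-hydropathy (Uversky) plane.

    ``<H>`` is the mean of window-averaged normalized Kyte-Doolittle
    hydropathies; ``<R>`` the absolute mean net charge.  Points above the
    boundary line (high charge, low hydropathy) are predicted disordered.
    """
    if len(seq) < window:
        raise ValueError(f"sequence shorter than window ({len(seq)} < {window})")
    if config is not None:
        b = config["seqdis"]["ch_boundary"]
        slope, intercept, eps = b["slope"], b["intercept"], b["eps"]
    else:
        slope, intercept, eps = C.CH_SLOPE, C.CH_INTERCEPT, C.CH_BOUNDARY_EPS

    h = float(np.mean(_windowed_hydropathy(seq, window)))
    r = mean_net_charge(seq.residues)
    dist = r - (slope * h + intercept)
    if abs(dist) <= eps:
        verdict = "boundary"
    elif dist > 0:
        verdict = "disordered"
    else:
        verdict = "ordered"
    return ChargeHydropathyPoint(h, r, verdict, dist)


def fold_index_profile(seq: SequenceRecord, window: int = 51) -> np.ndarray:
    """Per-window foldability index FI = 2.785 <H>_w - |<R>_w| - 1.151.

    Returns one value per window position (length N - window + 1);
    negative values predict locally unfolded segments.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if len(seq) < window:
        raise ValueError(f"sequence shorter than window ({len(seq)} < {window})")
    h = np.array([C.normalized_kd(r) for r in seq.residues])
    q = np.array([C.RESIDUE_CHARGE.get(r, 0) for r in seq.residues], dtype=float)
    kernel = np.ones(window) / window
    hw = np.convolve(h, kernel, mode="valid")
    qw = np.convolve(q, kernel, mode="valid")
    return C.CH_SLOPE * hw - np.abs(qw) + C.CH_INTERCEPT
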