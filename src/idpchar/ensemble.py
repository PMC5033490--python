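"""Ensemble-optimization analysis of SAXS data (EOM-style).

A flexible chain in solution is not one structure but an ensemble; its
scattering curve is the ensemble average.  The workflow here mirrors the
ensemble optimization method: build a large pool of random-coil
C-alpha conformers, compute each conformer's scattering with the Debye
formula, and let a genetic algorithm pick the sub-ensemble (a multiset of
pool members, uniformly weighted) whose average intensity best fits a
target curve in the chi^2 sense.  Comparing the Rg distribution of the
selected ensemble with that of the unselected pool reveals whether the
data demand conformations more compact or more extended than a plain
coil.

Chain model: C-alpha only, fixed 3.8 A virtual bonds, pseudo-bond-angles
uniform on [75, 150] degrees and pseudo-dihedrals uniform on
(-180, 180], with self-avoidance enforced by rejection at a 4.0 A clash
radius between residues at least 3 apart in sequence.  This is a
deliberately simple excluded-volume coil; it is the swappable default,
not a native-like dihedral library.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist

from . import constants as C
from .saxs import SAXSCurve

__all__ = [
    "ConformerChain",
    "ConformerPool",
    "EnsembleFit",
    "generate_chain",
    "generate_pool",
    "debye_intensity",
    "ga_select",
    "rg_report",
]


@dataclass(frozen=True)
class ConformerChain:
    """A C-alpha-only conformer: (N, 3) coordinates in Angstrom."""

    coords: np.ndarray
    rg: float
    dmax: float

    @property
    def n_residues(self) -> int:
        return self.coords.shape[0]


@dataclass
class ConformerPool:
    chains: list[ConformerChain]
    seed: int
    n_residues: int
    s_grid: np.ndarray | None = None
    intensities: np.ndarray | None = None  # (n_conf, len(s_grid))

    @property
    def rgs(self) -> np.ndarray:
        return np.array([c.rg for c in self.chains])

    def __len__(self) -> int:
        return len(self.chains)

    def compute_intensities(self, s_grid: np.ndarray) -> np.ndarray:
        """Per-conformer Debye intensity on a shared s grid (cached)."""
        s_grid = np.asarray(s_grid, dtype=float)
        if (self.intensities is not None and self.s_grid is not None
                and self.s_grid.shape == s_grid.shape
                and np.allclose(self.s_grid, s_grid)):
            return self.intensities
        self.s_grid = s_grid
        self.intensities = np.vstack(
            [debye_intensity(c.coords, s_grid) for c in self.chains]
        )
        return self.intensities


@dataclass(frozen=True)
class EnsembleFit:
    indices: tuple[int, ...]       # multiset over pool indices
    weights: dict[int, float]      # uniform-by-repetition, sums to 1
    intensity: np.ndarray          # scaled ensemble-average on target grid
    chi2: float
    scale: float
    chi2_history: tuple[float, ...]
    rgs: np.ndarray                # Rg of each selected conformer
    settings: dict


# --- chain generation ---------------------------------------------------

def _next_position(c3: np.ndarray, c2: np.ndarray, c1: np.ndarray,
                   bond: float, theta: float, phi: float) -> np.ndarray:
    """Place the next atom from the three previous ones (NeRF construction).

    ``theta`` is the pseudo-bond-angle at ``c1`` (angle between bonds),
    ``phi`` the pseudo-dihedral, both in radians.
    """
    b1 = c1 - c2
    b1 /= np.linalg.norm(b1)
    b0 = c2 - c3
    n = np.cross(b0, b1)
    nn = np.linalg.norm(n)
    if nn < 1e-10:  # collinear history: pick any perpendicular
        ref = np.array([1.0, 0.0, 0.0])
        if abs(b1[0]) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        n = np.cross(b1, ref)
        nn = np.linalg.norm(n)
    n /= nn
    m = np.cross(n, b1)
    # local displacement: bond along -b1 rotated by the deflection angle
    ang = math.pi - theta  # deflection from straight continuation
    d = bond * (math.cos(ang) * b1
                + math.sin(ang) * (math.cos(phi) * m + math.sin(phi) * n))
    return c1 + d


def generate_chain(
    n_residues: int,
    rng: np.random.Generator,
    bond: float = C.CA_BOND,
    angle_range: tuple[float, float] = C.CA_ANGLE_RANGE,
    clash_radius: float = C.CA_CLASH_RADIUS,
    max_step_retries: int = 60,
    max_restarts: int = 200,
) -> ConformerChain:
    """One self-avoiding random-coil chain by sequential placement."""
    if n_residues < 2:
        raise ValueError("need at least 2 residues")
    lo, hi = math.radians(angle_range[0]), math.radians(angle_range[1])
    for _restart in range(max_restarts):
        coords = np.empty((n_residues, 3))
        coords[0] = 0.0
        coords[1] = (bond, 0.0, 0.0)
        dummy = np.array([-bond, 0.0, 0.0])  # virtual atom before the chain
        ok = True
        for i in range(2, n_residues):
            placed = False
            c3 = coords[i - 3] if i >= 3 else dummy
            for _try in range(max_step_retries):
                theta = rng.uniform(lo, hi)
                phi = rng.uniform(-math.pi, math.pi)
                cand = _next_position(c3, coords[i - 2], coords[i - 1],
                                      bond, theta, phi)
                if i >= 3:
                    d2 = np.sum((coords[: i - 2] - cand) ** 2, axis=1)
                    if np.min(d2) < clash_radius**2:
                        continue
                coords[i] = cand
                placed = True
                break
            if not placed:
                ok = False
                break
        if ok:
            center = coords.mean(axis=0)
            rg = float(np.sqrt(np.mean(np.sum((coords - center) ** 2, axis=1))))
            dmax = float(pdist(coords).max()) if n_residues > 1 else 0.0
            return ConformerChain(coords=coords, rg=rg, dmax=dmax)
    raise RuntimeError(
        f"chain construction failed after {max_restarts} restarts "
        f"(N={n_residues}, clash={clash_radius} A): pool parameters too tight"
    )


def generate_pool(
    n_residues: int,
    n_conf: int,
    seed: int,
    s_grid: np.ndarray | None = None,
    **chain_kwargs,
) -> ConformerPool:
    """Pool of ``n_conf`` independent random-coil conformers (seeded)."""
    if n_conf < 1:
        raise ValueError("pool must contain at least one conformer")
    rng = np.random.default_rng(seed)
    chains = [generate_chain(n_residues, rng, **chain_kwargs)
              for _ in range(n_conf)]
    pool = ConformerPool(chains=chains, seed=seed, n_residues=n_residues)
    if s_grid is not None:
        pool.compute_intensities(np.asarray(s_grid, dtype=float))
    return pool


# --- Debye scattering ---------------------------------------------------

def debye_intensity(coords: np.ndarray, s_grid: np.ndarray) -> np.ndarray:
    """Orientation-averaged scattering of unit point scatterers.

    I(s) = sum_ij sinc(s * r_ij) = N + 2 * sum_{i<j} sin(s r_ij)/(s r_ij),
    with sinc(0) = 1, so I(0) = N^2.
    """
    coords = np.asarray(coords, dtype=float)
    s = np.asarray(s_grid, dtype=float)
    n = coords.shape[0]
    d = pdist(coords)  # n(n-1)/2 pair distances
    sd = np.outer(s, d)
    with np.errstate(invalid="ignore"):
        sinc = np.where(sd == 0.0, 1.0, np.sin(sd) / np.where(sd == 0, 1.0, sd))
    return n + 2.0 * sinc.sum(axis=1)


# --- chi^2 and GA selection ---------------------------------------------

def _chi2(model: np.ndarray, target: np.ndarray, sigma: np.ndarray) -> tuple[float, float]:
    """Reduced chi^2 with the analytic least-squares scale factor c."""
    w = 1.0 / sigma**2
    denom = float(np.sum(w * model**2))
    c = float(np.sum(w * model * target)) / denom if denom > 0 else 0.0
    k = target.size
    chi2 = float(np.sum(w * (c * model - target) ** 2)) / max(k - 1, 1)
    return chi2, c


def ga_select(
    pool: ConformerPool,
    target: SAXSCurve,
    ensemble_size: int = 20,
    population: int = 100,
    generations: int = 200,
    mutation_rate: float = 0.05,
    seed: int = 0,
) -> EnsembleFit:
    """Genetic-algorithm sub-ensemble selection against a target curve.

    Individuals are multisets of ``ensemble_size`` pool indices (repeats
    allowed, so repetition acts as weighting).  Fitness is the reduced
    chi^2 of the uniformly averaged ensemble intensity against the target,
    with an analytically optimal scalar scale per evaluation.  Evolution
    uses tournament selection (k=2), uniform crossover, per-slot mutation,
    a small random-immigrant fraction for exploration, and elitism of 1,
    so the best chi^2 is non-increasing.
    """
    if len(pool) == 0:
        raise ValueError("empty pool")
    if ensemble_size < 1:
        raise ValueError("ensemble_size must be >= 1")
    intens = pool.compute_intensities(target.s)  # (n_conf, K)
    if target.sigma is not None:
        sigma = target.sigma
    else:
        warnings.warn("target has no sigma; using sqrt(I) surrogate errors")
        sigma = np.sqrt(np.clip(target.intensity, 1e-12, None))
    y = target.intensity

    rng = np.random.default_rng(seed)
    n_conf = len(pool)
    pop = rng.integers(0, n_conf, size=(population, ensemble_size))

    def fitness(ind: np.ndarray) -> tuple[float, float]:
        model = intens[ind].mean(axis=0)
        return _chi2(model, y, sigma)

    scores = np.array([fitness(ind)[0] for ind in pop])
    best_i = int(np.argmin(scores))
    best_ind, best_chi2 = pop[best_i].copy(), float(scores[best_i])
    history = [best_chi2]

    n_immigrants = max(1, population // 10) if population > 2 else 0
    for _gen in range(generations):
        new_pop = np.empty_like(pop)
        new_pop[0] = best_ind  # elitism
        for j in range(1, population - n_immigrants):
            # tournament selection, k=2
            a, b = rng.integers(0, population, size=2)
            p1 = pop[a] if scores[a] <= scores[b] else pop[b]
            a, b = rng.integers(0, population, size=2)
            p2 = pop[a] if scores[a] <= scores[b] else pop[b]
            # uniform crossover over slots
            mask = rng.random(ensemble_size) < 0.5
            child = np.where(mask, p1, p2)
            # per-slot mutation
            mut = rng.random(ensemble_size) < mutation_rate
            child[mut] = rng.integers(0, n_conf, size=int(mut.sum()))
            new_pop[j] = child
        if n_immigrants:
            new_pop[population - n_immigrants:] = rng.integers(
                0, n_conf, size=(n_immigrants, ensemble_size))
        pop = new_pop
        scores = np.array([fitness(ind)[0] for ind in pop])
        gen_best = int(np.argmin(scores))
        if scores[gen_best] < best_chi2:
            best_chi2 = float(scores[gen_best])
            best_ind = pop[gen_best].copy()
        history.append(best_chi2)

    chi2, scale = fitness(best_ind)
    model = intens[best_ind].mean(axis=0) * scale
    idx, counts = np.unique(best_ind, return_counts=True)
    weights = {int(i): float(c) / ensemble_size for i, c in zip(idx, counts)}
    rgs = pool.rgs[best_ind]
    return EnsembleFit(
        indices=tuple(int(i) for i in best_ind),
        weights=weights,
        intensity=model,
        chi2=chi2,
        scale=scale,
        chi2_history=tuple(history),
        rgs=rgs,
        settings={"ensemble_size": ensemble_size, "population": population,
                  "generations": generations, "mutation_rate": mutation_rate,
                  "seed": seed},
    )


# --- reporting ----------------------------------------------------------

def rg_report(pool: ConformerPool, fit: EnsembleFit, bandwidth: float | None = None,
              n_grid: int = 256) -> dict:
    """Compare Rg distributions of the pool and the selected ensemble.

    Returns kernel-density summaries on a shared grid, the mean-Rg shift
    (selection minus pool), the detected number of modes of the selection
    density, and the per-conformer percentage contribution.
    """
    from scipy.stats import gaussian_kde

    pool_rgs = pool.rgs
    sel_rgs = fit.rgs
    lo = min(pool_rgs.min(), sel_rgs.min())
    hi = max(pool_rgs.max(), sel_rgs.max())
    pad = 0.1 * (hi - lo) if hi > lo else 1.0
    grid = np.linspace(lo - pad, hi + pad, n_grid)

    def kde(vals: np.ndarray) -> np.ndarray:
        if np.ptp(vals) < 1e-12:
            # degenerate sample: delta spike rendered as a narrow gaussian
            width = max(pad / 10.0, 1e-6)
            return np.exp(-0.5 * ((grid - vals[0]) / width) ** 2) / (
                width * math.sqrt(2 * math.pi))
        k = gaussian_kde(vals, bw_method=bandwidth)
        return k(grid)

    dens_pool = kde(pool_rgs)
    dens_sel = kde(sel_rgs)

    interior = (dens_sel[1:-1] > dens_sel[:-2]) & (dens_sel[1:-1] > dens_sel[2:])
    prominence = dens_sel[1:-1] >= 0.05 * dens_sel.max()
    n_modes = int(np.sum(interior & prominence))

    contributions = {i: 100.0 * w for i, w in fit.weights.items()}
    return {
        "grid": grid,
        "density_pool": dens_pool,
        "density_selection": dens_sel,
        "mean_rg_pool": float(pool_rgs.mean()),
        "mean_rg_selection": float(sel_rgs.mean()),
        "shift": float(sel_rgs.mean() - pool_rgs.mean()),
        "n_modes_selection": n_modes,
        "contribution_percent": contributions,
    }


def write_pdb(chain: ConformerChain, path) -> None:
    """Minimal C-alpha-only PDB for visual inspection."""
    with open(path, "w") as fh:
        for i, (x, y, z) in enumerate(chain.coords, start=1):
            fh.write(
                f"ATOM  {i:5d}  CA  GLY A{i:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n"
            )
        fh.write("END\n")
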