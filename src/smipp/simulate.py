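"""Synthetic P1 point-atom crystals and exact |E| datasets.

The generator emulates the three scatterer regimes the phasing thresholds
are tuned for: weak-only (C/N/O), medium (a few S among light atoms) and
strong (Fe/Zn among light atoms).  Moduli are exact — computed by direct
summation from the ground-truth sites and E-normalized — so downstream
behavior reflects the algorithm, not data quality.  An optional Gaussian
perturbation of |E| supports robustness checks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .cell import AtomSite, Structure, UnitCell
from .reflections import ReflectionSet
from .sfactors import direct_structure_factors, hkl_shell, normalize_to_E

#: solvent emulation: N handed to the engine is this factor times the atom
#: count, matching the average (protein+water)/protein ratio of ~1.22 seen
#: in well-solvated structures
SOLVENT_FACTOR = 1.22

_PACKING_RANGE = (8.0, 30.0)  # crystal-like A^3 per atom
_MAX_ATTEMPTS = 20_000

_LIGHT_Z = np.array([6, 7, 8])
_LIGHT_P = np.array([0.55, 0.20, 0.25])  # roughly organic composition


@dataclass
class ScenarioSpec:
    """Recipe for one synthetic crystal.

    heavy_fraction sets the share of medium (S) or strong (Fe/Zn) sites;
    min_dist is the periodic minimum interatomic distance in angstroms.
    """

    n_atoms: int = 30
    class_tag: str = "weak"
    heavy_fraction: float = 0.1
    cell_edges: tuple[float, float, float] = (13.0, 13.5, 12.6)
    d_min: float = 1.0
    min_dist: float = 1.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_atoms < 2:
            raise ValueError("need at least 2 atoms")
        if self.min_dist <= 0:
            raise ValueError("min_dist must be positive")
        if self.class_tag not in ("weak", "medium", "strong"):
            raise ValueError("class_tag must be weak, medium or strong")
        vol = float(np.prod(self.cell_edges))
        per_atom = vol / self.n_atoms
        lo, hi = _PACKING_RANGE
        if not lo <= per_atom <= hi:
            warnings.warn(
                f"{per_atom:.1f} A^3 per atom is outside the crystal-like "
                f"range [{lo}, {hi}] A^3 (sparse cells emulate solvent "
                "voids; dense ones may be unpackable)",
                stacklevel=2,
            )

    @property
    def n_heavy(self) -> int:
        if self.class_tag == "weak":
            return 0
        return max(1, round(self.heavy_fraction * self.n_atoms))


def weak_scenario(seed: int = 0, **kw) -> ScenarioSpec:
    """Small weak-scatterer crystal: 30 C/N/O atoms in a ~13 A cell.

    Deliberately sparse (~73 A^3 per atom, the empty space standing in for
    the solvent region of a real crystal) so that multi-trial refinements
    finish in seconds.
    """
    kw.setdefault("n_atoms", 30)
    kw.setdefault("cell_edges", (13.0, 13.5, 12.6))
    return ScenarioSpec(class_tag="weak", seed=seed, **kw)


def medium_scenario(seed: int = 0, **kw) -> ScenarioSpec:
    """Crambin-like composition scaled down: 300 atoms, 10% S, packed at
    ~12 A^3 per atom so grid-noise peak statistics sit in the regime of
    real protein cells."""
    kw.setdefault("n_atoms", 300)
    kw.setdefault("heavy_fraction", 0.1)
    kw.setdefault("cell_edges", (15.33, 15.94, 14.87))
    kw.setdefault("min_dist", 1.3)
    return ScenarioSpec(class_tag="medium", seed=seed, **kw)


def strong_scenario(seed: int = 0, **kw) -> ScenarioSpec:
    """Metalloprotein-like miniature: a few Fe/Zn among 60 light atoms,
    roomy enough that the heavy-heavy Patterson vectors resolve."""
    kw.setdefault("n_atoms", 60)
    kw.setdefault("heavy_fraction", 0.067)
    kw.setdefault("cell_edges", (11.8, 12.3, 11.4))
    kw.setdefault("min_dist", 1.3)
    return ScenarioSpec(class_tag="strong", seed=seed, **kw)


def _periodic_min_dist(frac: np.ndarray, others: np.ndarray, edges) -> float:
    d = np.abs(others - frac)
    d = np.minimum(d, 1.0 - d) * np.asarray(edges)
    return float(np.min(np.sqrt(np.sum(d**2, axis=1))))


def generate_structure(spec: ScenarioSpec) -> Structure:
    """Place atoms by rejection sampling with a periodic minimum distance.

    Heavy sites (S for medium, Fe/Zn for strong) are placed first, then the
    light C/N/O sites.  Reproducible from spec.seed.
    """
    rng = np.random.default_rng(spec.seed)
    heavy_z = {"weak": [], "medium": [16], "strong": [26, 30]}[spec.class_tag]
    zs: list[int] = []
    for i in range(spec.n_heavy):
        zs.append(int(heavy_z[i % len(heavy_z)]))
    zs += [int(z) for z in rng.choice(_LIGHT_Z, size=spec.n_atoms - len(zs),
                                      p=_LIGHT_P)]
    placed = np.empty((0, 3))
    sites: list[AtomSite] = []
    for z in zs:
        for _ in range(_MAX_ATTEMPTS):
            frac = rng.random(3)
            if (len(placed) == 0
                    or _periodic_min_dist(frac, placed, spec.cell_edges)
                    >= spec.min_dist):
                placed = np.vstack([placed, frac])
                sites.append(AtomSite(*frac, w=float(z)))
                break
        else:
            raise RuntimeError(
                "packing infeasible: could not place atom at min_dist "
                f"{spec.min_dist} A; use a larger cell"
            )
    cell = UnitCell(*spec.cell_edges)
    return Structure(cell, sites)


@dataclass
class GroundTruth:
    """Validation sidecar: true phases and the generating structure.

    Never handed to the phasing engine — the engine input carries moduli
    only.
    """

    structure: Structure
    true_phases: np.ndarray
    n_engine: int  # N to give the engine (atom count times solvent factor)


def make_dataset(
    structure: Structure,
    d_min: float,
    solvent_factor: float = SOLVENT_FACTOR,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[ReflectionSet, GroundTruth]:
    """Exact |E| data plus the ground-truth sidecar.

    noise_sd, if nonzero, multiplies each |E| by a 1 + N(0, sd) factor
    (clipped at zero) to emulate measurement scatter.
    """
    if d_min > 1.2:
        warnings.warn("d_min coarser than atomic resolution (1.2 A); the "
                      "delta/rho proportionality assumption degrades",
                      stacklevel=2)
    indices = hkl_shell(structure.cell, d_min)
    if len(indices) < 10:
        raise ValueError("fewer than 10 reflections; decrease d_min")
    F = direct_structure_factors(structure, indices)
    E = normalize_to_E(F, structure.weights)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        E = np.clip(E * (1.0 + rng.normal(0.0, noise_sd, size=E.shape)),
                    0.0, None)
    refl = ReflectionSet(structure.cell, indices, E, d_min)
    gt = GroundTruth(
        structure=structure,
        true_phases=np.mod(np.angle(F), 2.0 * np.pi),
        n_engine=int(round(solvent_factor * structure.n_atoms)),
    )
    return refl, gt


def interatomic_difference_vectors(structure_or_sites) -> np.ndarray:
    """Ordered difference vectors x_i - x_j (i != j), fractional, mod 1.

    Among n dominant scatterers there are n^2 - n of them — these are the
    non-origin image peaks such sites imprint on the modulus synthesis.
    """
    if isinstance(structure_or_sites, Structure):
        coords = structure_or_sites.coords
    else:
        coords = np.atleast_2d(np.asarray(
            [s.frac if isinstance(s, AtomSite) else s for s in structure_or_sites]
        ))
    n = len(coords)
    out = []
    for i in range(n):
        for j in range(n):
            if i != j:
                out.append(np.mod(coords[i] - coords[j], 1.0))
    return np.asarray(out).reshape(-1, 3)
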