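"""Unit cells and point-atom structures.

The crystal model is deliberately minimal: P1 symmetry, point atoms with an
integer scattering weight (the atomic number Z) and no displacement factor.
Synthetic data generated from such a model are "sharp" by construction, so
normalized structure factors need no resolution-dependent scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np

# Z >= 19 marks a strong scatterer (first transition series and beyond),
# 16 <= Z < 19 a medium one (S, Cl); everything lighter is weak.
_STRONG_Z = 19
_MEDIUM_Z = 16

_ELEMENTS = {
    6: "C", 7: "N", 8: "O", 15: "P", 16: "S", 17: "Cl",
    20: "Ca", 26: "Fe", 30: "Zn", 34: "Se",
}


@dataclass(frozen=True)
class UnitCell:
    """Triclinic unit cell; lengths in angstroms, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        for name in ("a", "b", "c"):
            if getattr(self, name) <= 0:
                raise ValueError(f"cell length {name} must be positive")
        for name in ("alpha", "beta", "gamma"):
            ang = getattr(self, name)
            if not 0.0 < ang < 180.0:
                raise ValueError(f"cell angle {name} must lie in (0, 180) deg")
        if self.gemmi().volume <= 0:
            raise ValueError("cell volume must be positive")

    def gemmi(self) -> gemmi.UnitCell:
        return gemmi.UnitCell(self.a, self.b, self.c, self.alpha, self.beta, self.gamma)

    @property
    def volume(self) -> float:
        """Cell volume V in cubic angstroms."""
        return self.gemmi().volume

    @property
    def lengths(self) -> tuple[float, float, float]:
        return (self.a, self.b, self.c)

    def metric_tensor(self) -> np.ndarray:
        """Direct-space metric tensor G (3x3, A^2)."""
        g = self.gemmi()
        basis = np.array(g.orth.mat.tolist())  # columns are a, b, c in cartesian
        return basis.T @ basis

    def d_spacing(self, hkl) -> float:
        """d-spacing of a Miller index (positive for any nonzero index)."""
        h, k, l = (int(v) for v in hkl)
        if (h, k, l) == (0, 0, 0):
            raise ValueError("d-spacing undefined for (0,0,0)")
        return self.gemmi().calculate_d((h, k, l))

    def orthogonalize(self, frac) -> np.ndarray:
        pos = self.gemmi().orthogonalize(gemmi.Fractional(*frac))
        return np.array([pos.x, pos.y, pos.z])


@dataclass(frozen=True)
class AtomSite:
    """Point atom at fractional coordinates with scattering weight w = Z."""

    x: float
    y: float
    z: float
    w: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.w <= 0:
            raise ValueError("scattering weight must be positive")
        object.__setattr__(self, "x", self.x % 1.0)
        object.__setattr__(self, "y", self.y % 1.0)
        object.__setattr__(self, "z", self.z % 1.0)
        if not self.label:
            object.__setattr__(self, "label", _ELEMENTS.get(int(round(self.w)), "X"))

    @property
    def frac(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass
class Structure:
    """A P1 point-atom crystal: unit cell plus ordered atom sites."""

    cell: UnitCell
    sites: list[AtomSite] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sites:
            raise ValueError("no atoms")

    @property
    def n_atoms(self) -> int:
        return len(self.sites)

    @property
    def coords(self) -> np.ndarray:
        """(N, 3) fractional coordinates."""
        return np.array([s.frac for s in self.sites])

    @property
    def weights(self) -> np.ndarray:
        return np.array([s.w for s in self.sites])

    @property
    def class_tag(self) -> str:
        """Scatterer class from the heaviest atom: weak / medium / strong."""
        zmax = max(s.w for s in self.sites)
        if zmax >= _STRONG_Z:
            return "strong"
        if zmax >= _MEDIUM_Z:
            return "medium"
        return "weak"

    def heavy_sites(self) -> list[AtomSite]:
        """Sites of the dominant scatterer class (medium or strong)."""
        return [s for s in self.sites if s.w >= _MEDIUM_Z]

    def to_pdb(self, path: str) -> None:
        """Write minimal PDB ATOM records (CRYST1 + orthogonalized sites)."""
        st = gemmi.Structure()
        st.cell = self.cell.gemmi()
        st.spacegroup_hm = "P 1"
        model = gemmi.Model("1")
        chain = gemmi.Chain("A")
        res = gemmi.Residue()
        res.name = "UNK"
        res.seqid = gemmi.SeqId(1, " ")
        for i, s in enumerate(self.sites):
            atom = gemmi.Atom()
            atom.name = f"{s.label}{i + 1}"[:4]
            atom.element = gemmi.Element(s.label)
            atom.occ = 1.0
            atom.b_iso = 0.0
            xyz = self.cell.orthogonalize(s.frac)
            atom.pos = gemmi.Position(*xyz)
            res.add_atom(atom)
        chain.add_residue(res)
        model.add_chain(chain)
        st.add_model(model)
        st.setup_entities()
        st.write_pdb(path)

    @classmethod
    def from_pdb(cls, path: str) -> "Structure":
        st = gemmi.read_structure(path)
        c = st.cell
        cell = UnitCell(c.a, c.b, c.c, c.alpha, c.beta, c.gamma)
        sites = []
        for model in st:
            for chain in model:
                for res in chain:
                    for atom in res:
                        frac = c.fractionalize(atom.pos)
                        z = atom.element.atomic_number
                        sites.append(AtomSite(frac.x, frac.y, frac.z, float(z),
                                              atom.element.name))
        return cls(cell, sites)
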