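"""Inner-pixel preservation: thresholded 26-neighbor peak search on eta.

A voxel is a peak when its value exceeds t_eta * sigma_eta and is strictly
larger than all 26 periodic nearest neighbors; no interpolation is ever
applied — the procedure operates on voxel indices only.  Density
modification preserves the 27-voxel core (peak + 26 neighbors) of the
min(N, N_eta) strongest peaks and zeroes everything else.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .cell import Structure, UnitCell
from .grids import RealGrid

_OFFSETS = [
    (i, j, k)
    for i in (-1, 0, 1)
    for j in (-1, 0, 1)
    for k in (-1, 0, 1)
    if (i, j, k) != (0, 0, 0)
]


@dataclass
class PeakList:
    """Peaks of a grid, strongest first; ties broken by voxel index."""

    voxels: np.ndarray  # (n, 3) int voxel indices
    values: np.ndarray  # (n,) eta values, strictly decreasing (ties by voxel)
    threshold: float  # t_eta * sigma_eta actually applied
    sigma: float

    @property
    def n_eta(self) -> int:
        return len(self.values)

    def to_table(self) -> str:
        """Text table: rank, i, j, k, eta/sigma."""
        lines = ["# rank i j k eta/sigma"]
        for r, (v, val) in enumerate(zip(self.voxels, self.values), start=1):
            lines.append(f"{r} {v[0]} {v[1]} {v[2]} {val / self.sigma:.3f}")
        return "\n".join(lines) + "\n"

    def to_pdb(self, path: str, cell: UnitCell, dims) -> None:
        """Dummy-atom records at peak voxels for map inspection."""
        from .cell import AtomSite

        if self.n_eta == 0:
            raise ValueError("empty peak list")
        sites = [
            AtomSite(v[0] / dims[0], v[1] / dims[1], v[2] / dims[2], 6.0, "C")
            for v in self.voxels
        ]
        Structure(cell, sites).to_pdb(path)


def find_peaks(eta: RealGrid, t_eta: float) -> PeakList:
    """All strict 26-neighbor local maxima of eta above t_eta * sigma_eta."""
    if t_eta <= 0:
        raise ValueError("t_eta must be positive")
    sigma = eta.sigma()
    if sigma == 0:
        raise ValueError("flat product function")
    v = eta.values
    threshold = t_eta * sigma
    is_peak = v > threshold
    for off in _OFFSETS:
        if not is_peak.any():
            break
        is_peak &= v > np.roll(v, off, axis=(0, 1, 2))
    vox = np.argwhere(is_peak)
    vals = v[is_peak]
    # decreasing value; ties by lexicographic voxel index (argwhere is sorted)
    order = np.argsort(-vals, kind="stable")
    return PeakList(vox[order], vals[order], threshold, sigma)


def preserve_inner_pixels(eta: RealGrid, peaks: PeakList, n_atoms: int) -> RealGrid:
    """Keep the 27-voxel cores of the min(N, N_eta) strongest peaks.

    Overlapping cores merge by set union; all other voxels become zero.
    An empty peak list yields an all-zero map (the driver treats this as a
    stalled trial rather than an error).
    """
    if n_atoms < 1:
        raise ValueError("N must be >= 1")
    if peaks.n_eta == 0:
        warnings.warn("empty peak list: eta zeroed, trial will stall", stacklevel=2)
        return RealGrid(np.zeros(eta.dims), eta.cell, "eta")
    top = peaks.voxels[: min(n_atoms, peaks.n_eta)]
    seed = np.zeros(eta.dims, dtype=bool)
    seed[top[:, 0], top[:, 1], top[:, 2]] = True
    keep = seed.copy()
    for off in _OFFSETS:
        keep |= np.roll(seed, off, axis=(0, 1, 2))
    return RealGrid(np.where(keep, eta.values, 0.0), eta.cell, "eta")


def q_statistic(n_eta_iter2: int, n_atoms: int) -> float:
    """Q = N_eta(2) / N, the peak-threshold tuning diagnostic.

    Suitable t_eta values give Q close to 1 (the preservation step never
    uses more than N peaks anyway).
    """
    if n_atoms <= 0:
        raise ValueError("N must be positive")
    return n_eta_iter2 / n_atoms
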