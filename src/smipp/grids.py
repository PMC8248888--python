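"""Periodic real-space grids over the unit cell and exact FFT transforms.

Conventions (fixed package-wide):

* synthesis:  g(x) = (1/V) sum_{full sphere} c_K exp(-2 pi i K.x), evaluated
  at voxel fractional coordinates i/n (0-based, periodic wrap);
* analysis:   c_K = V * ifftn(g)[K mod dims] — the exact inverse of
  synthesis for in-band coefficients;
* F(000) is never carried: every synthesized map is zero-mean.

Coefficient storage is Friedel-unique; the conjugate hemisphere is expanded
only inside the packed FFT array.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np

from .cell import UnitCell

_SMOOTH_PRIMES = (2, 3, 5)


@dataclass
class SpectralCoeffs:
    """Friedel-unique Fourier coefficients |C_K| exp(i alpha_K)."""

    indices: np.ndarray  # (M, 3) int
    amplitude: np.ndarray  # (M,) >= 0
    phase: np.ndarray  # (M,) in [0, 2 pi)

    def __post_init__(self) -> None:
        self.indices = np.atleast_2d(np.asarray(self.indices, dtype=np.int64))
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        self.phase = np.mod(np.asarray(self.phase, dtype=float), 2.0 * np.pi)
        if np.any(self.amplitude < 0):
            raise ValueError("amplitudes must be non-negative")

    @property
    def complex_values(self) -> np.ndarray:
        return self.amplitude * np.exp(1j * self.phase)


@dataclass
class RealGrid:
    """Real scalar field sampled on an n1 x n2 x n3 periodic grid."""

    values: np.ndarray
    cell: UnitCell
    role_tag: str = "rho"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("grid must be three-dimensional")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape

    def sigma(self) -> float:
        """RMS voxel value about zero (maps are zero-mean by construction)."""
        return float(np.sqrt(np.mean(self.values**2)))

    def to_ccp4(self, path: str) -> None:
        """Write the grid as a CCP4/MRC mode-2 map for external viewers."""
        grid = gemmi.FloatGrid(np.asfortranarray(self.values, dtype=np.float32))
        grid.unit_cell = self.cell.gemmi()
        grid.spacegroup = gemmi.SpaceGroup("P1")
        ccp4 = gemmi.Ccp4Map()
        ccp4.grid = grid
        ccp4.update_ccp4_header(2, True)
        ccp4.write_ccp4_map(path)


def _is_smooth(n: int) -> bool:
    for p in _SMOOTH_PRIMES:
        while n % p == 0:
            n //= p
    return n == 1


def next_smooth(n: int) -> int:
    """Smallest 5-smooth integer >= n (FFT-friendly length)."""
    n = max(int(n), 1)
    while not _is_smooth(n):
        n += 1
    return n


def choose_dims(cell: UnitCell, d_min: float, oversample: float = 3.0) -> tuple[int, int, int]:
    """FFT grid dimensions for a given resolution and oversampling factor.

    Each dimension is the smallest 5-smooth integer >= oversample * edge/d_min
    that also satisfies the anti-aliasing bound 2*max|h| + 1 for the indices
    reachable at d_min along that axis.
    """
    if oversample < 2:
        raise ValueError("oversample must be >= 2")
    dims = []
    for edge in cell.lengths:
        hmax = int(np.floor(edge / d_min))
        need = max(int(np.ceil(oversample * edge / d_min)), 2 * hmax + 1)
        dims.append(next_smooth(need))
    return tuple(dims)


def _check_aliasing(indices: np.ndarray, dims) -> None:
    if indices.size == 0:
        return
    for axis in range(3):
        bound = (dims[axis] - 1) // 2
        worst = np.argmax(np.abs(indices[:, axis]))
        if abs(int(indices[worst, axis])) > bound:
            raise ValueError(
                f"index {tuple(int(v) for v in indices[worst])} aliases on a "
                f"{dims[0]}x{dims[1]}x{dims[2]} grid (axis {axis})"
            )


def _pack(coeffs: SpectralCoeffs, dims) -> np.ndarray:
    """Scatter Friedel-unique coefficients into a full-sphere FFT array.

    c_K goes to (-K) mod dims and conj(c_K) to (+K) mod dims so that
    ifftn reproduces exp(-2 pi i K.x) terms.
    """
    arr = np.zeros(dims, dtype=complex)
    if coeffs.indices.size == 0:
        return arr
    vals = coeffs.complex_values
    neg = tuple((-coeffs.indices[:, i]) % dims[i] for i in range(3))
    pos = tuple((coeffs.indices[:, i]) % dims[i] for i in range(3))
    np.add.at(arr, neg, vals)
    np.add.at(arr, pos, np.conj(vals))
    return arr


def synthesize(coeffs: SpectralCoeffs, dims, cell: UnitCell, role_tag: str = "rho") -> RealGrid:
    """Zero-mean real map (1/V) sum_full c_K exp(-2 pi i K.x) on the grid."""
    _check_aliasing(coeffs.indices, dims)
    arr = _pack(coeffs, dims)
    nvox = int(np.prod(dims))
    g = np.fft.ifftn(arr) * (nvox / cell.volume)
    values = g.real
    if coeffs.indices.size:
        scale = max(np.max(np.abs(values)), 1e-300)
        if np.max(np.abs(g.imag)) > 1e-8 * scale:
            raise AssertionError("synthesis produced a non-real grid")
    return RealGrid(values, cell, role_tag)


def analyze(grid: RealGrid, indices) -> SpectralCoeffs:
    """Fourier coefficients of a real grid at the requested Miller indices.

    Exact inverse of `synthesize` for in-band coefficients (round trip
    identical to 1e-9 relative).
    """
    hkl = np.atleast_2d(np.asarray(indices, dtype=np.int64))
    _check_aliasing(hkl, grid.dims)
    spec = np.fft.ifftn(grid.values) * grid.cell.volume
    idx = tuple(hkl[:, i] % grid.dims[i] for i in range(3))
    c = spec[idx]
    return SpectralCoeffs(hkl, np.abs(c), np.angle(c))
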