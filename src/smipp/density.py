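"""Core real/reciprocal-space quantities of the modulus-sum phasing residual.

The phasing function compares two positive-definite maps of similar shape:
|rho|, obtained from the current density rho through a three-valued sign
mask m_rho, and the delta_M synthesis built from the origin-free
experimental coefficients (|E_K| - <|E|>) carried on the calculated phases
alpha_K.  Their product eta = delta_M * m_rho drives the phase update;
agreement is tracked by the correlation CC_M between experimental and
calculated modulus-function amplitudes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import RealGrid, SpectralCoeffs, synthesize

#: mask threshold factors t_rho recommended per scatterer class
T_RHO_DEFAULTS = {"weak": 2.5, "medium": 2.6, "strong": 2.8}


@dataclass
class SigmaStats:
    sigma: float
    n_voxels: int


@dataclass
class MaskGrid:
    """Three-valued sign mask m_rho with values in {-1, 0, +1}."""

    values: np.ndarray
    t_rho: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        extra = set(np.unique(self.values)) - {-1, 0, 1}
        if extra:
            raise ValueError(f"mask values outside {{-1,0,1}}: {extra}")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape


def grid_sigma(grid: RealGrid) -> SigmaStats:
    """RMS voxel value about zero (all syntheses exclude F(000))."""
    return SigmaStats(grid.sigma(), int(np.prod(grid.dims)))


def m_rho_mask(rho: RealGrid, t_rho: float) -> MaskGrid:
    """Sign mask: +1 for rho > 0, 0 down to -t_rho*sigma, -1 below.

    Boundaries belong to the band: rho = 0 and rho = -t_rho*sigma both map
    to 0 (a measure-zero convention fixed for determinism).
    """
    if t_rho <= 0:
        raise ValueError("t_rho must be positive")
    sigma = rho.sigma()
    if sigma == 0:
        raise ValueError("flat map")
    v = rho.values
    mask = np.zeros(v.shape, dtype=np.int8)
    mask[v > 0] = 1
    mask[v < -t_rho * sigma] = -1
    return MaskGrid(mask, t_rho)


def abs_rho(rho: RealGrid, mask: MaskGrid) -> RealGrid:
    """|rho| = m_rho * rho pointwise; non-negative, band voxels exactly 0."""
    if rho.dims != mask.dims:
        raise ValueError("grid/mask dimension mismatch")
    return RealGrid(mask.values * rho.values, rho.cell, "abs_rho")


def rho_synthesis(indices, E, phases, e_min: float, dims, cell) -> RealGrid:
    """Density from |E_K| exp(i phi_K) restricted to |E_K| >= e_min.

    e_min = 0 uses every reflection (the plain algorithm); the ipp variant
    works better with only the large and moderate moduli (e_min near 1.0).
    """
    if e_min < 0:
        raise ValueError("e_min must be non-negative")
    E = np.asarray(E, dtype=float)
    sel = E >= e_min
    if not np.any(sel):
        raise ValueError(f"no reflection with |E| >= {e_min}")
    hkl = np.atleast_2d(np.asarray(indices, dtype=np.int64))
    coeffs = SpectralCoeffs(hkl[sel], E[sel], np.asarray(phases, dtype=float)[sel])
    return synthesize(coeffs, dims, cell, "rho")


def delta_synthesis(indices, E, mean_E: float, alphas, dims, cell) -> RealGrid:
    """delta_M: synthesis of (|E_K| - <|E|>) exp(i alpha_K) over all K.

    With all alpha = 0 this is the origin-free modulus synthesis M, a
    Patterson-type map.
    """
    E = np.asarray(E, dtype=float)
    coeffs = SpectralCoeffs(indices, np.abs(E - mean_E),
                            np.asarray(alphas, dtype=float)
                            + np.pi * (E < mean_E))
    return synthesize(coeffs, dims, cell, "delta")


def eta_product(delta: RealGrid, mask: MaskGrid) -> RealGrid:
    """eta = delta_M * m_rho pointwise."""
    if delta.dims != mask.dims:
        raise ValueError("grid/mask dimension mismatch")
    return RealGrid(delta.values * mask.values, delta.cell, "eta")


def cc_m(E, mean_E: float, C_amplitudes) -> float:
    """Correlation between experimental and calculated modulus amplitudes.

    Centered Pearson correlation of {|E_K| - <|E|>} against {|C_K|};
    scale-free and in [-1, 1].  A sudden increase (typically 0.035-0.045 in
    a few cycles) signals convergence of the phase refinement.
    """
    x = np.asarray(E, dtype=float) - mean_E
    y = np.asarray(C_amplitudes, dtype=float)
    if x.shape != y.shape:
        raise ValueError("mismatched vector lengths")
    xc = x - x.mean()
    yc = y - y.mean()
    nx = np.sqrt(np.sum(xc**2))
    ny = np.sqrt(np.sum(yc**2))
    if nx == 0 or ny == 0:
        raise ValueError("zero-variance input vector")
    return float(np.dot(xc, yc) / (nx * ny))


def r_m_residual(delta: RealGrid, absrho: RealGrid) -> tuple[float, float]:
    """Least-squares residual sum (delta - k |rho|)^2 and its scale k.

    Diagnostic only; the iteration is driven by the tangent update, and
    minimizing this residual is equivalent to maximizing the modulus-sum
    phasing function.
    """
    if delta.dims != absrho.dims:
        raise ValueError("grid dimension mismatch")
    d = delta.values.ravel()
    r = absrho.values.ravel()
    denom = np.dot(r, r)
    if denom == 0:
        raise ValueError("|rho| is identically zero")
    k = float(np.dot(d, r) / denom)
    resid = float(np.sum((d - k * r) ** 2))
    return resid, k
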