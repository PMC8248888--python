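"""Direct-summation structure factors, E-normalization and resolution shells.

Direct summation is the brute-force Fourier oracle of the package: every FFT
synthesis elsewhere is validated against it.  Sign convention, shared by all
modules: F_K = sum_j w_j exp(+2 pi i K.x_j), density via exp(-2 pi i K.x).
"""

from __future__ import annotations

import warnings

import numpy as np

from .cell import Structure, UnitCell


def direct_structure_factors(structure: Structure, indices) -> np.ndarray:
    """Complex F_K for each Miller index by direct summation.

    F_K = sum_j w_j exp(+2 pi i K.x_j); Friedel mates follow by conjugation.
    """
    if structure.n_atoms == 0:
        raise ValueError("no atoms")
    hkl = np.atleast_2d(np.asarray(indices, dtype=np.int64))
    phases = 2.0 * np.pi * hkl @ structure.coords.T  # (M, N)
    return np.exp(1j * phases) @ structure.weights


def normalize_to_E(F, weights) -> np.ndarray:
    """|E_K| = |F_K| / sqrt(sum w_j^2) (point-atom normalization).

    For an equal-atom structure <|E|^2> tends to 1 over a large index set,
    the Wilson statistic for sharp data.
    """
    w = np.asarray(weights, dtype=float)
    s = np.sum(w**2)
    if s <= 0:
        raise ValueError("all-zero weights")
    return np.abs(np.asarray(F)) / np.sqrt(s)


def hkl_shell(cell: UnitCell, d_min: float) -> np.ndarray:
    """Friedel-unique Miller indices with d >= d_min, canonically ordered.

    One member per Friedel pair {K, -K} (representative: first nonzero
    component positive), (0,0,0) excluded, sorted lexicographically.
    The per-axis bound |h| <= a/d_min holds for any cell geometry since
    h = K.a and |K| = 1/d.
    """
    if d_min <= 0:
        raise ValueError("d_min must be positive")
    gcell = cell.gemmi()
    hmax = [int(np.floor(edge / d_min)) for edge in cell.lengths]
    out = []
    for h in range(-hmax[0], hmax[0] + 1):
        for k in range(-hmax[1], hmax[1] + 1):
            for l in range(-hmax[2], hmax[2] + 1):
                if (h, k, l) == (0, 0, 0):
                    continue
                first = h if h != 0 else (k if k != 0 else l)
                if first < 0:
                    continue  # keep the Friedel mate instead
                if gcell.calculate_d((h, k, l)) >= d_min:
                    out.append((h, k, l))
    if not out:
        warnings.warn(f"no reflections with d >= {d_min} A", stacklevel=2)
        return np.empty((0, 3), dtype=np.int64)
    out.sort()
    return np.asarray(out, dtype=np.int64)
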