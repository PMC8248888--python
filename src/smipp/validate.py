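"""Ground-truth scoring with origin and enantiomorph search.

In P1 every origin choice and either hand of the structure is an equally
valid solution, so a raw phase comparison is meaningless.  Scoring instead
computes the translation cross-correlation between the test E-map and the
true E-map over every voxel origin — via a single product transform — for
both the map and its inversion, and reports the global best.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cell import UnitCell
from .grids import RealGrid, SpectralCoeffs, synthesize
from .ipp import find_peaks


@dataclass
class AlignmentResult:
    best_cc: float
    best_shift: tuple[float, float, float]
    inverted: bool
    mean_phase_error: float  # degrees, after alignment

    def __post_init__(self) -> None:
        if not -1.0 - 1e-9 <= self.best_cc <= 1.0 + 1e-9:
            raise ValueError("correlation outside [-1, 1]")


def _emap(phases, E, indices, dims, cell: UnitCell) -> RealGrid:
    return synthesize(SpectralCoeffs(indices, E, phases), dims, cell, "rho")


def _cross_correlation(a: RealGrid, b: RealGrid) -> np.ndarray:
    """corr(u) between a translated by u and b, for every voxel shift u."""
    fa = np.fft.fftn(a.values)
    fb = np.fft.fftn(b.values)
    num = np.fft.ifftn(np.conj(fa) * fb).real
    denom = np.sqrt(np.sum(a.values**2) * np.sum(b.values**2))
    if denom == 0:
        return np.zeros(a.values.shape)
    return num / denom


def align_and_score(test_phases, true_phases, E, indices, dims,
                    cell: UnitCell) -> AlignmentResult:
    """Best aligned E-map correlation over all origins and both hands."""
    indices = np.atleast_2d(np.asarray(indices, dtype=np.int64))
    E = np.asarray(E, dtype=float)
    test_phases = np.asarray(test_phases, dtype=float)
    true_phases = np.asarray(true_phases, dtype=float)
    true_map = _emap(true_phases, E, indices, dims, cell)

    best = (-2.0, (0, 0, 0), False)
    for inverted, phases in ((False, test_phases), (True, -test_phases)):
        corr = _cross_correlation(_emap(phases, E, indices, dims, cell),
                                  true_map)
        vox = np.unravel_index(np.argmax(corr), corr.shape)
        if corr[vox] > best[0]:
            best = (float(corr[vox]), vox, inverted)

    cc, vox, inverted = best
    u = tuple(v / d for v, d in zip(vox, dims))
    sign = -1.0 if inverted else 1.0
    aligned = sign * test_phases + 2.0 * np.pi * (indices @ np.asarray(u))
    dphi = np.angle(np.exp(1j * (aligned - true_phases)))
    mpe = float(np.degrees(np.mean(np.abs(dphi))))
    return AlignmentResult(min(cc, 1.0), u, inverted, mpe)


def classify_success(alignment: AlignmentResult,
                     cc_threshold: float = 0.7) -> bool:
    """A trial is a correct solution when the aligned map CC clears the bar."""
    if not 0.0 < cc_threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    return alignment.best_cc >= cc_threshold


def count_peaks_above(grid: RealGrid, n_sigma: float) -> int:
    """N_p: peaks of the final E-map above the n * sigma threshold."""
    if n_sigma <= 0:
        raise ValueError("threshold multiple must be positive")
    return find_peaks(grid, n_sigma).n_eta
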