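"""In-memory container for a Friedel-unique reflection list."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cell import UnitCell


@dataclass
class ReflectionSet:
    """Friedel-unique Miller indices with normalized moduli |E|.

    <|E|> is fixed at construction over the whole working set and reused by
    every delta synthesis and correlation.  Phases are deliberately absent:
    the phasing engine only ever sees moduli.
    """

    cell: UnitCell
    indices: np.ndarray  # (M, 3) int, Friedel-unique
    E: np.ndarray  # (M,) non-negative
    d_min: float

    mean_E: float = field(init=False)

    def __post_init__(self) -> None:
        self.indices = np.atleast_2d(np.asarray(self.indices, dtype=np.int64))
        self.E = np.asarray(self.E, dtype=float)
        if len(self.indices) != len(self.E):
            raise ValueError("index/modulus length mismatch")
        if np.any(self.E < 0):
            raise ValueError("|E| must be non-negative")
        self._check_friedel_unique()
        self.mean_E = float(np.mean(self.E)) if len(self.E) else 0.0

    def _check_friedel_unique(self) -> None:
        seen: dict[tuple[int, int, int], tuple[int, int, int]] = {}
        for hkl in self.indices:
            key = tuple(int(v) for v in hkl)
            canon = min(key, tuple(-v for v in key))
            if canon in seen:
                raise ValueError(
                    f"duplicate or Friedel-mate duplicate index {key} "
                    f"(clashes with {seen[canon]})"
                )
            seen[canon] = key

    def __len__(self) -> int:
        return len(self.E)

    @property
    def n_reflections(self) -> int:
        return len(self.E)

    def strong_subset(self, e_min: float) -> np.ndarray:
        """Boolean selector for |E| >= e_min."""
        return self.E >= e_min
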