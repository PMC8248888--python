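"""The iterative dual-space phasing loop and its multi-trial driver.

One iteration (the recursive cycle, identical for both variants except for
the density-modification step):

1. rho        <- synthesis of |E| exp(i phi)   (ipp variant: only |E| >= E_min)
2. m_rho      <- sign mask of rho (stored), |rho| <- m_rho * rho
3. (|C|, a)   <- Fourier transform of |rho|;  CC_M from |C| vs |E|
4. delta_M    <- synthesis of (|E| - <|E|>) exp(i a) over all reflections
5. eta        <- delta_M * m_rho
6. ipp only:    keep the 27-voxel cores of the min(N, N_eta) strongest
                eta peaks, zero the rest
7. phi'       <- angular part of the Fourier transform of eta (modified
                tangent formula; amplitudes are discarded)

Starting phases are either random (Phi_rnd) or those of the modulus
synthesis shifted by a random vector u (Phi_M'), one u per trial.
Convergence is a sudden, sustained jump of the CC_M trace.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .density import (
    abs_rho,
    cc_m,
    delta_synthesis,
    eta_product,
    m_rho_mask,
    rho_synthesis,
)
from .grids import analyze, choose_dims
from .ipp import find_peaks, preserve_inner_pixels
from .reflections import ReflectionSet

#: default seed of the shift-vector sequence; deliberately independent of the
#: per-trial phase seeds so the same u sequence serves every dataset
U_SEQUENCE_SEED = 59_093


@dataclass
class PhasingConfig:
    """Tunable parameters of a phase-refinement run.

    t_rho controls the mask threshold (about 2.5 / 2.6 / 2.8 for weak /
    medium / strong scatterer classes); t_eta the peak-acceptance threshold
    (normally 3.5-4.0); e_min the modulus cutoff of the rho synthesis in the
    ipp variant (about 1.0; the plain variant always uses every reflection);
    n_atoms is N, the expected number of non-H atoms in the cell including
    solvent.
    """

    variant: str = "sm_ipp"  # "sm_ipp" or "sm"
    t_rho: float = 2.5
    t_eta: float = 3.7
    e_min: float = 1.0
    n_atoms: int = 1
    n_iter_max: int = 1000
    n_trials: int = 5
    oversample: float = 3.0
    seed: int = 0
    start_mode: str = "random"  # "random" or "shifted_modulus"
    u_seed: int = U_SEQUENCE_SEED
    jump: float = 0.03
    window: int = 5
    stability: float = 0.005
    min_iter: int = 10
    peak_count_override: Optional[int] = None  # e.g. 240 for dominant clusters

    def __post_init__(self) -> None:
        if self.variant not in ("sm", "sm_ipp"):
            raise ValueError("variant must be 'sm' or 'sm_ipp'")
        if self.start_mode not in ("random", "shifted_modulus"):
            raise ValueError("start_mode must be 'random' or 'shifted_modulus'")
        if self.t_rho <= 0 or self.t_eta <= 0:
            raise ValueError("thresholds must be positive")
        if self.e_min < 0:
            raise ValueError("e_min must be non-negative")
        if self.n_atoms < 1 or self.n_iter_max < 1 or self.n_trials < 1:
            raise ValueError("counts must be >= 1")

    @property
    def effective_peak_count(self) -> int:
        return self.peak_count_override or self.n_atoms


@dataclass(frozen=True)
class StartSpec:
    """Starting-phase recipe for one trial."""

    mode: str
    seed: int = 0
    u: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if any(not 0.0 <= v < 1.0 for v in self.u):
            raise ValueError("shift components must lie in [0, 1)")

    def phases(self, indices: np.ndarray) -> np.ndarray:
        if self.mode == "random":
            return start_random(indices, self.seed)
        return start_shifted_modulus(indices, self.u)


def start_random(indices, seed: int) -> np.ndarray:
    """I.i.d. uniform phases on [0, 2 pi), one per Friedel-unique index."""
    rng = np.random.default_rng(seed)
    return rng.uniform(0.0, 2.0 * np.pi, size=len(np.atleast_2d(indices)))


def start_shifted_modulus(indices, u) -> np.ndarray:
    """Phases of the modulus synthesis translated by the shift vector u.

    phi_K = (-2 pi K.u) mod 2 pi, so the delta synthesis computed with these
    phases is the zero-phase modulus synthesis M circularly shifted by u.
    """
    hkl = np.atleast_2d(np.asarray(indices, dtype=np.int64))
    return np.mod(-2.0 * np.pi * hkl @ np.asarray(u, dtype=float), 2.0 * np.pi)


@dataclass
class TrialResult:
    """Traces and outcome of a single phase-refinement trial."""

    cc_trace: np.ndarray
    n_eta_trace: np.ndarray
    n_iter: int
    converged: bool
    final_phases: np.ndarray
    start: StartSpec
    stalled: bool = False
    phase_history: Optional[list[np.ndarray]] = None

    @property
    def q(self) -> Optional[float]:
        """Q = N_eta(2)/N is attached by the driver; raw N_eta(2) here."""
        return None if len(self.n_eta_trace) < 2 else float(self.n_eta_trace[1])

    def iteration_log(self) -> str:
        lines = []
        for i, cc in enumerate(self.cc_trace, start=1):
            n_eta = int(self.n_eta_trace[i - 1]) if len(self.n_eta_trace) >= i else -1
            lines.append(f"{i} {cc:.4f} {n_eta}")
        return "\n".join(lines) + "\n"


def detect_convergence(
    cc_trace,
    window: int = 5,
    jump: float = 0.03,
    stability: float = 0.005,
    min_iter: int = 10,
) -> Optional[int]:
    """First iteration whose CC_M jump marks convergence, or None.

    Fires at the first iteration i >= min_iter with
    cc[i] - cc[i - window] >= jump whose following min(5, remaining)
    iterations stay within `stability` of cc[i].
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    cc = np.asarray(cc_trace, dtype=float)
    n = len(cc)
    for idx in range(max(min_iter - 1, window), n):
        if cc[idx] - cc[idx - window] >= jump:
            m = min(5, n - 1 - idx)
            if np.all(np.abs(cc[idx + 1 : idx + 1 + m] - cc[idx]) <= stability):
                return idx + 1  # iterations are 1-indexed
    return None


def iterate_once(phases, refl: ReflectionSet, dims, config: PhasingConfig):
    """One dual-space cycle; returns (new_phases, cc, n_eta, stalled).

    n_eta is -1 for the plain variant (no peak search is performed).
    """
    use_ipp = config.variant == "sm_ipp"
    e_min = config.e_min if use_ipp else 0.0
    try:
        rho = rho_synthesis(refl.indices, refl.E, phases, e_min, dims, refl.cell)
        mask = m_rho_mask(rho, config.t_rho)
    except ValueError:
        return phases, np.nan, -1, True
    absr = abs_rho(rho, mask)
    coeffs = analyze(absr, refl.indices)
    try:
        cc = cc_m(refl.E, refl.mean_E, coeffs.amplitude)
    except ValueError:
        return phases, np.nan, -1, True
    delta = delta_synthesis(refl.indices, refl.E, refl.mean_E, coeffs.phase,
                            dims, refl.cell)
    eta = eta_product(delta, mask)
    n_eta = -1
    if use_ipp:
        if eta.sigma() == 0:
            return phases, cc, 0, True
        peaks = find_peaks(eta, config.t_eta)
        n_eta = peaks.n_eta
        if n_eta == 0:
            return phases, cc, 0, True
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            eta = preserve_inner_pixels(eta, peaks, config.effective_peak_count)
    if not np.any(eta.values):
        return phases, cc, max(n_eta, 0), True
    new = analyze(eta, refl.indices)
    return new.phase, cc, n_eta, False


def run_trial(
    config: PhasingConfig,
    start: StartSpec,
    refl: ReflectionSet,
    dims,
    record_phases: bool = False,
) -> TrialResult:
    """Iterate from a starting-phase spec until convergence or the cap.

    A stalled trial (flat map or empty peak list) terminates immediately as
    unconverged.  The loop may run up to five iterations past the detected
    convergence point to confirm trace stability; n_iter reports the
    convergence iteration itself.
    """
    phases = start.phases(refl.indices)
    cc_trace: list[float] = []
    n_eta_trace: list[int] = []
    history: list[np.ndarray] = []
    converged = False
    stalled = False
    n_iter = config.n_iter_max
    for it in range(1, config.n_iter_max + 1):
        phases, cc, n_eta, stalled = iterate_once(phases, refl, dims, config)
        cc_trace.append(cc)
        if config.variant == "sm_ipp":
            n_eta_trace.append(n_eta)
        if record_phases:
            history.append(phases.copy())
        if stalled:
            n_iter = it
            break
        hit = detect_convergence(cc_trace, config.window, config.jump,
                                 config.stability, config.min_iter)
        if hit is not None and (len(cc_trace) - hit) >= min(
            5, config.n_iter_max - hit
        ):
            converged = True
            n_iter = hit
            break
    return TrialResult(
        cc_trace=np.asarray(cc_trace),
        n_eta_trace=np.asarray(n_eta_trace, dtype=int),
        n_iter=n_iter,
        converged=converged,
        final_phases=phases,
        start=start,
        stalled=stalled,
        phase_history=history if record_phases else None,
    )


def make_starts(config: PhasingConfig, n_trials: Optional[int] = None) -> list[StartSpec]:
    """Per-trial StartSpecs.

    Random-phase seeds derive from config.seed; the shift-vector sequence
    comes from its own generator (config.u_seed) so that the same u sequence
    is shared by every dataset.
    """
    n = n_trials or config.n_trials
    if config.start_mode == "random":
        ss = np.random.SeedSequence(config.seed)
        seeds = [int(s) % (2**31) for s in ss.generate_state(n)]
        return [StartSpec("random", seed=s) for s in seeds]
    u_rng = np.random.default_rng(config.u_seed)
    us = u_rng.random((n, 3))
    return [StartSpec("shifted_modulus", u=tuple(u)) for u in us]


class PhasingModel:
    """Phase-refinement model bound to one reflection dataset.

    Mirrors the fit/results idiom of statistical modelling packages:
    construct from data plus a configuration, call :meth:`fit` for a single
    trial or :meth:`fit_batch` for the multi-trial protocol.
    """

    def __init__(self, reflections: ReflectionSet, config: PhasingConfig):
        if len(reflections) < 10:
            raise ValueError("need at least 10 reflections")
        self.reflections = reflections
        self.config = config
        self.dims = choose_dims(reflections.cell, reflections.d_min,
                                config.oversample)

    @classmethod
    def from_file(cls, path: str, config: PhasingConfig) -> "PhasingModel":
        from .reflio import read_reflections

        return cls(read_reflections(path), config)

    def fit(self, start: Optional[StartSpec] = None,
            record_phases: bool = False) -> "PhasingResults":
        if start is None:
            start = make_starts(self.config, 1)[0]
        trial = run_trial(self.config, start, self.reflections, self.dims,
                          record_phases=record_phases)
        return PhasingResults(self, trial)

    def fit_batch(self, ground_truth=None,
                  starts: Optional[Sequence[StartSpec]] = None) -> "BatchResults":
        if starts is None:
            starts = make_starts(self.config)
        trials = [run_trial(self.config, s, self.reflections, self.dims)
                  for s in starts]
        return BatchResults(self, trials, ground_truth)

    def fit_matched_pair(self, ground_truth=None,
                         n_trials: Optional[int] = None):
        """Run ipp and plain variants on bitwise-identical starts.

        Returns (ipp_results, plain_results); the k-th trial of each variant
        shares the same StartSpec, making per-trial comparisons strict.
        """
        starts = make_starts(self.config, n_trials)
        ipp_model = PhasingModel(self.reflections,
                                 replace(self.config, variant="sm_ipp"))
        plain_model = PhasingModel(self.reflections,
                                   replace(self.config, variant="sm"))
        return (ipp_model.fit_batch(ground_truth, starts),
                plain_model.fit_batch(ground_truth, starts))


class PhasingResults:
    """Results of a single trial: traces, convergence outcome, diagnostics."""

    def __init__(self, model: PhasingModel, trial: TrialResult):
        self.model = model
        self.trial = trial

    @property
    def cc_trace(self) -> np.ndarray:
        return self.trial.cc_trace

    @property
    def n_eta_trace(self) -> np.ndarray:
        return self.trial.n_eta_trace

    @property
    def converged(self) -> bool:
        return self.trial.converged

    @property
    def n_iter(self) -> int:
        return self.trial.n_iter

    @property
    def final_phases(self) -> np.ndarray:
        return self.trial.final_phases

    @property
    def q(self) -> Optional[float]:
        n2 = self.trial.q
        return None if n2 is None else n2 / self.model.config.n_atoms

    def summary(self) -> str:
        c = self.model.config
        final_cc = self.cc_trace[-1] if len(self.cc_trace) else float("nan")
        lines = [
            "Phase refinement trial",
            f"  variant          {c.variant}",
            f"  start            {self.trial.start.mode}",
            f"  reflections      {len(self.model.reflections)}",
            f"  grid             {self.model.dims[0]}x{self.model.dims[1]}x{self.model.dims[2]}",
            f"  iterations run   {len(self.cc_trace)}",
            f"  converged        {self.converged} (N_iter={self.n_iter if self.converged else 'n.c.'})",
            f"  final CC_M       {final_cc:.3f}",
        ]
        if self.q is not None:
            lines.append(f"  Q = N_eta(2)/N   {self.q:.2f}")
        return "\n".join(lines)

    def plot_trace(self, ax=None):
        """CC_M (and N_eta for the ipp variant) against iteration number."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        it = np.arange(1, len(self.cc_trace) + 1)
        ax.plot(it, self.cc_trace, color="k", label="CC_M")
        ax.set_xlabel("iteration")
        ax.set_ylabel("CC_M")
        if len(self.n_eta_trace):
            ax2 = ax.twinx()
            ax2.plot(it, self.n_eta_trace, color="tab:red", label="N_eta")
            ax2.set_ylabel("N_eta")
        return ax


class BatchResults:
    """Multi-trial results with the success/iteration bookkeeping."""

    def __init__(self, model: PhasingModel, trials: list[TrialResult],
                 ground_truth=None):
        self.model = model
        self.trials = trials
        self.ground_truth = ground_truth
        self._frame: Optional[pd.DataFrame] = None

    def to_frame(self) -> pd.DataFrame:
        if self._frame is not None:
            return self._frame
        n_atoms = self.model.config.n_atoms
        rows = []
        for k, t in enumerate(self.trials, start=1):
            row = {
                "trial": k,
                "converged": t.converged,
                "n_iter": t.n_iter,
                "final_cc": float(t.cc_trace[-1]) if len(t.cc_trace) else np.nan,
                "n_eta_2": int(t.n_eta_trace[1]) if len(t.n_eta_trace) > 1 else -1,
                "q": (t.n_eta_trace[1] / n_atoms
                      if len(t.n_eta_trace) > 1 else np.nan),
            }
            if self.ground_truth is not None:
                from .validate import align_and_score, classify_success

                al = align_and_score(
                    t.final_phases, self.ground_truth.true_phases,
                    self.model.reflections.E, self.model.reflections.indices,
                    self.model.dims, self.model.reflections.cell,
                )
                row["aligned_cc"] = al.best_cc
                row["success"] = classify_success(al)
            rows.append(row)
        self._frame = pd.DataFrame(rows)
        return self._frame

    @property
    def n_converged(self) -> int:
        return sum(t.converged for t in self.trials)

    @property
    def mean_n_iter(self) -> Optional[float]:
        vals = [t.n_iter for t in self.trials if t.converged]
        return float(np.mean(vals)) if vals else None

    def censored_n_iter(self) -> np.ndarray:
        """n_iter with unconverged trials at the iteration cap."""
        return np.array([t.n_iter if t.converged else self.model.config.n_iter_max
                         for t in self.trials])

    @property
    def n_success(self) -> Optional[int]:
        df = self.to_frame()
        return int(df["success"].sum()) if "success" in df else None

    @property
    def mean_q(self) -> float:
        df = self.to_frame()
        return float(df["q"].mean())

    def summary(self) -> str:
        c = self.model.config
        df = self.to_frame()
        nc = len(self.trials) - self.n_converged
        head = [
            "Phase refinement batch",
            f"  variant {c.variant}, start {c.start_mode}, trials {len(self.trials)}",
            f"  t_rho {c.t_rho}, t_eta {c.t_eta}, E_min "
            f"{c.e_min if c.variant == 'sm_ipp' else 0.0}, N {c.n_atoms}",
            f"  converged {self.n_converged}, n.c. {nc}",
        ]
        if self.mean_n_iter is not None:
            head.append(f"  <N_iter> {self.mean_n_iter:.1f} "
                        f"({self.n_converged}x)")
        if self.n_success is not None:
            head.append(f"  successes (aligned CC) {self.n_success}")
        return "\n".join(head) + "\n\n" + df.to_string(index=False)

    def to_tsv(self, path: str) -> None:
        df = self.to_frame().copy()
        df["n_iter"] = [
            str(t.n_iter) if t.converged else "n.c." for t in self.trials
        ]
        df.to_csv(path, sep="\t", index=False)
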