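# Methods

## Model and assumptions

The package implements modulus-sum phasing: the observation that for data
at atomic resolution the positive-definite maps |ρ(Φ)| and δ_M(Φ) have
similar shape, so the phase set Φ can be refined by driving them toward
proportionality. The residual R_M = ∫(δ_M − k|ρ|)² dV is minimized
implicitly by a fixed-point iteration (a modified tangent formula: each
cycle keeps only the angular part of the Fourier transform of the modified
η = δ_M·m_ρ product and re-attaches the experimental moduli). Everything
is formulated in P1 — symmetry-free refinement is advantageous for ab
initio work, and any origin and either enantiomorph of a solution are
equally valid, which dictates how solutions are scored.

Assumptions inherited from the theory and kept by this implementation:

- **Atomic resolution.** δ_M ∝ ρ only holds when the data reach ~1.2 Å or
  better; `make_dataset` warns beyond that.
- **Complete data.** Every Friedel-unique reflection to d_min is present.
  Incompleteness and the structure-factor extrapolation techniques that
  mitigate it are out of scope.
- **Point atoms, P1, ε = 1.** Synthetic data are sharp by construction, so
  E-normalization is the exact point-atom formula |E| = |F|/√(Σw²); no
  Wilson fit, no special positions, no anomalous signal.

## Fixed conventions

All modules share one Fourier sign convention: F_K = Σ w exp(+2πi K·x),
maps via exp(−2πi K·x), with the 1/V factor on synthesis so ρ carries
density units (CC_M and the mask are scale-invariant, so this only affects
reported map values). F(000) is never carried: every map is zero-mean, and
σ is therefore the RMS about zero. Friedel-unique hemisphere storage
(first nonzero index component positive, lexicographic order); the
conjugate mates exist only inside the packed FFT array. Voxel (0,0,0) sits
at fractional (0,0,0), with periodic wrap on all axes. Boundary ties in
the mask go to the band (ρ = 0 and ρ = −t_ρσ_ρ both map to 0) — a
measure-zero choice fixed for determinism. ⟨|E|⟩ is the arithmetic mean
over the working set, fixed at load time. The peak search uses strict
inequality over all 26 periodic neighbors (plateaus yield no peaks), ties
between equal peaks break lexicographically, and no sub-voxel
interpolation exists anywhere, which is what makes ipp FFT-compatible.

## Parameters

| parameter | default | meaning |
| --- | --- | --- |
| t_ρ | 2.5 / 2.6 / 2.8 | mask band depth in σ_ρ units, by scatterer class (weak / medium / strong); `T_RHO_DEFAULTS` |
| t_η | 3.7 | peak-acceptance threshold in σ_η units; useful range 3.5–4.0, tuned so Q = N_η(2)/N ≈ 1 |
| E_min | 1.0 | modulus cutoff of the ρ synthesis in the ipp variant (the plain variant always uses all reflections) |
| N | — | expected non-H atom count including solvent; the ipp step preserves at most N peak cores. `peak_count_override` replaces it for dominant-cluster structures (e.g. 240 = 16²−16 for a 16-atom heavy cluster) |
| solvent factor | 1.22 | N handed to the engine is 1.22× the generated atom count, the mean (protein+water)/protein ratio of the benchmark survey (`smipp.tables`) |
| N_iter_max | 1000 | iteration cap per trial |
| n_trials | 5 | batch size (5/25/50 convention) |
| oversample | 3 | grid sampling factor; 3 keeps η peaks smooth for the 26-neighbor search, 2 is the floor for pure transform work; dimensions are 5-smooth and alias-free |
| jump / window / stability | 0.03 / 5 / 0.005 | convergence detector: CC_M must rise ≥ jump over `window` iterations and then hold within `stability`; detection is gated to iteration ≥ 10 |

The detector thresholds operationalize the observed convergence signature
(a sudden CC_M increase of a few hundredths within a few cycles); they are
config keys, and the ground-truth validator — not the detector — defines
success (aligned map correlation ≥ 0.7, chosen because converged refinements
sit well above it and failures well below; see the worked example).

The shift-vector sequence for Φ_M′ starts comes from its own generator
(`u_seed`, default fixed) so the same u sequence serves every dataset;
per-trial random-phase seeds derive from the run seed.

## Synthetic scenarios

`generate_structure` places point atoms uniformly at random with a
periodic minimum distance (rejection sampling); heavy sites first. Three
scenario families mirror the scatterer classes the thresholds are tuned
for:

- **weak** — 30 C/N/O atoms in a ~13 Å cell at 1.0 Å. Deliberately sparse
  (~73 Å³/atom): the empty space plays the role of the solvent region, and
  small cells keep a 10-trial batch in the tens of seconds. Multi-trial
  phasing solves it from random starts in ~10–20 iterations.
- **medium** — 300 atoms, 10% S, packed at 12 Å³/atom (crystal-like, the
  packing validator's range is 8–30 Å³/atom). This is the smallest scale
  at which grid-noise peak statistics behave as in real protein cells.
- **strong** — 60 atoms with 4 Fe/Zn in a roomy cell, sized so the
  heavy–heavy Patterson vectors resolve: the modulus synthesis demonstrably
  marks them (tested at ≥ 70% of the top n_H²−n_H non-origin peaks).

What the generator does **not** emulate: thermal displacement and static
disorder, measurement error (beyond an optional Gaussian |E| perturbation),
incompleteness, bonded molecular topology, and space-group symmetry.
Consequently a passing suite shows the algorithmic machinery is correct
and that the qualitative orderings (ipp faster than plain; random-start
first-iteration peak counts below N) transfer to desk scale — it does not
certify success rates on deposited data.

One qualitative regime does not survive miniaturization: with
shifted-modulus starts on exact point-atom data the first-iteration peak
count N_η(1) stays well below N (~0.15–0.2 N across 40–1500 atoms and a
wide packing/resolution range), whereas protein-scale experimental data
show N_η(1) ≫ N. The shifted modulus synthesis of a small exact crystal is
spike-dominated — a few heavy–heavy vectors carry the tail of the η
distribution, inflating σ_η so that almost nothing clears t_η·σ_η — while
the corresponding map of a large, thermally smeared structure is
mush-dominated and thousands of modest vector peaks clear the same
relative threshold. The test asserting both regimes is kept and the
shifted-start half fails honestly; the random-start half (N_η(1) < N) is
robust at crystal-like packing.

## Numerical choices

- FFT syntheses are validated against per-voxel direct summation (1e−9
  relative) and the analyze∘synthesize round trip is the identity on
  in-band coefficients; aliasing is impossible by construction
  (dims ≥ 2·max|index|+1, enforced with an error naming the offending
  index).
- Negative δ_M coefficients (|E| < ⟨|E|⟩) are stored as positive
  amplitudes with a π phase offset.
- A stalled trial (flat map, zero-variance |C|, or an empty peak list)
  terminates immediately as unconverged rather than raising — batches
  always complete.
- Stochastic acceptance checks (success rate, matched-pair medians) run
  ten trials of up to 500 iterations on the weak scenario; contract checks
  use 100–200 random 12³–16³ grids. These sizes keep the whole suite
  around two minutes while leaving each check statistically unambiguous.
- Unconverged trials enter median-iteration comparisons at the cap
  (censoring); both variants share the cap, so this is conservative for
  the ipp-faster ordering.
- Alignment scans every voxel origin via one product transform per hand;
  there is no sub-voxel origin refinement (adequate at oversample 3).

## Known limitations

- P1 only; no symmetry expansion, no per-reflection weighting, no
  refinement driven by R_M (it is reported as a diagnostic).
- The quasi-fixed point of the iteration is not exactly the true phase
  set: started from the truth with the solvent-inflated N, the preserved
  spurious peaks let the solution drift slowly (aligned CC ~0.87 after 50
  cycles on one seed); with N equal to the true atom count it holds at
  ≥ 0.93. Converged solutions correspondingly score 0.85–0.92, not 1.0.
- CC_M is rendered as the centered Pearson correlation between
  {|E|−⟨|E|⟩} and {|C|}: scale-free, in [−1,1], and on the scale of
  published converged values (~0.8). Its maximum is flat near the solution
  (within ~0.02 over a 30% phase perturbation), so it is a convergence
  signal, not a refinement target — R_M's minimum, which sits exactly at
  the truth, is.
- The MTZ/mmCIF adapter's shell-wise E-normalization of F columns is
  best-effort (20 equal-volume shells) and is not exercised against
  deposited data in the test suite.
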