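# smipp — dual-space |ρ|-based phasing with inner-pixel preservation

`smipp` solves the crystallographic phase problem *ab initio* for P1
structures at atomic resolution: given only normalized structure-factor
moduli |E<sub>K</sub>| (plus the unit cell and resolution limit), it
recovers the phases φ<sub>K</sub> — and therefore the electron density —
by an iterative dual-space FFT algorithm. It is aimed at method developers
and students of direct methods who want a compact, fully testable
implementation of modulus-sum phasing with a built-in synthetic-crystal
laboratory, rather than at production structure solution.

## The algorithm

Each cycle alternates between real and reciprocal space:

1. **ρ synthesis** — current phases are combined with the experimental
   moduli, ρ = FT⁻¹(|E| e<sup>iφ</sup>) (the ipp variant restricts this
   synthesis to reflections with |E| ≥ |E|<sub>min</sub> ≈ 1.0).
2. **Sign mask** — m<sub>ρ</sub> = +1 where ρ > 0, 0 down to
   −t<sub>ρ</sub>σ<sub>ρ</sub>, −1 below; |ρ| = m<sub>ρ</sub>·ρ is
   positive-definite. t<sub>ρ</sub> ≈ 2.5 / 2.6 / 2.8 for weak / medium /
   strong scatterer content.
3. **Modulus-function comparison** — the transform of |ρ| gives
   |C<sub>K</sub>| e<sup>iα<sub>K</sub></sup>; the correlation CC<sub>M</sub>
   between {|E<sub>K</sub>| − ⟨|E|⟩} and {|C<sub>K</sub>|} tracks progress,
   and minimizing the residual R<sub>M</sub> = ∫(δ<sub>M</sub> − k|ρ|)² dV
   is the quantity the iteration is implicitly descending.
4. **δ<sub>M</sub> synthesis** — the origin-free coefficients
   (|E<sub>K</sub>| − ⟨|E|⟩) e<sup>iα<sub>K</sub></sup> over *all*
   reflections give the Patterson-like δ<sub>M</sub> map; with all α = 0
   this is the modulus synthesis M.
5. **η product and ipp** — η = δ<sub>M</sub>·m<sub>ρ</sub>. The
   inner-pixel-preservation step finds all strict 26-neighbor maxima of η
   above t<sub>η</sub>σ<sub>η</sub> (t<sub>η</sub> ≈ 3.5–4.0), keeps the
   27-voxel cores of the min(N, N<sub>η</sub>) strongest peaks (N = expected
   atom count including solvent) and zeroes the rest.
6. **Modified tangent formula** — the new phases are the angular part of
   the transform of the modified η; amplitudes are discarded and the
   experimental |E| re-attached on the next cycle.

Trials start either from random phases (Φ<sub>rnd</sub>) or from the
modulus synthesis shifted by a random vector **u** (Φ<sub>M′</sub>).
Convergence announces itself as a sudden, sustained jump of the
CC<sub>M</sub> trace accompanied by a drop in N<sub>η</sub>; solutions are
scored against ground truth by an exhaustive origin/enantiomorph map
correlation, as P1 makes every origin and either hand equivalent.

## Worked example

```python
from smipp import PhasingConfig, PhasingModel
from smipp.simulate import weak_scenario, generate_structure, make_dataset

spec = weak_scenario(seed=11)            # 30 C/N/O atoms, ~13 A cell, 1.0 A
structure = generate_structure(spec)
refl, truth = make_dataset(structure, spec.d_min)   # exact |E|, blind engine

config = PhasingConfig(variant="sm_ipp", t_rho=2.5, t_eta=3.7,
                       n_atoms=truth.n_engine, n_iter_max=200,
                       n_trials=5, seed=1)
batch = PhasingModel(refl, config).fit_batch(ground_truth=truth)
print(batch.summary())
```

prints

```
Phase refinement batch
  variant sm_ipp, start random, trials 5
  t_rho 2.5, t_eta 3.7, E_min 1.0, N 37
  converged 4, n.c. 1
  <N_iter> 10.0 (4x)
  successes (aligned CC) 4

 trial  converged  n_iter  final_cc  n_eta_2        q  aligned_cc  success
     1       True      10  0.877019      186 5.027027    0.868212     True
     2       True      10  0.879394      174 4.702703    0.893922     True
     3       True      10  0.877350      184 4.972973    0.910989     True
     4       True      10  0.877538      194 5.243243    0.871412     True
     5      False     200  0.628772      194 5.243243    0.095014    False
```

Four of five random-start trials converge in ten iterations with final
CC<sub>M</sub> ≈ 0.88; their maps correlate at 0.87–0.91 with the ground
truth after origin/enantiomorph alignment (≥ 0.7 counts as solved). The
fifth trial never jumps and its map is uncorrelated — the normal fate of
an unlucky start in multisolution phasing. `q` is N<sub>η</sub>(2)/N, the
diagnostic used to tune t<sub>η</sub>.

The same pipeline is scriptable from a shell:

```sh
smipp simulate --scenario weak --seed 11 --out weak.txt
smipp phase weak.txt --n-trials 5 --seed 1 --out batch.tsv
smipp bench weak.txt --n-trials 10 --seed 1 --out bench.tsv   # ipp vs plain
```

## Layout

| module | contents |
| --- | --- |
| `smipp.cell` | unit cells, point-atom structures, PDB export |
| `smipp.sfactors` | direct-summation structure factors, E-normalization, resolution shells |
| `smipp.grids` | periodic grids, exact FFT synthesis/analysis, CCP4 export |
| `smipp.density` | σ statistics, m<sub>ρ</sub> mask, ρ/δ<sub>M</sub>/η syntheses, CC<sub>M</sub>, R<sub>M</sub> |
| `smipp.ipp` | 26-neighbor peak search, inner-pixel preservation, Q statistic |
| `smipp.engine` | the iteration, start generators, convergence detection, `PhasingModel`/results |
| `smipp.simulate` | synthetic scenario generators and exact datasets |
| `smipp.validate` | origin/enantiomorph alignment, success classification, peak counting |
| `smipp.reflio`, `smipp.cli` | text reflection format, MTZ/mmCIF adapter, YAML config, CLI |
| `smipp.tables` | benchmark-structure survey and derived constants |

See `docs/methods.md` for the model assumptions, parameter defaults and
known limitations.
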