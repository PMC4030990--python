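# fireflyfold

Protein structure prediction on 3D lattices with a firefly-guided,
population-based simulated-annealing search over pull moves.

## The problem

Lattice models reduce a protein to a self-avoiding walk on a regular 3D
graph — here the **cubic** lattice (6 neighbours per node) or the
**face-centred-cubic (FCC)** lattice (12 neighbours) — with one residue per
node.  Finding the embedding of minimum free energy is NP-hard even in the
simplest energy models, so practical structure prediction on lattices is a
question of heuristic search efficiency: how many objective-function
evaluations does it take to reach the known optimum of a benchmark sequence?

Two energy models are supported:

* **H-P (HP100)** — residues are hydrophobic (`h`) or polar (`p`), and

  `E = −(number of non-consecutive h–h lattice contacts)`,

  where a *contact* is a pair of residues on adjacent lattice nodes that are
  not neighbours in the chain;
* **pairwise contact matrix** (Miyazawa–Jernigan style) —

  `E = Σ_{i>j} e(a_i, a_j) · D(r_i − r_j)`,

  with `e` a symmetric 20×20 contact-energy matrix and `D = 1` exactly for
  non-covalent lattice contacts.  A transcription of the MJb
  (solvent-expulsion) matrix and a clearly-labelled synthetic
  hydropathy-based surrogate ship as packaged data files, and user matrices
  load from plain text.

## The search

The conformational neighbourhood is the **pull-move set** (with the end-move
repair that makes it fully reversible — see `docs/methods.md`).  The search
keeps a population of `N` conformations, each on its own infinite lattice:

1. initialise each member as a random self-avoiding walk and descend it
   greedily to a pull-move local minimum;
2. elect the lowest-energy member `S_best`;
3. for `T` shared steps: `S_best` proposes pull moves accepted by the
   Metropolis rule `exp(−|ΔE|/T_n)` under the geometric schedule
   `T_n = 4000·0.9999ⁿ`, while every other member proposes pull moves judged
   by a *structural* objective — the mean absolute change of its residues'
   Euclidean distances to a frozen snapshot of `S_best` (the "firefly"
   attraction: dimmer members drift toward the brightest one);
4. after each interval, re-elect `S_best` (ties broken at random) and repeat
   until an interval passes with no accepted annealing move and an unchanged
   `S_best`.

Cost is reported hardware-independently as **Oval**, the total number of
objective evaluations:

`Oval = Σᵢ Initᵢ + N·(k·T + T′) + (k+1)(N−1)`

(initialisation descents + one evaluation per member per step + the
re-elections).  `speed_up = Eval_avg / Oval_avg` compares against published
energy-evaluation counts.

## Worked example

```sh
fireflyfold fold hhhh --model hp --lattice cubic --seed 1 --max-steps 60
```

prints (abbreviated):

```json
{
  "best_energy": -1.0,
  "terminated_by": "max_steps",
  "k": 3,
  "t_prime": 15,
  "oval_total": 1776,
  "oval_decomposition": {
    "init": 1268, "energy": 60, "structural": 420, "reelection": 28
  },
  "effective_config": { "population_size": 8, "interval": 15,
                        "t0": 4000.0, "theta": 0.9999, "seed": 1 }
}
```

`best_energy = −1` is the exact optimum of the 4-mer `hhhh` on the cubic
lattice (verify with `fireflyfold enumerate hhhh`, which scans every
conformation).  The run took `k·T + T′ = 60` shared steps; 1268 evaluations
were spent descending the 8 initial walks, 60 on the annealing member, 420
(= 60 × 7) on the structural objective of the other members and 28
(= 4 × 7) on re-elections — summing to `oval_total`.  The full effective
configuration, including the seed, is recorded so the run can be reproduced
byte-for-byte.

Other entry points: `fireflyfold energy` re-scores a saved conformation
table, and `fireflyfold benchmark` drives seeded repeats over the twenty
packaged benchmark sequences (ten length-48 H-P chains with published cubic
and FCC minima, six length-48 contact-matrix chains, and four 54–61-residue
proteins for the FCC lattice).  Everything is also available as a library:

```python
from fireflyfold import CUBIC, HPModel, AnnealParams, FireflyParams, run_search
res = run_search("hphhpphh", CUBIC, HPModel(), AnnealParams(),
                 FireflyParams(seed=1, max_steps=1000))
print(res.best_energy, res.oval_total)
```

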