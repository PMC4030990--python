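# Methods

## Lattices and conformations

Both lattices are represented with exact integer arithmetic:

* **cubic** — all integer triples; two nodes are adjacent when their
  coordinate deltas satisfy `|Δx| + |Δy| + |Δz| = 1` (6 neighbours);
* **FCC** — the integer triples with even coordinate sum; adjacency holds
  when every delta is at most 1 in magnitude and `|Δx| + |Δy| + |Δz| = 2`,
  i.e. the 12 offsets that are permutations of (±1, ±1, 0).

The even-sum integer representation realises the FCC adjacency rule exactly
while keeping every test integral; the conventional real-space basis matrix
is stored only for Cartesian export (visualisation), where an even-sum point
is decomposed onto the primitive vectors (1,1,0), (1,0,1), (0,1,1).
Floating-point basis combinations would make adjacency tests fragile, so
they are never used operationally.

A conformation is a sequence plus an ordered list of nodes forming a
self-avoiding walk; each conformation owns its own occupancy map over
unbounded signed coordinates (a private "infinite lattice"), so population
members never block one another.  A *contact* is a non-consecutive residue
pair on adjacent nodes; both energy models are plain sums over the contact
set and are recomputed from scratch at every evaluation so that evaluation
counters correspond one-to-one with energy-function calls.

Initial conformations are grown incrementally, choosing uniformly among
unoccupied neighbour sites and restarting on dead ends (budget 1000
restarts).  The distribution over walks is therefore not uniform; nothing in
the method requires uniformity, only seeded reproducibility.

## Contact matrices

Matrices load from `#`-commented delimited text (full, checked symmetric to
1e-12, or lower-triangular, mirrored).  Two files ship with the package:

* `mjb_contact_energies.tsv` — an entry-by-entry transcription of the
  Miyazawa–Jernigan contact energies (solvent-expulsion variant, RT units),
  with a sha256 checksum of the numeric body recorded in the header at
  transcription time.  Individual entries may carry transcription error, and
  published benchmark minima for matrix models depend on exactly which
  variant/scaling of the matrix a study used — energies computed here are
  internally consistent but not guaranteed to be on the scale of any given
  published table.
* `berrera_synthetic_contact_energies.tsv` — a **synthetic** surrogate
  (`e(u,v) = −0.025·(KD(u)+4.5)·(KD(v)+4.5) − 0.2`, Kyte–Doolittle
  hydropathies), provided so the FCC contact-matrix pipeline runs
  end-to-end.  It is labelled synthetic in the filename and header and its
  energies are not comparable to published values.

## The pull-move set

A pull move relocates residue `i` to a free site `L` adjacent to its fixed
chain neighbour and repairs the chain on the other side.  Classes:

* **single-site move** — the chain reconnects immediately: either `L` is
  adjacent to the drag-side neighbour's current site (the square's fourth
  corner `C` coincides with that neighbour), or `i` is a chain end;
* **standard pull** — a free fourth corner `C` (any free common neighbour of
  `L` and the old site on the FCC lattice) receives the drag-side neighbour,
  and further residues follow pairwise: residue `j` takes the old site of
  residue `j ± 2`;
* **two-site end pull** — a chain end relocates through a free site pair
  (`C` adjacent to the end's current site, `L` adjacent to `C`), dragging
  the chain behind it.

Propagation admits *every* chain-reconnecting depth, not only the first.
Both repairs matter for reversibility, which the classical formulation
breaks in two places:

1. a pull that propagates all the way to a chain end leaves a conformation
   whose inverse must *push* the chain back from that end — that inverse is
   the two-site end pull;
2. the inverse of a deep end pull must sometimes keep dragging past the
   first depth at which the chain happens to reconnect.  Worked 3-mer
   example on the cubic lattice (x–y plane, chain 0–1–2):

   ```
   before:  2 1 0        after:   . 1'0'
            . . .                 . 2 .
   ```

   the end pull moves residue 0 to `L`, residue 1 to `C` and residue 2 into
   residue 0's old site.  Undoing it from the right-hand conformation
   requires an end pull at residue 2 that drags residue 0 even though
   residue 0's site is already adjacent to `C` — a depth the first-valid
   stopping rule would never reach.

With both repairs the set is closed under inversion: the test suite verifies
exhaustively, for every self-avoiding walk of length ≤ 6 on both lattices
(one representative per symmetry orbit — enumeration commutes with the 48
signed coordinate permutations), that every enumerated move applies to a
valid conformation and has an enumerated inverse, and that breadth-first
search over pull moves from a straight cubic 5-mer reaches the full
enumerated conformation set.  Moves are validated against the current
conformation when applied; a stale move raises instead of corrupting the
chain.

Greedy descent scores every legal move, picks uniformly at random among the
strictly improving ones (seeded), and stops when none improves — which
certifies a pull-move local minimum.  Termination is guaranteed because the
energy strictly decreases over a finite conformation set.

## Search parameters

| parameter | default | meaning |
|---|---|---|
| `t0` | 4000 | initial annealing temperature (energy units) |
| `theta` | 0.9999 | geometric cooling factor, `T_n = t0·theta**n` |
| `N` (`population_size`) | 8 | population members |
| `T` (`interval`) | 15 | steps between re-elections of `S_best` |
| `max_steps` | 5·10⁶ | safety cap on shared steps |
| `sof_mode` | `history` | structural-acceptance semantics (below) |

The defaults are the production settings used for the packaged benchmarks;
the shared step counter `n` advances once per population step, not per
member, so every member sees the same acceptance temperature at a given
step.  The Metropolis rule uses `|ΔE|`, so equal-energy proposals are always
accepted.  Proposals are drawn uniformly from the enumerated legal move
list.  One master seed spawns independent per-member streams (member
updates are order-independent); re-election tie-breaks draw from the master
stream.  Termination requires both conditions in the same interval: no
accepted annealing move for the elected member, and re-election returning
the same member.

### Structural objective

For a proposed move of member `i` displacing residues `j..k` (`m = k−j+1`),
with `d_t` the Euclidean distance of residue `t` to the interval's `S_best`
snapshot in raw lattice coordinates:

`sof = (1/m) Σ_{t=j}^{k} | d_t(before) − d_t(after) |`

Conformations are generated anchored at the origin and never re-centred, so
inter-conformation distances are measured in that common frame with no
superposition — a deliberate design choice; no alignment step is defined by
the objective itself.

The acceptance rule compares sof values at successive steps, which leaves
the baseline ambiguous.  Two readings are implemented:

* `history` (default): accept iff the member's previously *accepted* move's
  sof is ≥ the proposal's sof; the baseline resets to +∞ at each interval
  start so the first proposal of an interval is never frozen out;
* `distance`: accept iff the summed distance to the snapshot over the
  affected range does not increase (pure attraction).

Neither reading is asserted as canonical; both are tested.

### Evaluation accounting

`Oval = Σᵢ Initᵢ + N·(k·T + T′) + (k+1)(N−1)`, where `Initᵢ` counts the
evaluations of member `i`'s initial greedy descent, each shared step costs
one energy evaluation (elected member) plus `N−1` structural evaluations,
and each interval ends with an `N−1`-evaluation re-election (the elected
member's energy is already tracked; the initial election after descent is
likewise free).  `k` counts complete intervals before the final one and
`T′` is the final interval's length: `T′ = T` on converged runs (termination
is checked only at interval boundaries), and `T′ < T` only when the step cap
cuts an interval short, in which case a closing re-election is still
performed so the closed form holds exactly.  The accounting is asserted
exactly — raw counters, closed form and the reported total must agree — in
both the unit and acceptance suites.  A degenerate `N = 1` population
reduces to plain simulated annealing with zero structural and re-election
evaluations (the population-size floor is relaxed to 1 for exactly this
reduction).

## Problem sizes and what the tests show

Exhaustive oracles (contact/energy brute force, move reversibility,
BFS completeness) run on walks up to length 8 (cubic) / 6 (FCC) — beyond
that the walk count grows exponentially and the enumeration guard refuses.
Toy-optimality checks run 20 seeded searches of ≤ 300 steps on designed
sequences of length ≤ 8 whose optima are enumerated exactly.  Benchmark
runs in the test suite and the acceptance script are step-capped (15–30
shared steps after initialisation): they demonstrate monotone progress,
structural validity and exact accounting at the production parameter
settings, not convergence to the published minima — full runs to the
natural termination rule take hours per sequence and are available through
the benchmark driver with an uncapped budget.  The driver stores published
reference energies as metadata only; the search never sees them unless the
clearly-labelled `stop_at_reference` smoke flag is set.

## Known limitations

* The MJb transcription and especially the synthetic hydropathy matrix mean
  contact-matrix energies are not comparable across studies without
  confirming the matrix variant and units; observed energies here sit on a
  different scale from some published 48-mer benchmark minima.
* The origin-anchored distance frame makes the structural objective
  sensitive to absolute position: two structurally identical conformations
  displaced in space have nonzero distance.  This is faithful to the
  vector-space reading of the objective but is a modelling choice.
* Pull-move completeness is verified empirically for short chains only; no
  proof-level claim is made for the FCC lattice.
* The search neighbourhood is enumerated in full at every proposal, which
  dominates runtime for long chains; counters, not wall-clock time, are the
  intended cost measure.
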