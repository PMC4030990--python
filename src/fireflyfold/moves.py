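"""Pull-move neighbourhood on cubic and FCC lattices.

A pull move relocates one residue to a free site adjacent to its fixed
neighbour along the chain and repairs the chain on the opposite side by
pulling trailing residues two chain positions forward until the walk is valid
again.  The move set implemented here comprises:

* **single-site moves** — the relocated residue reconnects immediately
  (through the fourth corner of a lattice square already holding its chain
  neighbour, or, on the FCC lattice, by direct adjacency of the new site);
* **standard pulls** — the chain neighbour on the pulled side moves into the
  square-completing site and further residues follow pairwise until the chain
  reconnects;
* **simple end moves** — a chain end relocates to any free neighbour of the
  adjacent residue's site;
* **two-site end pulls** — a chain end relocates through a free pair of sites
  (a free site C adjacent to the end's current position and a free site L
  adjacent to C), dragging the chain behind it.  This last class is the
  repair that makes pulls which propagate all the way to a chain end
  reversible; without it the inverse of a full-chain pull is not in the move
  set.  See ``docs/methods.md`` for a worked diagram.

All moves are validated against the current conformation at application time;
applying a stale move raises instead of silently corrupting the chain.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .energy import EnergyModel
from .lattice import Conformation, Point

__all__ = [
    "PullMove",
    "IllegalMoveError",
    "EvalCounter",
    "enumerate_pull_moves",
    "apply_pull_move",
    "greedy_descent",
    "descend_with_energy",
]


class IllegalMoveError(ValueError):
    """The move is not legal for the conformation it was applied to."""


@dataclass(frozen=True)
class PullMove:
    """A reversible local modification of a conformation.

    ``changes`` maps each affected residue index to its new site; ``source``
    records the sites those residues occupied when the move was enumerated
    (used to detect stale application).  ``affected_range`` is the inclusive
    index span (j, k); every index inside it moves, none outside it does.
    """

    anchor_index: int
    target: Point
    auxiliary: Point | None
    affected_range: tuple[int, int]
    direction: str  # "toward_head": dragged residues have lower indices
    changes: tuple[tuple[int, Point], ...]
    source: tuple[tuple[int, Point], ...]

    @property
    def width(self) -> int:
        j, k = self.affected_range
        return k - j + 1

    def reverse_key(self) -> tuple[tuple[int, Point], ...]:
        return self.source


class EvalCounter:
    """Counts objective-function evaluations."""

    __slots__ = ("n",)

    def __init__(self) -> None:
        self.n = 0

    def add(self, k: int = 1) -> None:
        self.n += k

    def __repr__(self) -> str:
        return f"EvalCounter(n={self.n})"


def _common_neighbors(a: Point, b: Point, conf: Conformation) -> list[Point]:
    lat = conf.lattice
    ax, ay, az = a
    out = []
    for dx, dy, dz in lat.neighbor_offsets:
        c = (ax + dx, ay + dy, az + dz)
        if lat.is_adjacent(c, b):
            out.append(c)
    return out


def _make_move(
    conf: Conformation,
    anchor: int,
    target: Point,
    auxiliary: Point | None,
    direction: str,
    changes: dict[int, Point],
) -> PullMove:
    idxs = sorted(changes)
    return PullMove(
        anchor_index=anchor,
        target=target,
        auxiliary=auxiliary,
        affected_range=(idxs[0], idxs[-1]),
        direction=direction,
        changes=tuple((i, changes[i]) for i in idxs),
        source=tuple((i, conf.coords[i]) for i in idxs),
    )


def _propagate_variants(
    conf: Conformation, base: dict[int, Point], start: int, step: int
) -> list[dict[int, Point]]:
    """All valid pull propagations from ``start`` in the direction of ``step``.

    Dragged residues take the old site of the residue two chain positions
    closer to the initiating end (new[j] = old[j - 2*step]).  The chain is
    valid at every depth at which the next residue's old site is adjacent to
    the last dragged residue's new site — the classical rule stops at the
    first such depth, but the deeper variants are kept too: they are the
    inverses of pulls that propagated into a chain end, and dropping them is
    what breaks reversibility.
    """
    pos = conf.coords
    lat = conf.lattice
    n = len(pos)
    variants: list[dict[int, Point]] = []
    changes = dict(base)
    j = start
    while True:
        if not (0 <= j < n):
            variants.append(dict(changes))  # pulled through to the chain end
            break
        if lat.is_adjacent(pos[j], changes[j - step]):
            variants.append(dict(changes))  # chain reconnects here
        changes[j] = pos[j - 2 * step]
        j += step
    return variants


def enumerate_pull_moves(conf: Conformation) -> list[PullMove]:
    """All legal pull moves from ``conf``, deduplicated by effect and in a
    deterministic order (anchor index, then target site)."""
    n = len(conf)
    pos = conf.coords
    lat = conf.lattice
    moves: list[PullMove] = []
    seen: set[tuple[tuple[int, Point], ...]] = set()

    def emit(move: PullMove) -> None:
        if move.changes not in seen:
            seen.add(move.changes)
            moves.append(move)

    if n < 2:
        return moves  # a single residue has no pull moves (documented convention)

    for direction, fstep in (("toward_head", 1), ("toward_tail", -1)):
        # fstep: index offset of the fixed neighbour; drag side is -fstep.
        lo = 0 if fstep == 1 else 1
        hi = n - 2 if fstep == 1 else n - 1
        for i in range(lo, hi + 1):
            f = i + fstep
            d = i - fstep
            at_end = not (0 <= d < n)
            fx, fy, fz = pos[f]
            for dx, dy, dz in lat.neighbor_offsets:
                L = (fx + dx, fy + dy, fz + dz)
                if conf.occupied(L):
                    continue
                if at_end:
                    emit(_make_move(conf, i, L, None, direction, {i: L}))
                    continue
                for C in _common_neighbors(L, pos[i], conf):
                    if C == pos[d]:
                        # chain reconnects through the drag-side neighbour:
                        # a single-residue relocation
                        emit(_make_move(conf, i, L, None, direction, {i: L}))
                    elif not conf.occupied(C) and C != L:
                        for changes in _propagate_variants(
                            conf, {i: L, d: C}, d - fstep, -fstep
                        ):
                            emit(_make_move(conf, i, L, C, direction, changes))

    # Two-site end pulls: the end residue moves through a free site pair,
    # dragging the chain behind it.
    for e, step, direction in ((0, 1, "toward_tail"), (n - 1, -1, "toward_head")):
        if n < 3:
            break
        ex, ey, ez = pos[e]
        for dx, dy, dz in lat.neighbor_offsets:
            C = (ex + dx, ey + dy, ez + dz)
            if conf.occupied(C):
                continue
            cx, cy, cz = C
            for dx2, dy2, dz2 in lat.neighbor_offsets:
                L = (cx + dx2, cy + dy2, cz + dz2)
                if conf.occupied(L) or L == C:
                    continue
                for changes in _propagate_variants(
                    conf, {e: L, e + step: C}, e + 2 * step, step
                ):
                    emit(_make_move(conf, e, L, C, direction, changes))

    moves.sort(key=lambda m: (m.anchor_index, m.target, m.direction, m.changes))
    return moves


def apply_pull_move(conf: Conformation, move: PullMove) -> Conformation:
    """Apply ``move`` to ``conf``, returning a new valid conformation.

    The move is re-validated against ``conf``: the affected residues must sit
    where they sat at enumeration time and every target site must be free of
    unaffected residues.  ``conf`` itself is never modified.
    """
    n = len(conf)
    changed = dict(move.changes)
    for idx, src in move.source:
        if not (0 <= idx < n):
            raise IllegalMoveError(f"move index {idx} out of range for length {n}")
        if conf.coords[idx] != src:
            raise IllegalMoveError(
                f"stale move: residue {idx} is at {conf.coords[idx]}, "
                f"move was enumerated with it at {src}"
            )
    for idx, newpos in move.changes:
        holder = conf.index_at(newpos)
        if holder is not None and holder not in changed:
            raise IllegalMoveError(
                f"target site {newpos} for residue {idx} is occupied by "
                f"residue {holder}"
            )
    coords = list(conf.coords)
    for idx, newpos in move.changes:
        coords[idx] = newpos
    try:
        return conf.with_coords(coords)
    except Exception as exc:  # invariant violation -> illegal move, conf unchanged
        raise IllegalMoveError(f"move produces an invalid conformation: {exc}") from exc


def descend_with_energy(
    conf: Conformation,
    model: EnergyModel,
    rng: np.random.Generator,
    counter: EvalCounter | None = None,
) -> tuple[Conformation, float]:
    """Greedy pull-move descent to a local minimum; returns (conformation,
    energy).  Every energy evaluation increments ``counter``.

    At each step all legal moves are scored and one strictly improving move is
    chosen uniformly at random (seeded); descent terminates when no single
    pull move lowers the energy, which certifies a local minimum.
    """
    counter = counter if counter is not None else EvalCounter()
    current = conf
    e_cur = model.evaluate(current)
    counter.add()
    while True:
        improving: list[tuple[Conformation, float]] = []
        for move in enumerate_pull_moves(current):
            cand = apply_pull_move(current, move)
            e_new = model.evaluate(cand)
            counter.add()
            if e_new < e_cur:
                improving.append((cand, e_new))
        if not improving:
            return current, e_cur
        current, e_cur = improving[int(rng.integers(len(improving)))]


def greedy_descent(
    conf: Conformation,
    model: EnergyModel,
    rng: np.random.Generator,
    counter: EvalCounter | None = None,
) -> Conformation:
    """Greedy pull-move descent to a local minimum (see
    :func:`descend_with_energy`)."""
    best, _ = descend_with_energy(conf, model, rng, counter)
    return best
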