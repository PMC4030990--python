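"""Lattice geometry, self-avoiding-walk conformations and contact enumeration.

Two three-dimensional lattices are supported:

* the simple **cubic** lattice (integer points, 6 neighbours; two points are
  adjacent when their Manhattan distance is 1), and
* the **face-centred-cubic (FCC)** lattice, represented as the integer points
  with even coordinate sum; the 12 neighbour offsets are the permutations of
  (±1, ±1, 0).  Two FCC points are adjacent when every coordinate delta has
  absolute value at most 1 and the deltas sum (in absolute value) to 2.

A protein conformation is a self-avoiding walk on one of these lattices with
one residue per node.  Each conformation owns its own (conceptually infinite)
lattice: occupancy is tracked per conformation on unbounded signed integer
coordinates, so population members never collide with one another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Sequence, TextIO

import numpy as np

Point = tuple[int, int, int]

__all__ = [
    "Point",
    "LatticeSpec",
    "CUBIC",
    "FCC",
    "get_lattice",
    "ConformationError",
    "Conformation",
    "are_adjacent",
    "neighbors",
    "contacts",
    "random_self_avoiding_walk",
    "WalkGenerationError",
    "enumerate_walks",
    "write_conformation",
    "read_conformation",
    "fcc_to_cartesian",
]


def _cubic_offsets() -> tuple[Point, ...]:
    offs = []
    for axis in range(3):
        for s in (1, -1):
            d = [0, 0, 0]
            d[axis] = s
            offs.append(tuple(d))
    return tuple(offs)


def _fcc_offsets() -> tuple[Point, ...]:
    offs = []
    for a in (1, -1):
        for b in (1, -1):
            offs.extend([(a, b, 0), (a, 0, b), (0, a, b)])
    return tuple(offs)


@dataclass(frozen=True)
class LatticeSpec:
    """A lattice kind with its neighbour offsets and reference basis matrix.

    ``neighbor_offsets`` is the operational representation used for all
    adjacency arithmetic.  ``basis_matrix`` records the conventional real-space
    basis of the lattice and is used only when exporting Cartesian geometry.
    """

    kind: str
    neighbor_offsets: tuple[Point, ...]
    basis_matrix: np.ndarray = field(compare=False, repr=False)

    def __post_init__(self) -> None:
        if self.kind not in ("cubic", "fcc"):
            raise ValueError(f"unknown lattice kind: {self.kind!r}")

    def validate_point(self, p: Point) -> None:
        if len(p) != 3 or not all(isinstance(c, (int, np.integer)) for c in p):
            raise ValueError(f"not an integer 3-coordinate point: {p!r}")
        if self.kind == "fcc" and (p[0] + p[1] + p[2]) % 2 != 0:
            raise ValueError(
                f"invalid FCC point {p!r}: coordinate sum must be even"
            )

    def is_adjacent(self, p: Point, q: Point) -> bool:
        dx = abs(p[0] - q[0])
        dy = abs(p[1] - q[1])
        dz = abs(p[2] - q[2])
        if self.kind == "cubic":
            return dx + dy + dz == 1
        return dx <= 1 and dy <= 1 and dz <= 1 and dx + dy + dz == 2


_CUBIC_BASIS = np.eye(3)
# Conventional FCC primitive vectors with unit bond length (columns).
_FCC_BASIS = np.array(
    [
        [1.0, 0.5, 0.5],
        [0.0, math.sqrt(3.0) / 2.0, math.sqrt(3.0) / 6.0],
        [0.0, 0.0, math.sqrt(6.0) / 3.0],
    ]
)

CUBIC = LatticeSpec("cubic", _cubic_offsets(), _CUBIC_BASIS)
FCC = LatticeSpec("fcc", _fcc_offsets(), _FCC_BASIS)

_BY_NAME = {"cubic": CUBIC, "fcc": FCC}


def get_lattice(name: str) -> LatticeSpec:
    """Look a lattice up by its name (``"cubic"`` or ``"fcc"``)."""
    try:
        return _BY_NAME[name.lower()]
    except KeyError:
        raise ValueError(
            f"unknown lattice {name!r}; choose from {sorted(_BY_NAME)}"
        ) from None


def are_adjacent(p: Point, q: Point, lattice: LatticeSpec) -> bool:
    """True iff ``p`` and ``q`` are connected by a lattice edge.

    Symmetric in its point arguments and invariant under translation.  FCC
    points violating the even-coordinate-sum invariant are rejected.
    """
    lattice.validate_point(tuple(p))
    lattice.validate_point(tuple(q))
    return lattice.is_adjacent(p, q)


def neighbors(p: Point, lattice: LatticeSpec) -> frozenset[Point]:
    """The full neighbour shell of ``p``: 6 points (cubic) or 12 (FCC)."""
    lattice.validate_point(tuple(p))
    x, y, z = p
    return frozenset((x + dx, y + dy, z + dz) for dx, dy, dz in lattice.neighbor_offsets)


class ConformationError(ValueError):
    """A conformation violates one of its invariants."""


class Conformation:
    """A protein sequence with an ordered self-avoiding lattice embedding.

    Invariants (checked on construction): coordinates are pairwise distinct,
    every consecutive pair of residues occupies adjacent lattice nodes, and the
    chain has length >= 1.  Instances are immutable; move application returns
    new objects.
    """

    __slots__ = ("sequence", "coords", "lattice", "_occupancy")

    def __init__(
        self,
        sequence: str,
        coords: Sequence[Point],
        lattice: LatticeSpec,
        _validate: bool = True,
    ) -> None:
        self.sequence = sequence.lower()
        self.coords: tuple[Point, ...] = tuple(tuple(int(c) for c in p) for p in coords)
        self.lattice = lattice
        occ = {p: i for i, p in enumerate(self.coords)}
        self._occupancy = occ
        if _validate:
            self._check_invariants()

    def _check_invariants(self) -> None:
        n = len(self.sequence)
        if n < 1:
            raise ConformationError("conformation must have length >= 1")
        if len(self.coords) != n:
            raise ConformationError(
                f"sequence length {n} != number of coordinates {len(self.coords)}"
            )
        for i, p in enumerate(self.coords):
            try:
                self.lattice.validate_point(p)
            except ValueError as exc:
                raise ConformationError(f"residue {i}: {exc}") from None
        if len(self._occupancy) != n:
            seen: dict[Point, int] = {}
            for i, p in enumerate(self.coords):
                if p in seen:
                    raise ConformationError(
                        f"self-avoidance violated: residues {seen[p]} and {i} "
                        f"both occupy {p}"
                    )
                seen[p] = i
        for i in range(n - 1):
            if not self.lattice.is_adjacent(self.coords[i], self.coords[i + 1]):
                raise ConformationError(
                    f"chain broken between residues {i} and {i + 1}: "
                    f"{self.coords[i]} and {self.coords[i + 1]} are not adjacent"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Conformation):
            return NotImplemented
        return (
            self.sequence == other.sequence
            and self.coords == other.coords
            and self.lattice.kind == other.lattice.kind
        )

    def __hash__(self) -> int:
        return hash((self.sequence, self.coords, self.lattice.kind))

    def __repr__(self) -> str:
        return (
            f"Conformation({self.sequence!r}, len={len(self)}, "
            f"lattice={self.lattice.kind})"
        )

    def occupied(self, p: Point) -> bool:
        return p in self._occupancy

    def index_at(self, p: Point) -> int | None:
        return self._occupancy.get(p)

    def with_coords(self, coords: Sequence[Point]) -> "Conformation":
        return Conformation(self.sequence, coords, self.lattice)

    def translated(self, delta: Point) -> "Conformation":
        dx, dy, dz = delta
        if self.lattice.kind == "fcc" and (dx + dy + dz) % 2 != 0:
            raise ValueError("FCC translation vector must have even coordinate sum")
        moved = [(x + dx, y + dy, z + dz) for x, y, z in self.coords]
        return Conformation(self.sequence, moved, self.lattice, _validate=False)


def contacts(conf: Conformation) -> frozenset[tuple[int, int]]:
    """All residue pairs (i, j), i < j, in lattice contact.

    A contact is a pair of residues on adjacent lattice nodes that are not
    consecutive in the sequence (the covalent backbone bond never counts).
    """
    out = set()
    occ = conf._occupancy
    for i, (x, y, z) in enumerate(conf.coords):
        for dx, dy, dz in conf.lattice.neighbor_offsets:
            j = occ.get((x + dx, y + dy, z + dz))
            if j is not None and j > i + 1:
                out.add((i, j))
    return frozenset(out)


class WalkGenerationError(RuntimeError):
    """Incremental walk generation dead-ended past the retry budget."""


def random_self_avoiding_walk(
    sequence: str,
    lattice: LatticeSpec,
    rng: np.random.Generator,
    max_restarts: int = 1000,
) -> Conformation:
    """Grow a random self-avoiding walk for ``sequence``, anchored at the origin.

    The walk grows incrementally, choosing uniformly among unoccupied neighbour
    sites; a dead end restarts the whole walk.  The resulting distribution over
    walks is not uniform (and need not be).  Deterministic for a given ``rng``
    state.
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    n = len(sequence)
    for _ in range(max_restarts):
        coords: list[Point] = [(0, 0, 0)]
        occupied = {(0, 0, 0)}
        ok = True
        for _i in range(1, n):
            x, y, z = coords[-1]
            free = [
                (x + dx, y + dy, z + dz)
                for dx, dy, dz in lattice.neighbor_offsets
                if (x + dx, y + dy, z + dz) not in occupied
            ]
            if not free:
                ok = False
                break
            free.sort()
            nxt = free[int(rng.integers(len(free)))]
            coords.append(nxt)
            occupied.add(nxt)
        if ok:
            return Conformation(sequence, coords, lattice)
    raise WalkGenerationError(
        f"failed to generate a self-avoiding walk of length {n} on the "
        f"{lattice.kind} lattice within {max_restarts} restarts"
    )


_ENUM_LIMITS = {"cubic": 12, "fcc": 8}


def enumerate_walks(
    n: int,
    lattice: LatticeSpec,
    canonical_first_step: bool = True,
    max_n: int | None = None,
) -> Iterator[tuple[Point, ...]]:
    """Yield every self-avoiding walk of ``n`` nodes starting at the origin.

    With ``canonical_first_step`` (the default) the first step is fixed to the
    lexicographically smallest neighbour offset, quotienting the trivial
    point-group symmetry of the first bond: every walk appears exactly once in
    that quotient.  Intended as a brute-force oracle; ``n`` is guarded
    (default limit 12 on cubic, 8 on FCC).
    """
    limit = max_n if max_n is not None else _ENUM_LIMITS[lattice.kind]
    if n > limit:
        raise ValueError(
            f"enumerate_walks refuses n={n} > {limit} on the {lattice.kind} "
            "lattice: the walk count grows exponentially (raise max_n "
            "explicitly if you really need this)"
        )
    if n < 1:
        raise ValueError("n must be >= 1")
    origin: Point = (0, 0, 0)
    if n == 1:
        yield (origin,)
        return
    offsets = sorted(lattice.neighbor_offsets)
    first_steps = offsets[:1] if canonical_first_step else offsets

    def extend(path: list[Point], occupied: set[Point]) -> Iterator[tuple[Point, ...]]:
        if len(path) == n:
            yield tuple(path)
            return
        x, y, z = path[-1]
        for dx, dy, dz in offsets:
            q = (x + dx, y + dy, z + dz)
            if q not in occupied:
                path.append(q)
                occupied.add(q)
                yield from extend(path, occupied)
                path.pop()
                occupied.remove(q)

    for dx, dy, dz in first_steps:
        first = (dx, dy, dz)
        yield from extend([origin, first], {origin, first})


# --- conformation file format -------------------------------------------------
# Tab-separated table: header line "#lattice <kind>", then a column header,
# then one row per residue: index, residue letter, x, y, z.  Round-trips
# bit-exactly.

def write_conformation(conf: Conformation, fh: TextIO) -> None:
    fh.write(f"#lattice\t{conf.lattice.kind}\n")
    fh.write("index\tresidue\tx\ty\tz\n")
    for i, (aa, (x, y, z)) in enumerate(zip(conf.sequence, conf.coords)):
        fh.write(f"{i}\t{aa}\t{x}\t{y}\t{z}\n")


def read_conformation(fh: TextIO) -> Conformation:
    header = fh.readline().strip()
    if not header.startswith("#lattice"):
        raise ValueError("conformation file must start with a '#lattice <kind>' line")
    lattice = get_lattice(header.split("\t")[1])
    seq_chars: list[str] = []
    coords: list[Point] = []
    for line in fh:
        line = line.strip()
        if not line or line.startswith("index"):
            continue
        idx, aa, x, y, z = line.split("\t")
        if int(idx) != len(seq_chars):
            raise ValueError(f"residue indices out of order at index {idx}")
        seq_chars.append(aa)
        coords.append((int(x), int(y), int(z)))
    return Conformation("".join(seq_chars), coords, lattice)


def fcc_to_cartesian(conf: Conformation) -> np.ndarray:
    """Cartesian coordinates (unit bond length) of an FCC conformation.

    The even-sum integer point (x, y, z) is decomposed onto the primitive
    vectors (1,1,0), (1,0,1), (0,1,1) and mapped through the conventional FCC
    basis matrix.  Write-only export for visualization.
    """
    if conf.lattice.kind != "fcc":
        raise ValueError("Cartesian export via the FCC basis requires an FCC conformation")
    pts = np.array(conf.coords, dtype=float)
    x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
    abc = np.stack([(x + y - z) / 2, (x - y + z) / 2, (-x + y + z) / 2], axis=1)
    return abc @ _FCC_BASIS.T
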