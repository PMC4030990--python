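"""Octahedral-symmetry helpers for exhaustive move-set tests.

Pull-move enumeration commutes with every lattice automorphism (the 48 signed
coordinate permutations) and with translations, so set-level properties such
as reversibility need only be checked on one representative per symmetry
orbit, and move-effect lookups on arbitrary conformations can be answered
from a memo keyed by a canonical form.  The canonical form fixes the first
bond to a reference direction and minimises the (translated) coordinate tuple
over the stabiliser coset, which is a true canonical under the full group.
"""

from __future__ import annotations

from fireflyfold.lattice import Conformation, LatticeSpec
from fireflyfold.moves import enumerate_pull_moves

Point = tuple[int, int, int]


def _all_rotations() -> list[tuple[tuple[int, int, int], ...]]:
    import itertools

    mats = []
    for perm in itertools.permutations(range(3)):
        for signs in itertools.product((1, -1), repeat=3):
            rows = []
            for r in range(3):
                row = [0, 0, 0]
                row[perm[r]] = signs[r]
                rows.append(tuple(row))
            mats.append(tuple(rows))
    return mats


ROTATIONS48 = _all_rotations()


def apply_rot(g, p: Point) -> Point:
    return (
        g[0][0] * p[0] + g[0][1] * p[1] + g[0][2] * p[2],
        g[1][0] * p[0] + g[1][1] * p[1] + g[1][2] * p[2],
        g[2][0] * p[0] + g[2][1] * p[1] + g[2][2] * p[2],
    )


class CanonicalIndex:
    """Canonicalises conformations and answers move-effect membership."""

    def __init__(self, lattice: LatticeSpec) -> None:
        self.lattice = lattice
        self.ref_dir = min(lattice.neighbor_offsets)
        self.coset: dict[Point, list] = {
            d: [g for g in ROTATIONS48 if apply_rot(g, d) == self.ref_dir]
            for d in lattice.neighbor_offsets
        }
        self._effects: dict[tuple[Point, ...], frozenset] = {}

    def canonicalise(self, coords: tuple[Point, ...]):
        """Return (canonical coords, minimising rotation, origin shift)."""
        x0, y0, z0 = coords[0]
        b0 = (coords[1][0] - x0, coords[1][1] - y0, coords[1][2] - z0)
        best = None
        best_g = None
        for g in self.coset[b0]:
            cand = tuple(
                apply_rot(g, (x - x0, y - y0, z - z0)) for x, y, z in coords
            )
            if best is None or cand < best:
                best, best_g = cand, g
        return best, best_g, (x0, y0, z0)

    def key(self, coords: tuple[Point, ...]) -> tuple[Point, ...]:
        return self.canonicalise(coords)[0]

    def effects(self, canon_coords: tuple[Point, ...], sequence: str) -> frozenset:
        """Set of move effects (changes tuples) of the canonical conformation."""
        if canon_coords not in self._effects:
            conf = Conformation(sequence, canon_coords, self.lattice)
            self._effects[canon_coords] = frozenset(
                m.changes for m in enumerate_pull_moves(conf)
            )
        return self._effects[canon_coords]

    def has_move_effect(self, conf: Conformation, effect) -> bool:
        """Does some enumerated pull move of ``conf`` have exactly this
        effect (a tuple of (index, new site) pairs in conf's frame)?"""
        canon, g, origin = self.canonicalise(conf.coords)
        ox, oy, oz = origin
        transformed = tuple(
            (i, apply_rot(g, (p[0] - ox, p[1] - oy, p[2] - oz))) for i, p in effect
        )
        return transformed in self.effects(canon, conf.sequence)


def orbit_representatives(walks, lattice: LatticeSpec):
    """One coordinate tuple per symmetry orbit of the given walks."""
    idx = CanonicalIndex(lattice)
    reps: dict[tuple[Point, ...], tuple[Point, ...]] = {}
    for coords in walks:
        k = idx.key(tuple(coords))
        if k not in reps:
            reps[k] = k
    return list(reps.values()), idx
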