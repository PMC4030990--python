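"""Energy models for lattice conformations.

Two models are provided:

* **H-P** (the *HP100* variant): each residue is hydrophobic (``h``) or polar
  (``p``); the energy is minus the number of non-consecutive h-h lattice
  contacts.
* **Pairwise contact matrix** (Miyazawa–Jernigan style): the energy is the sum
  of matrix entries e(u, v) over all non-covalent lattice contacts between
  residue types u and v.  Matrices are loaded from delimited text files; the
  package ships an MJb transcription and a synthetic hydropathy-based matrix.

Energies are always recomputed from scratch, so one call equals one objective
evaluation wherever the search layer counts evaluations.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, TextIO, Union

import numpy as np

from .lattice import Conformation, contacts

AMINO_ACIDS = "acdefghiklmnpqrstvwy"
HP_ALPHABET = "hp"

__all__ = [
    "AMINO_ACIDS",
    "HP_ALPHABET",
    "AlphabetError",
    "MatrixFormatError",
    "ContactMatrix",
    "load_contact_matrix",
    "packaged_matrix",
    "hp_energy",
    "contact_energy",
    "EnergyModel",
    "HPModel",
    "ContactMatrixModel",
    "make_model",
    "read_sequences",
    "detect_alphabet",
]


class AlphabetError(ValueError):
    """A sequence contains residues outside the model's alphabet."""


class MatrixFormatError(ValueError):
    """A contact-matrix file failed to parse or validate."""


@dataclass(frozen=True)
class ContactMatrix:
    """A symmetric pairwise contact-energy matrix keyed by residue letter."""

    name: str
    alphabet: str
    values: np.ndarray = field(repr=False)
    _index: dict[str, int] = field(repr=False, compare=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        k = len(self.alphabet)
        if self.values.shape != (k, k):
            raise MatrixFormatError(
                f"matrix {self.name!r}: shape {self.values.shape} does not "
                f"match alphabet size {k}"
            )
        if not np.allclose(self.values, self.values.T, atol=1e-12, rtol=0.0):
            raise MatrixFormatError(f"matrix {self.name!r} is not symmetric")
        object.__setattr__(self, "_index", {aa: i for i, aa in enumerate(self.alphabet)})

    def energy(self, u: str, v: str) -> float:
        try:
            return float(self.values[self._index[u.lower()], self._index[v.lower()]])
        except KeyError as exc:
            raise AlphabetError(
                f"residue {exc.args[0]!r} not in matrix {self.name!r} alphabet"
            ) from None

    def contains(self, sequence: str) -> bool:
        return all(aa in self._index for aa in sequence.lower())


def load_contact_matrix(
    source: Union[str, Path, TextIO], name: str | None = None
) -> ContactMatrix:
    """Parse a contact matrix from delimited text.

    Format: ``#`` comment lines, then a header row of residue letters, then one
    labelled row per residue carrying either the full row (verified symmetric
    to 1e-12) or the lower triangle up to the diagonal (mirrored).
    """
    if isinstance(source, (str, Path)):
        with open(source, "rt") as fh:
            return load_contact_matrix(fh, name=name or Path(source).stem)
    lines = [ln.strip() for ln in source if ln.strip() and not ln.lstrip().startswith("#")]
    if not lines:
        raise MatrixFormatError("empty matrix file")
    header = [tok.lower() for tok in lines[0].split()]
    k = len(header)
    if len(set(header)) != k:
        raise MatrixFormatError("duplicate residue letters in matrix header")
    if len(lines) - 1 != k:
        raise MatrixFormatError(
            f"expected {k} labelled rows after the header, found {len(lines) - 1}"
        )
    values = np.full((k, k), np.nan)
    lower_triangle = False
    for r, line in enumerate(lines[1:]):
        toks = line.split()
        label = toks[0].lower()
        if label != header[r]:
            raise MatrixFormatError(
                f"row {r}: label {label!r} does not match header order ({header[r]!r})"
            )
        cells = toks[1:]
        if len(cells) == k:
            row_len = k
        elif len(cells) == r + 1:
            row_len = r + 1
            lower_triangle = True
        else:
            raise MatrixFormatError(
                f"row {label!r}: expected {k} (full) or {r + 1} (lower-triangle) "
                f"values, found {len(cells)}"
            )
        for c in range(row_len):
            try:
                values[r, c] = float(cells[c])
            except ValueError:
                raise MatrixFormatError(
                    f"non-numeric cell at row {label!r}, column {header[c]!r}: "
                    f"{cells[c]!r}"
                ) from None
    if lower_triangle:
        if np.isnan(values[np.tril_indices(k)]).any():
            raise MatrixFormatError("incomplete lower triangle")
        iu = np.triu_indices(k, 1)
        values[iu] = values.T[iu]
    else:
        asym = np.nanmax(np.abs(values - values.T))
        if np.isnan(values).any():
            raise MatrixFormatError("missing values in full matrix")
        if asym > 1e-12:
            r, c = np.unravel_index(np.argmax(np.abs(values - values.T)), values.shape)
            raise MatrixFormatError(
                f"full matrix asymmetric beyond tolerance at "
                f"({header[r]!r}, {header[c]!r}): {values[r, c]} vs {values[c, r]}"
            )
        values = (values + values.T) / 2.0
    alphabet = "".join(header)
    # an amino-acid matrix must carry all 20 residues; tiny toy alphabets
    # (e.g. a 2-letter h/p matrix) are allowed through
    if 2 < len(alphabet) and set(alphabet) <= set(AMINO_ACIDS) and len(alphabet) != 20:
        missing = sorted(set(AMINO_ACIDS) - set(alphabet))
        raise MatrixFormatError(
            f"amino-acid matrix is missing residues: {missing}"
        )
    if len(alphabet) == 20 and set(alphabet) != set(AMINO_ACIDS):
        raise MatrixFormatError(
            f"unrecognised 20-letter alphabet: {alphabet!r}"
        )
    return ContactMatrix(name or "matrix", alphabet, values)


_PACKAGED = {
    "mjb": "mjb_contact_energies.tsv",
    "berrera_synthetic": "berrera_synthetic_contact_energies.tsv",
}


def packaged_matrix(name: str) -> ContactMatrix:
    """Load one of the matrices shipped with the package (``mjb`` or
    ``berrera_synthetic``)."""
    try:
        fname = _PACKAGED[name]
    except KeyError:
        raise ValueError(
            f"unknown packaged matrix {name!r}; available: {sorted(_PACKAGED)}"
        ) from None
    text = resources.files("fireflyfold.data").joinpath(fname).read_text()
    return load_contact_matrix(io.StringIO(text), name=name)


def hp_energy(conf: Conformation) -> int:
    """HP100 energy: minus the number of non-consecutive h-h contacts."""
    seq = conf.sequence
    bad = set(seq) - set(HP_ALPHABET)
    if bad:
        raise AlphabetError(
            f"H-P model requires an h/p sequence; found {sorted(bad)}"
        )
    return -sum(1 for i, j in contacts(conf) if seq[i] == "h" and seq[j] == "h")


def contact_energy(conf: Conformation, matrix: ContactMatrix) -> float:
    """Pairwise contact energy: sum of e(type_i, type_j) over lattice contacts."""
    seq = conf.sequence
    if not matrix.contains(seq):
        bad = sorted(set(seq) - set(matrix.alphabet))
        raise AlphabetError(
            f"sequence contains residues {bad} outside matrix "
            f"{matrix.name!r} alphabet"
        )
    return float(sum(matrix.energy(seq[i], seq[j]) for i, j in contacts(conf)))


class EnergyModel:
    """Base class: an energy model maps a valid conformation to a real energy."""

    kind: str

    def evaluate(self, conf: Conformation) -> float:
        raise NotImplementedError

    def validate_sequence(self, sequence: str) -> None:
        raise NotImplementedError

    def __call__(self, conf: Conformation) -> float:
        return self.evaluate(conf)


class HPModel(EnergyModel):
    kind = "hp"

    def evaluate(self, conf: Conformation) -> float:
        return float(hp_energy(conf))

    def validate_sequence(self, sequence: str) -> None:
        bad = set(sequence.lower()) - set(HP_ALPHABET)
        if bad:
            raise AlphabetError(
                f"H-P model requires an h/p sequence; found {sorted(bad)}"
            )

    def __repr__(self) -> str:
        return "HPModel()"


class ContactMatrixModel(EnergyModel):
    kind = "contact_matrix"

    def __init__(self, matrix: ContactMatrix) -> None:
        self.matrix = matrix

    def evaluate(self, conf: Conformation) -> float:
        return contact_energy(conf, self.matrix)

    def validate_sequence(self, sequence: str) -> None:
        if not self.matrix.contains(sequence):
            bad = sorted(set(sequence.lower()) - set(self.matrix.alphabet))
            raise AlphabetError(
                f"sequence contains residues {bad} outside matrix "
                f"{self.matrix.name!r} alphabet"
            )

    def __repr__(self) -> str:
        return f"ContactMatrixModel({self.matrix.name!r})"


def make_model(name: str, matrix: ContactMatrix | str | Path | None = None) -> EnergyModel:
    """Build an energy model from a name: ``hp``, a packaged matrix name, or
    ``contact_matrix`` with an explicit matrix (object or file path)."""
    name = name.lower()
    if name == "hp":
        return HPModel()
    if name in _PACKAGED:
        return ContactMatrixModel(packaged_matrix(name))
    if name in ("contact_matrix", "mj"):
        if matrix is None:
            raise ValueError("contact_matrix model requires a matrix")
        if isinstance(matrix, (str, Path)):
            matrix = load_contact_matrix(matrix)
        return ContactMatrixModel(matrix)
    raise ValueError(f"unknown energy model {name!r}")


def detect_alphabet(sequence: str) -> str:
    """Classify a sequence as ``"hp"`` or ``"amino"`` by its letters."""
    s = set(sequence.lower())
    if s <= set(HP_ALPHABET):
        return "hp"
    if s <= set(AMINO_ACIDS):
        return "amino"
    raise AlphabetError(
        f"sequence letters {sorted(s)} fit neither the h/p nor the "
        "20-letter amino-acid alphabet"
    )


def read_sequences(source: Union[str, Path, TextIO]) -> list[tuple[str, str]]:
    """Read (id, sequence) pairs from FASTA text or a bare sequence string.

    Sequences are normalised to lower case.  A path or handle is treated as
    FASTA if it starts with ``>``, else as one bare sequence per line.
    """
    if isinstance(source, (str, Path)):
        p = Path(source)
        if p.exists():
            with open(p, "rt") as fh:
                return read_sequences(fh)
        # a bare sequence string
        return [("seq", str(source).strip().lower())]
    text = source.read()
    records: list[tuple[str, str]] = []
    if text.lstrip().startswith(">"):
        name = None
        chunks: list[str] = []
        for line in text.splitlines():
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    records.append((name, "".join(chunks).lower()))
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
        if name is not None:
            records.append((name, "".join(chunks).lower()))
    else:
        for i, line in enumerate(ln for ln in text.splitlines() if ln.strip()):
            records.append((f"seq{i + 1}", line.strip().lower()))
    return records


def hp_equivalent_matrix() -> ContactMatrix:
    """A 2-letter matrix with e(h,h) = -1 and 0 elsewhere: under it the contact
    energy coincides with the H-P energy (used as a cross-model check)."""
    return ContactMatrix("hp100", "hp", np.array([[-1.0, 0.0], [0.0, 0.0]]))
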