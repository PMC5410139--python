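"""Aligned nucleotide matrices and haplotype collapsing.

The study data are full cytochrome b (cyt b) alignments, 1,140 bp, with one
row per individual.  Rows are stored as a fixed-width character matrix over
the alphabet ``A C G T - N ?``; gap and ambiguity characters are treated as
missing data throughout the pipeline (pairwise deletion).
"""

from __future__ import annotations

import itertools
import string
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlignmentError, FormatError

ALLOWED_CHARS = frozenset("ACGT-N?")
#: Characters that carry no information at a site (excluded pairwise).
MISSING_CHARS = frozenset("-N?")
BASES = "ACGT"


@dataclass
class Alignment:
    """A rectangular nucleotide alignment.

    Attributes
    ----------
    ids : list of str
        Unique sequence identifiers, in file order.
    matrix : ndarray of shape (n, length), dtype ``<U1``
        Uppercase characters from ``A C G T - N ?``.
    """

    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype="U1")
        if self.matrix.ndim != 2:
            raise AlignmentError("alignment matrix must be 2-D")
        if len(self.ids) != self.matrix.shape[0]:
            raise AlignmentError("number of ids does not match number of rows")
        if len(set(self.ids)) != len(self.ids):
            raise AlignmentError("duplicate sequence identifiers")
        bad = set(np.unique(self.matrix)) - ALLOWED_CHARS
        if bad:
            raise AlignmentError(f"disallowed characters in alignment: {sorted(bad)}")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def row(self, i: int) -> np.ndarray:
        return self.matrix[i]

    def index_of(self, seq_id: str) -> int:
        try:
            return self.ids.index(seq_id)
        except ValueError:
            raise KeyError(f"unknown sequence id {seq_id!r}") from None

    @classmethod
    def from_strings(cls, ids: list[str], seqs: list[str]) -> "Alignment":
        lengths = {len(s) for s in seqs}
        if len(lengths) > 1:
            raise AlignmentError(f"ragged sequence lengths: {sorted(lengths)}")
        mat = np.array([list(s.upper()) for s in seqs], dtype="U1")
        return cls(ids=list(ids), matrix=mat)


def read_fasta(path) -> Alignment:
    """Read a pre-aligned multi-FASTA file.

    Lowercase bases are uppercased; record order is preserved.  Ragged
    lengths raise :class:`AlignmentError`, an empty file :class:`FormatError`.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return Alignment.from_strings(
        ids=[r.id for r in records], seqs=[str(r.seq) for r in records]
    )


def write_fasta(alignment: Alignment, path) -> None:
    records = [
        SeqRecord(Seq("".join(alignment.matrix[i])), id=alignment.ids[i], description="")
        for i in range(alignment.n)
    ]
    SeqIO.write(records, str(path), "fasta")


def _haplotype_labels() -> "itertools.chain":
    """A, B, ..., Z, AA, AB, ... — first-seen haplotype labels."""
    singles = iter(string.ascii_uppercase)
    doubles = (
        a + b for a, b in itertools.product(string.ascii_uppercase, repeat=2)
    )
    return itertools.chain(singles, doubles)


@dataclass
class HaplotypeTable:
    """Partition of alignment rows into identical-sequence haplotypes."""

    labels: list[str] = field(default_factory=list)
    representatives: list[int] = field(default_factory=list)  # row index per haplotype
    members: dict[str, list[str]] = field(default_factory=dict)  # label -> seq ids
    assignment: dict[str, str] = field(default_factory=dict)  # seq id -> label

    def n_haplotypes(self) -> int:
        return len(self.labels)


def _compatible(row_a: np.ndarray, row_b: np.ndarray) -> bool:
    """True if rows agree at every mutually non-missing site."""
    ok_a = ~np.isin(row_a, list(MISSING_CHARS))
    ok_b = ~np.isin(row_b, list(MISSING_CHARS))
    both = ok_a & ok_b
    return bool(np.all(row_a[both] == row_b[both]))


def collapse_haplotypes(alignment: Alignment) -> HaplotypeTable:
    """Collapse alignment rows into haplotypes.

    Two rows share a haplotype iff they are identical at all mutually
    non-missing sites; a row joins the first previously seen haplotype whose
    representative it is compatible with, so labels are deterministic in
    first-seen order (A, B, C, ...).
    """
    if alignment.n == 0:
        raise AlignmentError("cannot collapse an empty alignment")
    table = HaplotypeTable()
    label_gen = _haplotype_labels()
    for i, seq_id in enumerate(alignment.ids):
        assigned = None
        for label, rep in zip(table.labels, table.representatives):
            if _compatible(alignment.matrix[i], alignment.matrix[rep]):
                assigned = label
                break
        if assigned is None:
            assigned = next(label_gen)
            table.labels.append(assigned)
            table.representatives.append(i)
            table.members[assigned] = []
        table.members[assigned].append(seq_id)
        table.assignment[seq_id] = assigned
    return table
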