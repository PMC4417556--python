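"""Sequence containers, residue encoding, FASTA I/O and k-word utilities.

The hit-detection stage works on small integer residue codes rather than
characters: the twenty standard amino acids are assigned the codes 1..20
(``A`` = 1 through ``Y`` = 20 in alphabetical order), and 0 is reserved as a
null/sentinel code that never matches anything.  That convention makes
"unused array cell" and "ambiguous residue in permissive mode" impossible to
confuse with a real residue.

All user-facing coordinates in this package are 1-based and inclusive.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq as _BioSeq

from .exceptions import FastaParseError, MatrixFormatError, SequenceValidationError

PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
DNA_ALPHABET = "ACGT"

#: Ambiguity codes tolerated in permissive mode.  They are kept in the
#: residue string but encode to the sentinel 0, which never matches and
#: never scores above a mismatch.
AMBIGUITY_CODES = "XBZ"

#: Sentinel code for "no residue here" (array padding, ambiguity codes).
NULL_CODE = 0

RESIDUE_CODES: dict[str, int] = {aa: i + 1 for i, aa in enumerate(PROTEIN_ALPHABET)}
_CODE_TO_RESIDUE: dict[int, str] = {v: k for k, v in RESIDUE_CODES.items()}


class Alphabet(str, enum.Enum):
    PROTEIN = "protein"
    DNA = "dna"

    @property
    def letters(self) -> str:
        return PROTEIN_ALPHABET if self is Alphabet.PROTEIN else DNA_ALPHABET


@dataclass(frozen=True)
class Sequence:
    """A validated residue string with an identifier and alphabet tag.

    Parameters
    ----------
    id:
        Record identifier (FASTA header up to the first whitespace).
    residues:
        Upper-case residue string over ``alphabet``.
    alphabet:
        ``Alphabet.PROTEIN`` (20 standard amino acids) or ``Alphabet.DNA``
        (ACGT).
    permissive:
        When true, the ambiguity codes X/B/Z are accepted in protein
        sequences (N in DNA); they encode to the null sentinel and can
        therefore never seed or extend a match.
    """

    id: str
    residues: str
    alphabet: Alphabet = Alphabet.PROTEIN
    permissive: bool = False

    def __post_init__(self) -> None:
        if not self.residues:
            raise SequenceValidationError(f"sequence {self.id!r}: empty residue string")
        allowed = set(self.alphabet.letters)
        if self.permissive:
            allowed |= set(AMBIGUITY_CODES if self.alphabet is Alphabet.PROTEIN else "N")
        for pos, ch in enumerate(self.residues, start=1):
            if ch not in allowed:
                raise SequenceValidationError(
                    f"sequence {self.id!r}: illegal {self.alphabet.value} residue "
                    f"{ch!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, item):  # 0-based slicing convenience, internal use
        return self.residues[item]


def encode_residue(residue: str) -> int:
    """Map one amino-acid character to its integer code in 1..20.

    Ambiguity codes (X/B/Z) map to the null sentinel 0; any other character
    raises.  The assignment is alphabetical (A=1 ... Y=20) and bijective over
    the standard alphabet; :func:`decode_residue` inverts it.
    """
    try:
        return RESIDUE_CODES[residue]
    except KeyError:
        if residue in AMBIGUITY_CODES:
            return NULL_CODE
        raise SequenceValidationError(f"unknown amino-acid residue {residue!r}") from None


def decode_residue(code: int) -> str:
    """Inverse of :func:`encode_residue` for codes 1..20."""
    try:
        return _CODE_TO_RESIDUE[code]
    except KeyError:
        raise SequenceValidationError(f"residue code {code} outside 1..20") from None


def encode_sequence(seq: Sequence) -> list[int]:
    """Encode every residue; ambiguity codes become the null sentinel."""
    return [encode_residue(ch) for ch in seq.residues]


def read_fasta(
    path: str | Path,
    alphabet: Alphabet = Alphabet.PROTEIN,
    permissive: bool = False,
) -> list[Sequence]:
    """Read a (possibly multi-record, possibly line-wrapped) FASTA file.

    Records are returned in file order with residues upper-cased.  An empty
    file yields an empty list.  Malformed records and illegal residues raise
    with the offending record named.
    """
    path = Path(path)
    records = []
    try:
        parsed = list(SeqIO.parse(str(path), "fasta"))
    except Exception as exc:  # Biopython raises bare ValueError on bad input
        raise FastaParseError(f"{path}: not parseable as FASTA: {exc}") from exc
    with open(path) as fh:
        head = fh.read(1)
    if head and head != ">" and not parsed:
        raise FastaParseError(f"{path}: first record does not start with '>'")
    for rec in parsed:
        residues = str(rec.seq).upper()
        if not residues:
            raise FastaParseError(f"{path}: record {rec.id!r} has an empty sequence")
        records.append(Sequence(rec.id, residues, alphabet, permissive))
    return records


def write_fasta(sequences: Iterable[Sequence], path: str | Path, width: int = 60) -> None:
    """Write sequences as wrapped FASTA (deterministic byte output)."""
    with open(path, "w") as fh:
        for seq in sequences:
            fh.write(f">{seq.id}\n")
            for i in range(0, len(seq.residues), width):
                fh.write(seq.residues[i : i + width] + "\n")


def extract_kwords(seq: Sequence | str, k: int) -> list[tuple[int, str]]:
    """Split a sequence into its (m − k) + 1 overlapping k-words.

    Returns ``(start, word)`` pairs in sequence order with 1-based start
    positions; adjacent words overlap in exactly k − 1 characters.
    """
    residues = seq.residues if isinstance(seq, Sequence) else seq
    if k < 1:
        raise ValueError(f"word size k must be >= 1, got {k}")
    m = len(residues)
    if m < k:
        raise SequenceValidationError(
            f"sequence length {m} is shorter than word size k={k}"
        )
    return [(i + 1, residues[i : i + k]) for i in range(m - k + 1)]


def six_frame_translate(seq: Sequence) -> list[Sequence]:
    """Translate a DNA sequence in all six reading frames.

    Three frames on the forward strand and three on the reverse complement
    are translated under the standard genetic code.  Each frame is split at
    stop codons into separate protein segments, because downstream hit
    detection assumes the 20-letter alphabet; empty segments are dropped.
    Output ids are ``{id}|frame={f}|seg={n}`` with f in {+1,+2,+3,-1,-2,-3}.
    """
    if seq.alphabet is not Alphabet.DNA:
        raise SequenceValidationError(f"sequence {seq.id!r}: six-frame translation needs DNA")
    if len(seq) < 3:
        raise SequenceValidationError(
            f"sequence {seq.id!r}: length {len(seq)} < 3, nothing to translate"
        )
    forward = _BioSeq(seq.residues)
    reverse = forward.reverse_complement()
    out: list[Sequence] = []
    for strand, label in ((forward, "+"), (reverse, "-")):
        for offset in range(3):
            frame = strand[offset:]
            frame = frame[: len(frame) - len(frame) % 3]
            if not frame:
                continue
            protein = str(frame.translate(table=1))
            for n, segment in enumerate(p for p in protein.split("*") if p):
                out.append(
                    Sequence(
                        f"{seq.id}|frame={label}{offset + 1}|seg={n + 1}",
                        segment,
                        Alphabet.PROTEIN,
                        permissive=seq.permissive,
                    )
                )
    return out


def read_matrix_text(path: str | Path) -> dict[tuple[str, str], int]:
    """Parse an NCBI-style whitespace-delimited substitution-matrix file.

    The first non-comment line lists column residues; each following line is
    a row residue and its scores.  Returns the ordered-pair score dict; no
    symmetry or completeness validation happens here (see
    ``ungapped_ext.load_matrix`` for the validated entry point).
    """
    path = Path(path)
    columns: list[str] | None = None
    scores: dict[tuple[str, str], int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if columns is None:
                columns = fields
                if any(len(c) != 1 for c in columns):
                    raise MatrixFormatError(
                        f"{path}:{lineno}: header must be single-letter residue labels"
                    )
                continue
            row = fields[0]
            values = fields[1:]
            if len(values) != len(columns):
                raise MatrixFormatError(
                    f"{path}:{lineno}: row {row!r} has {len(values)} scores, "
                    f"expected {len(columns)}"
                )
            try:
                for col, val in zip(columns, values):
                    scores[(row, col)] = int(val)
            except ValueError as exc:
                raise MatrixFormatError(f"{path}:{lineno}: non-integer score: {exc}") from exc
    if columns is None:
        raise MatrixFormatError(f"{path}: no matrix header found")
    return scores
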