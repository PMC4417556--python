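"""Ungapped extension of merged hits into high-scoring segment pairs.

Each merged hit is grown one residue pair at a time in both directions,
accumulating BLOSUM50 substitution scores; directions are independent, so
the left extension runs to completion before the right one without affecting
the result.  Two termination rules are available:

``xdrop`` (default)
    Standard BLAST-style drop-off: a direction stops when its running score
    falls more than X below the best score seen in that direction (or the
    sequence end is reached), and the segment is trimmed back to the
    best-scoring endpoints.  The pair qualifies as an HSP iff its total score
    reaches the threshold T.

``paper_literal``
    Extension halts as soon as the cumulative score exceeds T, and the pair
    qualifies iff that halt condition was met.  This mirrors a
    stop-when-above-threshold hardware description; it is provided for
    fidelity experiments, not as a recommended mode (it truncates strong
    matches at the first moment they clear T).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

from .exceptions import MatrixFormatError, SablastError
from .hit_merge import MergedHit
from .seq_io import PROTEIN_ALPHABET, Sequence, read_matrix_text

DEFAULT_T = 20
DEFAULT_X = 7


class ScoreMatrix:
    """A symmetric 20×20 amino-acid substitution matrix.

    Lookups for residues outside the standard alphabet (the permissive-mode
    ambiguity sentinel) return the matrix minimum, so an ambiguous residue
    can never score above a mismatch.
    """

    def __init__(self, name: str, scores: dict[tuple[str, str], int]):
        for a in PROTEIN_ALPHABET:
            for b in PROTEIN_ALPHABET:
                if (a, b) not in scores:
                    raise MatrixFormatError(f"matrix {name!r}: missing pair ({a},{b})")
                if scores[(a, b)] != scores[(b, a)]:
                    raise MatrixFormatError(
                        f"matrix {name!r}: asymmetric at ({a},{b}): "
                        f"{scores[(a, b)]} != {scores[(b, a)]}"
                    )
        self.name = name
        self._scores = {
            (a, b): scores[(a, b)] for a in PROTEIN_ALPHABET for b in PROTEIN_ALPHABET
        }
        self._min = min(self._scores.values())

    def score(self, a: str, b: str) -> int:
        return self._scores.get((a, b), self._min)

    def __repr__(self) -> str:
        return f"ScoreMatrix({self.name!r})"


def load_matrix(path: str | Path, name: str | None = None) -> ScoreMatrix:
    """Load and validate an NCBI-style whitespace-delimited matrix file."""
    path = Path(path)
    return ScoreMatrix(name or path.name, read_matrix_text(path))


def blosum50() -> ScoreMatrix:
    """The packaged BLOSUM50 matrix (canonical NCBI values, 1/3-bit scale)."""
    resource = importlib.resources.files("sablast.data").joinpath("BLOSUM50")
    with importlib.resources.as_file(resource) as path:
        return load_matrix(path, name="BLOSUM50")


@dataclass(frozen=True)
class ExtensionConfig:
    """Ungapped-extension thresholds, in substitution-matrix units.

    T is the HSP qualification floor; X is the drop-off tolerance for the
    xdrop rule.  Defaults (T=20, X=7 in BLOSUM50 units) live in the packaged
    run configuration.
    """

    T: int = DEFAULT_T
    X: int = DEFAULT_X
    mode: str = "xdrop"

    def __post_init__(self) -> None:
        if self.T < 0:
            raise ValueError("T must be >= 0")
        if self.X <= 0:
            raise ValueError("X must be > 0")
        if self.mode not in ("xdrop", "paper_literal"):
            raise ValueError(f"unknown extension mode {self.mode!r}")


@dataclass(frozen=True)
class Hsp:
    """An ungapped high-scoring segment pair.

    Coordinates are 1-based inclusive; the seed's interval is contained in
    the HSP interval on both sequences and the score is the positional sum of
    matrix scores over the aligned span.
    """

    q_start: int
    q_end: int
    s_start: int
    s_end: int
    score: int
    seed: MergedHit
    query_id: str = ""
    subject_id: str = ""

    @property
    def length(self) -> int:
        return self.q_end - self.q_start + 1


def segment_score(
    query: Sequence, subject: Sequence, q_start: int, s_start: int, length: int,
    matrix: ScoreMatrix,
) -> int:
    """Positional sum of matrix scores over an ungapped aligned span."""
    return sum(
        matrix.score(query.residues[q_start - 1 + i], subject.residues[s_start - 1 + i])
        for i in range(length)
    )


def extend_hit(
    hit: MergedHit,
    query: Sequence,
    subject: Sequence,
    matrix: ScoreMatrix,
    config: ExtensionConfig = ExtensionConfig(),
) -> Hsp | None:
    """Extend one merged hit in both directions; return its HSP if it qualifies.

    The seed residues are scored with the same matrix, so the seed's own
    score is part of the total.  Returns ``None`` when the segment does not
    qualify under the configured termination rule.
    """
    if hit.q_start < 1 or hit.q_end > len(query) or hit.s_start < 1 or hit.s_end > len(subject):
        raise SablastError(
            f"hit {hit} out of bounds for query length {len(query)} / "
            f"subject length {len(subject)}"
        )
    seed_score = segment_score(query, subject, hit.q_start, hit.s_start, hit.length, matrix)
    if config.mode == "xdrop":
        left_gain, left_off = _xdrop_direction(hit, query, subject, matrix, config.X, -1)
        right_gain, right_off = _xdrop_direction(hit, query, subject, matrix, config.X, +1)
        total = seed_score + left_gain + right_gain
        if total < config.T:
            return None
        return Hsp(
            q_start=hit.q_start - left_off,
            q_end=hit.q_end + right_off,
            s_start=hit.s_start - left_off,
            s_end=hit.s_end + right_off,
            score=total,
            seed=hit,
            query_id=query.id,
            subject_id=subject.id,
        )
    return _extend_paper_literal(hit, query, subject, matrix, config, seed_score)


def _xdrop_direction(
    hit: MergedHit, query: Sequence, subject: Sequence, matrix: ScoreMatrix,
    X: int, step: int,
) -> tuple[int, int]:
    """Best cumulative score gain and offset in one direction under X-drop."""
    if step < 0:
        room = min(hit.q_start, hit.s_start) - 1
        q0, s0 = hit.q_start, hit.s_start
    else:
        room = min(len(query) - hit.q_end, len(subject) - hit.s_end)
        q0, s0 = hit.q_end, hit.s_end
    gain = best_gain = best_off = 0
    for off in range(1, room + 1):
        gain += matrix.score(
            query.residues[q0 - 1 + step * off], subject.residues[s0 - 1 + step * off]
        )
        if gain > best_gain:
            best_gain, best_off = gain, off
        elif gain <= best_gain - X:
            break
    return best_gain, best_off


def _extend_paper_literal(
    hit: MergedHit, query: Sequence, subject: Sequence, matrix: ScoreMatrix,
    config: ExtensionConfig, seed_score: int,
) -> Hsp | None:
    """Halt each direction as soon as the cumulative total exceeds T."""
    total = seed_score
    q_start, s_start = hit.q_start, hit.s_start
    q_end, s_end = hit.q_end, hit.s_end
    while total <= config.T and q_start > 1 and s_start > 1:
        q_start -= 1
        s_start -= 1
        total += matrix.score(query.residues[q_start - 1], subject.residues[s_start - 1])
    while total <= config.T and q_end < len(query) and s_end < len(subject):
        q_end += 1
        s_end += 1
        total += matrix.score(query.residues[q_end - 1], subject.residues[s_end - 1])
    if total <= config.T:
        return None
    return Hsp(
        q_start=q_start, q_end=q_end, s_start=s_start, s_end=s_end,
        score=total, seed=hit, query_id=query.id, subject_id=subject.id,
    )


def extend_all(
    hits: list[MergedHit],
    query: Sequence,
    subject: Sequence,
    matrix: ScoreMatrix,
    config: ExtensionConfig = ExtensionConfig(),
) -> list[Hsp]:
    """Extend every merged hit, deduplicating coordinate-identical HSPs.

    Distinct seeds inside one true homologous block all extend to the same
    endpoints; only the first-seen HSP is kept (its ``seed`` is the earliest
    seed in stream order).  Output preserves input order.
    """
    out: list[Hsp] = []
    seen: set[tuple[int, int, int, int]] = set()
    for hit in hits:
        hsp = extend_hit(hit, query, subject, matrix, config)
        if hsp is None:
            continue
        key = (hsp.q_start, hsp.q_end, hsp.s_start, hsp.s_end)
        if key in seen:
            continue
        seen.add(key)
        out.append(hsp)
    return out


def hsps_to_tsv(hsps: list[Hsp]) -> str:
    lines = ["query_id\tsubject_id\tq_start\tq_end\ts_start\ts_end\tscore"]
    lines += [
        f"{h.query_id}\t{h.subject_id}\t{h.q_start}\t{h.q_end}\t{h.s_start}\t{h.s_end}\t{h.score}"
        for h in hsps
    ]
    return "\n".join(lines) + "\n"
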