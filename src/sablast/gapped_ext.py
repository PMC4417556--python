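"""Needleman-Wunsch global alignment with zero-initialized margins.

The gapped stage aligns the full query/subject pair (or a window around an
HSP) by dynamic programming.  With the reference parameterization —
match = 1, mismatch = 0, gap penalty d = 0, and the first row and column of
the score matrix set to zero — the recurrence

    D(i,j) = max( D(i-1,j-1) + S_ij,  D(i-1,j) + d,  D(i,j-1) + d )

degenerates to the longest-common-subsequence recurrence, so D(M,N) equals
the LCS length of the two sequences; that equivalence is the main
correctness oracle for this module.  The parameters are configurable
(substitution scoring and a negative gap penalty give standard NW), but the
reference values are the packaged defaults.

Traceback runs from the bottom-right cell to the top-left.  When several
predecessors tie for a cell's value, the diagonal is preferred (it shortens
the path); between the two gap moves, the up move (gap in the subject) is
taken — a fixed, documented tie-break for determinism.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import SablastError
from .seq_io import Sequence
from .ungapped_ext import Hsp

GAP = "-"


@dataclass(frozen=True)
class NwParams:
    """Needleman-Wunsch scores: identical pair, non-identical pair, gap."""

    match: int = 1
    mismatch: int = 0
    gap: int = 0


@dataclass
class DpMatrix:
    """Filled (M+1)×(N+1) score grid; row/column 0 are the zero margins."""

    values: np.ndarray
    M: int
    N: int

    @property
    def score(self) -> int:
        return int(self.values[self.M, self.N])


@dataclass(frozen=True)
class GappedAlignment:
    """A global alignment: gapped strings, total score, and path length.

    ``aligned_q`` and ``aligned_s`` have equal length with no column gapped
    on both sides; stripping gaps recovers the aligned substrings exactly.
    Coordinates locate the aligned window in the original sequences (the
    whole sequences under the default full-window mode).
    """

    aligned_q: str
    aligned_s: str
    score: int
    path_length: int
    query_id: str = ""
    subject_id: str = ""
    q_start: int = 1
    q_end: int = 0
    s_start: int = 1
    s_end: int = 0


def _residues(seq: Sequence | str) -> str:
    return seq.residues if isinstance(seq, Sequence) else seq


def fill_matrix(Q: Sequence | str, S: Sequence | str, params: NwParams = NwParams()) -> DpMatrix:
    """Fill the DP score matrix; O(M+N) initialization then O(MN) fill."""
    q, s = _residues(Q), _residues(S)
    if not q or not s:
        raise SablastError("cannot align an empty sequence")
    M, N = len(q), len(s)
    D = np.zeros((M + 1, N + 1), dtype=np.int64)
    D[0, 1:] = params.gap * np.arange(1, N + 1) if params.gap else 0
    D[1:, 0] = params.gap * np.arange(1, M + 1) if params.gap else 0
    for i in range(1, M + 1):
        row_sub = np.where(
            np.frombuffer(s.encode(), dtype=np.uint8) == ord(q[i - 1]),
            params.match,
            params.mismatch,
        )
        prev, cur = D[i - 1], D[i]
        for j in range(1, N + 1):
            cur[j] = max(
                prev[j - 1] + row_sub[j - 1],
                prev[j] + params.gap,
                cur[j - 1] + params.gap,
            )
    return DpMatrix(values=D, M=M, N=N)


def traceback(
    D: DpMatrix, Q: Sequence | str, S: Sequence | str, params: NwParams = NwParams()
) -> GappedAlignment:
    """Reconstruct the alignment path from cell (M,N) back to (0,0).

    At each cell the predecessor is identified by which move reproduces the
    cell's value: diagonal emits an aligned pair, up emits the query residue
    against a gap in the subject, left emits a gap in the query against the
    subject residue.  Ties prefer diagonal, then up.
    """
    q, s = _residues(Q), _residues(S)
    V = D.values
    if V.shape != (len(q) + 1, len(s) + 1):
        raise SablastError(
            f"matrix shape {V.shape} inconsistent with sequence lengths "
            f"({len(q)}, {len(s)})"
        )
    i, j = D.M, D.N
    cols_q: list[str] = []
    cols_s: list[str] = []
    while i > 0 or j > 0:
        here = V[i, j]
        if (
            i > 0
            and j > 0
            and here
            == V[i - 1, j - 1] + (params.match if q[i - 1] == s[j - 1] else params.mismatch)
        ):
            cols_q.append(q[i - 1])
            cols_s.append(s[j - 1])
            i, j = i - 1, j - 1
        elif i > 0 and here == V[i - 1, j] + params.gap:
            cols_q.append(q[i - 1])
            cols_s.append(GAP)
            i -= 1
        elif j > 0 and here == V[i, j - 1] + params.gap:
            cols_q.append(GAP)
            cols_s.append(s[j - 1])
            j -= 1
        else:
            raise SablastError(f"matrix inconsistent with inputs at cell ({i},{j})")
    aligned_q = "".join(reversed(cols_q))
    aligned_s = "".join(reversed(cols_s))
    return GappedAlignment(
        aligned_q=aligned_q,
        aligned_s=aligned_s,
        score=D.score,
        path_length=len(aligned_q),
        q_end=len(q),
        s_end=len(s),
    )


def align(Q: Sequence | str, S: Sequence | str, params: NwParams = NwParams()) -> GappedAlignment:
    """Convenience: fill the matrix and trace back in one call."""
    return traceback(fill_matrix(Q, S, params), Q, S, params)


def gapped_extend_hsps(
    hsps: list[Hsp],
    query: Sequence,
    subjects: dict[str, Sequence] | list[Sequence],
    params: NwParams = NwParams(),
    window: int | str = "full",
) -> list[GappedAlignment]:
    """Run gapped extension for every HSP-bearing subject.

    One alignment per (query, subject) pair regardless of how many HSPs that
    subject produced.  ``window="full"`` (default) aligns the complete
    sequences; an integer flank aligns the region spanning all of the
    subject's HSPs plus that many residues on each side, clipped to the
    sequence ends.  No HSPs → no alignments (the stage is triggered only by
    a segment pair in the FIFO).
    """
    if isinstance(subjects, list):
        subjects = {s.id: s for s in subjects}
    by_subject: dict[str, list[Hsp]] = {}
    for hsp in hsps:
        by_subject.setdefault(hsp.subject_id, []).append(hsp)
    out: list[GappedAlignment] = []
    for sid, group in by_subject.items():
        subject = subjects[sid]
        if window == "full":
            q_lo, q_hi = 1, len(query)
            s_lo, s_hi = 1, len(subject)
        else:
            flank = int(window)
            q_lo = max(1, min(h.q_start for h in group) - flank)
            q_hi = min(len(query), max(h.q_end for h in group) + flank)
            s_lo = max(1, min(h.s_start for h in group) - flank)
            s_hi = min(len(subject), max(h.s_end for h in group) + flank)
        aln = align(
            query.residues[q_lo - 1 : q_hi], subject.residues[s_lo - 1 : s_hi], params
        )
        out.append(
            GappedAlignment(
                aligned_q=aln.aligned_q,
                aligned_s=aln.aligned_s,
                score=aln.score,
                path_length=aln.path_length,
                query_id=query.id,
                subject_id=sid,
                q_start=q_lo,
                q_end=q_hi,
                s_start=s_lo,
                s_end=s_hi,
            )
        )
    return out


def lcs_length(a: str, b: str) -> int:
    """Brute-force longest-common-subsequence length (independent oracle).

    Recursive two-pointer definition with memoization on suffixes — written
    without the NW recurrence so it can stand as an independent check of the
    reference-parameter alignment score.
    """
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> int:
        if i == len(a) or j == len(b):
            return 0
        if a[i] == b[j]:
            return 1 + rec(i + 1, j + 1)
        return max(rec(i + 1, j), rec(i, j + 1))

    return rec(0, 0)


def alignments_to_tsv(alignments: list[GappedAlignment]) -> str:
    lines = ["query_id\tsubject_id\tscore\talign_length\tq_start\tq_end\ts_start\ts_end"]
    lines += [
        f"{a.query_id}\t{a.subject_id}\t{a.score}\t{a.path_length}\t"
        f"{a.q_start}\t{a.q_end}\t{a.s_start}\t{a.s_end}"
        for a in alignments
    ]
    return "\n".join(lines) + "\n"


def format_pairwise(aln: GappedAlignment, width: int = 60) -> str:
    """Human-readable pairwise block with a midline of '|' on identities."""
    mid = "".join(
        "|" if a == b and a != GAP else " " for a, b in zip(aln.aligned_q, aln.aligned_s)
    )
    blocks = []
    for i in range(0, len(aln.aligned_q), width):
        blocks.append(
            f"Q {aln.aligned_q[i : i + width]}\n  {mid[i : i + width]}\nS {aln.aligned_s[i : i + width]}"
        )
    header = f"# {aln.query_id} vs {aln.subject_id}  score={aln.score}"
    return header + "\n" + "\n\n".join(blocks) + "\n"
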