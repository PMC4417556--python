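"""Hits-combination stage: merge overlapping k-word hits into longer hits.

When query and subject share a segment longer than the word size, the
detection array reports a run of overlapping k-word hits (e.g. "ATK" and
"TKP" inside a shared "ATKP").  Extending each of them separately would do
the same ungapped extension work repeatedly, so this stage scans the
stream-ordered hits FIFO and replaces each run of overlapping or contained
same-diagonal hits with a single merged record.

Merging is restricted to hits on the same diagonal (equal s_start − q_start
offset): only then is the merged span still an exact character-for-character
match, which the ungapped extension stage assumes.  On a sorted same-diagonal
stream the single left-to-right replacement pass below is equivalent to
interval union with the overlap rule "previous end ≥ next start"; strictly
adjacent hits (end = next start − 1) are left separate, matching the
overlap-only rule of the hardware block.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field, replace

from .exceptions import StreamOrderError
from .systolic_sim import HitRecord


@dataclass(frozen=True)
class MergedHit:
    """A maximal exact-match segment assembled from one or more raw hits.

    ``source_count`` records how many raw k-word hits were folded in; a merge
    of c hits each advancing the diagonal by one step has length k + (c − 1).
    """

    q_start: int
    s_start: int
    length: int
    source_count: int = 1

    @property
    def q_end(self) -> int:
        return self.q_start + self.length - 1

    @property
    def s_end(self) -> int:
        return self.s_start + self.length - 1

    @property
    def diagonal(self) -> int:
        return self.s_start - self.q_start


def derive_interval(hit: HitRecord) -> tuple[int, int, int, int]:
    """Start/end coordinates of a raw hit from its recorded middle address.

    The array records the address of the middle character of a k=3 hit, so
    the start is the recorded address minus 1 and the end is
    start + (length − 1).  Returns ``(s_start, s_end, q_start, q_end)``.
    """
    return (hit.s_start, hit.s_end, hit.q_start, hit.q_end)


def _as_merged(record: HitRecord | MergedHit) -> MergedHit:
    if isinstance(record, MergedHit):
        return record
    s_start, _s_end, q_start, _q_end = derive_interval(record)
    return MergedHit(q_start=q_start, s_start=s_start, length=record.length)


@dataclass
class HitFifo:
    """Stream-ordered buffer of hit records between pipeline stages.

    Ordering follows the direction of the stream flow: non-decreasing subject
    start position.
    """

    records: list[HitRecord | MergedHit] = field(default_factory=list)

    @classmethod
    def from_hits(cls, hits: list[HitRecord]) -> "HitFifo":
        return cls(list(hits))

    def __len__(self) -> int:
        return len(self.records)

    def merged_records(self) -> list[MergedHit]:
        return [_as_merged(r) for r in self.records]

    def check_order(self) -> None:
        starts = [_as_merged(r).s_start for r in self.records]
        for i in range(1, len(starts)):
            if starts[i] < starts[i - 1]:
                raise StreamOrderError(
                    f"hits FIFO not in stream order: record {i + 1} starts at "
                    f"subject {starts[i]} after a record starting at {starts[i - 1]}"
                )


def combine_hits(fifo: HitFifo) -> list[MergedHit]:
    """Collapse overlapping same-diagonal hits in a stream-ordered FIFO.

    One left-to-right pass: each incoming hit is compared with the most
    recent retained hit on its diagonal; if that hit's subject end address is
    ≥ the incoming hit's subject start address the two overlap and the
    retained record is extended in place (chains of overlaps collapse
    transitively to one record).  Hits with identical coordinates — possible
    when adjacent lanes both report a boundary hit — collapse to one record
    with an incremented ``source_count``.  Output preserves stream order; a
    single-record FIFO passes through unchanged.
    """
    fifo.check_order()
    out: list[MergedHit] = []
    last_on_diagonal: dict[int, int] = {}  # diagonal -> index in out
    for record in fifo.merged_records():
        idx = last_on_diagonal.get(record.diagonal)
        if idx is not None:
            prev = out[idx]
            if prev.s_end >= record.s_start:  # overlap or containment
                new_end = max(prev.s_end, record.s_end)
                out[idx] = replace(
                    prev,
                    length=new_end - prev.s_start + 1,
                    source_count=prev.source_count + record.source_count,
                )
                continue
        out.append(record)
        last_on_diagonal[record.diagonal] = len(out) - 1
    return out


def merge_fifos(fifos: list[HitFifo]) -> HitFifo:
    """K-way merge of per-lane FIFOs into one stream-ordered FIFO.

    Each input FIFO must be internally stream-ordered.  After the k-way merge
    by subject start one :func:`combine_hits` pass catches overlaps that
    straddle lane boundaries (including duplicate identical hits reported by
    adjacent lanes).
    """
    for fifo in fifos:
        fifo.check_order()
    streams = [
        [(m.s_start, m.q_start, m) for m in fifo.merged_records()] for fifo in fifos
    ]
    merged = [item[2] for item in heapq.merge(*streams, key=lambda t: (t[0], t[1]))]
    return HitFifo(list(combine_hits(HitFifo(merged))))


def merged_hits_to_tsv(hits: list[MergedHit]) -> str:
    lines = ["q_start\tq_end\ts_start\ts_end\tlength\tsource_count"]
    lines += [
        f"{h.q_start}\t{h.q_end}\t{h.s_start}\t{h.s_end}\t{h.length}\t{h.source_count}"
        for h in hits
    ]
    return "\n".join(lines) + "\n"
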