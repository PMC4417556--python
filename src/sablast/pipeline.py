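"""End-to-end search pipeline: detect → combine → extend → (gapped align).

Mirrors the lane-parallel organization of the hardware: every subject passes
through the detection array, its hits FIFO is combined, surviving merged
hits are ungapped-extended against the threshold, and HSP-bearing pairs go
through gapped extension.  Subjects are sharded across ``lanes`` for the
parallel organization; results are reassembled in subject order, so output
is identical for any lane count.

Program modes follow the BLAST family: blastp searches protein vs protein;
blastx six-frame-translates a DNA query; tblastn six-frame-translates DNA
subjects; tblastx translates both.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .exceptions import SablastError
from .gapped_ext import GappedAlignment, NwParams, gapped_extend_hsps
from .hit_merge import HitFifo, MergedHit, combine_hits
from .seq_io import PROTEIN_ALPHABET, Alphabet, Sequence, six_frame_translate
from .systolic_sim import ArrayConfig, CycleStats, load_query, stream_subject
from .ungapped_ext import ExtensionConfig, Hsp, ScoreMatrix, blosum50, extend_all

PROGRAMS = ("blastp", "blastx", "tblastn", "tblastx")


def _default_settings() -> dict[str, Any]:
    resource = importlib.resources.files("sablast.data").joinpath("default_config.yaml")
    return yaml.safe_load(resource.read_text())


@dataclass(frozen=True)
class PipelineConfig:
    """Full run configuration; defaults come from the packaged YAML."""

    k: int
    array: ArrayConfig
    extension: ExtensionConfig
    nw: NwParams
    lanes: int
    program: str
    gapped: bool
    window: int | str

    def __post_init__(self) -> None:
        if self.lanes < 1:
            raise ValueError("lanes must be >= 1")
        if self.program not in PROGRAMS:
            raise ValueError(f"program must be one of {PROGRAMS}, got {self.program!r}")

    @classmethod
    def from_settings(cls, settings: dict[str, Any]) -> "PipelineConfig":
        merged = _default_settings()
        unknown = set(settings) - set(merged)
        if unknown:
            raise SablastError(f"unknown config keys: {sorted(unknown)}")
        merged.update(settings)
        return cls(
            k=merged["k"],
            array=ArrayConfig(
                module_size=merged["module_size"],
                num_modules=merged["num_modules"],
                register_width=merged["register_width"],
                k=merged["k"],
                per_module_windows=merged["per_module_windows"],
            ),
            extension=ExtensionConfig(T=merged["T"], X=merged["X"], mode=merged["mode"]),
            nw=NwParams(
                match=merged["match"], mismatch=merged["mismatch"], gap=merged["gap"]
            ),
            lanes=merged["lanes"],
            program=merged["program"],
            gapped=merged["gapped"],
            window=merged["window"],
        )

    @classmethod
    def default(cls, **overrides: Any) -> "PipelineConfig":
        return cls.from_settings(overrides)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            settings = yaml.safe_load(fh) or {}
        return cls.from_settings(settings)


@dataclass
class SubjectReport:
    """Stage counts for one (query, subject) pass."""

    query_id: str
    subject_id: str
    hits_raw: int
    hits_merged: int
    hsps: int
    alignments: int
    stats: CycleStats


@dataclass
class RunReport:
    """Aggregate accounting for one search run."""

    per_subject: list[SubjectReport] = field(default_factory=list)

    @property
    def hits_before_combination(self) -> int:
        return sum(r.hits_raw for r in self.per_subject)

    @property
    def hits_after_combination(self) -> int:
        return sum(r.hits_merged for r in self.per_subject)

    @property
    def extensions_performed(self) -> int:
        return self.hits_after_combination

    @property
    def total_hsps(self) -> int:
        return sum(r.hsps for r in self.per_subject)

    @property
    def total_alignments(self) -> int:
        return sum(r.alignments for r in self.per_subject)

    @property
    def total_clocks(self) -> int:
        return sum(r.stats.clocks for r in self.per_subject)

    @property
    def total_comparisons(self) -> int:
        return sum(r.stats.comparisons for r in self.per_subject)

    @property
    def max_hits_one_clock(self) -> int:
        return max((r.stats.max_hits_one_clock for r in self.per_subject), default=0)

    def to_dict(self) -> dict[str, Any]:
        return {
            "totals": {
                "hits_before_combination": self.hits_before_combination,
                "hits_after_combination": self.hits_after_combination,
                "extensions_performed": self.extensions_performed,
                "hsps": self.total_hsps,
                "alignments": self.total_alignments,
                "clocks": self.total_clocks,
                "comparisons": self.total_comparisons,
                "max_hits_one_clock": self.max_hits_one_clock,
            },
            "per_subject": [
                {
                    "query_id": r.query_id,
                    "subject_id": r.subject_id,
                    "hits_raw": r.hits_raw,
                    "hits_merged": r.hits_merged,
                    "hsps": r.hsps,
                    "alignments": r.alignments,
                    "clocks": r.stats.clocks,
                    "comparisons": r.stats.comparisons,
                    "max_hits_one_clock": r.stats.max_hits_one_clock,
                }
                for r in self.per_subject
            ],
        }


def _expand_queries(query: Sequence, program: str) -> list[Sequence]:
    if program in ("blastx", "tblastx"):
        return six_frame_translate(query)
    return [query]


def _expand_subjects(subjects: list[Sequence], program: str) -> list[Sequence]:
    if program in ("tblastn", "tblastx"):
        out: list[Sequence] = []
        for s in subjects:
            out.extend(six_frame_translate(s))
        return out
    return list(subjects)


def _search_one(
    state, query: Sequence, subject: Sequence, matrix: ScoreMatrix, config: PipelineConfig
) -> tuple[list[Hsp], list[GappedAlignment], SubjectReport]:
    try:
        raw_hits, stats = stream_subject(state, subject)
        merged = combine_hits(HitFifo.from_hits(raw_hits))
        hsps = extend_all(merged, query, subject, matrix, config.extension)
        alignments = (
            gapped_extend_hsps(hsps, query, [subject], config.nw, config.window)
            if config.gapped
            else []
        )
    except SablastError as exc:
        raise SablastError(f"subject {subject.id!r}: {exc}") from exc
    report = SubjectReport(
        query_id=query.id,
        subject_id=subject.id,
        hits_raw=len(raw_hits),
        hits_merged=len(merged),
        hsps=len(hsps),
        alignments=len(alignments),
        stats=stats,
    )
    return hsps, alignments, report


def run_search(
    query: Sequence,
    subjects: list[Sequence],
    config: PipelineConfig | None = None,
    matrix: ScoreMatrix | None = None,
) -> tuple[list[Hsp], list[GappedAlignment], RunReport]:
    """Search one query against a subject collection.

    Results are concatenated in subject order (then frame order for
    translated programs) and are deterministic for a fixed config regardless
    of ``lanes``.
    """
    if config is None:
        config = PipelineConfig.default()
    if matrix is None:
        matrix = blosum50()
    if not subjects:
        raise SablastError("subject collection is empty")

    queries = _expand_queries(query, config.program)
    if config.program in ("blastx", "tblastx"):
        # translated frame segments shorter than one word cannot seed hits
        queries = [q for q in queries if len(q) >= config.k]
        if not queries:
            raise SablastError(
                f"query {query.id!r}: no translated frame segment reaches word size k={config.k}"
            )
    subjects = _expand_subjects(subjects, config.program)

    all_hsps: list[Hsp] = []
    all_alignments: list[GappedAlignment] = []
    report = RunReport()
    for q in queries:
        state = load_query(q, config.array)
        searchable = [s for s in subjects if len(s) >= config.k]
        # shard subjects across lanes, run each lane, reassemble in order
        lanes: list[list[tuple[int, Sequence]]] = [[] for _ in range(config.lanes)]
        for idx, s in enumerate(searchable):
            lanes[idx % config.lanes].append((idx, s))
        results: dict[int, tuple[list[Hsp], list[GappedAlignment], SubjectReport]] = {}
        for lane in lanes:
            for idx, s in lane:
                results[idx] = _search_one(state, q, s, matrix, config)
        for idx in sorted(results):
            hsps, alignments, sub_report = results[idx]
            all_hsps.extend(hsps)
            all_alignments.extend(alignments)
            report.per_subject.append(sub_report)
    return all_hsps, all_alignments, report


def generate_fixture(
    seed: int,
    m: int = 100,
    n: int = 120,
    planted_len: int = 10,
    mutations: int = 0,
) -> tuple[Sequence, Sequence, dict[str, Any]]:
    """Random query/subject pair sharing a planted homologous segment.

    Two i.i.d.-uniform protein sequences of lengths ``m`` and ``n``; a
    ``planted_len``-residue window of the query is copied into the subject
    with ``mutations`` point substitutions at recorded positions.  The truth
    record carries the planted coordinates (1-based) and the mutated offsets.
    Fully reproducible from ``seed``.
    """
    if planted_len > min(m, n):
        raise SablastError(
            f"planted_len {planted_len} exceeds min sequence length {min(m, n)}"
        )
    if mutations >= planted_len and planted_len > 0:
        raise SablastError("mutations must be fewer than planted_len")
    rng = np.random.default_rng(seed)
    aas = np.array(list(PROTEIN_ALPHABET))
    q = rng.choice(aas, size=m)
    s = rng.choice(aas, size=n)
    truth: dict[str, Any] = {"planted_len": planted_len, "mutations": []}
    if planted_len > 0:
        q_at = int(rng.integers(0, m - planted_len + 1))
        s_at = int(rng.integers(0, n - planted_len + 1))
        segment = q[q_at : q_at + planted_len].copy()
        offsets = rng.choice(planted_len, size=mutations, replace=False)
        for off in offsets:
            original = segment[off]
            choices = [a for a in PROTEIN_ALPHABET if a != original]
            segment[off] = rng.choice(choices)
            truth["mutations"].append(int(off) + 1)
        s[s_at : s_at + planted_len] = segment
        truth["q_start"] = q_at + 1
        truth["s_start"] = s_at + 1
        truth["mutations"].sort()
    query = Sequence(f"fixture_query_seed{seed}", "".join(q))
    subject = Sequence(f"fixture_subject_seed{seed}", "".join(s))
    return query, subject, truth


def cli_main(argv: list[str] | None = None) -> int:
    """Entry point for the command-line interface; returns the exit status."""
    from .cli import main

    return main(argv)
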