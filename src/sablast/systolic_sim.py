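"""Behavioral simulator of the multiple-hits detection systolic array.

The hardware being modeled is a chain of detection modules, each a systolic
array of 32 processing units (PEs).  The query is loaded first so every PE
holds one encoded query residue; the subject then streams through one
residue per clock.  Each PE compares its held query residue with the subject
residue passing by, and windows of k consecutive PE match-lines feed k-input
AND gates, so *every* k-word match present at a clock edge is reported in
that single cycle — the property that distinguishes this design from
word-position-table architectures, which emit at most one hit per cycle.

This module simulates the architecture at the behavioral level: its contract
is the exact k-mer match set, with clock stamps that are streaming-consistent
(a hit's clock is its subject start position plus the k − 1 cycle pipeline
latency, so hits further along the subject never carry earlier stamps).
Gate-level wiring, clock division, and register scanning are not modeled.

Two window-placement policies are offered.  By default AND windows slide
over every query position of the full concatenated array, spanning module
boundaries, so chaining modules never loses boundary hits.  A strict
per-module mode confines windows within each module for hardware-faithful
accounting of the 32-unit building block.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .exceptions import CapacityError, SequenceValidationError
from .seq_io import NULL_CODE, Sequence, encode_sequence

#: Paper-scale geometry of one detection module.
DEFAULT_MODULE_SIZE = 32
DEFAULT_REGISTER_WIDTH = 16
DEFAULT_WORD_SIZE = 3


@dataclass(frozen=True)
class ArrayConfig:
    """Geometry of the simulated detection array.

    ``module_size`` PEs per module (32 in the reference design), chained
    serially ``num_modules`` times; every ``register_width`` AND-gate outputs
    share one hit register (16-bit in the reference design, i.e. two
    registers per 32-unit module).  ``register_width`` affects only stats
    grouping, never the hit set.
    """

    module_size: int = DEFAULT_MODULE_SIZE
    num_modules: int = 1
    register_width: int = DEFAULT_REGISTER_WIDTH
    k: int = DEFAULT_WORD_SIZE
    per_module_windows: bool = False

    def __post_init__(self) -> None:
        if self.module_size < 1 or self.num_modules < 1 or self.k < 1:
            raise ValueError("module_size, num_modules and k must be positive")
        if self.module_size % self.register_width != 0:
            raise ValueError(
                f"module_size {self.module_size} is not a whole number of "
                f"{self.register_width}-bit registers"
            )

    @property
    def total_units(self) -> int:
        return self.module_size * self.num_modules

    @classmethod
    def sized_for(cls, query_length: int, **kwargs) -> "ArrayConfig":
        """Config with enough serially chained modules to hold the query."""
        module_size = kwargs.pop("module_size", DEFAULT_MODULE_SIZE)
        num_modules = kwargs.pop("num_modules", None)
        if num_modules is None:
            num_modules = max(1, -(-query_length // module_size))
        return cls(module_size=module_size, num_modules=num_modules, **kwargs)


@dataclass(frozen=True)
class HitRecord:
    """One exact k-word match, addressed by middle-character positions.

    ``q_mid``/``s_mid`` are 1-based positions of the word's middle character
    in query and subject (for the k=3 design the recorded address is the
    middle of the 3-word); ``clock`` is the cycle at which the hit was
    registered.  Start/end coordinates are derived: start = mid − (k−1)/2,
    end = start + length − 1.
    """

    q_mid: int
    s_mid: int
    length: int
    clock: int

    @property
    def q_start(self) -> int:
        return self.q_mid - (self.length - 1) // 2

    @property
    def s_start(self) -> int:
        return self.s_mid - (self.length - 1) // 2

    @property
    def q_end(self) -> int:
        return self.q_start + self.length - 1

    @property
    def s_end(self) -> int:
        return self.s_start + self.length - 1


@dataclass
class CycleStats:
    """Per-clock accounting from one subject pass through the array.

    ``comparisons`` counts residue comparisons performed by occupied PEs:
    clocks × active array length.  ``hits_per_clock[c-1]`` is the number of
    hits registered at clock c.
    """

    clocks: int
    comparisons: int
    hits_per_clock: list[int] = field(default_factory=list)

    @property
    def max_hits_one_clock(self) -> int:
        return max(self.hits_per_clock, default=0)

    @property
    def total_hits(self) -> int:
        return sum(self.hits_per_clock)

    def to_tsv(self) -> str:
        lines = ["clock\thits_at_clock"]
        lines += [f"{c}\t{h}" for c, h in enumerate(self.hits_per_clock, start=1)]
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class ArrayState:
    """A loaded array: one encoded query residue per PE, null-padded."""

    query: Sequence
    config: ArrayConfig
    codes: tuple[int, ...]

    @property
    def occupied(self) -> int:
        return len(self.query)


def load_query(query: Sequence, config: ArrayConfig | None = None) -> ArrayState:
    """Load the query into the array, one residue per processing unit.

    Trailing unused units hold the null code 0, which never equals any
    residue code, so padding cannot create spurious matches.
    """
    if config is None:
        config = ArrayConfig.sized_for(len(query))
    if len(query) > config.total_units:
        raise CapacityError(
            f"query {query.id!r} has {len(query)} residues but the array holds "
            f"{config.total_units} ({config.num_modules} module(s) of "
            f"{config.module_size}); raise num_modules to at least "
            f"{-(-len(query) // config.module_size)}"
        )
    if len(query) < config.k:
        raise SequenceValidationError(
            f"query {query.id!r} shorter than word size k={config.k}"
        )
    codes = encode_sequence(query)
    codes += [NULL_CODE] * (config.total_units - len(codes))
    return ArrayState(query=query, config=config, codes=tuple(codes))


def _window_starts(state: ArrayState) -> list[int]:
    """0-based query window starts eligible to fire an AND gate."""
    cfg = state.config
    m, k = state.occupied, cfg.k
    starts = range(m - k + 1)
    if not cfg.per_module_windows:
        return list(starts)
    # strict mode: a window may not straddle a module boundary
    return [i for i in starts if i // cfg.module_size == (i + k - 1) // cfg.module_size]


def stream_subject(state: ArrayState, subject: Sequence) -> tuple[list[HitRecord], CycleStats]:
    """Stream the subject through the loaded array and collect all hits.

    Returns every (query window, subject window) k-word equality as a
    :class:`HitRecord`, stamped with clock = subject start + (k − 1), in
    stream order (ascending clock, then ascending query position).  All hits
    sharing one clock are reported at that clock — the multi-hit-per-cycle
    behavior of the AND-gate bank.
    """
    cfg = state.config
    k = cfg.k
    n = len(subject)
    if n < k:
        raise SequenceValidationError(
            f"subject {subject.id!r} shorter than word size k={k}"
        )
    s_codes = encode_sequence(subject)
    q_codes = state.codes
    starts = _window_starts(state)

    hits: list[HitRecord] = []
    hits_per_clock = [0] * n
    # Clock c registers the window whose subject start is j = c - (k - 1);
    # the last subject residue of that window entered the array at clock c.
    for clock in range(1, n + 1):
        j = clock - (k - 1)  # 1-based subject window start
        if j < 1:
            continue
        window = s_codes[j - 1 : j - 1 + k]
        at_this_clock = 0
        for i in starts:  # 0-based query window start
            qw = q_codes[i : i + k]
            if all(a == b and a != NULL_CODE for a, b in zip(qw, window)):
                hits.append(
                    HitRecord(
                        q_mid=i + 1 + (k - 1) // 2,
                        s_mid=j + (k - 1) // 2,
                        length=k,
                        clock=clock,
                    )
                )
                at_this_clock += 1
        hits_per_clock[clock - 1] = at_this_clock

    stats = CycleStats(
        clocks=n,
        comparisons=n * state.occupied,
        hits_per_clock=hits_per_clock,
    )
    return hits, stats


def oracle_find_hits(query: Sequence | str, subject: Sequence | str, k: int) -> set[tuple[int, int]]:
    """Exhaustive reference: all (q_start, s_start) k-word equalities.

    The canonical truth set for the simulator, computed by a double loop over
    every query/subject window pair (1-based starts).  Deliberately naive.
    """
    q = query.residues if isinstance(query, Sequence) else query
    s = subject.residues if isinstance(subject, Sequence) else subject
    if len(q) < k or len(s) < k:
        raise SequenceValidationError(f"both sequences must have length >= k={k}")
    return {
        (i + 1, j + 1)
        for i in range(len(q) - k + 1)
        for j in range(len(s) - k + 1)
        if q[i : i + k] == s[j : j + k]
    }
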