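# sablast

Seed-and-extend protein sequence search, organized the way a systolic-array
hardware accelerator organizes it — implemented as a pure-software behavioral
model with a library API and a CLI.

BLAST-style search proceeds in three steps: **finding hits** (every length-k
word of the query is located exactly in the subject; k = 3 for proteins),
**ungapped extension** (each hit grows left and right without gaps,
accumulating BLOSUM50 substitution scores, until an X-drop rule stops it;
segments scoring ≥ T become high-scoring segment pairs, HSPs), and **gapped
extension** (Needleman-Wunsch global alignment of HSP-bearing pairs).

What makes the modeled architecture interesting is the first step.  Instead
of a word-position lookup table that can report at most one hit per clock
cycle, the query is held in a systolic array of processing units — one
residue per unit, residues encoded as integers 1..20 — while the subject
streams through one residue per cycle.  Windows of k consecutive match lines
feed AND gates, so *all* k-word matches present at a clock edge are reported
in that single cycle.  A hits-combination stage then merges runs of
overlapping same-diagonal hits (e.g. `ATK` + `TKP` → `ATKP`) so each shared
segment is extended once instead of once per constituent word.

`sablast` models this pipeline at the behavioral level: exact hit sets,
stream-ordered FIFOs, per-clock statistics, lane-parallel organization —
not gate-level timing.

## Worked example

```python
import sablast as sb

query = sb.Sequence("q", "PQGEFGVY")
print(sb.extract_kwords(query, 3))
# [(1, 'PQG'), (2, 'QGE'), (3, 'GEF'), (4, 'EFG'), (5, 'FGV'), (6, 'GVY')]
#   -> (m - k) + 1 = 6 overlapping 3-words for an 8-residue query

state = sb.load_query(query)                  # one residue per processing unit
hits, stats = sb.stream_subject(state, sb.Sequence("s", "PQGEFGVY"))
print([(h.q_mid, h.s_mid, h.clock) for h in hits])
# [(2, 2, 3), (3, 3, 4), (4, 4, 5), (5, 5, 6), (6, 6, 7), (7, 7, 8)]
#   -> all six diagonal hits, addressed by middle character, clock-stamped

hsps, alignments, report = sb.run_search(
    query, [sb.Sequence("s", "PQGEFGVY")], sb.PipelineConfig.default(T=0)
)
print(report.to_dict()["totals"])
# {'hits_before_combination': 6, 'hits_after_combination': 1,
#  'extensions_performed': 1, 'hsps': 1, 'alignments': 1,
#  'clocks': 8, 'comparisons': 64, 'max_hits_one_clock': 1}
```

The six raw hits collapse to one merged hit (the whole shared 8-mer), which
extends to a single full-length HSP of score 60 (the positional sum of
BLOSUM50 diagonal scores) and one gap-free global alignment.

With the packaged Needleman-Wunsch defaults (match = 1, mismatch = 0, gap
penalty d = 0, zero first row/column) the global score degenerates to the
longest-common-subsequence length:

```python
print(sb.align("TGGCCAGTCCG", "TTGCATG").score)   # 6
print(sb.lcs_length("TGGCCAGTCCG", "TTGCATG"))    # 6  (brute-force oracle)
```

## Command line

```
sablast simulate --seed 1 --length 100 --out fixture/        # planted-homology FASTA pair
sablast search --query fixture/query.fasta \
               --subjects fixture/subjects.fasta --out results/
sablast stats results/report.json
```

`search` writes `hsps.tsv`, `alignments.tsv` and `report.json`; a YAML config
(`--config`) can override any default (word size, array geometry, T/X
thresholds, NW scores, lane count, program mode blastp/blastx/tblastn/tblastx
with six-frame translation).

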