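# Methods

## Scope of the model

`sablast` is a behavioral software model of a systolic-array BLAST
accelerator pipeline: multi-hit k-word detection, combination of overlapping
hits, ungapped extension under BLOSUM50, and Needleman-Wunsch gapped
extension.  "Behavioral" means each stage is specified by its input/output
contract — the exact k-mer match set with streaming-consistent clock stamps,
the merged-hit set, the HSP set, the alignment — not by gate-level wiring.
Clock division waveforms, register scanning procedures, FPGA resource usage
and host-interface layers are out of scope, as is assignment of statistical
significance (E-values), which the modeled architecture delegates to host
software.

## Hit detection

The query is encoded one residue per processing unit (PE); residue codes are
integers 1..20 assigned alphabetically over the standard amino-acid alphabet
(A=1 … Y=20).  The published description of the encoding gives the code
*values* ("00001" to "10100", i.e. 1..20) but labels them 3-bit; five bits
are required for 20 values, so the model follows the codes and treats the
stated width as a typo.  No residue-to-code table was published; the
alphabetical assignment is this package's own deterministic choice and is
configurable in principle (any bijection works — the hit set depends only on
equality).

Unused trailing PEs hold the null code 0, which equals nothing, so padding
cannot create hits.  Ambiguity codes (X/B/Z), accepted only in permissive
mode, also encode to 0 and therefore never seed a hit and never score above
a mismatch in extension.

The subject streams through the array one residue per clock.  A hit is a
window of k consecutive PE match lines all high; its record stores the
1-based positions of the word's middle character in query and subject (the
address convention of the downstream combination stage) and a clock stamp
defined as subject start + (k − 1) — the cycle at which the last residue of
the window has entered the array.  This makes stamps a strictly increasing
function of subject position, and all hits sharing a cycle are reported at
that cycle.  `CycleStats` counts clocks (= subject length), comparisons
(= clocks × occupied PEs) and hits per clock.

**Window placement.** A 32-unit module has only 30 fully interior 3-windows,
yet the described hardware pairs 32 AND gates with 32 units; how boundary
gates are wired across chained modules is unstated.  The default model
therefore slides windows over every query position of the full concatenated
array, so chaining modules never loses a boundary hit and the hit set equals
the exhaustive k-mer truth set.  A strict per-module mode
(`per_module_windows: true`) confines windows within each module for
hardware-faithful accounting; it can only drop boundary-straddling hits,
never add any, and the tests pin exactly that relationship.

The simulator is validated against `oracle_find_hits`, a deliberately naive
double loop over all window pairs, on hundreds of randomized pairs (lengths
3–200, alphabet sizes 2–20).

## Hit combination

Overlapping hits are merged only when they lie on the same diagonal
(equal s_start − q_start).  The published description compares only
subject-side addresses, but merging across diagonals would produce records
whose query and subject segments differ, contradicting both the worked
merge examples and the exact-match invariant that ungapped extension
assumes; the same-diagonal restriction is this package's design decision.

A raw k=3 hit's start is its recorded middle address minus 1 and its end is
start + (length − 1).  The merge is a single left-to-right pass over the
stream-ordered FIFO: each record is compared with the most recently retained
record on its diagonal and folded in when that record's subject end ≥ the
incoming subject start.  On a sorted same-diagonal stream this is interval
union under the overlap-only rule: strictly adjacent hits (end = next start
− 1) stay separate, chains of overlaps collapse transitively, and
coordinate-identical hits (possible from adjacent lanes) collapse with an
incremented `source_count`.  Tests check equivalence to an independent
per-diagonal interval-union oracle, idempotence, per-diagonal coverage
conservation, and order preservation.  `merge_fifos` performs a k-way merge
of per-lane FIFOs by subject start followed by one combination pass for
cross-lane overlaps.

## Ungapped extension

Each merged hit extends one residue pair at a time in both directions,
scored by the substitution matrix; directions are independent, so
left-complete-then-right evaluation is exact, and the seed's own residues
are scored with the same matrix.

The published description of termination is contradictory (stop when the
score is *below* a threshold in one place, stop when it is *more than* a
threshold in another).  The default is therefore standard X-drop
termination: a direction stops when its running score falls more than X
below the best seen, the segment is trimmed to the best-scoring endpoints,
and the pair qualifies as an HSP iff total score ≥ T.  This is the only
reading that is simultaneously well defined, terminating, and consistent
with seed-and-extend practice.  A `paper_literal` mode implements the
stop-when-above-T wording verbatim for fidelity experiments; it truncates
strong matches at the first moment they clear T and is not recommended.
Defaults T = 20, X = 7 (BLOSUM50 units) live in the packaged
`default_config.yaml`; T = 20 is roughly four average identity scores, X = 7
tolerates one bad flank pair without ending extension.

**BLOSUM50.** The packaged matrix is the canonical NCBI BLOSUM50 (1/3-bit
scale), cross-checked entry-by-entry against Biopython's copy in the test
suite.  The architecture's published worked example quotes BLOSUM50 scores
(L,D) = −3 and (V,V) = 4; the canonical matrix has −4 and 5, and no standard
BLOSUM/PAM matrix has the quoted pair (the example also cites a figure that
is actually a speedup chart).  This package deliberately ships the canonical
values — corrupting a standard matrix to match a typo would poison every
downstream score — and keeps one intentionally failing acceptance test as a
record of the discrepancy.

HSPs with identical coordinates (several seeds inside one homologous block)
are deduplicated coordinate-exactly; containment-based filtering is not
attempted.

## Gapped extension

Needleman-Wunsch with the modeled parameterization: match = 1, mismatch = 0,
gap penalty d = 0, first row and column zero.  Under these values the
recurrence is the longest-common-subsequence recurrence, so the optimal
score equals the LCS length — the module's primary oracle (a brute-force
recursive LCS, tested on hundreds of random pairs of length ≤ 15).  General
parameters (substitution scores, negative gap penalty with cumulative
margins) are supported because the degenerate defaults are rarely what a
user wants, but the defaults are the packaged reference values.

Traceback runs from cell (M,N) to (0,0), identifying at each cell the
predecessor that reproduces its value.  Ties prefer the diagonal (the
published rule: it shortens the path); between the two gap moves the up move
(query residue against a gap in the subject) is taken — the source is silent
here, so the tie-break is fixed and documented for determinism.  Validity
invariants (gap-stripping recovers the inputs, no doubly-gapped column,
column-wise rescoring equals the matrix score) are part of the test surface.

By default the gapped stage aligns the complete query/subject pair, one
alignment per HSP-bearing subject; full-matrix DP is quadratic, so an
integer `window` config aligns only the HSP-spanning region plus that flank.

## Pipeline, lanes, and program modes

Per subject: detect → combine → extend → (gapped align), results
concatenated in subject order.  Subjects are sharded round-robin across
`lanes` and reassembled by index, so output is bitwise identical for any
lane count — the parallel organization is modeled as a determinism contract,
not a timing claim.  Array capacity is module_size × num_modules (32-unit
modules chained serially); a query that does not fit raises an error naming
the required module count.  Program modes follow the BLAST family: blastx
six-frame-translates the query, tblastn the subjects, tblastx both.
Translations are split at stop codons (downstream stages assume the
20-letter alphabet; stop handling is this package's choice) and frame
segments shorter than k are skipped on the query side.

## Synthetic fixtures

`generate_fixture` emulates the minimal structure the pipeline is sensitive
to: two i.i.d.-uniform random protein sequences with one planted copied
segment carrying a recorded number of point substitutions at recorded
positions.  A shared exact 10-mer guarantees 8 overlapping interior 3-word
hits on one diagonal that must merge to a single length-≥10 record — the
recovery property the tests and acceptance script check.  What the generator
does *not* emulate: real amino-acid composition bias, indels inside the
homologous segment, multi-domain repeat structure, or database-scale subject
collections.  Passing tests therefore demonstrate the pipeline's
correctness contracts (hit-set exactness, merge equivalence, score
identities, determinism), not retrieval sensitivity on real proteomes.

Default fixture geometry (query 100, subject 120, planted length 10, zero
mutations) keeps every randomized suite in the test run at a few seconds on
one CPU; the acceptance script uses 300-pair cross-validation suites at
lengths up to 150 for the same reason.

## Known limitations

- Hardware-scale figures (synthesis clock rates, words/s scanning rates,
  database timings) are properties of the physical design and are not
  modeled; `CycleStats` reports cycle counts without claiming equivalence.
- The per-module window mode models a plausible strict wiring, not the
  (unpublished) actual boundary wiring.
- Nucleotide-word (k = 11) search and affine-gap or local (Smith-Waterman)
  gapped extension are not implemented.
- E-value statistics are absent by design; scores are raw matrix units.
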