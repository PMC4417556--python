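# Default run configuration. Every tunable default lives here, not in code.
# Word size for hit detection (protein BLAST uses 3).
k: 3
# Detection-array geometry: processing units per module, modules chained
# serially, AND-gate outputs per hit register, window placement policy.
module_size: 32
num_modules: 1
register_width: 16
per_module_windows: false
# Ungapped extension, in BLOSUM50 (1/3-bit) units: qualification threshold T,
# X-drop tolerance, and termination rule (xdrop | paper_literal).
T: 20
X: 7
mode: xdrop
# Gapped extension (Needleman-Wunsch) scores: identical pair, non-identical
# pair, gap penalty. The reference values reduce the score to the LCS length.
match: 1
mismatch: 0
gap: 0
# Alignment window: "full" aligns whole sequences; an integer aligns the
# HSP-spanning region plus that many flanking residues.
window: full
# Parallel detection/extension lanes (subjects are sharded across lanes).
lanes: 1
# Program mode: blastp | blastx | tblastn | tblastx.
program: blastp
# Whether to run the gapped stage at all.
gapped: true
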