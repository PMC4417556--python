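import random

import pytest

from sablast import (
    ExtensionConfig,
    MergedHit,
    SablastError,
    Sequence,
    extend_all,
    extend_hit,
    load_matrix,
)
from sablast.exceptions import MatrixFormatError
from sablast.seq_io import PROTEIN_ALPHABET
from sablast.ungapped_ext import hsps_to_tsv, segment_score
from conftest import random_protein


def positional_sum(matrix, q, s, q_start, s_start, length):
    """Independent re-summation oracle over an ungapped span (1-based)."""
    return sum(
        matrix.score(q[q_start - 1 + i], s[s_start - 1 + i]) for i in range(length)
    )


class TestScoreMatrix:
    def test_canonical_blosum50_entries(self, matrix):
        # canonical NCBI BLOSUM50 values (cross-checked against Biopython)
        assert matrix.score("L", "D") == -4
        assert matrix.score("V", "V") == 5

    def test_symmetry_and_completeness(self, matrix):
        for a in PROTEIN_ALPHABET:
            for b in PROTEIN_ALPHABET:
                assert matrix.score(a, b) == matrix.score(b, a)

    def test_matches_biopython_reference(self, matrix):
        substitution_matrices = pytest.importorskip("Bio.Align.substitution_matrices")
        ref = substitution_matrices.load("BLOSUM50")
        for a in PROTEIN_ALPHABET:
            for b in PROTEIN_ALPHABET:
                assert matrix.score(a, b) == int(ref[a][b])

    def test_ambiguity_sentinel_scores_at_matrix_minimum(self, matrix):
        floor = min(matrix.score(a, b) for a in PROTEIN_ALPHABET for b in PROTEIN_ALPHABET)
        assert matrix.score("X", "A") == floor
        assert floor < 0

    def test_asymmetric_file_rejected(self, tmp_path):
        path = tmp_path / "bad.mat"
        header = "  " + " ".join(PROTEIN_ALPHABET)
        rows = []
        for i, a in enumerate(PROTEIN_ALPHABET):
            vals = [1 if j == i else 0 for j in range(20)]
            rows.append(a + " " + " ".join(map(str, vals)))
        rows[0] = "A 1 " + " ".join(["5"] + ["0"] * 18)  # break symmetry at (A,C)
        path.write_text(header + "\n" + "\n".join(rows) + "\n")
        with pytest.raises(MatrixFormatError, match="asymmetric"):
            load_matrix(path)

    def test_incomplete_file_rejected(self, tmp_path):
        path = tmp_path / "small.mat"
        path.write_text("  A C\nA 4 0\nC 0 9\n")
        with pytest.raises(MatrixFormatError, match="missing"):
            load_matrix(path)


class TestExtendHit:
    def test_identical_pair_extends_to_full_length(self, matrix):
        q = Sequence("q", "VVV")
        hit = MergedHit(q_start=1, s_start=1, length=3)
        hsp = extend_hit(hit, q, Sequence("s", "VVV"), matrix, ExtensionConfig(T=0, X=100))
        assert (hsp.q_start, hsp.q_end, hsp.s_start, hsp.s_end) == (1, 3, 1, 3)
        assert hsp.score == 15  # three V-V pairs under canonical BLOSUM50

    def test_full_span_score_matches_positional_sum(self, matrix, rng):
        res = random_protein(rng, 30)
        q = Sequence("q", res)
        s = Sequence("s", res)
        hit = MergedHit(q_start=12, s_start=12, length=3)
        hsp = extend_hit(hit, q, s, matrix, ExtensionConfig(T=0, X=10_000))
        assert (hsp.q_start, hsp.q_end) == (1, 30)
        assert hsp.score == positional_sum(matrix, res, res, 1, 1, 30)

    def test_boundary_seed_clamps_left_extension(self, matrix):
        q = Sequence("q", "KTPAAAA")
        s = Sequence("s", "KTPAAAA")
        hit = MergedHit(q_start=1, s_start=1, length=3)
        hsp = extend_hit(hit, q, s, matrix, ExtensionConfig(T=0, X=100))
        assert hsp.q_start == 1 and hsp.q_end == 7

    def test_mismatch_wall_keeps_seed_interval(self, matrix):
        # L-D pairs score -4 on both flanks; with X=3 the first flank step
        # already drops 4 below the best score, so the HSP is the seed itself
        q = Sequence("q", "LKTPL")
        s = Sequence("s", "DKTPD")
        hit = MergedHit(q_start=2, s_start=2, length=3)
        hsp = extend_hit(hit, q, s, matrix, ExtensionConfig(T=0, X=3))
        assert (hsp.q_start, hsp.q_end, hsp.s_start, hsp.s_end) == (2, 4, 2, 4)
        assert hsp.score == positional_sum(matrix, q.residues, s.residues, 2, 2, 3)

    def test_below_threshold_returns_none(self, matrix):
        q = Sequence("q", "AAA")
        hit = MergedHit(q_start=1, s_start=1, length=3)
        assert extend_hit(hit, q, Sequence("s", "AAA"), matrix, ExtensionConfig(T=50, X=5)) is None

    def test_out_of_bounds_hit_rejected(self, matrix):
        with pytest.raises(SablastError):
            extend_hit(
                MergedHit(q_start=3, s_start=1, length=3),
                Sequence("q", "AAA"),
                Sequence("s", "AAAAA"),
                matrix,
            )

    def test_xdrop_resumes_past_shallow_dips(self, matrix):
        # a -4 dip followed by strong matches is crossed when X allows it
        q = Sequence("q", "WWWLKTP")
        s = Sequence("s", "WWWDKTP")
        hit = MergedHit(q_start=5, s_start=5, length=3)
        wide = extend_hit(hit, q, s, matrix, ExtensionConfig(T=0, X=20))
        narrow = extend_hit(hit, q, s, matrix, ExtensionConfig(T=0, X=3))
        assert wide.q_start == 1 and narrow.q_start == 5
        assert wide.score > narrow.score

    def test_paper_literal_mode_halts_once_above_threshold(self, matrix):
        res = "W" * 10  # W-W scores 15; cumulative crosses T quickly
        q = Sequence("q", res)
        s = Sequence("s", res)
        hit = MergedHit(q_start=5, s_start=5, length=3)
        hsp = extend_hit(hit, q, s, matrix, ExtensionConfig(T=50, X=1, mode="paper_literal"))
        # seed scores 45; one leftward step reaches 60 > 50 and extension halts
        assert (hsp.q_start, hsp.q_end) == (4, 7)
        assert hsp.score == 60
        # a pair that never exceeds T yields no HSP in this mode
        weak = extend_hit(
            MergedHit(q_start=1, s_start=1, length=3),
            Sequence("q", "AAA"),
            Sequence("s", "AAA"),
            matrix,
            ExtensionConfig(T=100, X=1, mode="paper_literal"),
        )
        assert weak is None


class TestExtendAllProperties:
    def _random_case(self, rng):
        res_q = random_protein(rng, rng.randint(10, 40))
        res_s = list(random_protein(rng, rng.randint(10, 40)))
        # plant a short exact seed so extension has somewhere to start
        q_at = rng.randint(0, len(res_q) - 3)
        s_at = rng.randint(0, len(res_s) - 3)
        res_s[s_at : s_at + 3] = res_q[q_at : q_at + 3]
        q = Sequence("q", res_q)
        s = Sequence("s", "".join(res_s))
        return q, s, MergedHit(q_start=q_at + 1, s_start=s_at + 1, length=3)

    def test_score_resummation_identity_and_shape(self, matrix):
        rng = random.Random(5)
        for _ in range(200):
            q, s, hit = self._random_case(rng)
            hsp = extend_hit(hit, q, s, matrix, ExtensionConfig(T=0, X=7))
            assert hsp is not None  # T=0 keeps every segment
            assert hsp.q_end - hsp.q_start == hsp.s_end - hsp.s_start
            assert hsp.q_start <= hit.q_start and hsp.q_end >= hit.q_end
            assert hsp.score == positional_sum(
                matrix, q.residues, s.residues, hsp.q_start, hsp.s_start, hsp.length
            )
            seed_score = segment_score(q, s, hit.q_start, hit.s_start, hit.length, matrix)
            assert hsp.score >= seed_score  # x-drop gains are never negative

    def test_raising_threshold_never_adds_hsps(self, matrix):
        rng = random.Random(6)
        q_res = random_protein(rng, 80)
        s_res = q_res[:40] + random_protein(rng, 40)
        q = Sequence("q", q_res)
        s = Sequence("s", s_res)
        from sablast import HitFifo, combine_hits, load_query, stream_subject

        hits, _ = stream_subject(load_query(q), s)
        merged = combine_hits(HitFifo.from_hits(hits))
        counts = [
            len(extend_all(merged, q, s, matrix, ExtensionConfig(T=T, X=7)))
            for T in (0, 10, 20, 40, 80, 200)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_seeds_in_one_block_deduplicate(self, matrix):
        res = "WCWKTPELMNWCW"
        q = Sequence("q", res)
        s = Sequence("s", res)
        seeds = [MergedHit(q_start=i, s_start=i, length=3) for i in (4, 6, 8)]
        hsps = extend_all(seeds, q, s, matrix, ExtensionConfig(T=0, X=10_000))
        assert len(hsps) == 1
        assert hsps[0].seed == seeds[0]

    def test_empty_input(self, matrix):
        assert extend_all([], Sequence("q", "AAA"), Sequence("s", "AAA"), matrix) == []


def test_hsp_tsv_columns(matrix):
    q = Sequence("q", "VVV")
    hsp = extend_hit(
        MergedHit(q_start=1, s_start=1, length=3), q, Sequence("s", "VVV"),
        matrix, ExtensionConfig(T=0, X=5),
    )
    tsv = hsps_to_tsv([hsp])
    header, row = tsv.strip().split("\n")
    assert header.split("\t") == [
        "query_id", "subject_id", "q_start", "q_end", "s_start", "s_end", "score",
    ]
    assert row.split("\t") == ["q", "s", "1", "3", "1", "3", "15"]
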