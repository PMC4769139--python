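import numpy as np
import pytest
from Bio.Align import substitution_matrices

from extscan.homology import (
    ReferenceDomain,
    assign_domain_families,
    load_reference_bundle,
    smith_waterman,
)
from extscan.seqio import ProteinRecord
from oracles import sw_score_oracle

AA = "ACDEFGHIKLMNPQRSTVWY"


def _random_seq(rng, max_len=40, min_len=1):
    n = int(rng.integers(min_len, max_len + 1))
    return "".join(rng.choice(list(AA), size=n))


class TestSmithWaterman:
    def test_identity_score_is_diagonal_sum(self):
        b62 = substitution_matrices.load("BLOSUM62")
        expected = sum(int(b62[c, c]) for c in "ACDE")
        assert smith_waterman("ACDE", "ACDE").raw_score == expected

    def test_all_negative_pairs_floor_at_zero(self):
        aln = smith_waterman("AAAA", "WWWW")
        assert aln.raw_score == 0
        assert aln.a_interval == (0, 0) and aln.b_interval == (0, 0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            smith_waterman("", "ACDE")

    def test_matches_dp_oracle_on_random_pairs(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            a, b = _random_seq(rng), _random_seq(rng)
            assert smith_waterman(a, b).raw_score == sw_score_oracle(a, b)

    def test_symmetry(self):
        rng = np.random.default_rng(23)
        for _ in range(50):
            a, b = _random_seq(rng), _random_seq(rng)
            assert smith_waterman(a, b).raw_score == smith_waterman(b, a).raw_score

    def test_self_alignment_dominates(self):
        rng = np.random.default_rng(29)
        a = _random_seq(rng, max_len=60, min_len=20)
        self_score = smith_waterman(a, a).raw_score
        for _ in range(30):
            b = _random_seq(rng, max_len=60, min_len=5)
            assert self_score >= smith_waterman(a, b).raw_score

    def test_gap_costs_affect_score(self):
        # deletion of 2 residues: affine gap open dominates
        a = "MKWVFDERHNA"
        b = "MKWVFHNA"
        cheap = smith_waterman(a, b, gap_open=2, gap_extend=1).raw_score
        expensive = smith_waterman(a, b, gap_open=30, gap_extend=1).raw_score
        assert cheap > expensive

    def test_alignment_intervals_within_sequences(self):
        rng = np.random.default_rng(31)
        for _ in range(50):
            a, b = _random_seq(rng), _random_seq(rng)
            aln = smith_waterman(a, b)
            (a0, a1), (b0, b1) = aln.a_interval, aln.b_interval
            assert 0 <= a0 <= a1 <= len(a)
            assert 0 <= b0 <= b1 <= len(b)

    def test_x_scores_minus_one(self):
        # X vs anything = -1, so XX vs XX has no positive cell
        assert smith_waterman("XX", "XX").raw_score == 0


class TestReferenceBundle:
    def test_bundle_loads_with_families(self):
        refs = load_reference_bundle()
        families = {r.family for r in refs}
        assert {"LRR", "KINASE", "FH2"} <= families
        for r in refs:
            assert 40 <= len(r.sequence) <= 600

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="family"):
            ReferenceDomain("x", "WD40", "A" * 50)

    def test_length_bounds_enforced(self):
        with pytest.raises(ValueError, match="length"):
            ReferenceDomain("x", "LRR", "A" * 10)

    def test_missing_family_tag_rejected(self, tmp_path):
        path = tmp_path / "refs.fasta"
        path.write_text(">r1 no tag here\n" + "ACDEFGHIKLMNPQRSTVWY" * 3 + "\n")
        with pytest.raises(ValueError, match="family"):
            load_reference_bundle(path)


class TestAssignFamilies:
    def test_verbatim_copy_scores_one(self):
        refs = load_reference_bundle()
        kinase = next(r for r in refs if r.family == "KINASE")
        pad = "DKHEKQHDKNEQ" * 4
        record = ProteinRecord("q", "", pad + kinase.sequence + pad)
        hits = assign_domain_families(record, refs)
        kin_hit = next(h for h in hits if h.family == "KINASE")
        assert kin_hit.normalized_score == pytest.approx(1.0)
        assert kin_hit.query_interval == (len(pad), len(pad) + len(kinase.sequence))

    def test_proline_homopolymer_no_hits(self):
        refs = load_reference_bundle()
        record = ProteinRecord("q", "", "P" * 300)
        families = {h.family for h in assign_domain_families(record, refs)}
        assert "LRR" not in families and "KINASE" not in families and "FH2" not in families

    def test_threshold_above_one_empty(self):
        refs = load_reference_bundle()
        record = ProteinRecord("q", "", refs[0].sequence)
        assert assign_domain_families(record, refs, min_normalized=1.1) == []

    def test_empty_reference_set_rejected(self):
        record = ProteinRecord("q", "", "MKV")
        with pytest.raises(ValueError):
            assign_domain_families(record, [])

    def test_normalized_scores_bounded(self, default_records):
        refs = load_reference_bundle()
        for record in default_records[:10]:
            for hit in assign_domain_families(record, refs):
                assert 0.0 <= hit.normalized_score <= 1.0 + 1e-9


def test_copied_exemplars_are_motif_free():
    # exemplars that the synthetic generator copies into proteins must not
    # smuggle SP runs or YXY motifs past the planted truth
    from extscan.motifs import scan_sp_runs, scan_yxy

    for ref in load_reference_bundle():
        if ref.family in {"LRR", "KINASE", "FH2", "OTHER"}:
            assert scan_sp_runs(ref.sequence) == []
            assert scan_yxy(ref.sequence) == []
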