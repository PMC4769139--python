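import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from extscan.regions import (
    RegionKind,
    amino_acid_composition,
    combine_regions,
    find_hrgp_regions,
    hrgp_coverage,
    load_external_regions,
    predict_gpi_omega,
    predict_signal_peptide,
    predict_transmembrane,
    RegionCall,
)
from extscan.synthetic import sample_non_signal_nterm, sample_signal_peptide
from oracles import hrgp_covered_positions_oracle, tm_covered_positions_oracle

AA = "ACDEFGHIKLMNPQRSTVWY"


class TestComposition:
    def test_pure_proline(self):
        c = amino_acid_composition("PPPP")
        assert c.fractions == {"P": 1.0}
        assert c.hrgp6_fraction == 1.0

    def test_mixed(self):
        c = amino_acid_composition("PAVSGT")
        assert c.hrgp6_fraction == pytest.approx(1.0)
        assert c.past_fraction == pytest.approx(4 / 6)

    def test_no_hrgp(self):
        assert amino_acid_composition("WWWW").hrgp6_fraction == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            amino_acid_composition("")

    @settings(max_examples=40)
    @given(st.text(alphabet=AA + "X", min_size=1, max_size=200))
    def test_fractions_sum_to_one(self, seq):
        c = amino_acid_composition(seq)
        assert sum(c.fractions.values()) == pytest.approx(1.0, abs=1e-9)
        assert 0.0 <= c.hrgp6_fraction <= 1.0 + 1e-9


class TestHrgpRegions:
    def test_saturated(self):
        (region,) = find_hrgp_regions("P" * 100)
        assert (region.start, region.end, region.score) == (0, 100, 1.0)

    def test_none(self):
        assert find_hrgp_regions("W" * 100) == []

    def test_block_in_foreign_context(self):
        seq = "W" * 50 + "SPPPP" * 10 + "W" * 50
        (region,) = find_hrgp_regions(seq)
        oracle = hrgp_covered_positions_oracle(seq)
        assert set(range(region.start, region.end)) == oracle
        assert 30 <= region.start <= 50 and 100 <= region.end <= 120

    def test_short_sequence_whole_window(self):
        (region,) = find_hrgp_regions("PAVSGT" * 4)  # length 24 < window
        assert (region.start, region.end) == (0, 24)
        assert find_hrgp_regions("WFWKWE" * 4) == []

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            find_hrgp_regions("P" * 100, window=5)
        with pytest.raises(ValueError):
            find_hrgp_regions("P" * 100, threshold=1.5)

    def test_matches_bruteforce_oracle_random(self):
        rng = np.random.default_rng(42)
        for _ in range(60):
            n = int(rng.integers(10, 300))
            seq = "".join(rng.choice(list("PAWSKET"), size=n))
            regions = find_hrgp_regions(seq)
            covered = set()
            for r in regions:
                assert covered.isdisjoint(range(r.start, r.end))  # pairwise disjoint
                covered.update(range(r.start, r.end))
            assert covered == hrgp_covered_positions_oracle(seq)

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(7)
        seq = "".join(rng.choice(list("PAVWKE"), size=400))
        prev = None
        for threshold in (0.3, 0.5, 0.7, 0.9):
            total = sum(
                r.end - r.start for r in find_hrgp_regions(seq, threshold=threshold)
            )
            if prev is not None:
                assert total <= prev
            prev = total


class TestSignalPeptide:
    def test_constructed_positive(self):
        call = predict_signal_peptide("MKTLLVLALLAVALA" + "DKHKHDDKHKHDDD")
        assert call is not None
        assert (call.start, call.end) == (0, 15)
        assert call.region is RegionKind.SIGNAL_PEPTIDE

    def test_no_h_region(self):
        assert predict_signal_peptide("M" + "D" * 40) is None

    def test_length_guard(self):
        assert predict_signal_peptide("MKTLLVLALL") is None

    def test_generator_positives_and_negatives(self):
        # >= 95% recall and specificity on unambiguous planted N-termini
        rng = np.random.default_rng(11)
        body = "DKHEKQHDKNEQ" * 5
        tp = sum(
            predict_signal_peptide(sample_signal_peptide(rng) + body) is not None
            for _ in range(200)
        )
        tn = sum(
            predict_signal_peptide(sample_non_signal_nterm(rng, 30) + body) is None
            for _ in range(200)
        )
        assert tp >= 190
        assert tn >= 190

    def test_planted_cleavage_site_recovered_exactly(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            sig = sample_signal_peptide(rng)
            call = predict_signal_peptide(sig + "DKHEKQHDKNEQDKHEKQ")
            assert call is not None and call.end == len(sig)


class TestTransmembrane:
    def test_isoleucine_block(self):
        seq = "D" * 40 + "I" * 30 + "D" * 40
        (region,) = predict_transmembrane(seq)
        assert region.start < 45 and region.end > 65

    def test_all_hydrophilic(self):
        assert predict_transmembrane("D" * 100) == []

    def test_two_blocks(self):
        seq = "D" * 30 + "L" * 25 + "D" * 40 + "L" * 25 + "D" * 30
        regions = predict_transmembrane(seq)
        assert len(regions) == 2

    def test_matches_bruteforce_oracle_random(self):
        rng = np.random.default_rng(3)
        for _ in range(60):
            n = int(rng.integers(19, 250))
            seq = "".join(rng.choice(list("ILVFDKEG"), size=n))
            covered = set()
            for r in predict_transmembrane(seq):
                covered.update(range(r.start, r.end))
            assert covered == tm_covered_positions_oracle(seq)

    def test_signal_peptide_suppression(self):
        seq = "MKTLLVLALLAVALA" + "L" * 10 + "D" * 60
        sig = predict_signal_peptide(seq)
        assert sig is not None
        with_sig = predict_transmembrane(seq, signal_peptide=sig)
        without = predict_transmembrane(seq)
        assert len(without) >= 1
        assert all(r.start >= sig.end or r.end <= sig.start for r in with_sig)

    def test_short_sequence_empty(self):
        assert predict_transmembrane("I" * 10) == []


class TestGpiOmega:
    def test_constructed_positive(self):
        call = predict_gpi_omega("M" + "K" * 60 + "SASA" + "L" * 10)
        assert call is not None
        assert call.end - call.start == 1
        assert call.region is RegionKind.GPI_OMEGA

    def test_hydrophilic_tail_absent(self):
        assert predict_gpi_omega("M" + "K" * 60 + "E" * 10) is None

    def test_short_tail_rejected(self):
        assert predict_gpi_omega("M" + "K" * 60 + "SASA" + "L" * 4) is None

    def test_length_guard(self):
        assert predict_gpi_omega("SASALLLLLLLL") is None


class TestExternalRegions:
    def test_parse_one_line(self, tmp_path):
        path = tmp_path / "ext.tsv"
        path.write_text("p1\tSIGNAL_PEPTIDE\t0\t22\t0.98\n")
        (call,) = load_external_regions(path)
        assert call.record_id == "p1"
        assert call.source == "EXTERNAL"
        assert (call.start, call.end) == (0, 22)

    def test_empty_file(self, tmp_path):
        path = tmp_path / "ext.tsv"
        path.write_text("")
        assert load_external_regions(path) == []

    def test_header_line_accepted(self, tmp_path):
        path = tmp_path / "ext.tsv"
        path.write_text("record_id\tregion\tstart\tend\tscore\np1\tTM\t5\t30\t0.5\n")
        assert len(load_external_regions(path)) == 1

    def test_bad_interval_names_line(self, tmp_path):
        path = tmp_path / "ext.tsv"
        path.write_text("p1\tTM\t30\t5\t0.5\n")
        with pytest.raises(ValueError, match=":1"):
            load_external_regions(path)

    def test_unknown_region_token(self, tmp_path):
        path = tmp_path / "ext.tsv"
        path.write_text("p1\tCHLOROPLAST\t0\t10\t0.5\n")
        with pytest.raises(ValueError, match="unknown region"):
            load_external_regions(path)

    def test_external_overrides_heuristic(self):
        heur = [RegionCall("p1", RegionKind.TM, 10, 40, 0.5)]
        ext = [RegionCall("p1", RegionKind.TM, 12, 35, 0.9, source="EXTERNAL")]
        merged = combine_regions(heur, ext)
        assert len(merged) == 1 and merged[0].source == "EXTERNAL"

    def test_non_conflicting_kept(self):
        heur = [RegionCall("p1", RegionKind.HRGP_DOMAIN, 0, 60, 0.8)]
        ext = [RegionCall("p1", RegionKind.TM, 12, 35, 0.9, source="EXTERNAL")]
        assert len(combine_regions(heur, ext)) == 2


def test_hrgp_coverage_helper():
    calls = [
        RegionCall("p", RegionKind.HRGP_DOMAIN, 0, 50, 1.0),
        RegionCall("p", RegionKind.TM, 60, 80, 1.0),
    ]
    assert hrgp_coverage(calls, 100) == pytest.approx(0.5)
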