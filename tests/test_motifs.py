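"""IUPAC matching, promoter FASTA parsing, motif scanning and DBE/DAE
classification, checked against a written-out degeneracy table, a naive
position-by-position scanner, and generator ground truth."""

import logging

import pytest

from foxotarget.motifs import (
    DAE_MOTIFS,
    DBE_LOOSE_MOTIFS,
    DBE_MOTIFS,
    IupacMotif,
    Promoter,
    classify,
    format_both_report,
    iupac_char_match,
    parse_promoter_fasta,
    scan,
    upstream_distance,
)
from foxotarget.simulate import PromoterSpike, gen_promoters

# Independent statement of the IUPAC degeneracy sets (spelled out by hand,
# not derived from the implementation's table).
IUPAC_TRUTH = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


class TestIupacCharMatch:
    def test_purine_code(self):
        assert iupac_char_match("A", "R")
        assert not iupac_char_match("C", "R")

    def test_full_truth_table(self):
        for code, members in IUPAC_TRUTH.items():
            for base in "ACGT":
                assert iupac_char_match(base, code) == (base in members)
            # unknown sequence base matches no code, not even N
            assert not iupac_char_match("N", code)

    def test_invalid_characters_rejected(self):
        with pytest.raises(ValueError):
            iupac_char_match("X", "A")
        with pytest.raises(ValueError):
            iupac_char_match("A", "Z")


class TestMotifValidation:
    def test_lowercase_accepted(self):
        assert IupacMotif("DBE", "rtaaaya").consensus == "RTAAAYA"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            IupacMotif("bad", "")

    def test_non_iupac_rejected(self):
        with pytest.raises(ValueError):
            IupacMotif("bad", "GTAXACA")


class TestParsePromoterFasta:
    def test_two_clean_records(self, tmp_path, caplog):
        fasta = tmp_path / "p.fasta"
        fasta.write_text(f">g1 desc\n{'A' * 1000}\n>g2\n{'C' * 1000}\n")
        with caplog.at_level(logging.WARNING):
            promoters = parse_promoter_fasta(fasta)
        assert [p.gene for p in promoters] == ["g1", "g2"]
        assert not caplog.records

    def test_short_record_logs_warning(self, tmp_path, caplog):
        fasta = tmp_path / "p.fasta"
        fasta.write_text(f">g1\n{'A' * 800}\n")
        with caplog.at_level(logging.WARNING):
            promoters = parse_promoter_fasta(fasta)
        assert len(promoters) == 1
        assert any("800" in r.message for r in caplog.records)

    def test_duplicate_id_rejected(self, tmp_path):
        fasta = tmp_path / "p.fasta"
        fasta.write_text(">g1\nACGT\n>g1\nACGT\n")
        with pytest.raises(ValueError, match="duplicate"):
            parse_promoter_fasta(fasta)

    def test_u_mapped_to_t_and_upper(self, tmp_path):
        fasta = tmp_path / "p.fasta"
        fasta.write_text(">g1\nacgu\n")
        (p,) = parse_promoter_fasta(fasta)
        assert p.sequence == "ACGT"

    def test_invalid_character_names_record(self, tmp_path):
        fasta = tmp_path / "p.fasta"
        fasta.write_text(">g1\nACGT\n>g2\nAC-T\n")
        with pytest.raises(ValueError, match="g2"):
            parse_promoter_fasta(fasta)

    def test_generator_roundtrip(self, tmp_path):
        path, truth = gen_promoters(
            5, length=400, seed=11, out_path=tmp_path / "p.fasta"
        )
        promoters = parse_promoter_fasta(path, expected_length=400)
        assert [p.gene for p in promoters] == truth.genes
        assert all(len(p) == 400 for p in promoters)


def naive_scan_positions(sequence, consensus):
    """O(L*w) position-by-position reference scanner."""
    hits = []
    w = len(consensus)
    for start in range(len(sequence) - w + 1):
        window = sequence[start : start + w]
        if all(iupac_char_match(b, c) for b, c in zip(window, consensus)):
            hits.append(start + 1)
    return hits


class TestScan:
    def test_planted_hit_at_offset_108(self, tmp_path):
        path, _ = gen_promoters(
            10,
            spikes=[PromoterSpike(0, "GTAAACA", 108, "DBE")],
            seed=5,
            out_path=tmp_path / "p.fasta",
        )
        promoters = parse_promoter_fasta(path)
        hits = [h for p in promoters for h in scan(p, DBE_MOTIFS)]
        assert len(hits) == 1
        assert (hits[0].gene, hits[0].start, hits[0].word) == (
            promoters[0].gene, 108, "GTAAACA",
        )

    def test_adjacent_matches(self):
        hits = scan(Promoter("g", "GTAAACAGTAAACA"), [IupacMotif("DBE", "GTAAACA")])
        assert [h.start for h in hits] == [1, 8]

    def test_matches_naive_scanner_on_random_sequence(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=10000))
        promoter = Promoter("g", seq)
        for motif in DBE_MOTIFS + DAE_MOTIFS + DBE_LOOSE_MOTIFS:
            fast = [h.start for h in scan(promoter, [motif])]
            assert fast == naive_scan_positions(seq, motif.consensus)

    def test_sequence_n_matches_nothing(self):
        hits = scan(Promoter("g", "GTANACAAAA"), [IupacMotif("m", "GTANACA")])
        assert hits == []

    def test_motif_longer_than_sequence(self, caplog):
        with caplog.at_level(logging.WARNING):
            hits = scan(Promoter("g", "ACG"), [IupacMotif("m", "GTAAACA")])
        assert hits == []
        assert any("longer" in r.message for r in caplog.records)

    def test_deterministic(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=2000))
        p = Promoter("g", seq)
        assert scan(p, DBE_MOTIFS + DAE_MOTIFS) == scan(p, DBE_MOTIFS + DAE_MOTIFS)

    def test_degenerate_dbe_superset_of_strict(self, rng):
        """RTAAAYA must match everywhere GTAAACA does (loose-mode consistency)."""
        loose = DBE_LOOSE_MOTIFS[0]
        strict = IupacMotif("DBE", "GTAAACA")
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), size=3000))
            p = Promoter("g", seq)
            strict_pos = {h.start for h in scan(p, [strict])}
            loose_pos = {h.start for h in scan(p, [loose])}
            assert strict_pos <= loose_pos

    def test_upstream_distance_convention(self):
        # a 7-mer starting at 5'-offset 994 of a 1 kb window ends at the TSS:
        # its 3'-most base sits 1 position upstream
        assert upstream_distance(994, 1000, 7) == 1
        assert upstream_distance(1, 1000, 7) == 994


class TestClassify:
    def _planted_fixture(self, tmp_path):
        """10 promoters: 3 DBE only, 3 DAE only, 2 both, 2 neither."""
        spikes = (
            [PromoterSpike(i, "GTAAACA", 100 + i, "DBE") for i in range(3)]
            + [PromoterSpike(i, "TGATAAG", 200 + i, "DAE") for i in range(3, 6)]
            + [PromoterSpike(i, "GTAAACA", 100, "DBE") for i in (6, 7)]
            + [PromoterSpike(i, "CTTATCA", 500, "DAE") for i in (6, 7)]
        )
        path, _ = gen_promoters(
            10, spikes=spikes, seed=17, out_path=tmp_path / "p.fasta"
        )
        return parse_promoter_fasta(path)

    def test_planted_category_counts(self, tmp_path):
        promoters = self._planted_fixture(tmp_path)
        result = classify(promoters, DBE_MOTIFS, DAE_MOTIFS)
        assert result.counts == {
            "DBE_only": 3, "DAE_only": 3, "both": 2, "neither": 2,
        }
        assert sum(result.counts.values()) == len(promoters)

    def test_empty_motif_lists(self, tmp_path):
        promoters = self._planted_fixture(tmp_path)
        result = classify(promoters, [], [])
        assert result.counts["neither"] == len(promoters)

    def test_no_promoters_rejected(self):
        with pytest.raises(ValueError):
            classify([], DBE_MOTIFS, DAE_MOTIFS)

    def test_random_spiking_matches_ground_truth(self, tmp_path, rng):
        """Categories derived from the scanner equal those implied by the
        independently recorded spike list."""
        count = 200
        spikes = []
        expected = {}
        for i in range(count):
            has_dbe, has_dae = rng.random() < 0.4, rng.random() < 0.4
            if has_dbe:
                word = ["GTAAACA", "TGTTTAC"][rng.integers(2)]
                spikes.append(PromoterSpike(i, word, int(rng.integers(1, 400)), "DBE"))
            if has_dae:
                word = ["TGATAAG", "CTTATCA"][rng.integers(2)]
                spikes.append(PromoterSpike(i, word, int(rng.integers(500, 900)), "DAE"))
            expected[i] = {
                (True, True): "both", (True, False): "DBE_only",
                (False, True): "DAE_only", (False, False): "neither",
            }[(has_dbe, has_dae)]
        path, truth = gen_promoters(
            count, spikes=spikes, seed=23, out_path=tmp_path / "p.fasta"
        )
        promoters = parse_promoter_fasta(path)
        result = classify(promoters, DBE_MOTIFS, DAE_MOTIFS)
        for i, gene in enumerate(truth.genes):
            assert result.per_gene[gene] == expected[i], gene

    def test_both_report_format(self, tmp_path):
        promoters = self._planted_fixture(tmp_path)
        lines = format_both_report(promoters, DBE_MOTIFS, DAE_MOTIFS)
        assert len(lines) == 2
        assert lines[0].split("\t")[1] == "[GTAAACA: 100]"
        assert lines[0].split("\t")[2] == "[CTTATCA: 500]"
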