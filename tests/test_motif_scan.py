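import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from uprshift.motif_scan import (
    ATF4_MEF,
    BUILTIN_MOTIFS,
    CRE,
    Delete,
    MotifDef,
    Substitute,
    compile_motif,
    expansions,
    hits_to_bed,
    hits_to_tsv,
    motif_map_text,
    mutate_sequence,
    scan_promoters,
    scan_sequence,
)
from uprshift.sequence_io import GenomeSequence, TssRecord, extract_promoter

from oracles import IUPAC_ORACLE, brute_force_scan, revcomp_oracle

dna = st.text(alphabet="ACGT", min_size=0, max_size=400)


def _random_dna(n, seed):
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), size=n))


class TestCompileMotif:
    def test_literal_identity(self):
        assert compile_motif("TGACGT").matches("TGACGT")

    def test_atf4_mef_expansions(self):
        # TT(G/T)CATCA(G/T) expands to exactly these four concrete sites
        assert set(expansions("TTKCATCAK")) == {
            "TTGCATCAG", "TTGCATCAT", "TTTCATCAG", "TTTCATCAT"
        }

    def test_subject_n_never_matches_concrete_letters(self):
        assert not compile_motif("TGACGT").matches("TGACGN")

    def test_motif_n_matches_subject_n(self):
        assert compile_motif("TGACGN").matches("TGACGN")
        assert compile_motif("TGACGN").matches("TGACGA")

    def test_illegal_character_position(self):
        with pytest.raises(ValueError, match="position 2"):
            compile_motif("TGXCGT")

    def test_empty_consensus(self):
        with pytest.raises(ValueError):
            MotifDef("x", "")


class TestScanSequence:
    def test_empty_sequence(self):
        assert scan_sequence("", CRE) == []

    def test_exact_length_forward(self):
        assert scan_sequence("TGACGT", CRE, "forward") == [(0, "+", "TGACGT")]

    def test_motif_longer_than_sequence(self):
        assert scan_sequence("TGA", CRE) == []

    def test_palindrome_interior_reverse_hit(self):
        # TGACGTCA carries TGACGT forward at 0 and reverse at 2
        hits = scan_sequence("TGACGTCA", CRE, "both")
        assert hits == [(0, "+", "TGACGT"), (2, "-", "ACGTCA")]

    def test_ten_kb_oracle_equivalence(self):
        seq = _random_dna(10_000, seed=20_240_601)
        for motif in (CRE, ATF4_MEF):
            assert scan_sequence(seq, motif, "both") == brute_force_scan(
                seq, motif.consensus, "both"
            )

    @given(seq=dna, consensus=st.text(
        alphabet=sorted(IUPAC_ORACLE), min_size=1, max_size=8))
    @settings(max_examples=150, deadline=None)
    def test_oracle_equivalence_property(self, seq, consensus):
        assert scan_sequence(seq, consensus, "both") == brute_force_scan(
            seq, consensus, "both"
        )

    @given(seq=dna)
    @settings(max_examples=100, deadline=None)
    def test_strand_involution(self, seq):
        # hits on revcomp(s) = strand-flipped, coordinate-mirrored hits on s
        length = len(CRE)
        flipped = sorted(
            (len(seq) - length - off, {"+": "-", "-": "+"}[strand])
            for off, strand, _ in scan_sequence(seq, CRE, "both")
        )
        direct = sorted(
            (off, strand)
            for off, strand, _ in scan_sequence(revcomp_oracle(seq), CRE, "both")
        )
        assert flipped == direct

    @given(seq=dna)
    @settings(max_examples=100, deadline=None)
    def test_matched_revalidates(self, seq):
        cm = compile_motif(ATF4_MEF)
        for _, strand, matched in scan_sequence(seq, cm, "both"):
            if strand == "+":
                assert cm.matches(matched)
            else:
                assert cm.matches(revcomp_oracle(matched))

    def test_bad_strands_argument(self):
        with pytest.raises(ValueError):
            scan_sequence("ACGT", CRE, strands="minus")


class TestScanPromoters(object):
    def test_planted_cohort_positions(self, default_cohort, default_windows):
        _, _, truth = default_cohort
        hits, has_site = scan_promoters(
            default_windows, list(BUILTIN_MOTIFS.values())
        )
        found = {
            (h.gene_id, h.motif_name, h.pos_rel_tss, h.strand_rel) for h in hits
        }
        expected = {
            (g.gene_id, p.motif_name, p.pos_rel_tss, p.strand)
            for g in truth.genes
            for p in g.placements
        }
        assert found == expected
        assert has_site == {
            g.gene_id: bool(g.placements) for g in truth.genes
        }

    def test_requires_windows(self):
        with pytest.raises(ValueError):
            scan_promoters([], [CRE])

    def test_multi_tss_dedup_on_genomic_footprint(self):
        # two transcripts of one gene with overlapping windows: the shared
        # CRE is one site; the union also covers a second, window-specific one
        contig = "A" * 30 + "TGACGT" + "A" * 24 + "TGACGT" + "A" * 30
        genome = {"c": GenomeSequence("c", contig)}
        recs = [
            TssRecord("g", "t1", "c", 41, "+"),   # window [0, 50): first CRE only
            TssRecord("g", "t2", "c", 61, "+"),   # window [20, 70): both CREs
        ]
        windows = [extract_promoter(genome, r, 40, 10) for r in recs]
        hits, has_site = scan_promoters(windows, [CRE])
        assert has_site == {"g": True}
        footprints = {(h.genomic_start, h.genomic_strand) for h in hits}
        assert footprints == {(30, "+"), (60, "+")}
        assert len(hits) == 2  # the shared CRE deduplicates to one site

    def test_minus_strand_gene_genomic_mapping(self, default_cohort, default_windows):
        genome, _, _ = default_cohort
        hits, _ = scan_promoters(default_windows, [BUILTIN_MOTIFS["ATF4_MEF"]])
        (hit,) = [h for h in hits if h.gene_id == "g004"]
        # g004 is a '-'-strand gene with ATF4_MEF planted at -120 on the
        # promoter '-' strand: the forward genomic footprint must read as a
        # TTKCATCAK expansion or its reverse complement
        footprint = genome[hit.chrom].residues[hit.genomic_start : hit.genomic_end]
        assert brute_force_scan(footprint, "TTKCATCAK", "both")

    def test_hit_count_monotonicity(self, default_cohort):
        from uprshift.synthetic_data import Placement, plant_motifs

        genome, tss_records, truth = default_cohort
        placements = truth.placements_by_gene()
        n_before = sum(len(v) for v in placements.values())
        extra = dict(placements)
        extra["g009"] = (Placement("CRE", -1000, "+"),)
        genome2 = plant_motifs(genome, tss_records, extra, seed=5)
        windows = [extract_promoter(genome2, r) for r in tss_records]
        hits, _ = scan_promoters(windows, list(BUILTIN_MOTIFS.values()))
        assert len(hits) == n_before + 1


class TestMutateSequence:
    def test_delete_planted_atf4_site(self):
        seq = "A" * 20 + "TTGCATCAG" + "A" * 20
        assert len(scan_sequence(seq, ATF4_MEF)) == 1
        edited = mutate_sequence(seq, [Delete(20, 29)])
        assert len(edited) == len(seq) - 9
        assert scan_sequence(edited, ATF4_MEF) == []
        assert seq[20:29] == "TTGCATCAG"  # input untouched

    def test_two_point_substitutions_ablate_one_cre(self):
        seq = "C" * 10 + "TGACGT" + "C" * 10 + "TGACGT" + "C" * 10
        before = scan_sequence(seq, CRE)
        assert [h[0] for h in before] == [10, 26]
        edited = mutate_sequence(seq, [Substitute(12, "C"), Substitute(14, "A")])
        assert scan_sequence(edited, CRE) == [h for h in before if h[0] == 26]

    def test_right_to_left_application(self):
        out = mutate_sequence("ACGTACGT", [Delete(0, 2), Substitute(7, "A")])
        assert out == "GTACGA"

    def test_out_of_bounds(self):
        with pytest.raises(IndexError):
            mutate_sequence("ACGT", [Substitute(4, "A")])
        with pytest.raises(IndexError):
            mutate_sequence("ACGT", [Delete(2, 5)])

    def test_bad_base(self):
        with pytest.raises(ValueError):
            mutate_sequence("ACGT", [Substitute(0, "N")])

    def test_overlapping_deletions(self):
        with pytest.raises(ValueError, match="overlapping"):
            mutate_sequence("ACGTACGT", [Delete(0, 4), Delete(3, 6)])

    @given(seq=st.text(alphabet="ACGT", min_size=1, max_size=100),
           data=st.data())
    @settings(max_examples=100, deadline=None)
    def test_substitution_roundtrip(self, seq, data):
        pos = data.draw(st.integers(0, len(seq) - 1))
        base = data.draw(st.sampled_from("ACGT"))
        edited = mutate_sequence(seq, [Substitute(pos, base)])
        assert len(edited) == len(seq)
        assert edited[:pos] == seq[:pos] and edited[pos + 1:] == seq[pos + 1:]
        assert mutate_sequence(edited, [Substitute(pos, seq[pos])]) == seq


class TestOutputs:
    def test_tsv_and_bed(self, default_windows):
        hits, _ = scan_promoters(default_windows, [CRE])
        tsv = hits_to_tsv(hits)
        assert tsv.startswith("gene_id\t")
        assert len(tsv.strip().splitlines()) == len(hits) + 1
        bed = hits_to_bed(hits)
        for line in bed.strip().splitlines():
            chrom, start, end, name, score, strand = line.split("\t")
            assert int(end) - int(start) == len(CRE)
            assert score == "0" and strand in "+-"
            assert "|CRE" in name

    def test_motif_map_text(self, default_windows):
        hits, _ = scan_promoters(default_windows, list(BUILTIN_MOTIFS.values()))
        text = motif_map_text(default_windows, hits)
        lines = text.strip().splitlines()
        assert len(lines) == len(default_windows) + 1
        assert any(">" in l or "<" in l for l in lines)   # CRE arrowheads
        assert any("^" in l or "v" in l for l in lines)   # ATF4_MEF marks
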