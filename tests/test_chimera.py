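import random

import pytest

from p74kit.chimera import (
    ENZYMES,
    OrfRecord,
    assemble_chimera,
    apply_synonymous_edits,
    find_wdp_splits,
    restriction_scan,
    split_orf,
    translate,
)
from p74kit.simulate import OrfSpec, simulate_orf


class TestTranslate:
    def test_standard_code_with_stop(self):
        tr = translate("ATGTGGGATCCGTAA")
        assert tr.protein == "MWDP"
        assert tr.stop_codon == 5

    def test_no_stop(self):
        assert translate("ATG") == ("M", None)

    def test_trailing_bases_ignored_with_warning(self):
        with pytest.warns(UserWarning, match="trailing"):
            assert translate("ATGAA").protein == "M"

    def test_ambiguous_codon_gives_x(self):
        with pytest.warns(UserWarning, match="'X'"):
            assert translate("ATGANG").protein == "MX"


class TestOrfRecord:
    @pytest.mark.parametrize(
        "cds, message",
        [
            ("TGGGATCCGTAA", "ATG"),
            ("ATGTGGGATCCG", "stop codon"),
            ("ATGTAATGGTAA", "internal stop"),
            ("ATGTGGGATCCGTA", "divisible"),
        ],
    )
    def test_invalid_orfs_rejected(self, cds, message):
        with pytest.raises(ValueError, match=message):
            OrfRecord("bad", cds)

    def test_protein_and_codon_count(self, toy_orf):
        assert toy_orf.protein == "MWDP"
        assert toy_orf.n_codons == 4


class TestFindWdpSplits:
    def test_gat_triad_already_has_bamhi(self, toy_orf):
        (sp,) = find_wdp_splits(toy_orf)
        assert sp.bamhi_present and sp.required_edits == []
        assert (sp.w_codon, sp.d_codon, sp.p_codon) == (2, 3, 4)
        assert ENZYMES["BamHI"] in toy_orf.cds

    def test_gac_triad_needs_single_edit(self):
        orf = OrfRecord("gac", "ATGTGGGACCCGTAA")
        (sp,) = find_wdp_splits(orf)
        assert not sp.bamhi_present
        assert sp.required_edits == [(9, "C", "T")]  # 3 * d_codon

    def test_no_triad_gives_empty_list(self):
        assert find_wdp_splits(OrfRecord("x", "ATGGCCTAA")) == []

    def test_multiple_triads_in_order(self):
        orf = OrfRecord("two", "ATG" + "TGGGATCCG" + "GCA" + "TGGGACCCA" + "TAA")
        splits = find_wdp_splits(orf)
        assert [s.d_codon for s in splits] == [3, 7]
        assert [s.bamhi_present for s in splits] == [True, False]


class TestApplySynonymousEdits:
    def test_gac_to_gat_preserves_protein_creates_site(self):
        orf = OrfRecord("gac", "ATGTGGGACCCGTAA")
        (sp,) = find_wdp_splits(orf)
        assert ENZYMES["BamHI"] not in orf.cds
        edited = apply_synonymous_edits(orf, sp)
        assert edited.protein == orf.protein
        assert ENZYMES["BamHI"] in edited.cds
        assert edited.applied_edits == [(9, "C", "T")]

    def test_noop_when_site_present(self, toy_orf):
        (sp,) = find_wdp_splits(toy_orf)
        assert apply_synonymous_edits(toy_orf, sp).cds == toy_orf.cds

    @pytest.mark.parametrize("seed", range(5))
    def test_translation_preserved_on_random_orfs(self, seed):
        orf, truth = simulate_orf(
            OrfSpec(length=80, wdp_positions=[30], d_codon_choice="GAC",
                    seed=seed)
        )
        (sp,) = find_wdp_splits(orf)
        assert sp.required_edits == [(3 * 30, "C", "T")]
        assert apply_synonymous_edits(orf, sp).protein == orf.protein


class TestSplitOrf:
    def test_toy_split_by_hand(self, toy_orf):
        (sp,) = find_wdp_splits(toy_orf)
        nt, ct = split_orf(toy_orf, sp)
        assert nt.protein == "MWD" and ct.protein == "P"
        assert nt.cds + ct.cds == toy_orf.cds  # reassembly is the identity

    def test_fragment_lengths_sum(self):
        orf, _ = simulate_orf(
            OrfSpec(length=120, wdp_positions=[45], d_codon_choice="GAT", seed=2)
        )
        (sp,) = find_wdp_splits(orf)
        nt, ct = split_orf(orf, sp)
        assert len(nt.protein) == sp.split_after_codon == 45
        assert len(nt.protein) + len(ct.protein) == len(orf.protein)
        assert nt.protein.endswith("WD") and ct.protein.startswith("P")

    def test_split_of_foreign_orf_rejected(self, toy_orf):
        other = OrfRecord("gac", "ATGGCCTGGGACCCGTAA")
        (sp,) = find_wdp_splits(other)
        with pytest.raises(ValueError, match="WDP|outside ORF"):
            split_orf(toy_orf, sp)


class TestAssembleChimera:
    @pytest.fixture
    def donors(self):
        a, _ = simulate_orf(
            OrfSpec(length=60, wdp_positions=[20], d_codon_choice="GAC",
                    seed=10, id="donorA"))
        b, _ = simulate_orf(
            OrfSpec(length=90, wdp_positions=[35], d_codon_choice="GAT",
                    seed=11, id="donorB"))
        return a, b

    def test_cross_chimera_concatenates_fragment_proteins(self, donors):
        a, b = donors
        (spa,) = find_wdp_splits(a)
        (spb,) = find_wdp_splits(b)
        chi = assemble_chimera(a, spa, b, spb)
        assert chi.protein == a.protein[:20] + b.protein[35:]
        junction = chi.cds[3 * 17:3 * 21]
        assert ENZYMES["BamHI"] in chi.cds

    def test_self_chimera_reproduces_donor_protein(self, donors):
        a, _ = donors
        (spa,) = find_wdp_splits(a)
        chi = assemble_chimera(a, spa, a, spa)
        assert chi.protein == a.protein

    def test_bamhi_site_spans_junction(self, donors):
        a, b = donors
        (spa,) = find_wdp_splits(a)
        (spb,) = find_wdp_splits(b)
        chi = assemble_chimera(a, spa, b, spb)
        sites = restriction_scan(chi.cds, ["BamHI"])
        junction_nt = 3 * spa.split_after_codon  # junction after D codon
        assert any(s.position <= junction_nt <= s.position + 5 for s in sites)

    def test_nt_only_construct_terminated(self, donors):
        a, _ = donors
        (spa,) = find_wdp_splits(a)
        chi = assemble_chimera(a, spa)
        assert chi.cds.endswith("TAA")
        assert chi.protein == a.protein[:20]
        assert OrfRecord("check", chi.cds).protein == chi.protein

    def test_tag_prepended_in_frame(self, donors):
        a, b = donors
        (spa,) = find_wdp_splits(a)
        (spb,) = find_wdp_splits(b)
        tag = "ATGCATCACCATCACCATCAC"  # Met + 6xHis
        chi = assemble_chimera(a, spa, b, spb, tag_cds=tag)
        assert chi.protein == "MHHHHHH" + a.protein[:20] + b.protein[35:]

    def test_tag_with_stop_rejected(self, donors):
        a, _ = donors
        (spa,) = find_wdp_splits(a)
        with pytest.raises(ValueError, match="stop"):
            assemble_chimera(a, spa, tag_cds="ATGTAA")

    def test_tag_out_of_frame_rejected(self, donors):
        a, _ = donors
        (spa,) = find_wdp_splits(a)
        with pytest.raises(ValueError, match="divisible"):
            assemble_chimera(a, spa, tag_cds="ATGC")


class TestRestrictionScan:
    def test_single_site_at_start(self):
        (site,) = restriction_scan("GGATCC", ["BamHI"])
        assert (site.enzyme, site.position) == ("BamHI", 1)

    def test_two_sites(self):
        sites = restriction_scan("GGATCCGGATCC", ["BamHI"])
        assert [s.position for s in sites] == [1, 7]

    def test_overlapping_occurrences_found(self):
        # AGATCT overlapping itself is impossible, use a palindromic tandem
        rng = random.Random(0)
        dna = "AAGCTTAAGCTT"
        sites = restriction_scan(dna, ["HindIII"])
        positions = [s.position for s in sites]
        # exhaustive scan oracle
        oracle = [i + 1 for i in range(len(dna)) if dna[i:i + 6] == "AAGCTT"]
        assert positions == oracle

    def test_absent_motif_empty(self):
        assert restriction_scan("AAAA", ["BamHI"]) == []

    def test_unknown_enzyme_rejected(self):
        with pytest.raises(ValueError, match="unknown enzyme"):
            restriction_scan("GGATCC", ["EcoRI"])

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            restriction_scan("", ["BamHI"])
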