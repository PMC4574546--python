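import numpy as np
import pytest
from hypothesis import given, strategies as st

from trdj.align import AlignmentError
from trdj.germline import (GermlineGene, NumberedVRegion, RSSignal,
                           classify_functionality, find_j_motif,
                           load_germline_set, number_v_region, validate_rs,
                           write_germline_set)
from trdj.simulate import SimulationConfig, simulate_germline

from oracles import hamming, scan_fwgxg

CONS_H = "CACAGTG"
CONS_N = "ACAAAAACC"


# --- germline set I/O --------------------------------------------------------

def test_seven_d_four_j_fixture_round_trips(germline, tmp_path):
    """A set mirroring seven D, four J and one C gene keeps its genomic
    order lists and its coding sequences through write -> load."""
    assert len(germline.d_order) == 7
    assert len(germline.j_order) == 4
    fa, tsv = tmp_path / "g.fa", tmp_path / "g.tsv"
    write_germline_set(germline, fa, tsv)
    back = load_germline_set(fa, tsv)
    assert set(back.genes) == set(germline.genes)
    for name, gene in germline.genes.items():
        assert back.genes[name].nt_seq == gene.nt_seq
    assert back.d_order == germline.d_order
    assert back.j_order == germline.j_order


def test_empty_fasta_gives_empty_set(tmp_path):
    fa = tmp_path / "empty.fa"
    fa.write_text("")
    tsv = tmp_path / "empty.tsv"
    tsv.write_text("name\tgene_type\tlocus\tsubgroup\tstrand\tstart\tend\tframe\n")
    gs = load_germline_set(fa, tsv)
    assert len(gs) == 0


def test_unannotated_fasta_id_is_named_in_error(germline, tmp_path):
    fa, tsv = tmp_path / "g.fa", tmp_path / "g.tsv"
    write_germline_set(germline, fa, tsv)
    with open(fa, "a") as fh:
        fh.write(">ORPHAN1\nACGTACGTACGT\n")
    with pytest.raises(ValueError, match="ORPHAN1"):
        load_germline_set(fa, tsv)


def test_reverse_strand_loaded_in_coding_orientation(tmp_path):
    from Bio.Seq import Seq
    coding = "GGGACGTTTACGGATTACA" * 3
    fa = tmp_path / "g.fa"
    fa.write_text(f">DREV\n{Seq(coding).reverse_complement()}\n")
    tsv = tmp_path / "g.tsv"
    tsv.write_text(
        "name\tgene_type\tlocus\tsubgroup\tstrand\tstart\tend\tframe\n"
        "DREV\tD\tTRD\t\treverse\t10\t67\t0\n")
    gs = load_germline_set(fa, tsv)
    assert gs.genes["DREV"].nt_seq == coding


# --- recombination signals ---------------------------------------------------

def test_consensus_signal_passes_with_zero_mismatches():
    sig = RSSignal(CONS_H, 23, CONS_N)
    rep = validate_rs(sig)
    assert (rep.heptamer_mismatches, rep.nonamer_mismatches) == (0, 0)
    assert rep.passed


def test_three_heptamer_substitutions_fail():
    sig = RSSignal("TGTAGTG", 12, CONS_N)
    rep = validate_rs(sig, h_max=2)
    assert rep.heptamer_mismatches == 3
    assert not rep.passed


def test_bad_consensus_length_rejected():
    with pytest.raises(ValueError):
        validate_rs(RSSignal(CONS_H, 12, CONS_N), consensus_heptamer="CACAG")


@given(hept=st.text(alphabet="ACGT", min_size=7, max_size=7),
       nona=st.text(alphabet="ACGT", min_size=9, max_size=9))
def test_mismatch_counts_equal_hamming_distance(hept, nona):
    rep = validate_rs(RSSignal(hept, 12, nona))
    assert rep.heptamer_mismatches == hamming(hept, CONS_H)
    assert rep.nonamer_mismatches == hamming(nona, CONS_N)


def test_signal_shape_invariants_enforced():
    with pytest.raises(ValueError):
        RSSignal("CACAGT", 12, CONS_N)
    with pytest.raises(ValueError):
        RSSignal(CONS_H, 15, CONS_N)


# --- J motif -----------------------------------------------------------------

@pytest.mark.parametrize("aa,expected", [
    ("XXFGAGTR", 2),
    ("XXLGAGTR", None),
    ("WGAGFGAG", 0),   # 5'-most match wins
    ("FGF", None),
])
def test_j_motif_examples(aa, expected):
    assert find_j_motif(aa) == expected


def test_j_motif_agrees_with_window_scan(rng):
    aas = ["".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=20))
           for _ in range(300)]
    for aa in aas:
        assert find_j_motif(aa) == scan_fwgxg(aa)


# --- functionality classification --------------------------------------------

def _j_gene(seq):
    return GermlineGene(name="J1", gene_type="J", locus="TRD", nt_seq=seq,
                        rs_5p=RSSignal(CONS_H, 12, CONS_N), splice_donor="GT")


def test_j_with_intact_motif_is_functional():
    seq = "ACGATCGATTAGC" + "TTTGGAAAAGGT" + "ACCGATACCGATACC"
    verdict, reasons = classify_functionality(_j_gene(seq))
    assert verdict == "functional"
    assert reasons == []


def test_j_with_altered_motif_is_pseudogene():
    # F -> L at the motif site disrupts F/W-G-X-G
    seq = "ACGATCGATTAGC" + "CTTGGAAAAGGT" + "ACCGATACCGATACC"
    verdict, reasons = classify_functionality(_j_gene(seq))
    assert verdict == "pseudogene"
    assert "j_motif_altered" in reasons


def test_v_with_internal_stop_is_pseudogene():
    nt = "ATG" + "GCT" * 40 + "TAA" + "GCT" * 40
    gene = GermlineGene(name="V1", gene_type="V", locus="TRA", nt_seq=nt)
    verdict, reasons = classify_functionality(gene)
    assert verdict == "pseudogene"
    assert "stop_codon" in reasons


def test_v_missing_2nd_cys_detected():
    # a numbered view whose position 104 carries phenylalanine, not cysteine
    ref = NumberedVRegion.from_regions(
        "Q" * 22 + "C" + "QQQ", "DDDDDD", "TT" + "W" + "T" * 14, "NNN",
        "H" * 23 + "A" + "H" * 12 + "YF", "GGGG")
    numbered = number_v_region(ref.aa_seq, ref)
    gene = GermlineGene(name="V2", gene_type="V", locus="TRA",
                        nt_seq="GCT" * 70)
    verdict, reasons = classify_functionality(gene, numbered=numbered)
    assert verdict == "pseudogene"
    assert "missing_2nd_cys" in reasons


def test_rs_defect_downgrades_to_orf():
    gene = GermlineGene(name="D9", gene_type="D", locus="TRD",
                        nt_seq="ACGGATTACAGG",
                        rs_5p=RSSignal("TTTTTTT", 12, CONS_N))
    verdict, reasons = classify_functionality(gene)
    assert verdict == "ORF"
    assert reasons == ["rs_defect"]


def test_truncated_gene_is_undetermined():
    gene = GermlineGene(name="V3", gene_type="V", locus="TRD",
                        nt_seq="GCTGCA" * 20, truncated=True)
    verdict, reasons = classify_functionality(gene)
    assert verdict == "undetermined"
    assert reasons == ["truncated"]


def test_reasons_nonempty_iff_not_functional(germline):
    for gene in germline.genes.values():
        verdict, reasons = classify_functionality(gene)
        assert (verdict != "functional") == bool(reasons)


def test_simulated_pseudogene_j_is_the_only_nonfunctional_j(germline):
    verdicts = {name: classify_functionality(germline.genes[name])[0]
                for name in germline.j_order}
    assert verdicts["SIMJ3"] == "pseudogene"
    assert all(v == "functional" for n, v in verdicts.items() if n != "SIMJ3")


# --- IMGT-style numbering ----------------------------------------------------

@pytest.fixture(scope="module")
def reference_numbering():
    return NumberedVRegion.from_regions(
        fr1="QSVTQ" + "P" * 17 + "C" + "SLA",  # 26 AA, C at 23
        cdr1="DSSSTY",                         # 6 AA
        fr2="LF" + "W" * 1 + "YKQDSKK" + "LLKIM",  # 15 AA, W at 41
        cdr2="GHSNR",                          # 5 AA
        fr3="D" * 23 + "V" + "D" * 11 + "YFEC",  # 39 AA, hydrophobic 89, C 104
        cdr3="ALRG")


def test_numbering_reference_invariants(reference_numbering):
    ref = reference_numbering
    assert ref.residue_at(23) == "C"
    assert ref.residue_at(41) == "W"
    assert ref.residue_at(104) == "C"
    lens = ref.region_lengths()
    assert lens["CDR1"] in {5, 6, 7, 9}
    assert lens["CDR2"] in {0, 3, 4, 5, 6, 7, 8}
    assert lens["CDR3"] in {2, 3, 4, 5}


def test_numbering_is_identity_on_the_reference(reference_numbering):
    out = number_v_region(reference_numbering.aa_seq, reference_numbering)
    assert out.position_labels == reference_numbering.position_labels


def test_cdr2_deletion_preserves_framework_labels(reference_numbering):
    """Some TRDV1 genes lack the CDR2 entirely; the transferred numbering
    must show an empty CDR2 but intact FR labels."""
    ref = reference_numbering
    regions = ref.regions
    query = (regions["FR1"] + regions["CDR1"] + regions["FR2"]
             + regions["FR3"] + regions["CDR3"])
    out = number_v_region(query, ref)
    lens = out.region_lengths()
    assert lens["CDR2"] == 0
    assert lens["FR2"] == len(regions["FR2"])
    assert lens["FR3"] == len(regions["FR3"])
    assert out.residue_at(23) == "C" and out.residue_at(104) == "C"


def test_cdr1_shortening_matches_hand_alignment(reference_numbering):
    """Deleting 2 CDR1 residues drops exactly two CDR1 labels and keeps
    every framework label in place."""
    ref = reference_numbering
    regions = ref.regions
    query = (regions["FR1"] + regions["CDR1"][:-2] + regions["FR2"]
             + regions["CDR2"] + regions["FR3"] + regions["CDR3"])
    out = number_v_region(query, ref)
    assert out.region_lengths()["CDR1"] == len(regions["CDR1"]) - 2
    fr_labels = [l for l in out.position_labels
                 if int(str(l).split(".")[0]) <= 26]
    assert fr_labels == [str(i) for i in range(1, 27)]


def test_unalignable_query_refused(reference_numbering):
    with pytest.raises(AlignmentError, match="unalignable"):
        number_v_region("KKKKKKKKKKRRRRRRRRRR", reference_numbering)
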