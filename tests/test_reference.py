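"""Reference-alignment parsing, filtering, and taxonomic subsetting."""

import numpy as np
import pytest

from primerkit import (
    ReferenceAlignment,
    TaxonomyPath,
    drop_allgap_columns,
    filter_ambiguous,
    read_reference_alignment,
    screen_span,
    subset_by_taxon,
    write_reference_alignment,
)
from primerkit.reference import (
    FastaParseError,
    RaggedAlignmentError,
    phylum_of,
)

from conftest import make_alignment, random_alignment


@pytest.fixture
def silva_fasta(tmp_path):
    path = tmp_path / "ref.fasta"
    path.write_text(
        ">AANH01015347.5743.7741 Eukaryota;Metazoa;Chordata;Actinopterygii\n"
        "ACGU-UGCA-\n"
        ">X12345.1.10 Eukaryota;Metazoa;Arthropoda\n"
        "acgt.tgcat\n"
    )
    return path


def test_silva_header_parsing(silva_fasta):
    aln = read_reference_alignment(silva_fasta, header_dialect="silva")
    rec = aln[0]
    assert rec.record_id == "AANH01015347"
    assert (rec.span_start, rec.span_stop) == (5743, 7741)
    assert rec.taxonomy.ranks[:2] == ("Eukaryota", "Metazoa")
    # normalization: U->T, '.'->'-', uppercase
    assert aln[0].residues == "ACGT-TGCA-"
    assert aln[1].residues == "ACGT-TGCAT"
    assert aln.n_columns == 10


def test_malformed_span_reports_line_number(tmp_path):
    path = tmp_path / "bad.fasta"
    path.write_text(">OK.1.4 Metazoa\nACGT\n>ACC.x.7 Metazoa\nACGT\n")
    with pytest.raises(FastaParseError, match="line 3"):
        read_reference_alignment(path)


def test_ragged_alignment_names_record(tmp_path):
    path = tmp_path / "ragged.fasta"
    path.write_text(">A.1.4 Metazoa\nACGT\n>B.1.6 Metazoa\nACGTAA\n")
    with pytest.raises(RaggedAlignmentError, match="'B'"):
        read_reference_alignment(path)


def test_round_trip_is_lossless(silva_fasta, tmp_path):
    aln = read_reference_alignment(silva_fasta)
    out = tmp_path / "out.fasta"
    write_reference_alignment(aln, out)
    again = read_reference_alignment(out)
    assert [s.record_id for s in again] == [s.record_id for s in aln]
    assert [s.residues for s in again] == [s.residues for s in aln]
    assert [s.taxonomy for s in again] == [s.taxonomy for s in aln]
    assert [(s.span_start, s.span_stop) for s in again] == [
        (s.span_start, s.span_stop) for s in aln
    ]


def test_duplicate_ids_rejected():
    with pytest.raises(ValueError, match="duplicate"):
        make_alignment(["ACGT", "ACGT"]).take([0, 0])


# -- filter_ambiguous -------------------------------------------------------

def test_filter_ambiguous_removes_seeded_records(rng):
    aln = random_alignment(rng, 20, 30)
    rows = [s.residues for s in aln]
    for i in (3, 7, 11):  # seed ambiguity codes into three records
        rows[i] = rows[i][:5] + "N" + rows[i][6:]
    rows[7] = rows[7][:10] + "R" + rows[7][11:]
    aln = make_alignment(rows)
    kept, log = filter_ambiguous(aln)
    assert len(kept) == 17
    assert sorted(log["record_id"]) == ["seq11", "seq3", "seq7"]
    assert set(log["reason"]) == {"ambiguous_residues"}
    # idempotence and identity on clean alignments
    again, log2 = filter_ambiguous(kept)
    assert len(again) == len(kept) and log2.empty


def test_filter_ambiguous_keeps_gaps():
    aln = make_alignment(["AC-T", "ACGT"])
    kept, log = filter_ambiguous(aln)
    assert len(kept) == 2 and log.empty


# -- drop_allgap_columns ----------------------------------------------------

def test_drop_allgap_definition():
    aln = make_alignment(["AC-GT-ACGT", "AG-CT-AAGT"])
    out, index_map = drop_allgap_columns(aln)
    assert out.n_columns == 8
    assert index_map[2] == -1 and index_map[5] == -1
    assert index_map[0] == 0 and index_map[3] == 2


def test_drop_allgap_identity():
    aln = make_alignment(["ACGT", "A-GT"])
    out, index_map = drop_allgap_columns(aln)
    assert out is aln
    assert list(index_map) == [0, 1, 2, 3]


def test_drop_allgap_matches_brute_force_and_preserves_residues(rng):
    aln = random_alignment(rng, 15, 40, gap_rate=0.5)
    out, _ = drop_allgap_columns(aln)
    expected = sum(
        1
        for j in range(aln.n_columns)
        if any(s.residues[j] != "-" for s in aln)
    )
    assert out.n_columns == expected
    assert [s.ungapped() for s in out] == [s.ungapped() for s in aln]
    # idempotence
    again, imap = drop_allgap_columns(out)
    assert again.n_columns == out.n_columns and (imap >= 0).all()


# -- screen_span ------------------------------------------------------------

def _spans(seq, sites):
    nongap = [j for j, c in enumerate(seq) if c != "-"]
    if not nongap:
        return False
    return all(nongap[0] <= a and nongap[-1] >= b - 1 for a, b in sites)


def test_screen_span_drops_short_reads():
    aln = make_alignment(
        [
            "ACGTACGTAC",  # full length
            "---TACGT--",  # starts late, ends early
            "ACGTACG---",  # ends before the last site
        ]
    )
    sites = [(0, 3), (7, 10)]
    kept, log = screen_span(aln, sites)
    assert kept.record_ids == ["seq0"]
    assert sorted(log["record_id"]) == ["seq1", "seq2"]


def test_screen_span_identity_on_full_length(rng):
    aln = random_alignment(rng, 10, 20)
    kept, log = screen_span(aln, [(2, 8), (12, 18)])
    assert len(kept) == 10 and log.empty


def test_screen_span_brute_force_and_monotonicity(rng):
    aln = random_alignment(rng, 30, 25)
    rows = []
    for s in aln:
        r = s.residues
        # seed terminal truncations (SILVA-style short reads)
        cut_l = rng.integers(0, 10)
        cut_r = rng.integers(0, 10)
        r = "-" * cut_l + r[cut_l : 25 - cut_r] + "-" * cut_r
        rows.append(r)
    aln = make_alignment(rows)
    narrow = [(5, 8)]
    wide = [(2, 8), (20, 24)]
    kept_narrow, _ = screen_span(aln, narrow)
    kept_wide, _ = screen_span(aln, wide)
    assert kept_narrow.record_ids == [
        s.record_id for s in aln if _spans(s.residues, narrow)
    ]
    assert kept_wide.record_ids == [
        s.record_id for s in aln if _spans(s.residues, wide)
    ]
    # survivors of the wider requirement are a subset of the narrower one
    assert set(kept_wide.record_ids) <= set(kept_narrow.record_ids)
    # idempotence
    again, log = screen_span(kept_wide, wide)
    assert len(again) == len(kept_wide) and log.empty


def test_screen_span_requires_sites():
    aln = make_alignment(["ACGT"])
    with pytest.raises(ValueError):
        screen_span(aln, [])


# -- taxonomy ---------------------------------------------------------------

def test_subset_by_taxon_mixed_fixture():
    taxa = [
        ("Eukaryota", "Metazoa", "Arthropoda", "Insecta"),
        ("Eukaryota", "Metazoa", "Mollusca"),
        ("Eukaryota", "Metazoa", "Arthropoda", "Crustacea"),
    ]
    aln = make_alignment(["ACGT", "AGGT", "ACTT"], taxa=taxa)
    sub = subset_by_taxon(aln, "Arthropoda", rank_depth=2)
    assert sub.record_ids == ["seq0", "seq2"]
    sub2 = subset_by_taxon(aln, "Arthropoda")  # any-rank match
    assert sub2.record_ids == ["seq0", "seq2"]


def test_subset_by_taxon_absent_label_warns():
    aln = make_alignment(["ACGT"], taxa=[("Eukaryota", "Metazoa", "Porifera")])
    with pytest.warns(UserWarning, match="Chordata"):
        sub = subset_by_taxon(aln, "Chordata")
    assert len(sub) == 0


def test_taxonomy_depth_out_of_range():
    tax = TaxonomyPath(("Eukaryota", "Metazoa"))
    with pytest.raises(IndexError):
        tax.at_depth(5)


def test_phylum_extraction():
    tax = TaxonomyPath(("Eukaryota", "Metazoa", "Arthropoda", "Insecta", "Apis"))
    assert phylum_of(tax) == "Arthropoda"
    assert phylum_of(tax, depth=1) == "Metazoa"
    # no bundled name present: terminal label is the fallback
    assert phylum_of(TaxonomyPath(("Eukaryota", "GroupX"))) == "GroupX"
    assert phylum_of(TaxonomyPath()) is None
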