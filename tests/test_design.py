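"""Conserved-region discovery, consensus primers, and refinement."""

import numpy as np
import pytest

from primerkit import (
    DegeneratePrimer,
    PrimerSite,
    RefinementConfig,
    column_conservation,
    consensus_primer,
    degeneracy,
    find_conserved_regions,
    locate_primer_site,
    plant_mismatches,
    refine_primer,
)
from primerkit.design import conservation_profile
from primerkit.simulate import (
    ConservedBlock,
    SyntheticModel,
    VariableBlock,
    generate_reference,
)

from conftest import make_alignment, random_alignment


def test_column_conservation_examples():
    aln = make_alignment(["AAC-", "ACT-", "ACTA"])
    # column 0: all A
    assert column_conservation(aln, 0) == 1.0
    # column 1: A, C, C -> 2/3
    assert column_conservation(aln, 1) == pytest.approx(2 / 3)
    # column 3: gaps ignored; single non-gap base
    assert column_conservation(aln, 3) == 1.0


def test_column_conservation_all_gap_is_zero():
    aln = make_alignment(["A-", "C-"])
    assert column_conservation(aln, 1) == 0.0


def test_conservation_matches_brute_force(rng):
    aln = random_alignment(rng, 25, 40, gap_rate=0.2)
    prof = conservation_profile(aln)
    for j in range(aln.n_columns):
        col = [s.residues[j] for s in aln if s.residues[j] != "-"]
        expected = max((col.count(b) for b in "ACGT"), default=0) / len(col) if col else 0.0
        assert prof[j] == pytest.approx(expected)


def test_fully_conserved_alignment_single_region():
    aln = make_alignment(["ACGTACGTACGTACGTACGTAC"] * 5)
    regions = find_conserved_regions(aln, min_len=18, threshold=0.95)
    assert len(regions) == 1
    assert regions[0].columns == (0, 22)
    assert regions[0].min_conservation == 1.0


def test_random_alignment_has_no_conserved_regions(rng):
    aln = random_alignment(rng, 30, 300)
    assert find_conserved_regions(aln, min_len=10, threshold=0.95) == []


def _jaccard(a, b):
    sa = set(range(*a))
    sb = set(range(*b))
    return len(sa & sb) / len(sa | sb)


def test_planted_blocks_recovered(planted_reference):
    aln, truth, _ = planted_reference
    regions = find_conserved_regions(aln, min_len=18, threshold=0.85)
    planted = truth[truth["kind"] == "conserved"]
    assert len(regions) == len(planted)
    for (_, block), region in zip(planted.iterrows(), regions):
        assert _jaccard((block["start"], block["stop"]), region.columns) >= 0.9


def test_consensus_threshold_arithmetic():
    # 70% A / 30% C at threshold 0.2 -> M; 85/10/5 -> minor bases drop out
    col1 = ["A"] * 7 + ["C"] * 3
    col2 = ["A"] * 17 + ["C"] * 2 + ["G"] * 1
    aln = make_alignment(["A" + a + b for a, b in zip(col1 * 2, col2)])
    primer = consensus_primer(aln, (0, 3), include_threshold=0.2)
    assert primer.sequence[0] == "A"  # 100% A
    assert primer.sequence[1] == "M"  # 70/30 split
    assert primer.sequence[2] == "A"  # 85/10/5


def test_consensus_modal_base_always_included():
    # three-way split below threshold still yields the modal base
    aln = make_alignment(["A", "A", "C", "G", "T", "T", "T"])
    primer = consensus_primer(aln, (0, 1), include_threshold=0.5)
    assert primer.sequence == "T"


def test_consensus_zero_threshold_is_minimal_cover():
    aln = make_alignment(["AC", "AG", "AT"])
    primer = consensus_primer(aln, (0, 2), include_threshold=0.0)
    assert primer.sequence == "AB"  # B = C/G/T


def test_consensus_all_gap_column_errors():
    aln = make_alignment(["A-G", "C-G"])
    with pytest.raises(ValueError, match="gap"):
        consensus_primer(aln, (0, 3))


# ---------------------------------------------------------------------------
# refinement
# ---------------------------------------------------------------------------

def _planted(seed=3):
    primer = DegeneratePrimer(name="fwd", sequence="GGGAAAGAAGACCCTGTTGAG", gene="28S")
    model = SyntheticModel(
        phyla=(("Arthropoda", 40), ("Mollusca", 30), ("Nematoda", 20)),
        blocks=(
            VariableBlock(40, 0.3),
            ConservedBlock(primer.sequence, "site"),
            VariableBlock(40, 0.3),
        ),
        seed=seed,
    )
    aln, truth = generate_reference(model)
    site = PrimerSite(40, 40 + len(primer))
    return aln, primer, site


def test_refine_noop_when_already_compatible():
    aln, primer, site = _planted()
    refined, audit = refine_primer(aln, primer, site)
    assert refined.sequence == primer.sequence
    assert audit.converged
    assert len(audit.iterations) == 1 and audit.iterations[0].added is None


def test_refine_recovers_planted_shared_variant():
    aln, primer, site = _planted()
    # 30% of one phylum carries C where the primer reads G (position 4)
    aln = plant_mismatches(aln, site, "Arthropoda", 0.3, 4, "C")
    refined, audit = refine_primer(aln, primer, site)
    assert audit.converged
    assert refined.sequence[4] == "M"  # A widened by C
    assert refined.sequence[:4] + refined.sequence[5:] == primer.sequence[:4] + primer.sequence[5:]
    final_prev = audit.iterations[-1].prevalence
    assert all(p <= 0.20 for p in final_prev.values())


def test_refine_reports_nonconvergence_for_spread_variants():
    aln, primer, site = _planted()
    # mismatches spread thinly: disjoint 10% cohorts at three positions
    members = [i for i, s in enumerate(aln) if "Arthropoda" in s.taxonomy.ranks]
    rows = [s.residues for s in aln]
    for k, (pos, base) in enumerate(((2, "T"), (8, "C"), (15, "A"))):
        for i in members[4 * k : 4 * (k + 1)]:  # 4/40 = 10% each
            col = site.start + pos
            rows[i] = rows[i][:col] + base + rows[i][col + 1 :]
    aln = make_alignment(rows, taxa=[s.taxonomy.ranks for s in aln])
    refined, audit = refine_primer(aln, primer, site, relocate=False)
    assert not audit.converged
    assert "Arthropoda" in audit.unresolved_phyla
    assert refined.sequence == primer.sequence


def test_refine_audit_invariants():
    aln, primer, site = _planted(seed=9)
    aln = plant_mismatches(aln, site, "Mollusca", 0.4, 7, "T")
    aln = plant_mismatches(aln, site, "Nematoda", 0.55, 12, "G")
    refined, audit = refine_primer(aln, primer, site, relocate=False)
    degs = [degeneracy(it.primer_sequence) for it in audit.iterations]
    assert degs == sorted(degs)  # degeneracy never decreases
    assert all(d <= RefinementConfig().degeneracy_cap for d in degs)
    # per-phylum mismatch prevalence never increases for a fixed site
    for a, b in zip(audit.iterations, audit.iterations[1:]):
        for phylum in a.prevalence:
            assert b.prevalence[phylum] <= a.prevalence[phylum] + 1e-12


def test_refine_respects_degeneracy_cap():
    aln, primer, site = _planted()
    aln = plant_mismatches(aln, site, "Arthropoda", 0.3, 4, "C")
    cfg = RefinementConfig(degeneracy_cap=1)
    refined, audit = refine_primer(aln, primer, site, cfg)
    assert refined.sequence == primer.sequence
    assert not audit.converged and audit.unresolved_phyla == ["Arthropoda"]


def test_small_phyla_do_not_flag():
    aln, primer, site = _planted()
    # Nematoda has 20 > 10 sequences; shrink eligibility so it is ignored
    aln = plant_mismatches(aln, site, "Nematoda", 1.0, 3, "A")
    cfg = RefinementConfig(taxa_min_n=25)
    refined, audit = refine_primer(aln, primer, site, cfg)
    assert audit.converged
    assert "Nematoda" not in audit.iterations[-1].prevalence
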