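import numpy as np
import pytest

from primerkit import ReferenceAlignment, AlignedSequence, TaxonomyPath
from primerkit.simulate import ConservedBlock, SyntheticModel, VariableBlock, generate_reference

BASES = "ACGT"


def make_alignment(rows, taxa=None):
    """Build a ReferenceAlignment from raw residue strings.

    ``taxa`` is an optional list of taxonomy paths, each a tuple of labels.
    """
    records = []
    for i, residues in enumerate(rows):
        tax = TaxonomyPath(tuple(taxa[i])) if taxa else TaxonomyPath()
        records.append(
            AlignedSequence(record_id=f"seq{i}", residues=residues, taxonomy=tax)
        )
    return ReferenceAlignment(records)


def random_alignment(rng, n_seq, n_col, gap_rate=0.0):
    """i.i.d. random ACGT alignment with optional gaps."""
    mat = rng.choice(list(BASES), size=(n_seq, n_col))
    if gap_rate:
        mat = np.where(rng.random((n_seq, n_col)) < gap_rate, "-", mat)
    return make_alignment(["".join(r) for r in mat])


@pytest.fixture
def rng():
    return np.random.default_rng(20120925)


@pytest.fixture
def planted_reference():
    """Synthetic three-phylum reference with two plain conserved blocks
    flanking a variable insert; returns (alignment, truth, model)."""
    model = SyntheticModel(
        phyla=(("Arthropoda", 40), ("Mollusca", 30), ("Nematoda", 25)),
        blocks=(
            VariableBlock(60, 0.35),
            ConservedBlock("GGGAAAGAAGACCCTGTTGAG", "fwd_site"),
            VariableBlock(150, 0.35),
            ConservedBlock("TAACTGGCTTGTGGCAGCCAAGC", "rev_site"),
            VariableBlock(50, 0.35),
        ),
        seed=11,
    )
    aln, truth = generate_reference(model)
    return aln, truth, model
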