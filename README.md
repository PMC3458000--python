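# primerkit

Design and evaluation of universal degenerate PCR primers for metazoan
rRNA metabarcoding.

Amplicon-based biodiversity surveys of environmental samples depend on
"universal" primers: oligos that anneal to conserved stretches of a marker
gene — here the nuclear 18S and 28S ribosomal DNA — across as many animal
phyla as possible, while flanking a region variable enough to tell taxa
apart. Universality is bought with degeneracy: at positions where phyla
disagree, the primer carries an IUPAC ambiguity code (R = A/G, Y = C/T, …)
and is synthesized as a mixture of all the plain sequences it denotes. Too
little degeneracy and whole phyla drop out of the survey; too much and the
primer mixture stops amplifying anything reliably.

`primerkit` implements the in-silico side of this design problem as a
library plus a `primerkit` command-line tool:

- **Reference alignment handling** — aligned FASTA with SILVA-dialect
  headers (`accession.start.stop taxonomy;…`), filtering of ambiguous
  sequences, all-gap columns, and reads too short to span the primer
  sites, and taxonomic subsetting.
- **Degenerate-primer algebra** — degeneracy (the product over positions
  of IUPAC set sizes), expansion, IUPAC-aware reverse complement, and
  mismatch counting: a target position mismatches when its base set is not
  a subset of the primer's; a gap under the primer always counts.
- **Site discovery and refinement** — conserved regions as runs of
  columns whose modal base exceeds a frequency threshold; a degenerate
  consensus primer per region; and the iterative 20% rule: while any
  phylum with more than 10 sequences has >20% of them mismatching, find a
  mismatched base shared by >20% of that phylum at a single position, add
  it to the primer's code there, and rescan — stopping when every large
  phylum is covered or no single-site fix exists.
- **Compatibility tables** — per-phylum percentages of sequences with
  one and with two-or-more mismatches under each primer, rendered as
  `"P.PP (count)"` cells.
- **Nucleotide diversity** — sliding-window Nei's π (mean pairwise
  per-site difference, pairwise deletion for gaps; default window 99,
  step 10) and ranking of candidate amplicons by the diversity between
  their primer sites.
- **In-silico PCR** — amplicon prediction on unaligned templates with a
  per-primer mismatch budget, and product-length summaries.
- **Synthetic references** — a generator that plants conserved motifs and
  variable blocks of controlled diversity with taxonomy attached, so the
  whole workflow is testable without downloading a reference database.

The sixteen published 18S/28S primer positions this package was built
around ship as bundled data (`primerkit.load_primers()`), including the
forward/reverse-complement pairs and their published degeneracies.

## Worked example

Simulate a two-phylum reference with one conserved primer site, plant a
variant base in 30% of arthropods, profile the primer, and let refinement
repair it:

```python
import primerkit as pk
from primerkit.simulate import ConservedBlock, SyntheticModel, VariableBlock

model = SyntheticModel(
    phyla=(("Arthropoda", 40), ("Mollusca", 30)),
    blocks=(
        VariableBlock(60, 0.35),
        ConservedBlock("GGGAAAGAAGACCCTGTTGAG", name="28S#8"),
        VariableBlock(60, 0.35),
    ),
    seed=4,
)
aln, truth = pk.generate_reference(model)
primer = pk.load_primers()["28S#8"]
site = pk.locate_primer_site(aln, primer)

planted = pk.plant_mismatches(aln, site, "Arthropoda", 0.3, 4, "C")
print(pk.render_profile_table([pk.profile_mismatches(planted, primer, site)]))

refined, audit = pk.refine_primer(planted, primer, site)
print("refined:", refined.sequence, "degeneracy:", refined.degeneracy,
      "converged:", audit.converged)
```

Output:

```
Taxon	28S#8 One	28S#8 Two or more
Mollusca (30)	0.00 (0)	0.00 (0)
Arthropoda (40)	30.00 (12)	0.00 (0)

refined: GGGAMAGAAGACCCTGTTGAG degeneracy: 2 converged: True
```

The profile shows 30% of the 40 arthropod sequences (12) carrying exactly
one mismatch — above the 20% flag threshold — while molluscs are fully
matched. Refinement identifies the planted C, widens position 5 from A to
M (= A/C), doubling degeneracy to 2, and converges: afterwards every
phylum is below the 20% mismatch-prevalence ceiling.

The same steps are available from the shell:

```sh
primerkit simulate --config model.toml --out ref.fasta
primerkit filter ref.fasta filtered.fasta --drop-ambiguous --drop-allgap
primerkit design filtered.fasta --min-len 18 --threshold 0.85
primerkit profile filtered.fasta
primerkit pi filtered.fasta --window 99 --step 10
primerkit amplicon templates.fasta --fwd 28S#8 --rev 28S#11_RC --max-mismatch 2
```

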