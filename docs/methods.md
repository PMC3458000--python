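# Methods

## Scope and model

`primerkit` treats universal-primer design as a sequence of operations on
a multiple sequence alignment of reference rRNA genes annotated with
taxonomy. The package does not model annealing thermodynamics: a primer's
fitness for a taxon is summarized entirely by mismatch counts between the
primer's IUPAC base sets and the aligned target slice. This is the
standard desk approximation for metabarcoding primer screening — mismatch
load predicts amplification dropout well enough to rank primers and
phyla, while melting temperature and secondary structure are left to
downstream oligo-design tools.

### Alphabet conventions

Residues are normalized to uppercase DNA: `U → T`, and the terminal-gap
character `.` used by some alignment pipelines to `-`. "Ambiguous
sequence" means any record containing a symbol outside `{A,C,G,T,-}`;
such records are removed before scanning, because a reference base that
is itself uncertain contributes no evidence about primer compatibility.
Alignment columns are 0-based half-open in the API and 1-based inclusive
in all rendered reports.

### Mismatch semantics

At each position the primer denotes a set of bases. A target position is
a mismatch when the target's base set is not a subset of the primer's
set; for plain `ACGT` targets this reduces to "the target base is not
among those the primer mixture offers", and because positions are
independent the per-window count equals the minimum Hamming distance
over the primer's full expansion (the test suite checks this equivalence
against an exhaustive oracle). A gap in the target always counts as one
mismatch per gapped column: an indel under a primer disrupts annealing
regardless of which base the primer carries. No 3′-end weighting is
applied — the refinement criterion is a plain count — though terminal
mismatches are known to be more disruptive; this is a possible extension.

## Site discovery and consensus

Conservation of a column is the frequency of its modal non-gap base
among non-gap residues (0 for all-gap columns). Candidate regions are
maximal runs of at least `min_len` consecutive columns with conservation
≥ `threshold` and gap fraction ≤ `max_gap_fraction`. Defaults
(`min_len=18`, `threshold=0.85`, `max_gap_fraction=0.1`) reflect typical
primer lengths and the degree of conservation a usable universal site
needs; region finding in the original workflow this package mechanizes
was done by eye in an alignment viewer, so the numeric criterion is this
package's own. Note that a column occupied by a genuinely degenerate
site (e.g. a 50/50 Y) is *not* conserved under this criterion — modal
frequency 0.5 — so discovery finds sites that are conserved as concrete
bases, and degeneracy is introduced afterwards by consensus building and
refinement.

The consensus primer over a region includes, per column, every base
whose frequency among non-gap residues reaches `include_threshold`
(default 0.2, aligned with the refinement share threshold), always
including the modal base; the covering IUPAC code is emitted. At
threshold 0 this is the minimal IUPAC cover of all observed bases.

## The 20% refinement rule

Refinement enforces a coverage contract: in every phylum with more than
`taxa_min_n` (default 10) sequences, at most `flag_threshold` (default
20%) of sequences may carry ≥1 mismatch. Each iteration:

1. profile ≥1-mismatch prevalence per eligible phylum at the current
   site;
2. if none exceeds the threshold, stop (converged);
3. otherwise, across all flagged phyla, find offending target bases —
   bases observed at a primer position but absent from its current set —
   and their within-phylum sharing fractions;
4. if the best-shared base exceeds `site_share_threshold` (default 20%),
   add it (one base per iteration, ties broken toward the 5′-most
   position, then alphabetically), re-localize the site, and repeat;
5. if no single-site fix qualifies, or the addition would push degeneracy
   past `degeneracy_cap`, stop and report the flagged phyla unresolved.

Adding one base per iteration keeps the degeneracy increase minimal and
makes the audit trail readable; since additions only ever widen base
sets, every sequence's mismatch count is non-increasing across
iterations at a fixed site, and degeneracy is non-decreasing. The
degeneracy cap (default 64, above the bundled set's maximum of 48)
exists because highly degenerate mixtures dilute each variant below
useful concentration and fail to amplify; phyla whose mismatches are
spread thinly over several positions (each below the share threshold)
are intentionally left unresolved rather than repaired at any cost.
Primer length and site boundaries are held fixed throughout refinement.

## Compatibility profiling

`locate_primer_site` scans every column offset (optionally both strands,
via the IUPAC-aware reverse complement) and returns the window minimizing
total mismatches over all sequences, ties to the leftmost plus-strand
window. Profiles tally, per phylum, sequences with 0, 1, and ≥2
mismatches; the one- and two-plus percentages are reported independently
(each is `100·count/n`). A site slice
that is entirely gaps counts one mismatch per column and therefore lands
in the ≥2 class — total disruption — rather than being dropped; inputs
screened with `screen_span` beforehand never hit this case. Phylum
labels are extracted by matching path components (deepest first) against
a bundled list of metazoan phylum names, with an explicit-depth override;
rendered tables order rows by that bundled list.

## Nucleotide diversity

π is Nei's nucleotide diversity: the mean over unordered sequence pairs
of (differing comparable sites)/(comparable sites), where a site is
comparable when both sequences carry an unambiguous base (pairwise
deletion). Pairs with zero comparable sites in a window are excluded
from that window's mean; a window where no pair is comparable yields
NaN. Pairwise deletion wastes the least data in gappy rRNA alignments
and is the conventional choice for π. Windows default to length 99 and
step 10 — odd-length windows center on a column, and a 10-column step
keeps tracks smooth at ~10% of the window. The implementation
accumulates per-pair cumulative sums once, making each window an O(pairs)
difference; the suite verifies every window against an independent
all-pairs loop at 1e-12.

Amplicon ranking summarizes mean and max π over windows lying strictly
between a forward and reverse primer site and sorts pairs by mean (ties
by max); pairs with no fully interior window are flagged undefined and
ranked last. An optional pre-filter drops sequences whose ungapped
length deviates from the median by more than a configurable fraction
(default 20%, off by default), mirroring the manual removal of records
with very large indels before diversity scans.

## In-silico PCR

Templates are unaligned plus-strand sequences; the reverse primer is
given in oligo orientation and its plus-strand footprint recovered by
reverse complementation. All forward and reverse windows within the
per-primer mismatch budget are enumerated; valid pairings place the
reverse window entirely downstream of the forward one and within the
product-length cap (default 5000 nt, guarding against pathological
pairings on repetitive templates). The reported product is the best by
(total mismatches, product length, leftmost forward start); an
`--all-products` style call (`predict_amplicons`) returns every pairing
in that order. Product length runs from the forward primer's 5′ end
through the reverse primer's 5′ end on the opposite strand, so it
includes both primers.

## Synthetic references

The generator emulates a filtered, taxonomically annotated reference
alignment as an ordered block layout shared by all phyla: conserved
blocks emit a motif (IUPAC codes resolved uniformly per sequence —
a real template carries a concrete allele), and variable blocks draw
each column i.i.d. from a symmetric minor-allele model: one major base
at frequency p, the other three at (1−p)/3, with p solving
1 − p² − (1−p)²/3 = d so the expected per-site heterozygosity — and
hence expected π — equals the target diversity d (feasible for
d ≤ 0.75). Indels are single-column gaps at a per-cell rate in variable
blocks only. Output is deterministic given the seed.

What the generator does not emulate: phylogenetic correlation between
sequences (no tree; sequences are exchangeable within the shared column
frequencies), long or structured indels, compositional bias, alignment
error, and between-phylum divergence at variable sites. Passing tests on
synthetic data therefore demonstrate algorithmic correctness — planted
structure is recovered exactly — not performance on real curated
references, where rates of mismatch and indel clustering are
phylogenetically structured. `plant_mismatches` mutates the first
round(fraction·n) sequences of a phylum at one site position,
deterministically, which is what refinement tests need.

Test and demonstration models in this repository use variable-block
diversity 0.35 (modal-base frequency ≈ 0.80, safely below the 0.85
conservation threshold, and typical of rRNA variable regions across a
phylum), conserved blocks carrying concrete 21–23-nt primer footprints,
tens to hundreds of sequences across 2–4 phyla, and indel rates of
0–2% — small enough to keep planted sites intact, large enough to
exercise gap handling.

## Numerical and degenerate-input choices

- Degeneracy is exact integer arithmetic; expansion is capped (default
  1024) to keep the oracle path from exploding on `N`-rich strings.
- All-gap columns map to conservation 0 and are rejected by consensus
  building with a pointed error.
- `screen_span` requires at least one interval; an empty reference after
  filtering is legal and logged, not an error.
- Ranking and table ordering use stable sorts throughout, so equal keys
  preserve input order.
- One bundled primer records a published degeneracy (6) that disagrees
  with the product rule over its own sequence (12); the bundled table
  carries both values and the self-tests treat that row as a documented
  anomaly rather than forcing either number.

## Known limitations

Mismatch counting ignores position within the primer; refinement cannot
shift or resize a site; the generator's exchangeable-sequence model
understates the clustering of real mismatches; and π values are not
claimed to reproduce any particular external service's gap conventions
beyond the stated pairwise-deletion definition.
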