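# Methods

This note records the models behind `cisbind`, the defaults that matter,
and the choices made where the design was genuinely open.

## Motif model and comparison

A motif is a W×4 matrix of non-negative per-position base weights in fixed
A, C, G, T order (one convention everywhere prevents silent transposition
bugs).  Frequencies are obtained with a small background-distributed
pseudocount (default 0.01, uniform background): enough to avoid exact zeros
downstream, small enough to leave sharp columns essentially untouched.
Coordinates are 0-based and half-open throughout the API; only rendered
reports use 1-based positions.

Columns are compared with the Pearson correlation of their frequency
4-vectors.  Zero-variance (uniform) columns correlate 0 with anything by
decision: the statistic is undefined there and a flat column carries no
signal.  Pairwise alignment is ungapped, both strands, all offsets with at
least `min_overlap = 5` aligned columns (5 is the shortest motif width the
package's generators produce).  The alignment chosen is the one maximising
the **summed** column correlation; the reported `score` is the mean over
the aligned columns, so it stays in [−1, 1].  Selecting by the sum rather
than the mean is deliberate: under mean-scoring a chance 5-column overlap
between sharp motifs reaches ~1.0 with probability ≈ 4⁻⁵ per offset, so
short spurious overlaps would dominate both search results and the decoy
null, and no similarity threshold could separate a genuine full-width match
from them.  Ties break toward more aligned columns, then smaller |offset|,
then the forward orientation.

### Significance of motif similarity

E-values are calibrated against a seeded decoy null: `n_decoys = 1000`
alignments of a column-shuffled database motif against a column-shuffled,
width-adjusted database motif.  Column shuffling destroys positional
signal while preserving the database's column composition.  The decoy
best-alignment statistic is the maximum over a few dozen weakly dependent,
approximately Gaussian column-sums, so its upper tail decays like a
Gaussian (P(max ≥ s) ≤ m·Φ̄(s)), not exponentially.  The null is therefore
summarised by a location/scale (normal-tail) fit by moments, and
E = N_db · P(S ≥ s), capped at N_db.  A Gumbel moments fit was evaluated
and rejected: its exponential tail is so much fatter than the empirical
decoy tail that even a perfect self-alignment of a sharp 10-column motif
against a 50-motif database received E ≈ 10⁻³, i.e. the conventional 10⁻³
working threshold would sit exactly at the decision boundary and genuine
matches could never clear it with a sensible margin.  The normal-tail fit
is anti-conservative far beyond the decoy range; E-values should be read
as rankings with a calibrated working threshold (10⁻³ by default), not as
literal expectations, which is exactly how such thresholds are used in
motif-similarity searches.

### Trees and families

All-vs-all distances are d = (1 − score)/2 ∈ [0, 1].  Trees are built by
average-linkage (UPGMA) agglomeration — implemented directly so that
tie-breaking is fully deterministic (lexicographically smallest pair of
cluster labels; cross-checked against scipy's average linkage in the
tests) — and exported as Newick with node height = merge distance / 2.
Families are cut from the tree by joining leaves whose connecting path
uses only edges shorter than a branch-length threshold (default 0.05 on
this package's [0, 1] distance scale; the calibration to other tools'
tree scales is approximate).  All path edges count, including pendant
ones; this keeps the rule monotone (raising the threshold can only merge
groups).  A manual override mapping supports curated exceptions, mirroring
how published groupings occasionally move a single motif on biological
grounds.  Group labels are Roman numerals in decreasing group size.

## Protein–DNA interface

Interface residues are derived from PDB-format complexes: a protein
residue belongs to the DNA-binding interface when at least one of its
heavy atoms (hydrogens are excluded — most crystal structures lack them)
lies within 4.5 Å, inclusive, of at least one DNA **base-moiety** atom.
Backbone (phosphate/sugar) contacts are ignored as largely
sequence-unspecific.  The base atom set is the fixed name set
{N1, C2, N3, C4, C5, C6, N7, C8, N9, N2, N4, N6, O2, O4, O6}; the thymine
methyl carbon is excluded with the backbone.  Only the first model of a
file is read and alternate locations other than blank/'A' are dropped.

Interface similarity of a candidate homolog is the percentage of annotated
interface positions that are aligned (not to a gap) to a residue with a
strictly positive substitution score.  The matrix is pluggable; BLOSUM62
is the default.  Both cutoffs are inclusive (≤ 4.5 Å, ≥ 50 %).

## Homology transfer

The proteome search is exact Smith–Waterman local alignment (BLOSUM62,
gap open 11 / extend 1 — the first gap residue costs 12) via Biopython's
PairwiseAligner, with expectations E = K·m·n·e^(−λS) using the
conventional gapped-BLOSUM62 constants λ = 0.267, K = 0.041 (both
configurable).  An exact, deterministic aligner was preferred over a
heuristic external search tool because target proteomes here are small
and reproducibility matters more than speed; the E-value only serves as a
cutoff (default 10⁻¹⁰).  Candidates are deduplicated per protein, keeping
the chain with the lexicographically best (motif E, homology E) key, which
is also the ranking of the final prediction list.  Database TFs without an
interface annotation pass the interface filter with similarity recorded as
absent (structures exist only for a minority of TFs); a strict mode that
drops them is available via the filter parameters.

## Promoter screen and expression filter

Promoters are the 1,000 nt upstream of the transcription start site when
known, otherwise of the ATG; the anchor base itself is excluded, minus-
strand genes are reverse-complemented, and windows running off a contig
are truncated (never padded) and flagged.  Scanning uses IUPAC degenerate
patterns on both strands with overlapping matches reported.

The in-silico expression filter ranks conditions by the hypergeometric
tail probability of drawing at least the observed number of
motif-containing genes among that condition's up-regulated set (≥ 2-fold
induction, inclusive).  Presence/absence per gene feeds the test —
repeated hits in one promoter count once, which keeps the statistic robust
in repeat-rich promoters.  The published rule this filter reproduces is
applied verbatim on top of whatever enrichment score is plugged in: keep a
sequence when at least two drought-associated conditions rank among the
top three.  The original screening service did not document its exact
ranking statistic; the hypergeometric tail is the canonical enrichment
score and is recorded here as this package's choice.

## Gold standard and benchmark

The packaged fixture transcribes a yeast one-hybrid screen of 15 selected
cis-sequences (16 screened sequences in total; one extra sequence from the
selection table has no interaction rows and is kept with zero gold
interactions rather than guessed).  TF identity is the locus identifier.
Two screened sequences with no verified interactor are retained with empty
TF fields; they contribute to neither sensitivity numerator nor
denominator but are reported per element.  The opaque "flagged" markers of
the source table are preserved without interpretation, as their meaning is
not documented.  Summing distinct (element, TF-locus) pairs over the
fixture gives 81 verified interactions, and the per-element family tallies
and R2R3-MYB overlap percentages (12/18 = 66.7 %, 64.7 %, 70.6 %) are
recomputed from it by the tests and the acceptance script.

Sensitivity pools all gold TFs; specificity pools, per element, a
configurable candidate universe (default: the database TF list, standing
in for the cloned TF library a screen draws from — a full-proteome
universe can be passed instead).  The published headline benchmark figures
of the original screen depend on a 2013 database snapshot and proteome
release that cannot be reconstructed; the package's benchmark therefore
validates the machinery on synthetic data with planted truth and on the
gold standard's internal statistics instead.

## Synthetic data: what it emulates, what it does not

`generate_database` builds TF families with a characteristic sharp motif
(columns Dirichlet-concentrated on a consensus base, concentration 50),
per-member motif variants, a conserved 60-residue DNA-binding domain (DBD)
embedded in 40-residue random flanks, interface annotations on 25 % of DBD
positions, one planted proteome homolog per TF (DBD mutated at the
configured divergence, default 10 %) and an equal number of unrelated
decoy proteins.  Families are generated in sister pairs descended from a
common ancestral consensus differing at 2 positions — mirroring the
superfamily structure of real regulators, where G-box and E-box binders or
several AC-rich element binders recognise closely related sequences.
Motif widths are constrained to 5–10 columns (the usual range of de-novo
discovered promoter motifs), default 10.

Two query modes mirror how such screens are run: *per-site* queries are
individual clean sites sampled from a family motif; *discovered-motif*
queries are built the way de-novo discovery on co-regulated promoters
builds matrices — six sampled sites of which two come from the sister
family and each is shifted by one position with probability 0.25, the
chimerism and misalignment that blur real discovered matrices.  On these
conditions the planted family is recovered for ≥ 90 % (measured: 100 %)
of family-consensus queries at the default thresholds, and per-site
queries yield distinctly higher precision than discovered-motif queries —
the qualitative behaviour expected of the approach.

Promoter sets are iid uniform nucleotide backgrounds with sites planted in
a configurable fraction of promoters; expression tables give planted genes
uniform 2–10-fold induction in drought-flagged conditions and log-normal
(σ = 0.2) noise around 1 elsewhere, with non-drought conditions inducing
an independently drawn gene set.  None of this imitates real promoter
composition, GC bias, family-size distributions or the correlation
structure of real expression compendia — passing tests demonstrate that
the machinery recovers planted signal under clean conditions, not that it
would achieve the same rates on real genomes.

All generator randomness flows from one integer seed through named
substreams; outputs are byte-reproducible.

## Problem sizes and determinism

Default study sizes — 5 families × 4 members, 40-protein proteomes,
1,000 decoys per null, 20 seeds for the recovery rate, 5 seeds for the
precision comparison — were chosen so the full validation runs comfortably
on a single CPU while leaving the measured rates stable to within a few
percent across seed choices.  Every stochastic component takes an explicit
seed; identical commands with identical seeds produce hash-identical
output files.

## Known limitations

* The motif E-value's far tail is a model extrapolation (see above); only
  its threshold behaviour is calibrated.
* Ungapped motif alignment cannot represent insertions within a motif.
* The interface filter inherits whatever bias the structure-derived
  annotation has; residues contacting DNA only through backbone atoms are
  deliberately invisible to it.
* The gold standard is a transcription of a single published screen and
  shares its biases (library content, yeast expression artefacts).
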