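# Methods

This note documents the models, conventions and numerical choices behind
each analysis, what the synthetic-data generator does and does not emulate,
and the known limitations.

## Data model and coordinates

A genome is a circular DNA string with typed features drawn from a closed
label set of 38: the 13 protein-coding genes (PCGs), 22 tRNAs (with the
leucine and serine isoacceptors disambiguated as trnL1 = Leu(CUN),
trnL2 = Leu(UUR), trnS1 = Ser(AGY), trnS2 = Ser(UCN)), two rRNAs, and the
A+T-rich control region (CR). Internally all coordinates are 0-based
half-open on the plus strand; GenBank's 1-based inclusive intervals are
converted only at the I/O boundary, so coordinate arithmetic happens in one
convention. A feature annotated across the origin
(`join(X..L, 1..Y)`) is stored as a single span whose end exceeds the genome
length; span extraction is wrap-aware. Features sharing a label are reduced
to one primary copy (the longest) with the rest flagged as duplicates;
duplicates are retained for sequence work but excluded from gene-order
extraction, mirroring how a partially duplicated genome is usually treated
as a 37-gene arrangement.

Validation is report-only: it flags PCGs that do not start with ATN or end
with TAA (or the truncated polyadenylation-completed stops TA/T), tRNAs whose
annotated anticodon departs from the canonical trnK = TTT / trnS2 = TCT, gene
overlaps beyond a 10 bp tolerance (mitochondrial genes commonly overlap by a
few bases), and missing or duplicated canonical genes.

## Strand asymmetry

AT skew = (A−T)/(A+T) and GC skew = (G−C)/(G+C). The majority strand is the
strand encoding more genes (CR excluded; ties break toward the strand
carrying cox1). Whole-genome profiles measure the majority strand of the
full circular sequence; the all-PCG scope concatenates each protein-coding
gene's majority-strand image (a `sense` switch reads each gene in its own
coding orientation instead — the distinction matters because roughly a third
of the genes are minority-strand). Ambiguity characters are excluded from
numerators and denominators; a skew whose denominator is empty is reported
as absent rather than 0. Rounding (2 decimals) is applied only at the
reporting layer.

The asymmetry call uses the GC skew of the majority strand, the more
reliable of the two skews for strand discrimination: below −ε the genome is
`normal` (the ancestral insect condition), above +ε `reversed`, otherwise
`indeterminate`. ε defaults to 0.02, small enough that any realistic skew
(observed values are ±0.05–0.28) is called unambiguously while near-zero
noise is not over-interpreted.

## Gene-order rearrangement

A gene order is a signed circular permutation over the canonical labels,
normalized to anchor cox1 first with positive sign (cox1 is unrearranged in
all relevant taxa). The normalization makes orders invariant under rotation
of the molecule and under reverse-complementing the whole genome. Breakpoint
distance counts signed circular adjacencies of one order absent from the
other, where an adjacency is identified with its reading on the opposite
strand.

Classification compares each gene to the ancestral hexapod arrangement
(trnI trnQ− trnM nad2 trnW trnC− trnY− cox1 … rrnS− CR). Statuses:

* **ancestral** — in place, same strand;
* **local_inversion** — in place, strand flipped ("inverted but remaining in
  position");
* **shuffled** — moved ≤ W gene ranks, strand kept;
* **translocation** — moved > W ranks, strand kept;
* **remote_inversion** — moved and strand flipped.

"In place" is judged strand-blind on neighbour labels: a gene is in place
when either both ancestral neighbours still flank it in any order (the
interior of an inverted block keeps its neighbour set), or at least one
oriented adjacency — same predecessor or same successor reading the circle
in a fixed direction — survives. The oriented clause keeps bystanders at an
excision or insertion junction from being flagged, while an adjacent
transposition (the classic trnK/trnD swap) still marks both participants as
shuffled; which of the two "moved" is mathematically undecidable, so both
are reported. The displacement of a moved gene is the smaller ancestral-rank
distance to either of its new neighbours; W defaults to 3 ranks, enough to
cover the tRNA-cluster shuffles this taxonomy was coined for while keeping
long-range moves in the translocation class.

Two refinements make the classifier exact on scripted events:

1. **Reflection parsimony.** Anchoring cox1 with positive sign cannot
   distinguish "cox1 inverted in place" from "all other genes inverted", so
   both reflection interpretations of the observed order are evaluated and
   the one implying fewer changed genes is kept.
2. **Bystander rescue.** A stationary gene loses both ancestral adjacencies
   when both of its flanking genes translocate away. Each gene flagged as
   moved-without-inversion is therefore re-examined with every other such
   gene bridged out of both orders; if its reduced neighbourhood is
   ancestral it is reclassified as ancestral. The rescue is refused when a
   bridged-out gene is simultaneously an observed and an ancestral
   neighbour of the candidate — the signature of a genuine mutual swap.

Genes absent from a partially sequenced genome are skipped and their
neighbours bridge over the gap in both orders. A PCG projection (tRNAs
dropped before neighbour comparison, rRNAs and CR kept) is available so that
tRNA traffic alone never marks a protein-coding gene as changed — the
convention used when counting how many PCGs a heavily rearranged genome has
moved. Block events are summarized by greedily merging observed runs of
adjacent changed genes of the same event family that are also
ancestral-adjacent; mechanism attributions (recombination vs tandem
duplication/random loss) are narrative and deliberately not inferred.

Pseudogene remnants are sought by aligning a gene's coding sequence and its
reverse complement (edlib, infix mode) against every feature-free interval
of ≥ 20 bp; hits at ≥ 60% identity are reported with the matching strand,
and where the two strand interpretations of one locus overlap only the
better one is kept. In ~85% A+T sequence, unrelated spacers align at ~55–60%
identity, so calls near the threshold warrant inspection; the remnant of an
inverted-and-translocated gene matches on the minus strand.

## Control region

The five canonical elements are detected per strand: the longest polyT run
allowing a single interruption (≥ 14 T); a maximal [TA(A)]n tract of ≥ 5
TA/TAA units (copy number by exact tiling); the best hairpin with a perfect
8–25 bp stem — searched vectorized over all stem/loop combinations, longest
stem first — with loop 3–30 bp; TATA and G(A)nT motifs within 30 bp upstream
and downstream of that stem; and the longest ≥ 20 bp window of ≥ 70% purines
downstream of the stem. Thresholds are deliberately strict and
config-exposed: in ~90% A+T sequence, 4–7 bp motifs and weak hairpins occur
constantly by chance, so the defaults were calibrated against the generator
and an A+T-matched random null model (the stem must be perfect and ≥ 12 bp;
the polyT minimum is 14 with ≤ 1 interruption). Hairpin matching is
Watson–Crick DNA only, with no thermodynamic folding.

Orientation is the argmax of per-strand layout scores, where a strand's
score is the longest chain of element kinds in the canonical 5'→3' order
(polyT → TA(A)n → TATA → stem-loop → G(A)nT → GA-rich) along that strand,
anchored at a polyT hit — without the 5' polyT anchor a scatter of weak
downstream motifs carries no orientation information. Ties (including no
elements at all) are `indeterminate`. Because a hairpin is strand-symmetric,
stem hits alone never decide orientation.

Tandem repeats are found by comparing the sequence with itself at every
shift d ≥ 20 bp and taking, per diagonal, the best-scoring window (+1 match,
−3 mismatch) spanning at least one unit at ≥ 85% identity; the score-based
extension ends tracks where self-similarity ends rather than letting them
degrade to the identity floor. Overlapping tracks keep the highest
copy-number × identity.

## Ka/Ks (Nei–Gojobori)

The classic unweighted Nei–Gojobori method under the invertebrate
mitochondrial code (table 5: TGA = Trp, AGA/AGG = Ser; stops TAA/TAG only).
Per codon position, the synonymous site fraction is the fraction of the
possible single-base changes that are synonymous, with changes into stop
codons excluded from the denominator; differences between codon pairs are
averaged over all orderings of the single-base steps, discarding pathways
through stops (a pair with no stop-free pathway is skipped with a warning).
Codons containing gaps or ambiguity in either sequence are excluded pairwise
(partial genomes make complete-column deletion wasteful). Site counts are
averaged over the two sequences; proportions are corrected with
K = −(3/4)·ln(1 − (4/3)p), raising a saturation error at p ≥ 3/4; fewer than
30 comparable codons is an error; Ka/Ks is undefined (not 0) when Ks = 0.

Genome-level rates concatenate the comparable codons of all shared PCGs
(optionally excluding genes, e.g. one that failed to amplify in several
taxa) and also report per-gene estimates; saturated or data-poor genes are
flagged and left out of the concatenation. When no externally computed codon
alignment is supplied, gene pairs are trimmed to their shared codon count
from the start — a deterministic gap-free fallback adequate for indel-free
comparisons such as the synthetic pairs; supply alignments for real
divergent taxa.

Recovery behaviour: on simulated 3000-codon pairs the estimator shows a
small (~+10%) upward bias in Ka/Ks at moderate divergence, because
two-state degeneracy classes saturate faster than the four-state
Jukes–Cantor correction assumes; medians over 50 replicates stay within 15%
of truth across dN/dS from 0.05 to 1.0 (measured by the acceptance script).

## Phylogenetic matrices

Per-gene codon alignments are concatenated following the ancestral gene
order into four matrix kinds: `aa` (table-5 translations), `pos123`,
`pos12`, and `pos12ry3` (positions 1–2 as nucleotides, position 3 RY-recoded
— purines → R, pyrimidines → Y — the standard remedy for third-position
saturation and compositional bias). Gaps stay gaps; other ambiguity becomes
`?`; the two symbols are written bit-identically across the FASTA, relaxed
PHYLIP and NEXUS writers. Partitions are emitted per gene and codon
position (pos3RY as a single partition per gene) and are machine-checked to
tile the matrix exactly; NEXUS charsets use stride notation. Taxa missing a
gene are padded with `?` and listed in the matrix provenance. Column masks
(0-based half-open intervals per gene) implement manual exclusion of
ambiguously aligned regions explicitly rather than by an irreproducible
by-eye step; alignment computation itself is out of scope — the module
consumes alignments, with translation-checked back-alignment
(amino-acid gap → codon gap) to lift protein alignments to codon level.

## Synthetic genomes

The generator emulates the statistical structure the analyses assume, not
biology in detail:

* **Composition** — per-gene coding sequences are sampled i.i.d. from base
  probabilities chosen so the plus-strand image matches the configured
  majority-strand targets (defaults: 85% A+T, AT skew −0.06, GC skew +0.15 —
  the braconid-like reversed-asymmetry condition; observed braconid genomes
  span ~82–87% A+T with GC skews +0.05–0.28). PCGs start ATN, end TAA and
  contain no internal stops; realized whole-genome A+T is rejection-sampled
  to within ±1%. tRNAs (66 bp) and rRNAs are composition-matched random
  strings with no folding constraints — downstream analyses use only
  position, strand and composition. Homopolymer runs in background sequence
  are capped so the control-region polyT signal stays unique.
* **Control region** — polyT (15–18 T), TAA-repeats, TATA, a 16–20 bp
  perfect-stem hairpin, G(A)nT and a purine tract are laid out in canonical
  order (plus optional tandem repeats), then reverse-complemented for the
  inverted orientation.
* **Rearrangement scripts** — shuffle (offset ≤ W), local inversion,
  translocation, remote inversion, block inversion and duplication rewrite
  both annotation and sequence consistently; moves can leave a spacer
  (presets 23 and 52 bp, the observed remnant spacer lengths) or a mutated
  pseudogene copy in ancestral orientation at the source locus. Ground-truth
  statuses follow the classifier's documented semantics: offset-1 shuffles
  mark both participants; block inversions mark interior genes as local and
  the two boundary genes as remote inversions.
* **Divergence** — a target Ks is realized by inverting the Jukes–Cantor
  correction to a synonymous-difference count and accepting uniform
  single-base codon proposals with probability 1 (synonymous) or ω
  (nonsynonymous), rejecting stop-creating changes; non-coding positions
  substitute at the synonymous-equivalent per-site rate. This
  acceptance-thinning scheme gives direct control of the realized ω that the
  rate module must recover. Default simulated divergence is Ks = 0.3,
  a moderate congeneric-scale distance.

Everything is a deterministic function of the seed (byte-identical GenBank
output for identical configs). What passing the synthetic suite does *not*
show: tolerance to annotation noise (boundary errors, missing qualifiers),
indels in coding genes, tRNA/rRNA structural realism, correlated multi-taxon
evolution along a tree, or divergence high enough to saturate.

## Problem sizes and runtime

The validation experiments use 200 single-event scripts, 100 multi-event
scripts (≤ 5 non-adjacent events), 50 replicates × 4 dN/dS values of
3000-codon pairs, and 100 + 100 control-region orientation/null trials —
sizes at which every recovery statistic is stable across seeds while the
whole suite runs in well under a minute on one core. The acceptance script
reruns all of them from a single seed.

## Known limitations

* Accession-based reproductions (published skew tables, control-region
  metrics, rearrangement counts) require a one-time download of the nine
  GenBank records; without them those tests fail with an explicit
  "record not available" error rather than being skipped.
* The rearrangement classifier reports per-gene statuses against a fixed
  ancestral order; it does not reconstruct minimum rearrangement scenarios
  (no sorting-by-reversals/DCJ) or intermediate arrangements.
* Breakpoint distance is a dissimilarity, not a metric on event counts;
  appended events never decreased it in scripted checks, but pathological
  event combinations could in principle cancel.
* The gap-free pairing fallback in genome-level Ka/Ks mis-pairs codons if
  real indels are present; supply codon alignments in that case.
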