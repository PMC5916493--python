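# Methods

This note records the models, conventions and numerical choices behind
`tetracomp`, and what the synthetic-data tests do and do not demonstrate.

## HGT scoring

For each query gene, hits are admitted at E ≤ 10⁻⁵, self-hits and
unclassified subjects are excluded (the latter counted in logs), an
optional subject exclusion list removes same-phylum database entries, and
only the best-scoring hit per subject is kept (avoiding multi-HSP double
counting; the choice is configurable).

* **HGT index**: *h*<sub>U</sub> = *B*<sub>OUT</sub> − *B*<sub>IN</sub>,
  where *B* is the best bitscore in each taxon class and an absent class
  contributes 0, so *h*<sub>U</sub> is defined for every gene. It is exactly
  antisymmetric under swapping the class labels of every hit.
* **Consensus Hit Support**: the winning class is the one with the larger
  *sum* of bitscores (ties go to the ingroup — conservative against false
  HGT calls); CHS is the *count* fraction of classified hits in that class.
  A `chs_weighting="bitscore"` switch uses bitscore mass instead, since the
  count-vs-mass reading of "proportion of hits" is genuinely ambiguous.
* **Candidacy**: *h*<sub>U</sub> ≥ 30 and outgroup CHS ≥ 0.90, both
  inclusive.
* **HGT-heavy scaffolds**: any scaffold whose candidate fraction is ≥ 0.95
  (inclusive; single-gene scaffolds count, with `min_scaffold_genes`
  configurable) has its candidates demoted — such scaffolds behave like
  unremoved contaminant sequence. The rule is applied to the pre-linkage
  candidate set.
* **Linkage**: a candidate is linked when its scaffold also carries a gene
  with *h*<sub>U</sub> ≤ 0, ingroup class and CHS ≥ 0.90.
* **Tree tests**: trees are treated as unrooted and evaluated purely
  topologically (no bootstrap weighting). For every edge bipartition, the
  side holding the query is tested: *clan* support means ≥ 1 nonmetazoan
  and 0 metazoan companions; *monophyly* means all nonmetazoan leaves and 0
  metazoan ones. Monophyly is not applicable when no metazoan leaves are
  present; trees with < 4 leaves are not analysable.

## Collinearity

Anchors are homologous gene pairs with 0-based gene-order ranks. Within
each scaffold pair the chainer finds, repeatedly, the best chain that is
strictly monotone in both rank coordinates (ascending or descending in the
partner rank) where each step skips fewer than `max_gaps = 10` intervening
genes (the larger of the two scaffolds' gaps); chains shorter than
`min_genes = 5` anchors are discarded and each anchor joins at most one
block. "Best" means longest, with ties broken by the lexicographically
smallest rank sequence, so the output is deterministic; the test suite
checks the DP against exhaustive chain enumeration. The exact scoring
internals of the original MCScanX implementation are not restated anywhere
authoritative; this chainer is documented on its own terms.

* **Collinearity index**: CI = (2 × anchor pairs) / (genes spanned by the
  block's two boundary intervals). CI = 1 exactly when no non-collinear
  gene interrupts either interval.
* **Homolog/ohnolog partition**: block mean *K*<sub>S</sub> < 0.3 →
  homolog, ≥ 0.3 → ohnolog, undefined → unassigned. The 0.3 default sits
  between observed homologous block means (≲ 0.14) and ohnologous means
  (≳ 0.6) in published degenerate-tetraploid genomes, and is configurable.
* **Breakpoints**: homologous blocks linking the same scaffold pair are
  taken in order along the focal scaffold; an adjacency is a breakpoint
  when the two blocks cannot be aligned without rearrangement — differing
  orientations, or a partner-scaffold order inconsistent with the focal
  order (matching order for same-orientation pairs, reversed order for
  inverted pairs, since flipping a whole scaffold is not a rearrangement).
  Each unordered scaffold pair is scanned once, so the count is invariant
  under relabelling block sides and under reversing a scaffold's coordinate
  system. The reported fraction is breakpoints / homologous blocks.
* **Same-scaffold blocks**: non-overlapping copy intervals are required
  (overlap indicates a self-match artefact); inverted orientation is a
  palindrome (g1 g2 g3 … g3′ g2′ g1′), same orientation a tandem array.
  Nested arrangements report per innermost block.

## Ka/Ks

Protein pairs are aligned with a built-in deterministic Needleman–Wunsch /
Gotoh aligner (BLOSUM62; gap open 10, extend 1, a length-L gap costing
open + (L−1)·extend; ties resolved match-state first) rather than an
external aligner call, keeping results byte-reproducible; precomputed
alignments can be supplied instead. Alignments are back-translated to
codons (residue gaps become whole-codon gaps; CDSs must translate exactly,
one trailing stop tolerated).

Counting follows Nei–Gojobori (1986): per codon, each position contributes
(synonymous one-step alternatives)/3 synonymous sites, with changes to stop
codons counted nonsynonymous; site totals average the two sequences and
satisfy S + N = 3 × codons. Differences at multi-hit codons average over
all minimal substitution paths with equal weight, excluding paths through
stop codons (if all are blocked, all paths are used). p<sub>S</sub> = S_d/S
and p<sub>N</sub> = N_d/N receive the Jukes–Cantor correction
K = −¾ ln(1 − 4p/3); p ≥ ¾ leaves the rate undefined, and undefined pairs
are excluded (and counted) from block means. The implementation matches an
exhaustive path-enumeration oracle exactly on short alignments and agrees
with Biopython's independent NG86 routine on long simulated pairs.

## SNP-based divergence and collapse diagnostics

SNP calls are filtered with mapping quality ≥ 30, site quality ≥ 20 and
total allele depth ≥ 25% of the library's mean coverage (all inclusive;
the mean is taken from the depth histogram). The collapsed-homolog
divergence bound is 100 × SNPs / CDS span in percent; the CDS span is
summed over genes on the scaffolds named in the VCF header. Folded MAF is
min(d_alt, d_ref)/depth — computed on integer depths first, which is
mathematically the same as min(f, 1−f) but exactly invariant under ref/alt
swap at bin edges — histogrammed in 0.02-wide bins on (0, 0.5]. Identity
distributions use 0.25-percent bins for mode estimation. Coverage-collapse
profiles assign sites and SNP sites to the nearest user-supplied coverage
peak within 25% of the peak value; automatic peak detection (local maxima
of a Gaussian-smoothed histogram) is provided but heuristic, and
single-sample allele depths are used throughout (no genotype fields).

## Synthetic genome generator

The generator emulates the structure of a degenerate tetraploid genome:
per ancestral scaffold, copy A1 is the ancestor, A2 = A1 mutated at
*d*<sub>hom</sub>, B1 = A1 mutated at *d*<sub>ohn</sub>, B2 = B1 mutated at
*d*<sub>hom</sub>, so homologous pairs diverge by *d*<sub>hom</sub> and
ohnologous pairs by ≈ *d*<sub>ohn</sub>. Mutation events number
Binomial(L, d) and land uniformly with multiple hits allowed, so *d* is
substitutions per site and Jukes–Cantor-corrected estimates are
asymptotically unbiased for it; no stop codons are ever introduced.

Defaults define the study conditions: 4 scaffold quartets × 200 genes
(80–250 codons, 1–6 exons with intron lengths from a two-class mixture
around 65 bp and 320 bp, intergenic spacers 150–600 bp — compact but
structurally realistic), *d*<sub>hom</sub> = 0.001 (a *Rotaria*-like
collapsed-homolog regime), *d*<sub>ohn</sub> = 0.25, `syn_bias = 0.5`
(half of substitution events forced synonymous, emulating purifying
selection so that ohnologous *K*<sub>S</sub> ≈ 0.6 clearly exceeds
genome-wide divergence, as observed in real tetraploid genomes; parameter
recovery of *K*<sub>S</sub> as substitutions/site is tested at
`syn_bias = 0`), 10% foreign genes planted *before* tetraploidisation (so
they occur as quartets; a post-duplication option yields pairs/singletons
via the arrangement machinery), 12 planted inversions, 3 palindromes, 2
tandems, no gene loss, 100× read depth, 0.5% base-error rate, collapsed
haplotypes.

Design notes:

* Inversions are planted at scaffold ends (tail slots first, then heads,
  at most 4 per quartet) and each contributes exactly one orientation
  breakpoint, making the planted count recoverable exactly.
* Tandem/palindrome arrangements live on dedicated scaffolds whose
  homologous partners are "collapsed elsewhere", so they cannot perturb
  the breakpoint census.
* Hit tables give each gene 9 true-class hits and 1 opposite-class hit
  (CHS = 0.9 at the candidate boundary) with the best true-class bitscore
  exactly `margin` (default 50) above the opposite class and noise clipped
  at 3σ, so planted foreign genes always satisfy *h*<sub>U</sub> ≥ 30.
* Read sampling draws site depth Poisson(2 × mean) on collapsed scaffolds
  and Binomial(n, ½) allele splits at every homologous difference;
  base-error records carry site quality below the filter threshold.
* A single numpy Generator with fixed draw order makes every output byte a
  function of the parameters; the VCF and depth histogram use offset seeds
  derived from the same seed.

**What passing tests do not show about real data**: the generator has no
indels, no repeats or TEs, no annotation error, no assembly fragmentation,
no gene-conversion tracts, uniform codon usage, and its hit profiles are
noise-clipped caricatures of database searches. Exact planted-truth
recovery therefore validates the *computations*, not the field performance
of the thresholds on real genomes.

## Pipeline

Stages run in dependency order (qc → hgt → synteny → diverge → collapse);
any stage is skippable, missing inputs fail before computation, and reruns
on fixed inputs are byte-identical (no hidden state). All thresholds carry
the defaults above in one config mapping. The `tetracomp` CLI wraps the
library thinly; `compare_species` aligns per-species summaries without any
tree inference.

## Known limitations

* Ka/Ks is NG86-only; maximum-likelihood codon models are out of scope, and
  NG86's *K*<sub>S</sub> is mildly biased upward at moderate divergence
  (measured ≈ +6% at d = 0.25 under uniform mutation).
* The breakpoint definition is this package's operationalisation of
  "cannot be aligned without rearrangement"; other tools may count
  differently around nested or overlapping blocks.
* Gene-tree evaluation is topological only; bootstrap support is ignored.
* Automatic coverage-peak detection is heuristic; supplying peaks is
  preferred.
* The acceptance round trip runs a deliberately compact genome
  (4 quartets × 200 genes, ~8 Mb); block censuses scale with genome size
  and are compared against planted truth, not against any published census.
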