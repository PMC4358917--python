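# Methods

This note documents the models, decision rules, numerical choices and
known limitations of `abc_evolve`, and what the synthetic-data generators
do and do not emulate.

## Subfamily classification

A protein's architecture is the ordered string of NBD/TMD tokens by start
coordinate. Orientation is *forward* when the first core token is a TMD
with at least one NBD after it (subfamilies A–D), *reverse* when an NBD
precedes a TMD (subfamily G), *soluble* when no TMD is present (E, F, and
the single-NBD prokaryotic type I). Size class is *full* with ≥ 2 NBD and
≥ 2 TMD, *half* with exactly one NBD and ≥ 1 TMD.

Topology alone cannot separate A from B from C from D — all are forward —
so discrimination is carried by an editable diagnostic-label table
(`DIAG:<label>` hits mapping to subfamilies), standing in for family-level
profile models (Pfam/PANTHER-style). Decision order: a single
topology-compatible diagnostic label wins; contradictory labels yield
`unclassified` with the conflict named in the evidence trail; otherwise
topology rules apply (reverse half → `G_WBC`, reverse full → `G_PDR`,
detached single NBD → `I`); everything else stays `unclassified` with its
topology string. Every protein receives exactly one label, and every
non-`unclassified` label carries non-empty evidence.

TMD hits shorter than 60 aa (configurable, `min_tmd_len`) are ignored for
orientation so stray fragments cannot flip a reverse protein to forward.
The ABC signature scan (`[LIVMFY]S[SG]Gx(3)[RKA][LIVMYA]x[LIVFM][AG]`,
overlapping matches, 1-based positions) is reported as supporting evidence
only: it marks the superfamily, not any subfamily.

## Nei–Gojobori selection statistics

For each sense codon, each of the 9 single-nucleotide changes contributes
1/3 of a site, synonymous or nonsynonymous by whether the amino acid is
preserved. Changes to stop codons count as nonsynonymous by default
(`stops_nonsyn=True`); the alternative (exclude and renormalize) is a
switch. For codon pairs differing at k ∈ {2, 3} positions, the k!
single-step pathway orderings are averaged with equal weight; pathways
through stop codons are excluded and the average renormalized (with a
logged fallback including them if none survive — unreachable under the
standard code).

Per pair: S and N site totals are the per-codon counts averaged over the
two sequences and summed over columns; pS = Σsd/S and pN = Σnd/N are
Jukes–Cantor corrected, d = −(3/4)·ln(1 − 4p/3). p ≥ 0.75 flags the pair
saturated; saturated pairs propagate as missing. Codon columns with less
than 80% ungapped rows (`site_coverage_min`, MEGA partial-deletion
semantics) are eliminated before any counting. Gapped or ambiguous codons
are masked per site; rows with internal stop codons are dropped with a log
entry.

Subfamily-level δ and ω are computed from the subfamily-mean dN and dS
(mean of distances, not mean of per-pair ratios), matching the convention
of reporting one δ/ω per group. The strict-neutrality test resamples codon
columns (default 1000 replicates) to estimate var(δ); z = δ/√var; the
reported p-value is the smaller one-tailed normal tail doubled, capped at
1; verdict at α = 0.05 is positive (dN > dS), negative (dN < dS) or
neutral. π is nucleotide-level mean pairwise p-distance with pairwise
deletion, computed on the same coverage-filtered columns.

**Known limitation** — counting-method bias: NG86's equal-weight pathway
averaging assumes no transition/transversion bias. Simulating with κ = 2
biases ω̂ down by ~20% at ω = 1 (a property of the method, not the
implementation); the parameter-recovery tests therefore simulate under the
estimator's own model (κ = 1), where ω̂ is unbiased to within sampling
error at ω ∈ {0.2, 1, 2} (8 taxa, 300 codons) and the bootstrap Z-test
rejects at ≈ 5% under neutrality.

## SLAC-style per-codon scan

Ancestral codon states are reconstructed per column by unordered Fitch
parsimony on the 61 sense-codon states (missing tips unconstrained; ties
broken toward the lexically first codon, with the parent's state preferred
when admissible). Substitutions along each branch are split into
synonymous/nonsynonymous by the same pathway-averaged counting; the
expected synonymous fraction is the mean synonymous site fraction
(count_sites/3) over all observed and inferred states at that column. A
two-tailed binomial test compares the observed synonymous count (rounded
to the nearest integer, since pathway averages are fractional; raw values
are reported alongside) with that expectation over the integer number of
nucleotide substitutions; sites with nonsynonymous excess at p < α are
classed positive, synonymous excess negative. Outputs are labelled
"SLAC-style": this is a counting re-implementation in the SLAC spirit, not
the Datamonkey pipeline.

**Known limitation — power.** On a 16-taxon tree (30 edges) a single site
exposes at most ~13–20 parsimony-visible substitutions. With the null
synonymous fraction ≈ 0.25, the two-tailed binomial only rejects for 0
observed synonymous events when n ≤ 17 (and ≤ 1–2 when n ≈ 20–30), and
multi-hit branch differences dilute the signal (their pathway-averaged
split is fixed by the genetic code, not by ω). Detection probability for a
planted ω = 5 site among ω = 0.2 background therefore tops out around
10–35% at this scale regardless of branch lengths; reliable per-site
detection needs the sequence counts of real subfamily alignments
(~100–200 sequences). The false-positive half of the property — ≤ 10% of
neutral sites flagged positive at α = 0.05 — holds comfortably.

## Duplication detection

Candidate groups are clades with bootstrap support strictly greater than
80; within a clade, maximal cliques of the ≥ 70% (inclusive) all-pairs CDS
identity graph are kept. Identity is computed on CDS by global alignment
(match 1, mismatch 0, gap open −10, gap extend −0.5) with both-gap columns
and terminal overhangs excluded from the denominator. Co-localization
types an event: *tandem* when all members form one tightly linked run —
consecutive genes within 100 kb **or** within 5 intervening annotated
genes (both configurable) — *block* when members form ≥ 2 runs of ≥ 2
genes each on at most two chromosomes, *rejected* otherwise (e.g.
dispersed singletons). Smaller clades are processed first and genes are
consumed once, so events partition genes (criterion 4's one-event rule).
Lowering the identity threshold can only add events; raising it only
removes them.

The intervening-gene arm of the linkage rule means that on gene-sparse
annotations two distant genes with nothing annotated between them count as
linked; real plant genomes are gene-dense, where the arm matches the usual
tandem-array convention.

## Chromosome distribution and k profiles

Under the null, each gene lands on chromosome c with probability
length(c)/Σlength. The statistic is Σ(obs − exp)²/exp; the p-value is
Monte-Carlo with the +1 correction, p = (1 + #{T_rep ≥ T_obs})/(n_mc + 1),
replicates drawn by multinomial placement — valid at small counts where
the χ² asymptotics are not. Unanchored "chromosome 0" scaffolds are
excluded from the test (no meaningful length expectation) but flagged.
The k profile is count/proteome-size per subfamily with a total row. A
gene-content (rather than bp-length) null is a noted alternative, not
implemented.

## Expression layer

TPM from RPKM is per-tissue renormalization: TPM_g = RPKM_g/ΣRPKM × 10⁶
(raw read counts are out of scope; RPKM is the processed input). The
expressed call is strictly TPM > 2 (configurable). Venn regions assign
each gene to its exact expressed-tissue set, so regions partition the
expressed genes. The subfamily table counts expressed genes per subfamily
× tissue with any-tissue and total rows; unassigned genes count as
unclassified.

## Synthetic-data generators

All generators are deterministic given (parameters, seed); the
ground-truth object (`SimTruth`) is checkable by re-running the relevant
stage.

* **Codon simulator** — Muse–Gaut-style continuous-time jump chain per
  branch and codon: single-nucleotide proposals, rate κ× for transitions
  and ω× for nonsynonymous changes, stop-codon proposals rejected. Rates
  are normalized so one unit of branch length is one expected substitution
  per codon at the dataset-level (ω, κ) under uniform codon frequencies;
  per-site ω overrides keep that scale so high-ω sites genuinely evolve
  faster. It does not emulate indels, codon-frequency bias, or rate
  variation beyond the ω map.
* **Gene families** — fixed-length stop-free random CDS (so the set is
  trivially alignable); duplicate groups derive from one ancestor, each
  member mutated at a private, disjoint set of ⌈(1−identity)/2·L⌉
  positions so every pair meets the identity target within ±2%. Tandem
  groups are placed as adjacent runs (2–10 kb gaps); block groups (size
  ≥ 4) as two runs on different chromosomes, because on these sparse
  synthetic chromosomes a same-chromosome distant run would be captured by
  the intervening-gene linkage arm (the same-chromosome block geometry is
  covered by hand-built unit fixtures). Background genes are mutually
  < 60% identical; optional decoys plant a high-identity cross-chromosome
  pair and a co-located low-identity pair.
* **Architecture tables** — per-subfamily templates (e.g. half-size D as
  TMD–NBD + `DIAG:ABCD`; soluble E as NBD–NBD + `DIAG:ABCE`; reverse full
  PDR + `DIAG:PDR`; forward-full-without-diagnostic as the planted
  `unclassified` case) with jittered coordinates.
* **Expression matrices** — TPM columns are constructed to sum to 10⁶
  exactly with expressed entries ≥ threshold + margin (default 2.5) and
  silent entries ≤ threshold − margin (default 1.5), then scaled per
  column into RPKM units. Because a matrix of only silent genes cannot sum
  to 10⁶ while staying under the threshold, a block of always-expressed
  housekeeping genes carries the column mass — mirroring the fact that a
  real transcriptome matrix contains far more than the profiled family.
  Truth distinguishes target from housekeeping genes. Expressed/silent
  recovery is exact whenever the margins clear the threshold by ≥ 0.5 TPM,
  as they do by construction.

Passing tests on these generators demonstrate the decision rules and
estimators on clean, saturation-free, contamination-free inputs; they do
not certify behaviour on real annotations with fragmented gene models,
splice variants (each FASTA entry is treated as one unit), alignment
error, or rate heterogeneity.

## Phylogenetics

Distances are p-distances or Jukes–Cantor (b = 3/4 nucleotide, 19/20
protein) with pairwise deletion; pairs at or beyond the JC domain fall
back to p-distance with a log entry. Trees come from neighbor joining
(scikit-bio's implementation behind `nj_tree`), with negative branch
lengths clamped to zero. An externally computed tree — e.g. a maximum
likelihood tree from another program — can be imported from Newick and
used anywhere a tree is consumed, since the duplication and clade rules
only read supports and tip sets; NJ with bootstrap is the built-in
default engine. Bootstrap supports are replicate frequencies of the point
tree's internal bipartitions under column resampling, mapped onto the
point tree (not a majority-rule consensus). Clade extraction is inclusive
at both thresholds (support ≥ 70, ≥ 4 tips) and reports nested qualifying
clades.

## Problem sizes

Default test and acceptance runs use 8-taxon × 300-codon alignments (50
replicates per ω), 16-taxon × 100-codon scans (50 replicates), ~20-gene
families with 100 bootstrap replicates, 200 simulated datasets × 999
Monte-Carlo replicates for the distribution-test calibration, and 60-gene
× 5-tissue expression matrices — sizes at which every property above is
measurable in seconds to a few minutes on one core.
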