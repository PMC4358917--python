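# abc-evolve

Comparative evolutionary analysis of plant **ATP-binding cassette (ABC)
transporter** gene families. ABC transporters — one of the largest protein
superfamilies in plants, with 100+ members per genome — fall into
subfamilies (A–I) defined by the order of their nucleotide-binding domains
(NBD) and transmembrane domains (TMD). This package re-implements, as a
tested and reusable library, the standard comparative pipeline applied to
such families:

* **Subfamily classification** from domain architecture: forward
  (TMD–NBD, subfamilies A–D), reverse (NBD–TMD, subfamily G: half-size
  `G_WBC`, full-size `G_PDR`), soluble (NBD-only, E/F), and
  prokaryotic-type (I), plus a scan for the ABC signature motif
  `[LIVMFY] S [SG] G x(3) [RKA] [LIVMYA] x [LIVFM] [AG]`.
* **Selection pressure** at the codon level via the Nei–Gojobori (1986)
  counting method: synonymous/nonsynonymous site and difference counts
  with equal-weight pathway averaging, Jukes–Cantor correction, δ = dN − dS
  and ω = dN/dS, a codon-column bootstrap test of strict neutrality
  (H₀: dN = dS), nucleotide diversity π, and a SLAC-style per-codon scan
  (Fitch parsimony ancestors + binomial test).
* **Recent duplication detection** by four criteria: clade bootstrap
  support > 80 (strict), alignable CDS identity ≥ 70% (inclusive),
  physical co-localization, and one event per tightly linked run —
  classified tandem vs block.
* **Genomic distribution**: Monte-Carlo chi-square test of gene placement
  against the chromosome-length-proportional null, and k-value profiles
  (subfamily count / proteome size).
* **Expression profiling**: RPKM → TPM normalization (columns sum to 10⁶),
  expressed calls at TPM > 2 (strict), tissue Venn regions, per-subfamily
  expression tables.
* **Phylogenetics**: NJ trees with bootstrap supports, clade extraction
  under the support ≥ 70 / ≥ 4 members rule, pairwise identity with
  terminal-gap exclusion.

Every stage is exercised end-to-end on **synthetic data with known ground
truth** generated by the built-in simulator (`abc_evolve.synthetic_data`):
codon alignments evolved under a chosen ω along a tree, gene families with
planted tandem/block duplications and decoys on synthetic chromosomes,
domain tables with known subfamily labels, and RPKM matrices with known
expressed/silent sets.

## Worked example

Selection analysis on an 8-taxon alignment of 300 codons simulated under
purifying selection (ω = 0.3):

```bash
python examples/selection_pressure.py
```

```
sequences            n  = 8
nucleotide diversity pi = 0.1378
dN = 0.1038   dS = 0.3398
delta = dN - dS = -0.2360   omega = dN/dS = 0.305
bootstrap Z = -7.90, p = 0.0000 -> verdict: negative
(simulated under omega = 0.3; omega < 1 with a
 significant negative delta indicates purifying selection)

SLAC-style scan: 13 sites under negative selection, 0 positive, of 300 codons (alpha = 0.05).
```

The estimator recovers ω ≈ 0.305 against a simulated truth of 0.3; the
strongly negative δ with a significant bootstrap Z-test is the signature
of purifying selection, and the per-site scan attributes it to individual
codons.

Duplication detection on a planted scenario:

```bash
python examples/duplication_detection.py
```

```
event: ['g001', 'g002']  type=tandem  support=100  min identity=0.90  chroms=('chr3',)
event: ['g003', 'g004', 'g005', 'g006']  type=block  support=100  min identity=0.88  chroms=('chr2', 'chr3')
```

Both planted events are recovered with their types; the high-identity
cross-chromosome decoy and the co-located 60%-identity decoy are rejected
by the co-localization and identity criteria respectively.

Other examples: `classify_architectures.py`, `chromosome_distribution.py`,
`expression_profiles.py`, `full_pipeline.py`. The full pipeline is also
available from the shell:

```bash
abc-evolve run --workdir out --seed 5
abc-evolve simulate --scenario duplication --out sim --seed 4
abc-evolve classify --domains sim/domains.tsv --out assignments.tsv
```

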