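# barcodekit

Evaluation toolkit for short DNA-barcode markers (ITS2-style loci): given a
set of marker sequences labeled with species, it measures how well the marker
separates and identifies those species. It was built around the classic
single-genus barcoding workflow — e.g. evaluating the nuclear ribosomal ITS2
region across a few dozen *Physalis* species — and is aimed at researchers who
want that whole analysis reproducible from two plain text files (a FASTA and a
metadata table) instead of a chain of GUI tools.

## What it computes

**Distances.** Sequences are filtered (length < 100 bp, open-nomenclature
"aff." labels), progressively aligned (affine-gap Gotoh along a UPGMA guide
tree; a precomputed alignment can be supplied instead), and all pairs are
scored under the Kimura 2-parameter model with pairwise deletion:

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

with *P* and *Q* the observed transition and transversion proportions.

**Divergence metrics.** Six standard quantities, mean ± sd: the pooled
inter-specific distance, θ′ (per-species-pair means, debiasing unequal
sampling), the per-species minimum inter-specific distance; and on the
intra-specific side the pooled conspecific distance, θ (per-species means) and
the coalescent depth (per-species maxima).

**Barcoding gap.** Relative-frequency histograms of both distance classes at
0.005 substitutions/site per bin, the fraction of inter-specific pairs at
exactly zero distance or above an authentication threshold (default 0.035),
and a two-sided Wilcoxon rank-sum comparison (exact null distribution for
small samples, tie-corrected normal otherwise).

**Identification.** Every record is queried leave-one-out against the rest by
(a) nearest K2P distance and (b) best global-alignment score (a "BLAST1"-style
best-hit rule ranked by exhaustive optimal alignment). A query is *correct*
when all tied best hits are conspecific, *ambiguous* when the tie spans
several species including the query's, *incorrect* otherwise; rates are
reported per method.

**Separability.** Per species: worst-case within-species distance
(heterogeneity) vs best-case distance to any other species (separability),
with the closest relative named — the taxon-gap view of which species the
marker can and cannot discriminate.

**Phylogeny.** Neighbor-joining tree on the K2P matrix with column-resampling
bootstrap supports on internal edges and outgroup rooting; Newick in/out.

**Synthetic data.** A calibrated generator produces ITS2-like multi-species
datasets (controlled intra/inter divergence, transition/transversion ratio,
GC content, lengths, indels, and an optional fraction of taxon pairs forced to
share an identical sequence), so the entire pipeline is testable offline.

## Worked example

Simulate a 12-species dataset (3 samples each, 2 outgroup samples, two taxon
pairs sharing an identical sequence) and run the full analysis:

```bash
barcodekit simulate --n-species 12 --samples 3 --n-outgroup 2 \
    --identical-pair-fraction 0.167 --seed 7 --outdir ex/data
barcodekit run-all --fasta ex/data/sequences.fasta \
    --metadata ex/data/metadata.tsv --outdir ex/out --n-reps 200 --seed 7
```

`ex/out/divergence.tsv` then contains

```
Measurement	K2P value
All interspecific distance	0.063 ± 0.012
Theta prime	0.063 ± 0.011
The minimum interspecific distance	0.036 ± 0.018
All intraspecific distance	0.008 ± 0.012
Theta	0.008 ± 0.009
Coalescent depth	0.012 ± 0.014
```

— within-species variation (~0.008) sits an order of magnitude below
between-species divergence (~0.063), i.e. the marker shows a barcoding gap.
The report (`ex/out/report.json`) adds the gap statistics (1.0% of
inter-specific pairs at zero distance, 98.3% above 0.035, Wilcoxon
p ≈ 1.6e-22) and the identification rates: 83.3% correct / 13.9% ambiguous /
2.8% incorrect for both methods. The ambiguous queries are exactly the
samples of the two taxon pairs that share a sequence — those pairs also show
separability 0 in `ex/out/separability.tsv` (16.7% of taxa). `ex/out/tree.nwk`
holds the bootstrapped NJ tree, rooted on the outgroup:

```
((Outgroup-1:0.0,Outgroup-2:0.0)100:0.063,((Species_10-1:0.007,...
```

Every stage is also available as its own subcommand (`filter`, `align`,
`distances`, `metrics`, `gap`, `identify`, `separability`, `tree`), and
`run-all` reuses artifacts already present in the output directory — delete
one to regenerate it and everything downstream.

To analyze real data, provide your own ITS2-trimmed FASTA plus a tab-separated
metadata table with columns `id`, `species` (and optionally `subgenus`,
`section`, `accession`, `role` — records with `role=outgroup` are used for
rooting and excluded from the species-level statistics).

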