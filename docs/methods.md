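# Methods

This note documents the models, conventions and design choices behind
barcodekit, in the order the pipeline runs. Nothing here reports an empirical
result that the test suite or `scripts/acceptance.py` does not itself compute.

## Input model and filters

A dataset is an ordered set of IUPAC DNA sequences, each carrying an
operational taxonomic unit (OTU) label. Named infraspecific varieties are
treated as distinct OTUs: single-genus barcode studies typically count them as
separate species-level units, and the identification and separability
statistics only make sense if the labels being discriminated are the labels
being counted. The metadata table is authoritative for taxonomy; FASTA headers
are opaque IDs, because header conventions in public repositories are too
inconsistent to parse.

Two exclusion rules run before any analysis: sequences shorter than 100 bp
(too short to be a credibly complete ITS2-class marker), and records whose
species label contains the token "aff." — open nomenclature flagging uncertain
identification or possible contamination. The token match is word-bounded and
case-insensitive so that legitimate epithets such as *affinis* survive. The
rules are applied to the trimmed marker sequences as provided; upstream
ITS2 extraction/trimming is out of scope and assumed done.

GC content resolves ambiguity codes fractionally (S = 1, R/Y/K/M = 1/2,
B/V = 2/3, D/H = 1/3, N = 1/2) over the full sequence length — deterministic
and independent of record order. It is computed on the unaligned input
sequences.

## Alignment

The aligner is a three-state affine-gap global dynamic program (Gotoh), used
twice: on sequence pairs, and on frequency profiles during the progressive
merge along a UPGMA guide tree built from pairwise p-distances ("once a gap,
always a gap"). It is a documented stand-in for Clustal-style alignment, not
an emulation of any specific program; at the scale this pipeline targets
(~220 bp sequences a few percent divergent) distance estimates are robust to
reasonable aligner differences, and a precomputed alignment can always be
ingested verbatim (`--alignment`).

Scoring: match +1, mismatch −1, gap open −10, gap extend −0.5 (Clustal-like
magnitudes); a gap run of length L costs `open + (L−1)·extend`. A pair
involving an ambiguity code scores 0 when the IUPAC sets intersect (R vs A is
consistent with a match but not evidence of one) and mismatch otherwise.
Traceback ties prefer diagonal, then up, then left, which — together with the
deterministic guide tree — makes alignment byte-reproducible. In profile
scoring, a gap contributes zero to the column score; gap penalties are not
scaled by column occupancy (a simplification that matters little at the low
gap densities here). The profile-profile score grid is computed as one matrix
product of the two column-frequency matrices through the substitution matrix.

The DP score recurrences are exact in floating point for the pairwise case
(all increments are dyadic rationals), so the oracle tests compare scores with
`==`. The traceback selects predecessors by first-maximum rather than
equality against a recomputed target, which stays correct under the last-ulp
rounding that profile grids can exhibit.

## K2P distances

The Kimura 2-parameter distance is computed per pair from the observed
transition proportion P and transversion proportion Q:

    d = −1/2 ln(1 − 2P − Q) − 1/4 ln(1 − 2Q)

Sites where either row carries a gap or an ambiguity code are excluded pair by
pair (*pairwise deletion*). This is the common default of distance software
and maximizes the number of comparable sites per pair; the alternative
(complete deletion) discards whole columns and was not used. `1 − 2P − Q ≤ 0`
or `1 − 2Q ≤ 0` is reported as saturation, not silently clamped. Distances are
carried at full float precision; rounding happens only in human-readable
reports. A vectorized all-pairs implementation backs the matrix computation;
the scalar per-pair routine is the reference, and the tests assert they agree
exactly alongside a brute-force site-classification oracle.

## Divergence metrics

Six metrics summarize the two sides of the species boundary; all are means ±
dispersion over the ingroup distance matrix:

* **all_intra** — pooled conspecific pairs;
* **theta (θ)** — per-species mean conspecific distance, averaged over
  species with ≥ 2 samples (each species counts once regardless of sampling);
* **coalescent depth** — per-species *maximum* conspecific distance, averaged
  over the same species;
* **all_inter** — pooled heterospecific pairs;
* **theta prime (θ′)** — per-species-pair mean distance, averaged over pairs.
  This is invariant under duplicating all samples of a species, the debiasing
  property that motivates it (asserted as a test);
* **min_inter** — each species' minimum distance to any heterospecific
  individual, averaged over species. A global-minimum variant (the single
  smallest heterospecific distance) is available behind a flag.

Singleton species contribute to the inter-specific metrics but not the
intra-specific ones (no conspecific pair exists). Dispersion is the standard
deviation with ddof = 0 — it is defined even for a single value, and the
"mean ± spread" convention of barcode tables does not specify a ddof;
standard error is available via `dispersion="se"`.

## Barcoding gap

Both distance classes are binned into half-open intervals `[k·w, (k+1)·w)` at
w = 0.005 substitutions/site and reported as relative frequencies. Two scalar
summaries target authentication practice: the percentage of inter-specific
*pairs* at exactly zero distance (taxa indistinguishable by the marker; zero
means exactly zero after K2P on the compared sites, no epsilon) and the
percentage strictly above a threshold (default 0.035). The distributional
comparison is a two-sided Wilcoxon rank-sum (Mann-Whitney U) test: the exact
null distribution of U when both samples have ≤ 25 values, otherwise the
tie-corrected normal approximation with continuity correction. (Literal
enumeration of assignments is infeasible beyond tiny samples; the exact-U
recurrence is the standard meaning of "exact" here, and the tests check it
against literal enumeration at enumerable sizes.)

## Identification

Both procedures run leave-one-out: each record queries the remaining ones.
The query is excluded from the reference set by default because a
self-inclusive search degenerates (every query's best hit is itself); the
degenerate behavior remains available via `include_self` for comparison.
Outgroup records are excluded from identification and the other species-level
statistics.

*Nearest distance*: best hits are all references at the minimum K2P distance.
*Best hit (BLAST1-style)*: best hits are all references at the maximum global
alignment score. BLAST itself is not run — at reference-set sizes of order
10²–10³ an exhaustive optimal-alignment ranking is exact, deterministic and
free of heuristic seeding effects, which is the property the best-hit rule
needs. Outcomes: *correct* iff the hit species set is exactly the query's
species; *ambiguous* iff several species tie and the query's is among them;
*incorrect* otherwise. Ties use exact equality — scores and distances derive
deterministically from discrete site counts, so an epsilon would only blur
genuinely identical sequences, which are precisely the interesting case.

## Separability

Per species: heterogeneity = maximum conspecific distance (0 for singletons),
separability = minimum distance to any heterospecific individual, closest
relative = the species attaining that minimum (ties broken alphabetically,
all tied labels retained). The maximum/minimum convention is the stricter
taxon-gap reading — a "clear species boundary" compares worst-case within to
best-case without; the mean conspecific distance is emitted as a secondary
column. A species is discriminable when separability exceeds heterogeneity
and is non-zero. The per-species separability values are by construction the
per-species minima that `min_inter` averages, and a test asserts that
identity.

## Phylogeny

Neighbor joining on the K2P matrix replaces likelihood-based tree search: it
is deterministic, desk-scale, consistent on additive matrices, and the
questions asked of the tree here (deep, well-separated groups; an isolated
taxon; outgroup rooting) do not require topology-for-topology identity with a
likelihood tree. An externally built tree can be imported from Newick for
comparison on the same bipartition basis.

Conventions: Q-matrix ties are resolved toward the pair whose (smallest leaf
label, largest) sorts first — note that when a tie is only broken at the last
ulp of the floating Q values, the numerically smaller entry wins, which is
deterministic for a given input but can differ between near-identical inputs.
Negative NJ branch lengths are clamped to zero with the deficit moved to the
sister branch, preserving the path length between the joined nodes. Bootstrap:
alignment columns are resampled with replacement to full length; a replicate
whose K2P matrix is undefined is redrawn (at most 10 times, then the run
errors); each internal edge of the full-data tree is scored by the percentage
of replicate trees containing the same bipartition, canonicalized relative to
the alphabetically smallest leaf. Supports ≥ 50 are the conventional display
threshold; the Newick output carries all of them as internal labels.
Outgroup rooting bisects the edge separating the outgroup clade; a
non-monophyletic outgroup produces a warning and rooting falls back to the
edge above the largest outgroup-only clade.

## Synthetic data generator

The generator emulates the statistical shape of a single-genus ITS2 barcode
study; its defaults are the study conditions the rest of the toolkit is
evaluated under:

| parameter | default | meaning |
|---|---|---|
| `n_species` | 45 | number of OTUs |
| `samples_per_species` | skewed profile, 86 total | 1–9 samples per OTU (six taxa at 3–9, eleven doubletons, 28 singletons) |
| `target_intra` | 0.007 | expected conspecific K2P distance |
| `target_inter` | 0.073 | expected heterospecific K2P distance |
| `kappa` | 2.0 | transition/transversion rate ratio |
| `gc_content` | 0.72 | target tip GC fraction |
| `length_range` | (210, 218) | sequence length bounds, bp |
| `indel_rate` | 0.05 | per-sequence chance of one 1–4 bp indel |
| `identical_pair_fraction` | 0.0 | fraction of taxa in forced sequence sharing |

Sequences evolve down a two-level tree: root → species ancestors → samples,
under two-rate (transition κ-weighted) substitution kinetics whose per-branch
change probabilities are the K2P closed forms, so branch lengths are expected
substitutions per site and expected tip-tip K2P distances are simply path
lengths. Sample branches are `target_intra/2`; species branches are
`(target_inter − target_intra)/2`, so the expected heterospecific divergence
is `target_inter` exactly rather than `target_inter + target_intra`. The
default species tree is a star — the divergence summaries being emulated pool
over species pairs, and a star makes the inter target directly interpretable
for every pair; a rescaled pure-birth (Yule) option exists for tree-inference
tests.

The root sequence uses exact-count composition at the middle of the length
range, with the root GC inflated by `e^{2(α+β)t}` to compensate the known
decay of composition toward 0.5 under symmetric kinetics (every transition
and half of all transversions flip a site's GC status), so the *tips* land on
the GC target. Composition bias plus two-rate kinetics is an approximation —
the pure K2P model assumes equal base frequencies — and the calibration
contract is therefore the realized distances, which `realized_divergence`
measures on the pre-indel sequences (equal-length, gap-free, so the
measurement is aligner-independent).

Forced sharing emulates taxa whose marker sequences are identical to a sister
taxon's: for each chosen disjoint species pair, one shared sequence (drawn
from the first species' ancestor) overwrites two samples of each species.
Two per species — rather than one, or all — so that a shared sample ties at
distance zero with both a conspecific and a heterospecific, which is what
turns these queries *ambiguous* rather than *incorrect* and reproduces the
observed real-data pattern (ambiguity without misidentification). The
parameter is interpreted as the fraction of *taxa* participating (pairs =
`round(f·n_species/2)`), matching how such sharing is reported ("8 of 45
taxa"). With 45 species × 2 samples and `f = 8/45`, exactly 16/90 = 17.8% of
queries are ambiguous and 8/45 = 17.8% of taxa have zero separability.

What the generator does **not** emulate: phylogenetic structure among species
(under the default star, between-species divergences are exchangeable, so the
per-species *minimum* inter-specific distance sits well below its mean —
real data with structured divergence give a higher minimum); within-species
coalescent structure; rate variation across sites; recombination; alignment
ambiguity beyond small indels. Tests passing on synthetic data therefore
validate the computational pipeline and its statistical conventions, not the
biological realism of any particular dataset.

A known tail behavior, measured and accepted rather than tuned away: at the
default targets (0.007 vs 0.073 over ~214 sites) the realized intra- and
inter-specific distance distributions overlap for roughly one seed in ten,
producing a single misidentified query out of 90. The identification-pattern
checks therefore pool queries over ten seeds instead of asserting on one
arbitrary dataset.

## Problem sizes and numerical choices

The test suite and acceptance script run at the study's own scale (45 taxa /
86–90 samples, ~214 bp) — full progressive alignment of such a dataset takes
on the order of ten seconds — with bootstrap runs at 200 replicates for the
scripted checks (the CLI default remains 1000). Distance matrices round-trip
through PHYLIP at 17 significant digits so that a resumed pipeline reproduces
the original report byte-for-byte. All pipeline randomness (bootstrap,
simulation) derives from one top-level seed.

## Known limitations

* The aligner is intentionally minimal: no iterative refinement, no
  position-specific gap penalties; pathological alignments of highly divergent
  inputs should be done externally and supplied via `--alignment`.
* K2P variance and gamma-corrected variants are not computed.
* The best-hit method's exhaustive ranking is quadratic in dataset size;
  beyond a few thousand records a real BLAST run would be preferable.
* Reproduction of a published study's exact numbers requires that study's
  sequences (and identical upstream trimming); the pipeline consumes them
  when provided but cannot fetch them.
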