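# Methods

`cladepan` implements a genus-scale comparative-genomics analysis as a
deterministic, testable pipeline: genomic species are delineated from
pairwise whole-genome metrics, the pangenome is partitioned and its
openness quantified, and gene gain/loss histories are reconstructed by
Wagner parsimony on a rooted species tree. Every stage can be validated
end-to-end against a synthetic clade whose ground truth is known exactly.

## Pairwise genome metrics

**ANI (average nucleotide identity).** The query genome is cut into
consecutive 1020-nt fragments (per contig; trailing partial fragments are
dropped). Each fragment is located in the subject genome by shared
16-mers: sampled fragment 16-mers vote for an alignment diagonal, and the
modal diagonal wins (ties to the smallest offset). The fragment is then
aligned semi-globally (edlib, band-equivalent window of ±64 nt around the
diagonal) and retained when its identity is ≥30% and the modal diagonal
is supported across ≥70% of the fragment — the seed-level analogue of the
classic local-alignment coverage rule, which rejects fragments straddling
rearrangement or gene gain/loss breakpoints. Identity is always
matches / alignment columns, read off the extended CIGAR, so alignment
scoring only affects the path. Directional ANI is the mean identity of
retained fragments; the reported ANI averages both directions. A pair
with no retained fragments is recorded as missing ("no homology") and
fails every threshold downstream.

**TETRA.** Counts of all 2-, 3- and 4-mers are accumulated over every
contig and its reverse complement, windows never crossing contig ends and
windows containing N skipped. The expected 4-mer count follows the
maximal-order Markov model, E(n1n2n3n4) = O(n1n2n3)·O(n2n3n4)/O(n2n3),
with variance V = E·(O(n2n3)−O(n1n2n3))·(O(n2n3)−O(n2n3n4))/O(n2n3)²;
z = (O−E)/√V with z = 0 where V = 0. The TETRA statistic for a genome
pair is the Pearson correlation of the two 256-component z-score
signatures. Signatures of genomes below ~100 kb are noticeably noisy
(the module warns below 50 kb); the statistic is intended for
megabase-scale assemblies and correlates near 1 only when the underlying
compositional signal dominates sampling noise.

**AAI.** Candidate protein hits are found by shared amino-acid 5-mers;
the per-query best hit must reach ≥30% identity (global alignment,
matches/columns) with a length ratio of at least 70% (the global
alignment makes the shorter sequence's aligned coverage trivially
complete, so the length ratio stands in for the coverage test).
Reciprocal best hits define ortholog pairs and AAI is their mean
identity, averaging the two directions of each pair.

**16S identity.** Global alignment with free end gaps (Biopython
PairwiseAligner; match +1, mismatch −1, gap −2). Identity is matches over
aligned columns excluding terminal overhangs; each sequence's coverage is
its aligned span over its length.

## Species delineation

Two genomes belong to the same genomic species when simultaneously
ANI > 95%, TETRA > 0.99 and AAI > 95%, with strict inequalities. Species
clusters are connected components of the resulting graph. Because
near-threshold intransitivity is a documented reality of these metrics,
member pairs inside a component that fail the triple criterion are
reported (`incomplete_pairs`) rather than resolved by an undocumented
merge rule. Inter-cluster pairs passing some but not all criteria are
flagged as gray zones, and the report includes the fraction of all pairs
inside the 83–95% ANI "discontinuity zone". Naming precedence: a cluster
containing a reference type-strain genome takes that species name (two
type strains in one cluster are reported as a merge with both names);
otherwise a member 16S longer than 1400 nt matching a reference at ≥99%
identity with both coverages ≥80% names the cluster; otherwise the
cluster receives a deterministic "unknown group" letter (clusters ordered
by size, then representative ID).

## Pangenome

Gene families come from a deterministic greedy clustering (CD-HIT
style): proteins sorted by length descending (then genome and gene ID),
each protein joining the earliest-founded cluster whose representative it
matches at ≥80% identity over ≥80% of the shorter sequence, else founding
a new cluster. This is a stand-in for gene-neighbourhood-aware tools; at
genus-scale divergence it may split a deep family between distant species
(exactly as identity-threshold tools do) but never merges unrelated
families, and the split behaviour is covered by tests. Categories follow
the conventional cutoffs — core: 100% of genomes; soft-core: ≥95%;
shell: ≥15%; cloud: below — and always partition the family total.

Rarefaction draws random genome orderings (default 1000, seeded) and
records cumulative pan (union), core (intersection) and newly-seen family
counts; medians and 2.5/97.5% quantiles summarise the permutations. The
openness fit regresses log Δn(N) on log N for N ≥ 2 (the first genome's
whole repertoire is not a discovery rate; zero medians are excluded),
giving Δn(N) = κ·N^−α. α < 1 diagnoses an open pangenome, α > 1 a closed
one. Per-genome rates: new families gained per additional genome at
N_max is κ·N_max^−α; core loss per genome is the drop of the median core
curve from N = 2 to N_max divided by N_max − 2.

KEGG-style module completeness takes a family→step annotation and a
module→required-steps table as inputs: completeness is the percentage of
required steps covered by families present in every genome of the chosen
subset, reported only at ≥50%.

## Species tree

Single-copy core families (occurrence exactly 1 in every genome
considered) are extracted from an orthogroup matrix built at a permissive
homology threshold (40% identity over 50% of the shorter sequence) so
that families span the outgroup; the pangenome's 80% threshold is
deliberately not reused here. Pairwise distances are p-distances,
1 − length-weighted mean identity over globally aligned family sequences
— parameter-free and monotone in divergence at the ranges of interest.
The tree is built by neighbor joining with deterministic tie-breaking
(lexicographically smallest pair among minimal Q), negative branch
lengths clamped to zero with the deficit shifted to the sister branch,
and rooted at the midpoint of the outgroup's pendant edge. Maximum
likelihood inference, bootstrap and SNP trees are out of scope; an
externally inferred rooted Newick tree is accepted wherever a tree is
needed.

## Gain/loss reconstruction

Occurrence counts are binarised and each family's history is solved by a
two-state Sankoff dynamic program with gain penalty g and loss penalty l
(defaults 1 and 1). A family present at the root pays one gain for its
origination, so a root gain competes on equal terms with later
independent gains; root-present families are booked as gains on the
root's virtual branch and the reported total cost is exactly
g·(gains incl. origination) + l·losses, verified minimal against
exhaustive enumeration on small trees. Ties are broken toward absence,
resolved root-first — when an early gain plus later losses ties with
independent later gains, the reconstruction prefers the later gains
(conservative about ancestral content; a "prefer presence" mode is
available). A consequence worth knowing: with equal penalties, a true
loss whose surviving complement can be covered by equally many gains is
reconstructed as gains; at the low event rates where parsimony is
trustworthy this affects only losses adjacent to the root and the
per-family event recovery stays above 95%.

## Synthetic clades

The generator produces the regime the species criterion assumes, with
full ground truth (tree, per-node family sets, per-branch events):

* **Tree.** Pure-birth species topology, ultrametric at depth
  `tree_depth` (default 0.12 substitutions/site). Species splits are
  confined to the upper 70% of the depth, bounding the minimum
  inter-species path at ~0.6·tree_depth (≥5% observed divergence at the
  default), well clear of the intra-species level. Strains attach in a
  star at half of `intra_species_divergence` (default 0.01), making
  strain pairs exactly that divergent. An optional outgroup attaches
  below the root (default 0.1 extra on each side, i.e. ~33% observed
  divergence to the ingroup — a neighbouring genus).
* **Gene content.** The root carries `root_family_count` families
  (default 2000, ~900-nt mean gene length: a ~1.8-Mb genome); each branch
  gains Poisson(gain_rate·t) families (fresh IDs under the default
  infinite-pool model — an open pangenome by construction — or drawn from
  a fixed catalogue under a finite pool, which closes it) and loses
  Poisson(loss_rate·t) uniformly chosen present families. Defaults of
  300 gains and 100 losses per unit branch length give tips a few
  hundred private families at default depth, in line with genus-scale
  collections. No duplications are simulated; occurrence counts are 0/1.
* **Sequences.** Site-independent Jukes–Cantor substitution per branch:
  each site changes with probability 3/4·(1−exp(−4t/3)) to a uniformly
  chosen different base — the exact JC kernel, so divergence composes
  correctly along paths. Root gene sequences are drawn from a genus-wide
  order-3 Markov chain whose transition probabilities have a log-normal
  spread (`composition_bias`, default 0.3). This gives genomes a
  heritable compositional signature with tetranucleotide z-scores in the
  ±20 range typical of bacteria — the signal TETRA reads; without it,
  same-species signatures would correlate no better than sampling noise
  allows. Proteins are direct translations (stop codons remapped to
  sense codons), keeping AAI and ANI coherently coupled; a 1550-nt
  16S-like marker evolves at 5% of the genomic rate. Leaf genomes
  concatenate family sequences into 1–10 contigs split at gene
  boundaries.

What the generator does **not** emulate: intergenic DNA, operon and
synteny structure, rate heterogeneity and purifying selection (amino
acid divergence is therefore ~2× more per nucleotide substitution than
in real proteomes), indels, assembly artifacts, contamination, and
horizontal transfer from outside the clade. Tests passing on these data
show the algorithms are correct under the stated model, not that the
metrics' biological thresholds are right for any particular genus.

## Problem sizes and numerics

The validation suite runs the full metric stack on a 24-genome clade
(8 species × 3 strains, ~200-kb genomes of 222 families — a scaled-down
genus chosen so the whole suite stays interactive), parsimony oracles on
trees of ≤6 leaves against exhaustive enumeration, event recovery on a
16-leaf clade at ≤0.3 expected events per family, and openness
classification at 200 permutations (the pipeline default is 1000).
Determinism: every random draw flows from a single integer seed
(simulation substreams are derived with fixed offsets); caches store
floats at full precision (%.17g, round-trip parsing) so resumed runs are
bit-identical. Degenerate inputs are errors, not guesses: empty
matrices, zero-variance TETRA profiles, all-zero new-gene curves,
missing outgroups and unrooted trees for gain/loss all raise with
actionable messages.
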