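# Methods

This note states the model behind each `cultcov` component, the exact
conventions and parameters used, how the synthetic generators work, and
the limits of the implementation.

## Sequence identity

**Global nucleotide identity.** Two DNA sequences are aligned with
Needleman–Wunsch global alignment under affine gap scoring: match +1,
mismatch −1, a gap run of length L costs 2 + 0.5·L. Terminal gap runs are
charged in the alignment score like any other gap (plain global
alignment), but the reported identity excludes them from the denominator:
identity = matched columns / alignment columns, counting columns only
from the first to the last aligned residue pair. When the optimal
alignment pairs no residues at all, identity is reported over zero
columns and treated as no match. Ties among optimal alignments are broken
by the underlying aligner; the test suite verifies that the reported
(matches, columns) pair belongs to the set attained by *some* optimal
alignment, enumerated independently by a brute-force Gotoh DP.

**Fragment-based ANI.** The query genome is cut into consecutive,
non-overlapping 1020 bp fragments (a trailing remainder is dropped). Each
fragment is located in the subject by 16-mer seeding: every 16-mer of the
fragment (sampled every 8 bp) votes for a diagonal in the subject, and a
candidate window (padded by 48 bp) requires at least two votes. The
fragment is then aligned to the window with an infix (semi-global)
edit-distance alignment. A fragment is *retained* when its identity
exceeds 0.30 over more than 0.70 of its length; ANI is 100 × the mean
identity of retained fragments. When no fragment is retained the ANI is
**undefined** (`None`) — never reported as 0. Multi-contig subjects are
concatenated with a 16-base `N` spacer so seeds cannot span contigs; a
fragment straddling a contig boundary may be lost or slightly penalised,
which matches the behaviour of fragment-based ANI on draft assemblies.

**POCP.** For proteomes P1 (T1 proteins) and P2 (T2 proteins), a protein
is *conserved* when it has a local alignment hit in the other proteome
with identity ≥ 0.40 over ≥ 0.50 of its own length and e-value ≤ 1e−5.
Local alignment uses BLOSUM62 with gap open 12, extend 1; the e-value is
Karlin–Altschul E = K·m·n·exp(−λS) with the gapped BLOSUM62 constants
λ = 0.267, K = 0.041, where m is the query length and n the total residue
count of the subject proteome. POCP = 100·(C1 + C2)/(T1 + T2).

## Taxonomy workflow

**Dereplication.** Isolate 16S sequences are sorted by length
(descending), then id (ascending), and processed greedily: each sequence
joins the first existing cluster whose centroid it matches at ≥ 0.98
global identity, otherwise it founds a new cluster with itself as
centroid. Removing failed isolates re-centroids affected clusters (same
ordering rule among survivors) and drops clusters left empty.

**Assignment.** A taxon is assigned to a reference only when its best
global identity against the reference database is strictly greater than
the threshold (default 0.98). The best-scoring reference is reported even
when unassigned. Identity exactly at the threshold does not assign.

**Novelty calls.** Species novelty requires all three of: 16S identity
< 98 %, ANI < 95 %, dDDH < 70 %. dDDH is an input (from an external
genome-to-genome distance tool), not computed here. If 16S fails the
cutoff the call is *not novel*; if 16S passes but ANI or dDDH is missing
the call is *indeterminate* — absence of evidence never produces a
positive call. Genus novelty is only evaluated for taxa already called
novel species (otherwise a precondition error) and requires at least 3 of
5 criteria: 16S identity ≤ 95 % (inclusive), placement in a separate
phylogenetic clade, POCP < 50 %, marker-gene novelty at genus rank, and a
distinct phenotype. Unknown criteria count as unsatisfied.

## Amplicon coverage

Coverage is **read-weighted**: an OTU *hits* a catalog when its
representative sequence matches any catalog 16S above the identity
threshold (strict >; 0.97 at species level, 0.95 at genus level), and a
sample's coverage is the fraction of its reads belonging to hit OTUs.
Summaries report mean ± SEM over samples (SEM with n−1; a single sample
has undefined SEM). Samples with zero reads have undefined coverage. The
two-catalog Venn decomposition splits each sample's reads into
only-A / only-B / shared / neither fractions, which partition 1 exactly.
Annotation rate compares a base database against base ∪ augmentation;
base hits are reused for the augmented side, so the augmented rate is
never below the base rate by construction.

## Core/pan structure

Per genus, frequency of occurrence (FO) is the fraction of samples where
the genus has nonzero reads, and mean relative abundance (RA) is the mean
over samples of its read fraction. Reads without a genus label stay in
the per-sample denominators but form no genus of their own. *Core*:
FO > 0.80 and mean RA > 0.001. *Pan*: FO > 0.05 (core ⊆ pan). Catalog
coverage of each set is reported as an integer percentage with
round-half-up (banker's rounding is deliberately not used).

## Functional coverage

Genomes are reduced to KO presence/absence sets. Partitions between two
pooled profiles are exact set arithmetic. Accumulation curves draw random
genome orderings with `numpy.random.default_rng(seed)` and report, for
each k, the mean and standard deviation over draws of the fraction of the
target KO set covered by the first k genomes; each draw's curve is
monotone by construction. Gene catalog coverage is the fraction of
catalog proteins with a conserved-style hit in the pan-proteome at a
configurable identity cutoff; an empty catalog has undefined coverage.

## Enrichment

Each taxon's relative abundances in two groups are compared with Welch's
t-test (Student's pooled-variance test optional). Stars are strict:
p < 0.05 → `*`, p < 0.01 → `**`, p < 0.001 → `***`, otherwise `ns`;
p exactly 0.05 is not significant. Starred taxa get an `enriched_in`
label equal to the group with the larger mean; unstarred taxa get none.
Benjamini–Hochberg q-values are available but stars are based on raw
p-values unless requested otherwise. Count summaries report the number of
starred taxa enriched in each group. A published two-group species
summary (110 taxa, 22 and 17 starred per side) ships as package data.

## Synthetic generators

All generators are pure functions of their arguments including an integer
seed, and return planted ground truth alongside the data:

- `mutate_sequence` applies substitutions at a given per-base rate
  (substituted bases always change) and optional indels, returning a
  `MutationMap` with exact positions, so identity oracles can be computed
  by counting rather than aligning.
- `gen_genome_pair(ani_target, length, seed)` mutates a random ancestor
  at rate 1 − target/100; recovered ANI matches the target to within
  binomial noise.
- `gen_proteome_pair` builds two proteomes sharing a chosen number of
  near-identical proteins, the rest unrelated.
- `gen_community` plants per-genus occupancy and relative-abundance
  targets and draws per-sample read counts.
- `gen_ko_profiles` plants a target pool, per-genome overlap and
  redundancy, returning the exact planted union coverage.
- `gen_two_group_ra` plants per-taxon fold changes between groups.
- `gen_reference_and_isolates` plants which isolates derive from
  references (close mutation rate, assignable) and which are deeply
  diverged (novel); the assignment truth is returned per isolate.

## Limits

- The identity engines are exact dynamic programming (via Biopython's
  `PairwiseAligner`) and scale quadratically; they suit 16S genes,
  proteins and 1020 bp fragments, not whole-genome alignment. ANI is
  feasible to a few hundred kb per genome; for larger genomes use a
  dedicated ANI tool and feed the result into the novelty calls.
- ANI fragment placement relies on 16-mer seeding; below roughly 70 %
  identity seeds become sparse and fragments drop out, which is the
  intended retention behaviour but means ANI values far under the species
  boundary are noisy.
- The Karlin–Altschul constants are the standard gapped BLOSUM62 values,
  not re-estimated per scoring system; e-values are indicative filters,
  not calibrated significance.
- Statistical outputs (SEM, t-tests, accumulation curves) assume
  independent samples/draws; compositional effects in relative-abundance
  data are not modelled.
- dDDH, phylogenetic clade placement and phenotype distinctness are
  consumed as evidence, not computed.
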