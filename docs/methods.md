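# Methods

## Substitution scoring model

Substitutions are inferred parsimoniously from aligned triplets: two
closely related ingroup sequences and one outgroup. A column where the
ingroups agree is a conserved observation regardless of the outgroup; a
column where they differ and the outgroup matches one of them is scored as
a substitution from the outgroup (ancestral) state to the non-matching
(derived) state; three-way differences are ignored. This is valid only at
low divergence, where the probability that two changes hit the same site is
negligible — the simulator's default branch lengths (0.5% substituted sites
per ingroup branch, 0.8% on the outgroup branch, 0.2% on the shared
internal branch) keep the ingroup pair at ~0.7–1.0% observed divergence,
the regime the defaults are meant to emulate. No multiple-hit correction is
applied anywhere, deliberately: the count matrices are read as direct
approximations of the instantaneous mutation process.

Two window filters guard against scoring misaligned sequence: among the 10
columns flanking a site (5 per side, truncated at alignment ends, the site
itself excluded), at least `min_ungapped_pairs_in_window = 8` columns must
have no gap in either ingroup, and among those columns the ingroup identity
fraction must be at least `min_ingroup_similarity_in_window = 0.70`. The
similarity denominator is the number of ungapped-pair columns, not 10 —
the only computable reading when gaps are present. End-truncated windows
still face the 8-pair minimum, so the outermost ~3 columns of an alignment
effectively never score; alignments of 70 columns or fewer are skipped
outright (exclusive bound). A scored site additionally requires its two
immediate 5' and two immediate 3' columns to be gap-free and identical
across all three sequences, because the site's tetranucleotide context must
be unambiguous; coordinates are 0-based throughout, and FASTA record order
(ingroup1, ingroup2, outgroup) defines the roles.

In coding mode (`fourfold_degenerate_only`) only third codon positions
whose codon prefix is conserved in all three sequences and fourfold
degenerate are scored; the prefix conservation is already implied by the
context filter, which is why the two filters are defined jointly.

## Context matrices and equilibria

Counts are tallied per tetranucleotide context (written `NN_NN`), rows =
ancestral base, columns = derived base, diagonal = conserved sites.
Complementary contexts — the same double-stranded neighbourhood read from
the other strand — are combined by adding the partner's counts with both
axes complement-relabelled; the kept key is the lexicographically smaller
of the pair, and the 16 self-complementary contexts pass through
unchanged, giving 136 canonical matrices.

Pooling into 48 generic matrices keys each context by its immediate 5' and
3' neighbour and the composition class (A+T count or pyrimidine count, 0–2)
of the two outer bases. The default path pools the raw 256 matrices
directly (each pooled matrix is the plain sum of its 4 or 8 members, so
counts are conserved exactly); pooling a complement-combined set instead
folds every canonical matrix into both strand orientations, which makes
complementary pooled keys exact mirrors but represents each observation
once per strand. The two paths answer slightly different questions and the
package keeps both; the raw-256 path is what the pipeline commands use.

A count matrix becomes a stochastic matrix Π by row normalization. Zero
off-diagonal cells receive a pseudocount of one substitution first (per
matrix, before normalization — the narrower of the two readings of "no
observed substitutions of a given type"), so the chain is irreducible; a
row that is wholly empty becomes an identity (absorbing) row and is the
caller's signal of an unusable matrix. The stationary vector Φ solves
Φ = ΦΠ and is computed by repeated squaring of Π until the rows agree to
1e-12 in max norm (equivalent to Π^t for astronomically large t; the cap
of 200 doublings is unreachable for an irreducible aperiodic 4-state
chain), then verified against the fixed-point identity at 1e-8.

## Homogeneity test

The distance between two matrices is the sum of squared differences of the
12 off-diagonal rates. Under the null that both count matrices share one
set of per-row substitution probabilities, the pair is pooled element-wise,
per-row off-diagonal probabilities are taken from the pool, and each
matrix's off-diagonal row counts are redrawn from a multinomial with its
own original row total — diagonals stay fixed, so each matrix keeps its
depth and the rate denominators include the conserved counts. P = 1 −
(fraction of 100 resampled pairs with smaller distance); rejection uses
p ≤ 0.05 (ties on the 100-point grid resolved conservatively), and the
all-pairs driver applies no multiple-test correction because its output of
interest is the rejection *fraction*, not which pairs reject. Because the
observed pair is nearly exchangeable with the resampled pairs, the
discrete rank construction gives a type-I error slightly above 1/20
(≈6/101); the calibration check asserts the 3–8% band.

## Codon-usage statistics

ENC follows Wright: per-family homozygosity F̂ = (nΣp̂² − 1)/(n − 1),
class averages over the 2-, 3-, 4- and 6-fold families, ENC = 2 + 9/F̄₂ +
1/F̄₃ + 5/F̄₄ + 3/F̄₆, truncated at 61 (finite equal counts push raw
values slightly above it). Families with n < 2 or F̂ ≤ 0 are dropped from
their class average; an absent 3-fold class is repaired as (F̄₂ + F̄₄)/2
per Wright, an absent 6-fold class the same way, and any class still
missing falls back to the mean of the available class averages — needed
for short or compositionally narrow genes and for resampled sequences.
Sixfold amino acids are single 6-codon classes for ENC and for the
clustering distance, but split into their fourfold/twofold subgroups
wherever per-site expectations are formed, because a third-position draw
can never move a codon between subgroups.

CAI is the count-weighted geometric mean of relative adaptiveness w over
degenerate codons (Met, Trp and stops excluded). Fitness tables come from
pooled reference counts, w = count/max within each amino-acid family, with
zero counts replaced by 0.5 occurrences (a configurable convention) before
division. PR-AT = 100·N_A/(N_A+N_T) and PR-GC = 100·N_G/(N_G+N_C) are
taken over fourfold degenerate third positions (including the fourfold
subgroups of Leu/Ser/Arg); C2 = 100·NNC/(NNC+NNT) over exactly the six
twofold NNY groups Phe, Tyr, Cys, His, Asn, Asp (AGY-Ser is not one of
them); GC3 runs over all sense-codon third positions. All statistics
accept real-valued counts so observed genes, resampled draws and
deterministic expectations share one code path.

## Context-dependent expectations

The context of a third codon position is the first two bases of its codon
plus the first two bases of the downstream codon, read from the observed
nucleotide sequence — fixed, not iterated, which is exact rather than
approximate: a third-position change never alters a downstream codon's
first two bases. Each degenerate position takes Φ of its context restricted
to the synonymous third bases and renormalized; the positional vectors are
summed with the fixed (nondegenerate) codons into a real-valued expected
usage table from which ENC_CD (homozygosity F = Σp̂², the infinite-sample
form, since expected usage has no sample size), PR-AT_CD, PR-GC_CD, C2_CD,
CAI_CD and expected GC3 are computed. A trailing stop codon supplies the
final sense codon's downstream context; without one the terminal codon has
no context and contributes its observed codon as a fixed count. Genes are
expected to exceed 300 codons for stable statistics (the length filter
used in the source analyses), but shorter genes are accepted.

## Nested resampling test

The outer loop (default 100 iterations) redraws each pooled matrix's
off-diagonal row counts from its own rates (diagonals fixed) and recomputes
all needed stationary vectors, propagating matrix sampling error; the inner
loop (default 100) draws a synonymous realization of the gene from those
equilibria and computes ENC, CAI, PR-AT and C2 with the same code used for
the observed gene. The 10⁴ pooled draws form the null; z = (observed −
mean)/SD with SD the sample standard deviation of the pooled draws, and
|z| > 3.5 (a Bonferroni-style 5% cutoff, exposed as a parameter) flags
significance. An SD of zero (e.g. a gene with no degenerate site) reports
z as undefined rather than a spurious significance.

## Clustering

Pairwise distance: within each degenerate amino acid present in both genes,
codon frequencies relative to that amino acid's total are differenced,
squared and summed; the total is divided by the number of shared degenerate
amino acids. The matrix is clustered by complete linkage (the default of
the standard agglomerative routine) with ties broken deterministically by
scipy's ordering, and serialized as Newick with branch lengths equal to
merge-height differences.

## Simulator

A model is 256 row-stochastic per-branch matrices plus a root composition,
branch lengths and an indel rate. Branch lengths rescale every matrix's
off-diagonal mass uniformly (P_b = I + α(Π − I) with α = b divided by the
set's mean off-diagonal mass), which leaves each context's stationary
vector invariant, so equilibria are branch-length-free model properties.
Context is read from the pre-branch (parent) sequence — a single-step
approximation that is order-independent and essentially exact below ~1%
divergence — and the terminal two bases never substitute, mirroring the
estimator. Gaps are independent single-base deletions per leaf taxon: just
enough to exercise the gap filters, with no indel length model.

Presets: `null_uniform` (one matrix everywhere, ts:tv 2, uniform
equilibrium) is the calibration null; `at_context` scales the transition
bias down and the pull towards A/T up with the flanking A+T count,
reproducing the qualitative pattern of chloroplast intergenic data;
`table1_like` anchors the three built-in reference matrices at their own
contexts (flanking A+T counts 0, 2, 4) and interpolates linearly in
between, so all contexts with the same flanking A+T count share a
generating matrix. Root compositions are uniform for the null preset and
A+T-rich (66–70%) otherwise, matching the genomes emulated.

`simulate_neutral_gene` fixes each codon's first two bases from the amino
acid (choosing a sixfold subgroup uniformly at random), then draws each
degenerate third base from the restricted equilibrium of its context; a
trailing `*` appends TAA, and a final codon with nothing downstream draws
its third base uniformly over the synonymous set.

What the simulator does *not* emulate: rate heterogeneity beyond context,
indel length distributions, non-equilibrium base composition, selection,
or the taxon-sampling procedure that builds real triplets. Passing tests
therefore demonstrate the estimator and tests are correct and calibrated
under a known context-dependent neutral process — not that any real genome
satisfies that process.

## Problem sizes and numerical choices

The test suite runs the type-I calibration of the homogeneity test on
1,000 simulated matrix pairs (≈10⁴ sites per row), the nested-test null
calibration on 500 neutral genes of 310 codons at a reduced 30×30 nesting,
and parameter recovery on ~6×10⁶ simulated sites; these sizes give
binomial/Monte-Carlo error comfortably inside the asserted bands. One
statistical caveat is recorded about per-context parameter recovery: the
stationary vector of a matrix carrying only ~200 substitutions has an
irreducible sampling noise of several percentage points (median max-entry
error ≈6.5 pp in a pure-multinomial experiment), so recovery to 3 pp is
demonstrated on matrices pooled to ≥2,000 substitutions; an acceptance
check that demands 3 pp at the 200-substitution threshold fails for
statistical, not implementation, reasons.

Other conventions: stationary iteration tolerance 1e-12 (max norm) with a
fixed-point verification at 1e-8; ENC truncation at 61; CAI zero-count
replacement 0.5; p-value grid 1/repetitions with p ≤ α rejection;
significance threshold 3.5 SD; all random streams are numpy Generators
seeded explicitly, and the CLI derives per-stage substreams from the root
seed by hashing, keeping every derived seed below 2³¹.
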