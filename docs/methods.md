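# Methods

This note documents the models, parameter choices and numerical conventions
behind snoevo, and what the synthetic test bed does and does not show about
real data.

## Structural model of a C/D box snoRNA

A gene is modelled as, 5'→3': a terminal stem arm (4–5 nt), the C box
(consensus `RUGAUGA`, R ∈ {A,G}), antisense element 1, the internal D' box
(`CUGA`), the internal C' box, unconstrained filler, antisense element 2,
the D box (`CUGA`), and the 3' stem arm complementary to the 5' arm. The
stems may pair through G:U wobble (thermodynamically standard); "perfect
binding" in the duplex module is strict Watson–Crick only, with wobble
behind a flag, because mismatch counting in guide duplexes conventionally
treats G:U as a non-pair.

Annotation searches the best C hit in a 25-nt window after the 5' stem
(ties to the 5'-most position) and the best D hit in a 15-nt window before
the 3' stem (ties to the 3'-most position, since the D box abuts the stem).
Internal D'/C' boxes are optional; the D' search prefers the position one
ASE length downstream of the C box, its expected location. ASE2 is up to
18 nt immediately 5' of the D box and ASE1 up to 18 nt immediately 5' of
D' (or following the C box when D' is absent); 18 nt is the length of the
functional guide duplex. Everything unassigned is `REST`, and the five
classes plus boxes tile the sequence exactly — an invariant asserted on
every annotation.

The acceptance score is a transparent linear gate,
`2·(7−mm_C) + 3·(4−mm_D) + stem_len`, accepted at ≥ 24; a perfect gene
scores 31. The score is deliberately simple: it preserves a tunable
accept/reject threshold without re-implementing an external screening
program, and its weights (D box heaviest, then C box, then stem) reflect
the relative functional importance of the elements. Whether this scale is
numerically comparable to other published screening scores is unknowable;
treat the threshold as a knob.

Pseudogenes are called from lesions that abolish snoRNP assembly: C box
with >1 mismatch or absent, D box with any mismatch or absent, no terminal
stem, or length < 50 nt. These thresholds are explicit configuration, not
inferred fact — published descriptions of imprinted snoRNA pseudogenes
stop at "box-disrupting mutations". Annotation operates on the gene
sequence proper; flanking sequence is trimmed by the caller.

## Family assignment

Homology assignment uses exact Smith–Waterman (match 2, mismatch −3, gap
open −5, extend −2) rather than a heuristic seeded search; at snoRNA scale
the exact DP is fast and removes word-size artifacts. E-values use
`E = K·m·n·e^{−λS}` with λ solved numerically from the scoring moments
under uniform base composition (λ ≈ 0.634) and K fixed at 0.41, the
tabulated ungapped value for this match/mismatch scheme. Applying ungapped
theory to a gapped score makes these e-values calibrated approximations;
the null test (random 80-mers against real references are unassigned at
the 1e-3 cutoff in ≥ 99/100 trials) is the operational check.

Clade assignment runs on neighbor-joining trees with column-resampling
bootstrap supports, condensed at 50%. Because NJ trees are effectively
unrooted, both sides of every supported bipartition are candidate clades;
a candidate takes the family of the smallest side with support > 50% that
contains at least one reference and whose references are all one family.
A star tree therefore assigns nothing. This replaces Bayesian posterior
supports with a deterministic, seedable equivalent carrying the same
downstream contract (supports in [0, 100]).

NJ clamps negative branch lengths to zero and transfers the deficit to the
sister edge, keeping path lengths additive; on additive matrices the tree
reproduces the input distances exactly (tested).

## Reconciliation

Gene trees are mapped into the species tree by LCA parsimony. A gene node
is a duplication iff a child maps to the same species node; duplications
at species node *v* are charged to the branch entering *v* (a convention —
parsimony only locates them somewhere on that branch), with the species
root's entering branch serving as the virtual root branch. A child lineage
spanning *d* species-tree edges implies *d−1* losses under a speciation
and *d* under a duplication, each charged to the branch where the lineage
disappears. Polytomies (from condensed trees) are resolved minimally:
children whose species-LCA is deepest merge first.

Ancestral copy numbers come from lineage-interval counting: a copy born by
duplication on the branch entering *v* is already present at node *v*; an
edge whose child is a duplication at *v* terminates above *v*; a family
whose gene-root LCA maps below the species root originates on the branch
entering that mapping, and counts above it are zero. This bookkeeping
satisfies `count(v) = count(u) + gains − losses` on every branch, which is
asserted after every reconciliation. (The superficially simpler identity
"total extant = root count + total gains − total losses" is false on
branching species trees, since each speciation doubles lineages.)

Same-species cherries with genomic order indices differing by exactly 1
are tandem duplications; other indexed cherries are ectopic. Genes without
an order index are counted unclassified rather than guessed.

## Rates and selection

K2P distances use pairwise deletion (complete deletion is available), and
saturation (`1−2P−Q ≤ 0` or `1−2Q ≤ 0`) is a value, not an exception, so
between-group averages can drop invalid pairs exactly as "all valid
inter-group pairwise comparisons" requires. Bootstrap SEs resample
alignment columns (500 replicates by default) and match delta-method
variances within 20% on kilobase-scale pairs. Partitioned rates restrict
the between-group computation to the columns of each structural class and
report classes with fewer than 5 sites as undefined.

Birth rates divide newly derived genes on a terminal lineage by the time
since that species split from its closest sampled relative. The packaged
divergence times (human–chimp 6.75 My, human–rhesus 30.95 My, mouse–rat
36.9 My, ...) are editable configuration chosen for consistency with the
packaged birth-rate inputs; the published table they reproduce mixes a
36.9- and a 37.0-My rodent rounding between columns, so the non-imprinted
mouse row carries 37.0 My. Printed-precision arithmetic (round the rate to
2 decimals before the per-family division; per-family rates of the
~180–195-family non-imprinted set to 4 decimals) is confined to
`pipeline.birth_rate_table`; the core functions never round.

Tajima's D uses complete deletion and the full published constant chain
(a1…e2); significance comes from the beta approximation on
[D_min, D_max]. Applying a population-genetic statistic to paralogous
family members within one genome treats the family as the sample — the
standard move for multigene families, documented here because the
"population" assumptions (free recombination, random sampling) do not
hold; the neutral-coalescent calibration (mean D ≈ −0.03, 5% type-I error
≈ 4–5% at n=10, θ=5) shows the implementation, not the paralog
application, is well calibrated. Nei–Gojobori counts synonymous site
fractions per codon (changes to stops count as nonsynonymous), averages
multi-difference codons over all single-step pathway orderings excluding
paths through stops, applies the Jukes–Cantor correction, and reports
Ka/Ks as undefined ("-") when Ks = 0. The purifying-selection p-value is a
one-tailed Z-test with the variance of dS − dN from a 500-replicate codon
bootstrap — chosen over the analytic variance for transparency and
testability.

## Duplex scanning

All maximal runs of strict complementarity between the region 5' of the
D box and the target are found by exact diagonal scanning (supersedes the
heuristic alternative; exactness is cheap at these sizes). Distance 0
means the duplex ends immediately 5' of the D box. Position *i* of the
anchored duplex is the i-th snoRNA nucleotide upstream of the D box and
pairs the i-th base of the target site read 5'→3' (the duplex is
antiparallel); the +5 rule predicts methylation of the target base paired
to position 5, invalid when that position is mismatched. Distances count
nucleotides, not alignment offsets.

## The simulator

`simulate_family` runs an exact continuous-time (Gillespie) birth–death
process per gene lineage along the dated species tree — exact event times
so expectations have closed forms for oracle tests (E[n] = e^{(λ−μ)T} per
founding lineage). Duplicates insert adjacent to the parent copy (tandem)
or uniformly at random in the cluster (ectopic, probability `p_ectopic`).
Defaults: λ = 0.04, μ = 0.008 /gene/My (net growth turning one ancestral
copy into tens of genes per species over ~100 My, the observed scale of
these clusters), substitution rate 2×10⁻³ /site/My for unconstrained
sequence (a typical neutral mammalian rate), κ = 4 transition bias, and
region multipliers {BOX 0.05, STEM 0.075, ASE1 1.0, ASE2 0.1, REST 1.0}
reproducing the observed conservation hierarchy boxes < stem < ASE2 <
{remainder, ASE1} for a guide family whose functional element is ASE2. The
stem multiplier sits between the boxes and ASE2 because terminal stems are
observed among the most conserved regions (K ≲ 0.1).

Pseudogenization is emergent — substitutions that hit box positions
disrupt annotation downstream — matching the mutational account of gene
death; a direct pseudogenization rate exists for targeted tests. The event
log replays exactly to the final per-species counts (asserted every run),
and per-branch *visible* duplications (both daughter lineages left extant
descendants) are logged separately: reconciliation of the true pruned gene
tree can recover visible duplications exactly, and with μ = 0 every
duplication is visible — the condition under which terminal-branch gain
recovery is tested exactly. With NJ-inferred trees, recovery is tested at
a substitution rate of 0.01/site/My, enough signal to resolve
within-species expansions; aggregate terminal gains come back within ±20%
of truth over 50 replicates. At the default (lower) rate, near-identical
paralogs make within-species topology arbitrary and gains are
systematically undercounted — a real limitation of gene-tree-based gain
counting at low divergence, not an implementation artifact.

What the simulator does **not** emulate: indels (alignments are trivial by
construction, so the aligner is exercised only by its own tests), gene
conversion (invoked in the literature for these clusters but with no
stated procedure), imprinting state, and genome assembly artifacts.
Passing tests therefore validate the estimators under a clean birth–death
substitution model; on real data, alignment error, conversion-driven
homogenization and assembly collapse of near-identical repeats will all
bias family sizes and gain counts in ways the synthetic bed cannot reveal.

## Problem sizes

The validation suites use desk-scale problem sizes chosen to make each
statistical check decisive: 1000 random proportion pairs and 100 10-kb
pairs per distance for K2P calibration, 200 simulated families for the
conservation identity, 1000 neutral coalescent replicates (n=10, θ=5) for
Tajima's D, 100 replicates of 150 concatenated loci for the partition
hierarchy, 100 planted-site simulants for duplex recall, and 20 + 50
replicates for gain recovery. Genome-scale repertoires (hundreds of genes
across 12 real genomes) are deliberately out of scope; the published
per-species counts and birth-rate inputs ship as packaged reference data
and their arithmetic is recomputed, not their discovery.
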