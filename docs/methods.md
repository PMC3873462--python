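# Methods

This note documents the models, estimators and numerical choices behind
`sporeseg`, and what the synthetic-data generator does and does not
emulate.

## The measurement problem

A coenocytic fungal mycelium carries a population of nuclei that may
differ at a marker locus. A spore receives a finite sample of those
nuclei, so the set of alleles observable in one spore understates the
parent's allele complement, and amplicon sequencing of the spore
understates it further (finite reads, sequencing error, chimeras). The
package separates these effects: sequencing artefacts are removed by QC,
preclustering and chimera screening; the residual sampling gap is then
quantified with a nonparametric richness estimator.

## Read quality control

Reads are eliminated (never trimmed by quality) under four criteria,
applied in a fixed order for deterministic attribution: (i) the read
must begin with the exact MID + forward primer (zero mismatches; the
reverse adaptor is checked only when configured, since pyrosequencing
reads frequently end before reaching it); (ii) any non-ACGT base is
disqualifying; (iii) any 50 bp sliding window with mean quality below 35
(reads shorter than the window are judged on their whole-read mean — the
stringent reading); (iv) any homopolymer run longer than 8 bp. Counts
are conserved by construction: raw = retained + Σ per-criterion
failures, per sample.

## Preclustering and chimera screening

Residual sequencing error inflates richness, so dereplicated sequences
are preclustered: sorted by abundance (ties broken lexicographically so
the result is independent of input order), each rarer sequence merges
into the first kept sequence within ⌈t·L⌉ differences, where t = 0.01 by
default and L is the pairwise alignment length. A maximal contiguous gap
run counts as one difference and terminal overhangs are free; unequal
lengths are globally aligned first. This greedy, abundance-ranked scheme
is verified in tests against a brute-force re-implementation on small
instances.

Chimera screening is reference-based: every query is compared with its
best single reference and with the best two-parent model (prefix from
one reference, suffix from another, crossover scanned over every
column — an exhaustive version of the heuristic search used by
ChimeraSlayer-style tools). A query is chimeric when the two-parent
model strictly beats the single parent and at least 90% of column
bootstrap replicates (default 100) agree; the chimeric test takes
precedence over the identity floor, since a clean chimera of two distant
references may itself fall below it. Queries under the identity floor
(default 0.80) against every reference are reported `no_match` and
removed, matching a screening policy that keeps only reads anchored to a
trusted allele database.

## Richness, bottleneck and related estimators

**Chao1.** The bias-corrected form S_obs + n1(n1−1)/(2(n2+1)), with a
95% CI from the classical log-normal construction on T = chao1 − S_obs.
The variance uses the standard three branches (n1>0,n2>0; n1>0,n2=0;
n1=0 with the exponential-in-coverage degenerate form). The lower bound
is clamped at S_obs. The point estimate is cross-checked against an
independent implementation (scikit-bio) in tests.

**Bottleneck.** 100·(1 − S_obs/chao1), with lower/upper bounds obtained
by substituting the CI endpoints. Reported integers use round-half-up,
which reproduces the published integer table for the rows the acceptance
suite checks; two published cells are known rounding edge cases of the
printed (already rounded) Chao1 bounds and are deliberately not
asserted.

**Rarefaction.** The exact hypergeometric expectation
E[S(n)] = Σ_i [1 − C(N−N_i, n)/C(N, n)], evaluated in log-gamma space
for stability and verified against without-replacement subsampling.

**Shared Chao1.** The two-community shared-richness estimator with
singleton/doubleton corrections on both margins and a +1 correction for
zero doubleton denominators.

**Saturation curves.** At each depth, the sequence multiset is
subsampled without replacement (1000 replicates by default) and distinct
variants are counted under either the conventional rule (every SNP
real) or the conservative rule (column states carried by exactly one
sequence are replaced by the column majority before collapsing; majority
ties break toward a reference state when given, else alphabetically).
The masking is idempotent and can only merge sequences, so the
conservative count never exceeds the conventional one. Bands are
mean ± 1.96·sd over replicates.

**Nucleotide diversity.** Per column, π = 1 − Σ_s f_s² with
relative-abundance weights (a population-level profile, no small-sample
correction), averaged over sliding windows.

## Community comparisons

jclass (presence/absence Jaccard) and thetaYC (Yue & Clayton) are the
two dissimilarities; significance machinery includes weighted and
unweighted UniFrac (branch-mass formulation, normalised so both lie in
[0,1]) with a read-relabelling permutation test (reads pooled per tip
and re-split keeping sample sizes fixed), distance-based AMOVA (sums of
squares from squared pairwise distances, F by label permutation) and
HOMOVA (Bartlett-style statistic on within-group mean squared
distances), and the standard two-sample Kolmogorov–Smirnov test.
Permutation p-values use the add-one correction, so p ≥ 1/(n_perms+1);
the default 1000 permutations gives a floor of ~0.001, matching the
resolution at which such tests are conventionally reported. Bonferroni
correction within a test family is provided as a helper. When no tree
is supplied, UniFrac consumes a neighbor-joining tree built from
pairwise-difference distances, with negative NJ branch lengths clamped
to zero and the deficit moved to the sibling edge.

The published per-allele KS column ("number of alleles for which the
null hypothesis is rejected") corresponds to a per-allele testing scheme
whose definition is not recoverable from the methods available to us;
the package reports the standard two-sample KS instead.

## Segregation / anastomosis simulator

Each lineage is a pool of allele frequencies. Per generation, a lineage
may first fuse with a random sister lineage (probability =
`anastomosis_rate`; frequencies averaged — the model's only mechanism
for regaining alleles), then produces the next spore by a multinomial
draw of nuclei. The draw size is either fixed (`nuclei_per_spore`) or
bridged from a target per-generation richness retention f: n is solved
(bisection on the pool's actual frequencies) so that
Σ_i [1 − (1−p_i)^n] = f·R. Solving on the actual frequencies matters:
drift skews the pool over generations and the uniform-pool closed form
would systematically under-retain.

Defaults are the study conditions this package models: 8 coexisting
lineages (the spore count of the experiment), retention 0.6 (the 40%
per-generation diversity loss discussed for this system), and an
initial frequency law equal to the generator's geometric
ranked-abundance distribution (top-4 dominance 0.6) — the observed
allele distribution of the parent pool is heavily skewed, and a skewed
pool loses richness much faster than a uniform one (median ≈ 5 vs ≈ 11
generations to monomorphy at these settings). A uniform law is
available for idealised runs and is used in tests against the
deterministic decay oracle R₀·f^g.

Randomness comes from counter-based streams keyed by (seed, replicate,
generation, lineage), so sweeps over `anastomosis_rate` are paired
common-random-numbers comparisons: runs differing only in the rate share
every draw up to the first fusion event. This makes the directional
effect of rare anastomosis (e.g. 2%) measurable with a few hundred
replicates, where an unpaired design would need orders of magnitude
more. Monomorphy is defined as a single remaining allele; replicates
that never reach it within the simulated horizon are reported censored,
and the median is withheld when more than half are censored.

## Synthetic data generator

The generator emulates the experiment's structure: a parent pool of
distinct alleles derived from one random reference by 1–4 point
mutations (70% placed in the intron by default, mirroring where the real
marker's diversity sits), geometric ranked abundances with the top four
alleles carrying 60% of mass, three plants carrying 3/3/2 spores, nuclei
drawn multinomially per spore, and reads laid out as
MID + forward primer + insert + reverse adaptor with optional
substitution errors, ±1 homopolymer-length errors on runs ≥ 3, and
two-parent chimeras with a uniform crossover and abundance-weighted
parents. Ground truth (template, chimera flag, planted QC failures)
is emitted as a sidecar table keyed by read id.

What it does **not** model: whole-genome-amplification bias, flowgram-
level pyrosequencing chemistry, position-dependent quality decay,
paired-end layouts, or PCR-cycle-dependent chimera formation. Passing
tests therefore demonstrate correctness of the analysis chain under the
assumed error structure, not robustness to every artefact of real 454
data. Note also that closely related synthetic alleles (1–4 mutations
apart) merge under 1% preclustering exactly as real near-identical
alleles would; end-to-end identity tests against ground truth therefore
run with the precluster threshold at 0.

## Numerical and design choices

- Coordinates are 0-based half-open internally; region specs are
  validated for contiguity and frame.
- Integer percent reporting uses round-half-up (floor(x+0.5)), not
  banker's rounding.
- Equal-abundance ties everywhere break lexicographically by sequence,
  making every stage deterministic and order-independent.
- All stochastic operations take explicit seeds; the pipeline manifest
  records seeds, parameters and per-stage record counts, and a rerun
  with the same config is byte-identical.
- Problem sizes in tests (synthetic pools of 10–60 alleles, hundreds of
  reads per spore, 99–1000 permutations, 150–200 simulator replicates)
  were chosen as the smallest instances at which each statistical check
  is well-powered.

## Known limitations

- The chimera detector assumes references and queries share one
  alignment length (the pipeline guarantees this for a fixed amplicon);
  indel-bearing chimeras are out of scope.
- The conservative variant-calling rule realises "singleton SNPs are
  artefacts" as majority-state replacement; other realisations (e.g.
  dropping singleton sequences entirely) would give different counts.
- HOMOVA's B statistic is used only with permutation p-values; no
  chi-squared approximation is provided.
- The simulator's anastomosis is a whole-pool average between two
  lineages; partial cytoplasmic exchange and spatial structure are not
  modelled.
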