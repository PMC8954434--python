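# Methods

This note documents the models, parameter choices and numerical decisions
behind `dispersalscreen`, and what the simulation-based tests do and do not
establish.

## The screening model

The workflow assumes a study system in which large-fruited plants lost
their long-distance seed disperser at a known horizon (in eastern
Australia, the megafauna extinction, taken here as 30 kya — inside the
50–16 kya extinction window) while small-fruited plants kept theirs (birds,
bats). Three dispersal histories are then distinguishable in principle:

* **long-term faunal dispersal** — low differentiation, isolation by
  distance (IBD), range-wide chloroplast haplotype sharing;
* **long-term isolation** — high differentiation, divergent site-private
  haplotypes;
* **dispersal following long-term isolation** — the candidate human
  footprint: one or more of the four signals below.

Signals are tri-state. *Not assessable* is reserved for a missing data
layer (no chloroplast data for signal 4, fewer than three sites for the
Mantel test behind signal 1, a one-population ancestry model for signals
2–3) and never counts toward the candidate tally.

### Signal 1 — low F<sub>ST</sub> without IBD

Pairwise F<sub>ST</sub> uses the Weir–Hill ratio-of-averages estimator
computed from allele frequencies (the form used by allele-count-based
implementations): per-locus between/within mean squares are summed across
loci before the ratio is taken, loci monomorphic across a pair contribute
zero to both sums, missing calls reduce the per-locus allele counts, and
negative estimates are retained (truncation would bias means upward). The
heterozygosity-bearing genotypic variant of the estimator is deliberately
not used: the pipeline's inputs are allele counts, and the two agree in the
random-union-of-gametes regime the simulations operate in.

The Mantel test correlates F<sub>ST</sub>/(1 − F<sub>ST</sub>) with the
natural log of great-circle distance (haversine, Earth radius
6371.0088 km), one-sided for positive IBD, p = (#{r* ≥ r} + 1)/(n + 1)
under joint row/column permutation; 999 permutations by default. Values
F<sub>ST</sub> ≥ 0.999 make the linearisation blow up and raise an error
unless the configured capping policy is enabled (cap at 0.999).

Signal 1 fires when the median pairwise F<sub>ST</sub> is below 0.05 *and*
the Mantel test shows no appreciable IBD (r < 0.30 or p > 0.05). The 0.05
and 0.30 cuts are package defaults, configurable: the screen weighs overall
pattern, not significance alone. With two sites the Mantel test cannot run
and the signal is not assessable.

### Signals 2–3 — admixture and within-site outliers

The ancestry model is STRUCTURE-like sparse NMF. Genotypes are one-hot
encoded into three classes per locus; X ≈ Q·G with rows of Q on the
K-simplex and each (ancestral population, locus) triplet of G a genotype
class distribution. The objective ‖W ⊙ (X − QG)‖² + α‖Q‖² (α = 10 by
default; the regulariser mainly stabilises near-empty components) is
minimised by alternating projected-gradient steps with backtracking line
search; steps are only accepted when they lower the objective, so the
objective is non-increasing by construction. Convergence is a relative
objective change below 1e-5 (default cap 200 iterations); non-convergence
is reported, never silent.

Model choice holds out 5% of the observed genotype entries before fitting
and scores each K by the masked cross-entropy (mean −log predicted
probability of the held-out classes). The mask stream is shared across K
(one mask per replicate index) so every K is scored on the same entries;
K* is the arg-min of the mean over replicates, ties to the smaller K, and
the per-K table is returned for plateau heuristics. Replicate Q matrices
are label-aligned by greedy column matching on correlation before
averaging; the best replicate per K is the lowest cross-entropy one.

PCA mean-imputes missing calls per locus, centres, scales by the binomial
standard deviation √(p̂(1−p̂)) (configurable), and fixes each axis's sign so
the largest-magnitude loading is positive.

Signal 2 flags a site iff more than half its samples have dominant ancestry
≤ 0.75 *and* the site's two largest mean ancestry components each dominate
at least one other site — separating between-site admixture from
within-site noise. Signal 3 flags a sample iff its dominant component
differs from its site's modal component with coefficient ≥ 0.60 *and* its
nearest site centroid in the first three PCA axes is not its own site; the
conjunction of both methods is required, since either alone is noisy under
sparse sampling.

### Signal 4 — chloroplast haplotype LDD

Alignments are collapsed to haplotypes over their variable columns
(constant columns carry no information and are dropped; under the
`pairwise_complete` policy, gap/ambiguity positions act as wildcards and a
partially missing sequence merges into the most frequent compatible
haplotype, ties lexicographic). The network is the minimum-spanning network
(union of all minimum spanning trees over pairwise-complete Hamming
distances), augmented median-joining style: candidate medians are
positionwise majority consensi of node triplets mutually close in the
current network, added greedily while they strictly reduce total spanning
length (the epsilon = 0 setting); inferred nodes that end as leaves are
pruned. On genealogy-like data this greedy reaches the exhaustive-search
minimum (tested); on adversarial random sequences it is only guaranteed
never to exceed the plain MST length, as for median-joining generally.

The LDD pattern fires when a haplotype (or pair within 2 mutations) is
shared between sites at least the species' median between-site distance
apart whose nuclear F<sub>ST</sub> is ≥ 0.15 (or, lacking a nuclear
estimate, which lie in different declared regions). The widespread pattern
fires when one haplotype carries ≥ 80% of samples and occurs at every site.
The median-distance default makes "disjunct" scale-free across species
with very different ranges.

### Decision rule

Candidate ⇔ fruit-size class is large (maximum fruit width ≥ 30 mm; an
explicit override exists for species whose published classification
overrules the raw maximum, e.g. thin-fleshed fruit) **and** (≥ 2 detected
signals or signal 4 detected). The "or signal 4" arm reflects that
chloroplast LDD between differentiated sites is on its own the sharpest
seed-movement evidence; the rule reproduces the published east Australian
cohort's five starred candidates exactly (golden test). History labels
(long-term faunal / long-term isolation / post-isolation dispersal /
ambiguous) are advisory; the candidate flag is the operative output.

## The scenario simulator

Scenarios are epoch-structured coalescent models (msprime) over six demes
of 1000 diploids in a 100-km chain (30-year generations, long-lived
trees), splitting from a panmictic ancestor 200 kya. Migration matrices
are forwards-in-time ("fraction of deme i replaced by migrants from deme j
per generation"), which coincides with msprime's backwards lineage-movement
convention. Times are years BP, floored to generations.

Two design points matter and were settled by experiment:

* **Megafauna-era background connectivity.** The large-fruited scenarios
  share a weak distance-limited migration background
  (m₀ = 2×10⁻⁴, decay 120 km) between the deep split and the extinction at
  30 kya, rather than panmixia until the scenario onset. With a panmictic
  recent ancestor, chloroplast lineages from different demes frequently
  coalesce immediately at the split and sit within 2 mutations of each
  other — incomplete lineage sorting that makes the isolation scenario
  mimic haplotype LDD. With structured ancestry, between-deme chloroplast
  coalescence predates the isolation by thousands of generations and the
  LDD detector separates the isolation and pulse-dispersal scenarios
  cleanly. Faunal scenarios (fd1/fd2) instead keep continuous
  bird-mediated connectivity (m₀ = 2×10⁻³, decay 80 km) to the present —
  volant dispersers were unaffected by megafauna loss; fd2 multiplies
  migration across the mid-chain boundary by 0.01 (a persistent dry-corridor
  barrier).
* **Range expansion (hd4) is disjunct.** The founded deme sits 400 km
  beyond the range edge and is founded from the edge deme 4 kya. Founding
  an in-chain deme instead removes that deme from the megafauna era, which
  isolates its neighbour and raises the remaining pairs' equilibrium
  F<sub>ST</sub> by almost exactly what the low founded pair subtracts —
  erasing the expected "isolation shows the greatest structure" ordering.
  The disjunct geometry matches the range-expansion hypothesis the
  screening is meant to generate (a far colony founded by people) and its
  pre-founding absence is demographically negligible.

Human-dispersal rates are island-model m = 0.01 per generation (sustained,
8–0 kya, for hd1/hd5; pulsed 5000–4000 BP for hd3/hd6; hd2 is hd1 at
m/10). Under these conditions hd2 retains substantial structure
(grand F<sub>ST</sub> ≈ 0.40), so the qualitative claim "island-model
dispersal homogenises more than faunal dispersal" holds for hd1
(≈ 0.02 vs ≈ 0.19), not hd2.

Nuclear data are biallelic SNPs (binary mutation model, μ = 10⁻⁸/bp/gen)
from 10 diploids per deme over 1.5 Mb, sized to yield ≈ 2000 segregating
sites; monomorphic sites are dropped and zero variation is an explicit
error. The per-bp recombination rate is 10⁻⁷ — deliberately high so the
~750-bp-spaced SNPs are effectively unlinked, emulating a genome-wide
sparse genotyping-by-sequencing panel rather than one linked window. (With
linked markers, held-out genotype entries become genuinely predictable from
extra ancestry components and cross-entropy overfits K; this is a property
of dense linked data, not of the selector.) The chloroplast locus is
haploid, non-recombining, uniparental (effective size = deme size / 2),
100 kb, 3 samples per deme — matching the study scale at which cpDNA
sampling is known to be limiting. Seed movement carries both genomes, so
chloroplast migration uses the nuclear matrices; pollen-only gene flow is
not modelled.

The island-model oracle uses the pairwise-F<sub>ST</sub> coalescent
expectation 1/(1 + 4Nm·d/(d−1)) (from E[T_within] = 2Nd and
E[T_between] = 2Nd + (d−1)/2m). The familiar (d/(d−1))² correction applies
to one deme against the pooled metapopulation and is *not* the estimand of
two-deme Weir–Hill θ; simulations at 4Nm = 1 match the pairwise form
(0.445 ± 0.016 vs 0.4545) and exclude the squared form (0.410).

## What the synthetic data do and do not show

The generator reproduces the *population-genetic* structure of the study
system: deme-structured drift, epoch migration, haploid vs diploid
contrast, DArT-like marker sparsity, small chloroplast sample sizes. It
does not emulate genotyping error or missingness (simulated QC metadata are
perfect — the QC filters are exercised on constructed tables instead),
ascertainment bias of the genotyping platform, pollen/seed dispersal
kernels, spatially continuous landscapes, selection, or uneven
opportunistic sampling. Passing scenario-recovery tests therefore show the
*statistics and decision rule* behave as designed under known histories;
they do not certify performance under real-world sampling noise.

Known limitations: with only 3 chloroplast samples per site the LDD
detector misses genuine pulse-dispersal events in a minority of replicates
and retains a residual false-positive rate (~0.2–0.4 of isolation
replicates show some ≤2-mutation between-deme pair) — the
pulse-vs-isolation contrast is a rate difference, not a deterministic
separation, mirroring the published recommendation to sequence more
chloroplasts per site. The admixture flag for symmetric all-deme contact is
diffuse (every deme is equally admixed and K collapses), so its positive
control is an asymmetric contact-zone configuration. Classification is a
pure function of the signal profile and traits, and every stochastic step
is seeded; identical seeds reproduce datasets bit-for-bit.

## Default thresholds

| quantity | default |
|---|---|
| marker reproducibility / call rate | ≥ 0.96 / ≥ 0.80 (boundaries kept) |
| cp coverage / consensus | ≥ 8 reads / ≥ 0.60 (per-sample call masking) |
| large fruit | max width ≥ 30 mm |
| signal 1: median F<sub>ST</sub>, Mantel r, p | < 0.05, < 0.30, > 0.05 |
| Mantel permutations | 999 |
| ancestry: K range, replicates, α, mask, iterations, tol | 1–10, 10, 10, 5%, 200, 1e-5 |
| signal 2: dominance, site majority | ≤ 0.75, > 0.5 |
| signal 3: foreign dominance, PCA axes | ≥ 0.60, 3 |
| signal 4: mutations, nuclear F<sub>ST</sub>, distance, widespread | ≤ 2, ≥ 0.15, ≥ median between-site km, ≥ 0.80 |
| distance bins | 50-km half-open (lower, upper], 0–700 km, 301–700 pooled |
| haplotype network epsilon | 0 |
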