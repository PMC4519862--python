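# Methods

`invabc` reconstructs the invasion history of an introduced species from
multi-locus sequence surveys: descriptive population genetics first, then
explicit scenario testing by Approximate Bayesian Computation (ABC).  The
reference design it ships is a crayfish survey — 37 sampling populations (35
in China, one in Japan, one in the USA), a maternally inherited
mitochondrial control-region locus (291 sequences) and an X-linked nuclear
intron (196 sequences) — but every component takes arbitrary alignments,
population maps and scenario definitions.

## Site handling and haplotype identity

All sequence comparisons use *complete deletion*: an alignment column
containing a gap (`-`) or `N` in any sequence is removed before anything is
counted.  Haplotype identity, segregating sites, pairwise differences and
the neutrality tests all share this rule, so the haplotype count is
invariant to indel placement and the statistics are mutually consistent.
The one exception is the mutational-step distance inside haplotype
networks, which drops only sites gapped in either member of the pair
(pairwise deletion); the network literature counts steps this way, and it
can differ from a complete-deletion count by a step or two when gap columns
are common.  Site positions in reports are 1-based.

Columns are classified as: gap sites; singleton variable sites of two
variants (minor variant in exactly one sequence); parsimony-informative
sites of two or of three variants (≥2 variants each carried by ≥2
sequences); all remaining variable columns are tallied once as "other".

## Diversity and neutrality statistics

* Haplotype diversity `Hd = n(1 − Σp̂ᵢ²)/(n − 1)` with Nei's sampling
  variance.  Mean pairwise differences `k` average over all C(n,2) pairs;
  nucleotide diversity is `π = k / (complete sites)` with no additional
  n/(n−1) factor (the two conventions differ in the third decimal at survey
  sample sizes; this package's convention is stated here precisely so the
  reported value is reproducible).
* Pairwise distances: p-distance, JC69, K2P
  (`d = −½ln(1−2P−Q) − ¼ln(1−2Q)`), and an `MCL` mode — a Tamura–Nei-form
  distance whose base frequencies are pooled across all sequences so every
  pair shares the same frequency parameters, the composite-likelihood
  convention.  Saturated pairs (a log of a non-positive argument) are
  flagged `nan` and excluded from the mean with a warning.  K2P is the
  working model everywhere; MCL exists for the mean-distance report.
* Tajima's D and Fu & Li's D* (no outgroup) use the standard
  frequency-spectrum constants; both are undefined (flagged, never silently
  zero) when there are no segregating sites or n < 4.
* Fu's Fs uses the Ewens sampling formula:
  `S′ = P(K ≥ k_obs | θ̂_π)` computed from unsigned Stirling numbers of the
  first kind (log-space recursion, stable to n in the hundreds) and
  `Fs = ln(S′/(1−S′))`.  θ̂_π is the observed mean pairwise difference; the
  allele count is the number of distinct haplotypes.  Its p-value is the
  fraction of seeded neutral constant-size coalescent simulations at θ̂_π
  (default 1000) with `Fs_sim ≤ Fs_obs`.  Statistics are computed on the
  full sequence multiset, not the collapsed haplotype set, because allele
  frequencies enter all three tests.

## Population structure

Two-level AMOVA partitions the squared pairwise distance (= pairwise
difference count, the squared-Euclidean convention for haplotypic data)
among and within populations; variance components come from the
method-of-moments equations and Φ_ST's significance from permuting
individuals among populations.  Permutation p-values count the observed
arrangement in both numerator and denominator, so p is never zero.

Isolation by distance correlates pairwise-population Φ_ST (each entry from
a two-population AMOVA) with great-circle distance (haversine, Earth radius
6371 km) through a Mantel test: Pearson r over the upper triangles,
two-sided by default, with joint row/column permutations; an exhaustive
mode enumerates all n! permutations for small matrices.  Because the
genetic matrix is a distance, *positive* r indicates isolation by distance;
surveys that correlate a similarity matrix instead will report the opposite
sign for the same data.

## Statistical parsimony networks

The 95% connection limit is the largest mutational step count j for which
parsimony (no superimposed or parallel change on the connecting path) still
holds with probability ≥ 0.95.  The probability model: per-site mutation
counts on the path are Poisson with Jukes–Cantor kinetics; the per-site
expected hit count λ is the usual multiple-hit inversion of the observed
difference fraction p = j/L, and

    P(parsimony) = P(1 hit | site differs)^j · P(0 hits | identical)^(L−j).

This is derived here from first principles under the same modelling
assumptions as the classical treatment (the limit grows with sequence
length and shrinks with divergence); its Monte-Carlo validation simulates
the generative model directly and conditions by rejection.  At survey-scale
lengths it gives limits of 5 steps (300 bp), 7 (600 bp) and 9 (~960 bp).

Networks are built level by level (1, 2, …, limit steps): every pair whose
subnetworks were still separate at the start of a level is connected, and
equal-length alternatives are all retained, producing closed loops where
homoplasy creates them rather than resolving ties arbitrarily.  Multi-step
edges pass through inferred intermediate haplotypes (zero frequency,
excluded from weighting).

Ancestral ("outgroup") weights follow the neutral-coalescent logic that
older haplotypes are more frequent and more central.  The exact
root-probability constants are left open in the classical reference, so the
implemented weight is frequency-proportional with a connectivity bonus:
`raw(h) = count(h) + ½·Σ count(observed neighbours)`, normalized within
each component.  It is strictly increasing in a haplotype's own count at
fixed topology, the centre of a star receives the maximum, and a singleton
component has weight 1.

## Coalescent scenario engine

Scenarios are declarative: populations (sampled or unsampled "ghost"
sources), founding events `(t, source, target, Nf, db)` and uniform priors
with ordering constraints.  Forward in time an event means the target was
founded from the source `t` generations ago through a bottleneck of
effective size `Nf` lasting `db` generations, then held its stable size
`N`.  Backward in time the simulator runs a structured coalescent with
piecewise-constant sizes and merges target lineages into the source at age
t.  Validation rejects founding cycles, doubly founded populations and
sampled populations without common ancestry.  The DSL is divergence-only
(no two-source admixture events) and non-recombining; times are generations
throughout, with no year conversion.

Gene-copy numbers scale with inheritance: N/2 (mitochondrial), 3N/2
(X-linked), 2N (autosomal).  Mutation is finite-sites K2P: Poisson events
at rate μ per variable site per generation, transition probability
κ/(κ+2), multiple hits allowed; `floor(0.10·L)` invariant sites are drawn
once per dataset and never mutate.  Demographic priors default to the
survey's: 1 < t1 < … < 100 generations, 5 < db < 25, 1000 < N < 10⁶,
1 < Nf < 10⁴, all uniform, enforced by rejection.  Mutation priors default
to log-uniform μ ∈ [10⁻⁹, 10⁻⁷] and uniform κ ∈ [0.05, 20], the documented
defaults of the standard sequence-ABC tooling; both are configurable.

Calibration (reproduced by the acceptance script): E[pairwise differences]
= θ = 2Gμ·L(1−p_inv) and E[S] = θ·a_{n−1} within 5% over 5000 replicates;
mean TMRCA for two copies matches an independent coalescent implementation
(msprime) at the same haploid size; mitochondrial:autosomal diversity ≈
1:4; mean Tajima's D over neutral replicates lies in [−0.3, 0.1] (the
slight negative bias is the well-known finite-sample property of the
statistic, not a simulator artefact).

## ABC: summaries, model choice, validation

The summary vector concatenates, in fixed order per locus: per population
the haplotype count, segregating sites and mean pairwise differences; per
population pair W (mean of the two within-population means) and B (mean
cross-population pairwise differences).  Populations sampled with < 2
sequences contribute zeros to within-population entries (recorded as
masked) so observed and simulated vectors stay aligned.

Model choice is the *direct estimate*: Euclidean distance on MAD-normalized
statistics (median absolute deviation over the pooled reference table;
zero MADs are replaced by 1 so constant statistics carry no weight), and
the posterior probability of a scenario is its share among the `n_closest`
rows (default 500).  The 95% CI is a Wilson binomial interval on that
share — it quantifies rejection-sampling noise only, which is narrower
than regression-based intervals; published CIs from regression machinery
are not comparable.  Distance ties at the cutoff are broken by row order
and logged.  Logistic-regression model choice is deliberately omitted.

Parameter estimation accepts the `n_closest` rows of one scenario and
applies the local linear regression adjustment; strictly positive
parameters (all sizes, times and rates here) are adjusted on the log scale
and transformed back — the standard treatment, which keeps draws positive
and measurably improves 95%-interval coverage (≈0.94 mean across
parameters at 10,000-row tables in the shipped calibration, versus ≈0.87
unadjusted-scale).  A singular regression design falls back to the plain
rejection posterior.

Confidence evaluation simulates pseudo-observed datasets (PODs) per
scenario from its priors: type I for scenario s is the fraction of
s-generated PODs where s does not attain the highest posterior
probability; type II the fraction of other-scenario PODs where s does.
Relative bias and RMSE compare posterior medians with generating values.
The PCA prior check projects MAD-normalized reference rows onto leading
principal components and flags the observation when it falls outside a
scenario's 99% centroid-distance envelope.

## Synthetic studies and what they do and do not show

The generator simulates at the level of scenario demes (the entry-point
trio LA/Japan/Nanjing, or the five Chinese regions) and attributes deme
rows to sampling populations at their designed per-population sample
sizes — valid because lineages within a deme are exchangeable.  It writes
FASTA + popmap + coordinates + a JSON truth file and is byte-reproducible
under a fixed seed.  Desk-scale locus lengths are 400 bp (control-region
surrogate) and 250 bp (intron surrogate) to keep the full pipeline fast;
survey-scale lengths are a flag away.  The synthetic data emulate the
statistical structure of a survey (sample sizes, inheritance modes, founder
events), not real haplotype sequences, sequencing error, alignment
ambiguity or within-region substructure — so green tests demonstrate the
machinery's correctness and calibration, not field-data conclusions.

A deliberate finding worth knowing before use: under the survey priors
(divergence within 1–100 generations, stable sizes up to 10⁶), competing
invasion topologies leave almost no trace in the summaries, and scenario
choice between the ghost-origin and USA-origin alternatives is near chance
level.  That is a property of the study design, mirrored by the original
survey's own large cluster-1 type I error, and it is why the machinery
validation uses a deliberately separable scenario pair (disjoint size
priors, fixed mutation rate) while the study-prior error rates are reported
as they come out.

## Numerical choices

* One seeded `numpy` generator threads through each stage; the pipeline
  derives independent per-stage seeds from a single top-level seed, and all
  tables are written with fixed column order and 6 significant digits for
  diffability.
* Undefined statistics are `nan` plus a flag, never silent zeros.
* Stirling numbers, Ewens probabilities and tail sums are computed in log
  space.
* The Mantel permutation count defaults to 10,000; AMOVA to 10,000;
  Fu's-Fs null simulations to 1000; all seeded.
* Validation problem sizes (10,000-row reference tables, 100–200 PODs,
  2000–5000 calibration replicates, desk-scale locus lengths) are the
  package's chosen validation scale; the survey's production setting of
  10⁶ simulations per scenario is reachable through the same API.

## Known limitations

* The connection-limit probability is this package's own derivation of the
  parsimony-probability model, not a line-by-line port of the classical
  recursion; limits may differ by a step at extreme divergences.
* Outgroup weights use the documented frequency-plus-connectivity scheme;
  they satisfy the qualitative root-probability properties but are not
  numerically identical to any specific legacy implementation.
* AMOVA is two-level only (among/within populations); no three-level
  region/population/individual partition.
* No recombination, no admixture events, no microsatellite or SNP loci.
* The direct-estimate CI is binomial, not regression-based (see above).
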