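# Methods

This note records the models implemented in `hybridscan`, their
assumptions, the tunable parameters and the numerical and design choices
made where the design was genuinely open. It states no empirical result
beyond what the test suite and `scripts/acceptance.py` themselves compute.

## Admixture model (`admixture_inference`)

The model is a two-cluster mixture for codominant diploid genotypes. Latent
variables: allele-origin indicators *z* (one per allele copy), cluster
allele frequencies *P* (per locus, Dirichlet(λ) prior over the alleles
observed in the dataset, independent across clusters — the
independent-frequencies variant), individual admixture vectors
*q<sub>i</sub>* ~ Dirichlet(α, α), and a single scalar α shared by all
individuals. Gibbs updates cycle z → P → q, with α updated by a random-walk
Metropolis step (normal proposal, sd 0.025) under a Uniform(0, 10) prior.
Missing genotypes contribute no likelihood term; an individual with no
genotyped locus is flagged and reported at Q = (0.5, 0.5).

Defaults: λ = 1, α initialised at 1.0, thinning 10. Two presets:
*desk* (burn-in 3,000, 30,000 sweeps, 2 replicates) and *paper-scale*
(burn-in 100,000, 1,000,000 sweeps, 5 replicates). The desk preset was
sized by checking that on the least favourable generator seed the recovery
statistics are unchanged when burn-in and sweeps are raised by more than
a factor of two; all fast analyses and the acceptance script use it.
Posterior summaries are means over the thinned post-burn-in chain.

Label switching: within a chain the two clusters are exchangeable.
Replicates are aligned by choosing, per replicate, the column permutation
closest to replicate 1; the species identity of the columns is then
anchored by the mean membership of reference individuals of known putative
species (normally allopatric sites), with an error if the anchor is
uninformative. Correctness of the sampler is pinned by an exact-integration
anchor: at one biallelic locus with two opposite homozygotes, the sampler's
posterior mean and the label-invariant co-assignment functional
E[q₁q₂ + (1−q₁)(1−q₂)] match a numerical integration of the exact
posterior to well under 0.02 (see `test_acceptance.py`).

## Genotype-class model (`class_inference`)

Six classes — parental F and O, F1, F2 and the two first-generation
backcrosses — are characterised by exact Mendelian per-locus ancestry
proportions (p<sub>FF</sub>, p<sub>FO</sub>, p<sub>OO</sub>), verified in
the tests against a brute-force Punnett enumeration of two-generation
crosses. Given an ancestry state the genotype likelihood is a
Hardy–Weinberg product of pool frequencies; the one-from-each state gives
p<sub>F</sub>(a)p<sub>O</sub>(b) + p<sub>F</sub>(b)p<sub>O</sub>(a) for
heterozygotes and p<sub>F</sub>(a)p<sub>O</sub>(a) for homozygotes. Priors:
class mixing proportions Dirichlet(1); pool allele frequencies
Dirichlet(1/A<sub>l</sub>) per locus ("Jeffreys-like", keeping rare or
unobserved alleles plausible in either pool). No prior population
information enters the likelihood. The Gibbs sampler alternates class
assignments (sampled from their conditional posterior, which is also the
quantity averaged — a Rao-Blackwellised summary), per-locus ancestry
states, allele-origin orientations within heterozygous mixed states, pool
frequencies and mixing proportions. The two latent pools are exchangeable;
replicates are aligned by the pool-swap permutation (F↔O, BCF↔BCO) and
anchored as above, and replicate agreement is monitored by the maximum
row-wise total-variation distance (warning above 0.1).

## Threshold calibration (`calibration`)

Hybrid genotypes are simulated from parental reference allele frequencies
in the HybridLab manner: parental genotypes are Hardy–Weinberg draws, an F1
carries one allele from each pool per locus, an F2 one gamete from each of
two independently simulated F1 parents, a backcross one F1 gamete plus one
parental allele; loci are independent. Frequencies are observed relative
counts without pseudo-counts (a 1/(2n) smoothing option exists but is off
by default). The reference pools default to allopatric reference
individuals.

*TQ*: simulated individuals of all six classes are run through the
admixture model jointly with the references; at each grid threshold
(0.50–0.99, step 0.01) an individual is called pure iff max(Q) ≥ t, and the
total misclassification (pure called hybrid + hybrid called pure, all
classes weighted equally) is minimised; ties resolve to the midpoint of the
minimising plateau, which is stable under re-runs.

*TPp*: the classifier is the genotype-class model; an individual is
*assigned* at threshold t iff its maximum class posterior reaches t, and
pure/hybrid by that class. An individual is correctly classified only when
it is assigned on the correct side, so the minimised total counts
wrong-side assignments **plus** unassigned individuals. Minimising
wrong-side errors alone is degenerate — raising the threshold converts
errors into unassignment and the optimum escapes to the top of the grid —
whereas the chosen objective matches the operational reading of "correct
classification" used when such thresholds are reported alongside the
fraction of individuals they leave unclassified. Wrong-side and unassigned
rates are reported separately in the curve, with per-class
correct-assignment rates at the optimum.

All boundary rules are inclusive: q ≥ TQ is pure, Pp ≥ TPp is assigned,
shape/genital posteriors ≥ cutoff are assigned.

Local-scale calibration groups each sympatric site on its own; an
allopatric site is paired with the nearest site (great-circle distance on
the bundled coordinates) carrying the species it lacks, with equidistant
ties resolved to the lexicographically smaller code (logged). Each grouping
re-estimates its own reference frequencies.

## Statistical parsimony and introgression (`mtdna`)

Haplotypes are collapsed by exact sequence identity; ambiguous sites (N)
and gaps act as wildcards only in pairwise distance computation (excluded
pairwise, preserving the global alignment frame). The parsimony-connection
probability of *j* observed differences over *m* sites is computed from an
explicit model: per-site mutation counts are independent Poisson(θ) with
two effective states, so a site differs iff its count is odd;
θ̂ = −½·log(1 − 2j/m) is the ML value given the observed difference
fraction, and the probability that the parsimonious interpretation is exact
is (θ/sinh θ)<sup>j</sup> · (cosh θ)<sup>−(m−j)</sup> — every differing
site mutated exactly once, every identical site never. The connection limit
is the largest *j* keeping this probability at or above the confidence
level, floored at 1; at 569 bp and 95% it is 7 steps. A brute-force
Poisson-series evaluation of the same probabilities serves as the test
oracle. This is a transparent analogue of the classic
statistical-parsimony criterion rather than a line-by-line port of the
original program, whose exact constants are not recoverable from public
descriptions; its qualitative behaviour (monotone in sequence length,
collapsing to single-step trust as confidence → 1) matches.

The network is a minimum-spanning forest over pairs within the limit,
built by Kruskal's algorithm with ties broken by (distance, lexicographic
haplotype ids); an edge of *d* steps implies *d* − 1 unobserved
intermediates. Components are clades; the two largest are labelled I and
II and any remainder is flagged unconnected. Clade-to-species polarity is
set by the majority clade within each genetically pure species, making all
percentages invariant to clade relabelling. The introgression summary
reports, per location and in total, the counts and percentages of each
genetic species carrying its atypical clade, the fraction of
sympatric vs allopatric sites containing atypical haplotypes (sites of
undetermined context excluded), and the clade composition of hybrids — by
location for admixture-detected hybrids and by genotype class for
class-assigned individuals (the two sets need not coincide).

## Shell and genital morphometrics (`morphometrics`)

GPA centres and scales configurations to unit centroid size
(CS = √Σ(centred coordinates)²) and rotates them onto an iteratively
refined consensus (SVD rotations, reflections excluded). Semilandmarks then
slide along the chord tangent defined by their outline neighbours; slide
amounts minimise the thin-plate-spline bending energy of the deviation from
the consensus (the energy matrix is the upper block of the inverted TPS
system built on the consensus), with a flag switching to the
Procrustes-distance criterion (plain tangent projection). Alignment and
sliding alternate until the consensus changes by less than 1e−8 (10
iterations maximum). Shape variables are Procrustes residuals projected
into the tangent space at the consensus — the projection removes the size
and rotation directions that superimposition cancels only to first order —
so their rank is at most 2p − 4 (52 for the 28-point scheme). New
individuals are projected into a training alignment's frame without moving
its consensus.

The permutational GLM uses sequential (Type-I) sums of squares of
(squared) Procrustes distances, with terms entered in the stated order; a
nested location factor is entered after its parent factor, interactions
after main effects. For each term the residuals of the reduced model are
permuted (RRPP); because the reduced-model fit is annihilated by the
between-model projector, the permuted SS reduces to a quadratic form in the
residual Gram matrix, which is what the implementation evaluates. p =
(1 + #{SS* ≥ SS})/(nperm + 1); the standardized effect size Z is computed
on the log-transformed SS distribution with the observed value included.
Significant-but-moderate Z values (≈1.5–6) with saturated p-values are the
expected behaviour of this statistic.

Discriminant analyses use scikit-learn's linear discriminant with priors
equal to training class frequencies. The shell DFA operates on
principal-component scores retaining 99% of the shape variance (the raw
residuals are rank-deficient and would make the pooled covariance
singular); if the retained dimensionality exceeds what the smallest class
supports it is reduced further with a warning. Training posteriors are
leave-one-out; the assignment cutoff is Pp ≥ 0.90 for shells and ≥ 0.99
for the 7-feature genital DFA, below which an individual is
"intermediate". The visual genital rule classifies by filament-to-total
length ratio: [0.10, 0.25] obtusata-typical, (0.25, 0.30) intermediate,
[0.30, 0.60] fabalis-typical, otherwise unknown. Of the seven genital
features, five (filament length, total length, gland-row length, number of
rows, number of glands) are the documented discriminating set; base and
tip width complete the panel as neutral fillers.

## Synthetic data (`synthetic_data`)

The generator's defaults are the study conditions: 11 microsatellite loci
with 8 alleles each, two parental pools at target multi-locus
F<sub>ST</sub> = 0.45, 569 bp haplotypes in two clades 20 mutational steps
apart with intra-clade star variants 1–3 steps from the clade centre,
introgression probabilities 0.185 (into *L. fabalis*) and 0.16 (into
*L. obtusata*), rare hybrids concentrated in sympatric sites
(F2 1.5%, BCF 1%, BCO 3.5% of a sympatric site's sample — backcrosses to
*L. obtusata* dominating, as observed), an 80% probability that a hybrid
carries the obtusata-typical clade, and 28-point shell outlines whose
species means sit at Procrustes distance 0.06 (rounder, wider-aperture vs
more elongated, narrower-aperture forms) with isotropic landmark noise
0.01, a fixed allometric deformation axis (slope 0.05 per unit log CS),
location offsets in both size (sd 0.1 log units) and shape (sd 0.005), and
species log-CS means 2.0 / 2.3 (the obtusata-like form larger). Genital
measurements are multivariate normal around species means whose
filament-to-total ratios (≈0.44 vs ≈0.18) fall inside the visual bands.
Six locations are generated by default: two sympatric and two allopatric
per species, 30 individuals per species per occupied site.

Allele-frequency divergence uses a Balding–Nichols Dirichlet
parameterization (pool frequencies drawn around a common ancestral vector
with concentration (1 − F)/F, for which the large-sample two-deme
Weir–Cockerham θ equals F in expectation). Because the raw model's
per-locus θ is heavily dispersed, draws are screened to keep the
parametric per-locus θ within 0.1 of the target (best of a bounded number
of attempts), which keeps the realized multi-locus Weir–Cockerham estimate
within a few points of the target without changing the model family.
Setting the target to 0 returns identical pools. mtDNA mutations are
transitions placed uniformly without replacement, with intra-clade variant
sites disjoint from the inter-clade sites so step distances are exact.

What the generator does **not** emulate — so what passing tests do not
show about field data: linkage disequilibrium and physical linkage, null
alleles, allele-size homoplasy and genotyping error; mutation models
beyond what distance-based clade assignment needs (no transversions,
recurrent sites, or coalescent genealogy); phenotypic plasticity,
measurement error in digitisation, and ecotype-specific shape structure
beyond the single allometric axis; and the sampling imbalance of real
surveys. Recovery rates measured on it are therefore upper bounds for
marker panels of equal information content, not guarantees for field data.

## Known limitations

* Under the default generator conditions the admixture model's pure
  individuals concentrate near Q = 1 but a small tail sits just below
  0.95; the acceptance script reports the measured recovery rate
  (`sim_pure_q95_recovery_pct`), typically a point or two either side of
  99%. With the true generator frequencies the exact posterior puts
  ~99.8% of pure individuals above 0.95, so the tail reflects
  allele-frequency estimation uncertainty at 11 loci, not sampler error.
* The TPp optimum depends visibly on how unassigned individuals are scored
  (see the calibration section); both components of the trade-off are
  reported so users can apply a different rule to the curve.
* k is fixed at 2 and the genotype classes stop at first-generation
  backcrosses; later-generation hybrids are absorbed by the nearest class.
* The statistical-parsimony limit is an analogue, not a port; networks at
  the boundary of the limit may differ from legacy software in which
  long-range edges survive.
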