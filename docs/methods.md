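# Methods

## Founder genomes

Founders are phased biallelic haplotypes on `n_chromosomes` linear
chromosomes (default 10) of 1.0 Morgan each, with locus positions uniform
on the map. The default generator draws, per locus, a derived-allele count
`i` from the neutral site-frequency spectrum, `P(i) ∝ 1/i` over the
`n_founders·φ` haploid copies, and places the copies exchangeably across
haplotypes. Every locus therefore segregates, genotype frequencies are at
Hardy–Weinberg proportions in expectation, and the panel is at linkage
equilibrium. Founder linkage disequilibrium affects the realized H0, so an
optional msprime coalescent backend (`backend="coalescent"`, population
size 100, 1 Mb per Morgan) generates LD-structured founders instead; the
default stays dependency-free and fast. QTL and SNP-chip markers (default
100/chromosome, never varied) are sampled uniformly without replacement
per chromosome, independently of each other, so panels may overlap as on a
real chip. Polyploid founders are built by stacking φ independent
haplotypes per individual; only the haplotype count emulates ploidy, not a
ploidy-scaled coalescent history.

## Trait architecture and scaling

Additive effects are i.i.d. standard normal; dominance degrees are
`N(meanDD, varDD)` and `d = DD·|a|` (hand-built architectures may set `d`
directly). After sampling, both effect vectors are multiplied by one
constant so that the variance of founder breeding values is exactly 1, and
μ centres the founder mean at 0. Breeding values use the gamete-share
weighted average effect

    BV_i = Σ_j (x_ij − φp_j) [2a_j + 4d_j(φ−1)(1−2p_j)/φ]/φ,

the derivative of the population mean in allele frequency, which reduces
to the classical `Σ a(x − 2p)` + `d(q−p)` form at φ = 2. σ_G0 is the
empirical SD of the 80 founders' genetic values (population convention,
ddof = 0); the phenotype error variance is frozen at σ_G0², giving
cycle-0 broad-sense heritability 0.5 and falling heritability later as
genetic variance is consumed — constant phenotyping effort, in other
words. Closed-form population summaries use binomial(φ, p) dosage moments:
`E[x(φ−x)] = φ(φ−1)p(1−p)`, hence
`P_HWE − P_I = Σ_j d_j·4(φ−1)p_j q_j/φ`. Architectures with negative
realized H0 (meanDD = 0, varDD > 0 draws) are kept; they are legitimate
populations with net-negative directional dominance.

## Meiosis and mating

All ploidies pair bivalently: the φ homologues shuffle into φ/2 random
pairs, each pair recombines with `Poisson(chromosome length in Morgans)`
crossovers placed uniformly (no interference, no obligate chiasma), and
one recombinant chromatid per bivalent enters the gamete. There is no
double reduction and no multivalent pairing. Doubled haploids (diploids
only) duplicate one gamete. Maximum avoidance of inbreeding keeps two full
sibs per family and mates each sib pair to the sib pair of the least
related family, measured by pedigree kinship (Wright's recursion,
truncated five generations back; ties broken toward the lowest family
index). Selfing is excluded everywhere; mother/father labels are
positional (hermaphroditic parents).

## Estimation methods

*True values* use the QTL effects directly: breeding value as above, cross
performance as the exact expected progeny mean from the per-locus
hypergeometric gamete-dosage moments (`E[g] = x/2`,
`Var[g] = x(φ−x)/(4(φ−1))`), and GCA as cross performance against the
opposite pool's gamete-dosage mixture. These closed forms treat loci as
independent, which is exact for the expectation over one round of meiosis.
*Phenotypic values* are the entry's single plot record; phenotypic GCA is
the mean of an entry's two testcross hybrids. *Genomic values* come from
two ridge-regression BLUP models fitted to a rolling training window
(default capacity 2000 most recent evaluations; inter-pool records for
two-pool programs, intra-pool for one-pool). RRBLUP_D regresses phenotypes
on a fixed intercept, the fixed marker-inbreeding covariate
`f = 1 − W·1/N` (coefficient b = inbreeding depression), and random
additive (Z) and dominance (W) marker effects. RRBLUP_GCA regresses hybrid
phenotypes on two independent additive effect vectors over maternal and
paternal dosages coded `(x − φ/4)(4/φ)`; pool A always plays the maternal
role, so pool-specific effects stay attached to the right pool.

Variance components are estimated by REML: the residual variance is
profiled out and the restricted deviance is minimised over log variance
ratios with Nelder–Mead (tolerance 1e-6) on the n×n observation
covariance, one Cholesky factorization per evaluation; marker effects are
the standard BLUP back-solutions. By default the ratios are frozen after
the first fit of a scenario and only effects are re-solved each cycle
(`freeze_varcomp=False` re-estimates every cycle). When the training set
has no variation in f (e.g. all doubled haploids), b is dropped with a
warning and the model reduces to additive-plus-dominance RRBLUP; with W=0
it reduces to plain additive RRBLUP.

## Strategies, costs, cycle lengths

Cycle machines follow a common skeleton — cross, evaluate, select two per
family, recycle through a maximum-avoidance plan — with strategy-specific
structure: testcrossing every candidate to two random opposite-pool
testers (one progeny each, so w = 4z hybrids per cycle across pools),
advancement of the top ceil(0.75·family) on breeding value before
testcrossing in the BV+GCA variants, DH conversion of all intra-pool
progeny in the DH variants, and exhaustive scoring of inter-family member
crosses within maximum-avoidance family pairs for one-pool cross
performance (the best two disjoint-parent crosses per pair recycle; the
disjointness rule is this package's choice where the procedure is
otherwise under-determined). In the first genomic cycle, before any
training data exist, BV/GCA scores fall back to uninformed (random)
ranking; from cycle one onward fits exist. Selection intensity fixes
recycled parents at 40 (one-pool) / 20 per pool (two-pool) at high
intensity and 200/100 at low.

Costs are plot-equivalents: each phenotyped entry 1, each genotyped entry
1, each DH line 3; crossing, multiplication, and non-evaluated grow-outs
are free. True-value scenarios are costed as their genomic twins (they
model perfect accuracy at identical size). `equalize_costs` shrinks
progeny per cross first, then crosses (parent count follows, preserving
two sibs per family). Cycle lengths in seasons: 2 for true/genomic
everywhere; phenotypic fast/slow: 3/4 (one-pool BV, two-pool BV), 4/7
(GCA and BV+GCA), 5/8 (DH variants); one-pool cross performance has no
phenotypic variant. Year horizons map to cycles by `round(years/L)`
(half-up), so 15 and 50 years at L = 2 are cycles 8 and 25.

## Responses and analysis

Responses are measured on the product pool — the intra-pool cohort for
one-pool strategies, the realized inter-pool hybrids for two-pool — and
standardized by σ_G0: genetic gain, mean additive and dominance value,
inbreeding depression `P_ID = (P_I − P_HWE)/σ_G0` (so cycle-0 P_ID = −H0),
panmictic heterosis (two-pool only; null for one-pool by definition), and
genomic inbreeding from `mean diag(G) = 1 + (φ−1)f` with G built VanRaden
method 1 against the scenario's initial marker frequencies. The
experiment driver enumerates the architecture factorial (paper grid
3 nQTL × 5 meanDD × 4 varDD × 3 ploidies = 180 cells, 10 replicates =
1800 populations), runs every valid scenario on every replicate, and
writes long-form response tables plus a seed manifest.

Responses at a timepoint are analysed by OLS with scenario, H0 and their
interaction (`Y ~ C(scenario)·H0`), replicate error random; no
significance tests are reported, only estimates, standard errors and
confidence intervals. Strategy crossovers
`H0* = (intercept_B − intercept_A)/(slope_A − slope_B)` get a paired
nonparametric bootstrap CI over replicate populations (rows of the same
population resample together); crossovers are flagged when outside the
surveyed H0 range or when the CI half-width exceeds it (inestimable).
Using a bootstrap rather than a likelihood-based standard error keeps the
interval assumption-free at the cost of some Monte-Carlo noise — the
native choice here, since replicate populations are cheap to resample.

## Scales used by the shipped tests

The regression-level test suite runs one reduced experiment: the four core
strategies under high-intensity genomic selection in diploids, nQTL =
100/chromosome, meanDD ∈ {0, 0.5, 1, 1.5, 3} at varDD = 0.2 (spanning
H0 ≈ 0–12), four replicate populations, 25 cycles, training window 500,
50 markers/chromosome, and cost equalization at 800 plot-equivalents per
cycle (20 progeny/cross one-pool vs 8 two-pool). These sizes are the
package's desk-scale rendering of a cluster-scale factorial; the
acceptance-style checks they support are sign-level (slope directions) and
band-level (crossover locations under scaled-down tolerances).

## What the generator does and does not emulate

Synthetic founders match the study conditions in structure (80 outbred
founders, 10 chromosomes, segregating biallelic loci with a neutral-like
spectrum, 100-marker/chromosome chip) but not in linkage disequilibrium
(default backend is LE) or mutation-calibrated site counts. Passing tests
therefore demonstrate the mechanics and the direction of strategy
contrasts, not calibrated absolute gains for any real crop. Absolute or
standardized responses are never compared across ploidies in built-in
reports, because the scaling makes such comparisons meaningless.

## Known limitations

* Crossover locations converge toward their full-scale values only as
  program size, training window and H0 range grow: the diploid 15-year
  crossover of RRS-on-GCA vs the best one-pool strategy rises from ≈5.4
  at a 400-plot budget to ≈7.5 at the 800-plot budget used in the tests.
  The long-horizon result that RRS on GCA dominates at essentially all
  positive H0 after 50 years is *not* reproduced at desk scale (the
  50-year crossover sits near H0 ≈ 5 here); one-pool gain saturation
  under inbreeding at full program sizes appears to be required, and
  `examples/crossover_fullscale.py` exists to run that experiment at
  scale. Autotetraploid and autohexaploid 50-year crossovers occur at H0
  values (≈32 and ≈57) that desk-scale QTL counts cannot even bracket.
* No epistasis, genotype×environment, multi-trait indices, multivalent
  pairing/double reduction, multiple parallel cohorts per season, or
  optimal-contribution selection.
* The intersection CI is bootstrap-based, not likelihood-based; with
  nearly-parallel regressions it is reported but flagged inestimable.
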