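# heterosim

Stochastic simulation of clonal diploid and autopolyploid breeding programs
that differ in how they harness heterosis due to dominance.

Breeders of clonal crops (cassava, potato, yam, sweetpotato, bananas, many
forages) face a strategic choice: run a single recurrent-selection pool, or
split the germplasm into two heterotic pools and practice reciprocal
recurrent selection (RRS) on general combining ability, paying extra cost
and cycle length for access to panmictic heterosis. `heterosim` provides
the machinery to ask when each choice wins: founder-genome simulation,
trait architectures with directional digenic dominance, meiosis and
doubled-haploid production at ploidy 2x/4x/6x, seven breeding strategies
under true, phenotypic, or genomic (RRBLUP) estimation, and a
regression-based analysis of responses against initial population
heterosis, including strategy-crossover estimation.

## Model

A trait is controlled by QTL with additive effects `a_j` and dominance
effects `d_j = DD_j |a_j|`, `DD_j ~ N(meanDD, varDD)`. For an individual
with allele dosages `x` at ploidy φ,

    GV(x) = μ + Σ_j a_j·xA_j + Σ_j d_j·xD_j
    xA = (x − φ/2)(2/φ)          xD = x(φ − x)(2/φ)²

so polyploid dominance is digenic (pairwise within-locus). Effects are
scaled so founders have mean genetic value 0 and additive variance 1, and
the phenotype error variance is fixed at the founders' genetic variance
(initial broad-sense heritability H² = 0.5, eroding afterwards).

Key population quantities, standardized by the founder genetic SD σ_G0:

* initial heterosis `H0 = (P_HWE − P_I)/σ_G0` — the value separating the
  Hardy–Weinberg population from its fully homozygosified counterpart;
* inbreeding depression `P_ID = (P_I − P_HWE)/σ_G0`;
* panmictic heterosis `PH = (P_F1 − ½(P_A_HWE + P_B_HWE))/σ_G0` for
  two-pool programs;
* genomic inbreeding `f` from `mean diag(G) = 1 + (φ−1) f` (VanRaden
  method 1 against the initial population's marker frequencies).

Genomic selection uses ridge-regression BLUP with REML variance components:
RRBLUP_D (`y = Xβ + f b + Z a + W d* + e`, with `f = 1 − W·1/N` the marker
inbreeding covariate absorbing directional dominance) for breeding values
and cross performance, and RRBLUP_GCA (pool-specific additive effects on
parental dosages coded `(x − φ/4)(4/φ)`) for GCA, each trained on a rolling
window of the most recent evaluations.

The seven strategies — one-pool selection on breeding value or on expected
cross performance, two-pool terminal crossing on breeding value, RRS on
GCA, RRS with within-pool advancement (BV+GCA), and the two doubled-haploid
RRS variants — are cycle-state machines sharing maximum-avoidance-of-
inbreeding mating, two-sibs-per-family recycling, plot-equivalent cost
accounting (phenotyping = genotyping = 1 plot, a DH line = 3) and
strategy-specific cycle lengths in seasons.

## Worked example

`python examples/founders_and_heterosis.py` builds 80 outbred diploid
founders on a 10-chromosome map and a trait with meanDD = 1, varDD = 0.2,
1000 QTL:

```
founders: 80 individuals, 1500 segregating loci
mean GV after scaling:        +5.33e-16   (should be ~0)
genetic SD sigma_G0:          1.200
HWE mean P_HWE:               +0.079
fully-inbred mean P_I:        -9.036
initial heterosis H0:         7.60
```

The population would lose 7.6 genetic SDs of value if driven to full
homozygosity — that store of dominance value is what two-pool strategies
compete for. `python examples/single_scenario_run.py` then runs RRS on GCA
with genomic selection for 8 rapid cycles (H0 = 9.61 in that draw):

```
cycle   dG     additive  dominance   P_ID     PH    genomic_f
   1   -0.24      0.48      9.59    -9.19    0.07    -0.012
   ...
   8    1.58      1.21     10.68    -9.71    1.56     0.036
```

Genetic gain (`dG`, in σ_G0 units) comes from both rising additive value
and rising dominance value; panmictic heterosis `PH` builds steadily as
the pools' allele frequencies diverge. `examples/strategy_comparison.py`
runs a small cost-equalized factorial and prints the crossover H0* above
which RRS on GCA beats each one-pool strategy;
`examples/crossover_fullscale.py` is the long-running version with
polyploids and full-size programs.

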