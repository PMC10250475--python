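"""The seven breeding strategies as cycle-state machines.

Strategies (one cycle = cross, evaluate, select, recycle):

* OnePoolBV      — recurrent selection on breeding value in one pool.
* OnePoolCP      — recurrent selection on expected cross performance:
                   maximum-avoidance family pairs are identified, all
                   inter-family member crosses scored, and the best two
                   disjoint-parent crosses per pair are recycled.
* TwoPoolBV      — terminal crossing: within-pool selection on breeding
                   value, inter-pool hybrids made via two random testers
                   per pool for evaluation of the product.
* TwoPoolGCA     — reciprocal recurrent selection: as TwoPoolBV but parents
                   are recycled on GCA estimated from the testcross hybrids.
* TwoPoolBVGCA   — intra-pool evaluation first, top ~75% per family
                   advanced on breeding value, then testcrossing and
                   selection on GCA.
* TwoPoolDH_GCA / TwoPoolDH_BVGCA — diploid-only variants in which every
                   intra-pool progeny is converted to a doubled haploid
                   line before testcrossing (and, for BVGCA, before
                   intra-pool evaluation and advancement).

Selection intensity fixes the recycled parent count (high: 40 one-pool /
20 per pool two-pool; low: 200 / 100); two full sibs per family are always
kept so the maximum-avoidance plan stays feasible. Costs are expressed in
evaluation-plot equivalents (phenotyping = genotyping = 1 plot, a doubled
haploid line = 3 plots; crossing and multiplication are free) and cycle
lengths in seasons depend on strategy x estimation method x multiplication
speed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np

from . import estimation as est
from .genomes import GenomeMap, Population
from .reproduction import (
    CrossPlan,
    PedigreeBook,
    make_crosses,
    make_dh_population,
    max_avoidance_plan,
    random_plan,
    testcross_plan,
)
from .traits import TraitArchitecture, genetic_value

__all__ = [
    "STRATEGIES",
    "CYCLE_LENGTHS",
    "ScenarioConfig",
    "CycleState",
    "ScenarioRunner",
    "select_two_per_family",
    "advance_within_family",
    "cycle_cost",
    "equalize_costs",
    "years_to_cycles",
]

STRATEGIES = (
    "OnePoolBV",
    "OnePoolCP",
    "TwoPoolBV",
    "TwoPoolGCA",
    "TwoPoolBVGCA",
    "TwoPoolDH_GCA",
    "TwoPoolDH_BVGCA",
)
ONE_POOL = {"OnePoolBV", "OnePoolCP"}
DH_STRATEGIES = {"TwoPoolDH_GCA", "TwoPoolDH_BVGCA"}
BVGCA_STRATEGIES = {"TwoPoolBVGCA", "TwoPoolDH_BVGCA"}

# seasons per cycle, keyed (strategy, estimation[, multiplication])
_PHENO_L = {
    "OnePoolBV": (3, 4),
    "TwoPoolBV": (3, 4),
    "TwoPoolGCA": (4, 7),
    "TwoPoolBVGCA": (4, 7),
    "TwoPoolDH_GCA": (5, 8),
    "TwoPoolDH_BVGCA": (5, 8),
}
CYCLE_LENGTHS = {}
for _s in STRATEGIES:
    CYCLE_LENGTHS[(_s, "true")] = 2
    CYCLE_LENGTHS[(_s, "genomic")] = 2
for _s, (_fast, _slow) in _PHENO_L.items():
    CYCLE_LENGTHS[(_s, "phenotypic", "fast")] = _fast
    CYCLE_LENGTHS[(_s, "phenotypic", "slow")] = _slow

_HIGH_INTENSITY_PARENTS = {"one": 40, "two": 20}
_LOW_INTENSITY_PARENTS = {"one": 200, "two": 100}


@dataclass
class ScenarioConfig:
    """One scenario: strategy x estimation x intensity x sizes x cycle length."""

    strategy: str
    estimation: str = "true"  # {"true", "genomic", "phenotypic"}
    intensity: str = "high"  # {"high", "low"}
    ploidy: int = 2
    progeny_per_cross: int = 10  # y
    n_parents_per_pool: int | None = None  # r; derived from intensity if None
    advance_fraction: float = 0.75
    multiplication: str = "fast"  # {"fast", "slow"}; phenotypic cycle length only
    training_capacity: int = 2000
    freeze_varcomp: bool = True  # re-use variance components after the first REML fit
    kinship_depth: int = 5

    def __post_init__(self):
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.estimation not in ("true", "genomic", "phenotypic"):
            raise ValueError(f"unknown estimation method {self.estimation!r}")
        if self.strategy in DH_STRATEGIES and self.ploidy != 2:
            raise ValueError("Strategies with doubled haploids were only run for ploidy = 2")
        if self.strategy == "OnePoolCP" and self.estimation == "phenotypic":
            raise ValueError(
                "a phenotypic estimate of One-Pool Cross Performance is not supported"
            )
        if self.n_parents_per_pool is None:
            tier = _HIGH_INTENSITY_PARENTS if self.intensity == "high" else _LOW_INTENSITY_PARENTS
            self.n_parents_per_pool = tier["one" if self.strategy in ONE_POOL else "two"]
        if self.n_parents_per_pool % 2:
            raise ValueError("parent count must be even (two sibs per family)")

    @property
    def n_pools(self) -> int:
        return 1 if self.strategy in ONE_POOL else 2

    @property
    def n_crosses(self) -> int:
        """x: each recycled parent enters exactly one cross."""
        return self.n_parents_per_pool // 2

    @property
    def progeny_per_pool(self) -> int:
        """z = x * y evaluated intra-pool candidates per pool."""
        return self.n_crosses * self.progeny_per_cross

    @property
    def cycle_length(self) -> int:
        if self.estimation == "phenotypic":
            return CYCLE_LENGTHS[(self.strategy, "phenotypic", self.multiplication)]
        return CYCLE_LENGTHS[(self.strategy, self.estimation)]


def years_to_cycles(years: float, cycle_length: int) -> int:
    """Cycles elapsed after `years` seasons-worth of breeding (half-up)."""
    if cycle_length < 1:
        raise ValueError("cycle length must be >= 1 season")
    return int(math.floor(years / cycle_length + 0.5))


def select_two_per_family(candidates: Population, scores: np.ndarray) -> Population:
    """Keep the top two per full-sib family (ties broken by lowest id)."""
    keep = []
    for fam in np.unique(candidates.family):
        rows = np.where(candidates.family == fam)[0]
        if len(rows) < 2:
            raise ValueError(f"family {fam} has fewer than 2 members")
        order = rows[np.lexsort((candidates.ids[rows], -scores[rows]))]
        keep.extend(order[:2])
    return candidates.subset(np.sort(np.array(keep)))


def advance_within_family(
    candidates: Population, scores: np.ndarray, fraction: float = 0.75
) -> Population:
    """Advance the top ceil(fraction * family size) members of each family."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    keep = []
    for fam in np.unique(candidates.family):
        rows = np.where(candidates.family == fam)[0]
        k = math.ceil(fraction * len(rows))
        order = rows[np.lexsort((candidates.ids[rows], -scores[rows]))]
        keep.extend(order[:k])
    return candidates.subset(np.sort(np.array(keep)))


# ---------------------------------------------------------------------------
# cost model


def cycle_cost(config: ScenarioConfig) -> int:
    """Plot-equivalents consumed per cycle.

    Phenotyping and genotyping each cost one plot-equivalent; a doubled
    haploid line costs three. True-value scenarios are costed as their
    genomic twins (they exist to model perfect accuracy at identical size).
    Crossing, multiplication and non-evaluated grow-outs are free.
    """
    z = config.progeny_per_pool
    pools = config.n_pools
    n_cand = z * pools
    if config.strategy in BVGCA_STRATEGIES:
        n_test = pools * 2 * math.ceil(config.advance_fraction * z)
    elif config.strategy in ONE_POOL:
        n_test = 0
    else:
        n_test = pools * 2 * z  # w hybrids: every candidate x two testers
    dh = n_cand if config.strategy in DH_STRATEGIES else 0
    estim = "genomic" if config.estimation == "true" else config.estimation
    if estim == "phenotypic":
        # hybrids are always phenotyped; intra-pool candidates only where the
        # strategy evaluates them (BV selection or BV-based advancement)
        intra_eval = config.strategy in ONE_POOL or config.strategy in BVGCA_STRATEGIES or (
            config.strategy == "TwoPoolBV"
        )
        phenotyped = (n_cand if intra_eval else 0) + n_test
        genotyped = 0
    else:  # genomic
        if pools == 1:
            phenotyped = n_cand  # training records
            genotyped = n_cand
        else:
            # candidates genotyped for prediction; hybrids genotyped + phenotyped
            phenotyped = n_test + (n_cand if config.strategy in BVGCA_STRATEGIES else 0)
            genotyped = n_cand + n_test
    return phenotyped + genotyped + 3 * dh


def equalize_costs(
    configs: list[ScenarioConfig], budget: int
) -> list[ScenarioConfig]:
    """Shrink programs to a common per-cycle budget.

    Progeny per cross is reduced first, then the number of crosses (which
    reduces the recycled parent count in lockstep, keeping two selected
    sibs per family); the minimum viable program is 2 crosses of 1 progeny.
    """
    out = []
    for cfg in configs:
        c = dc_replace(cfg)
        while cycle_cost(c) > budget and c.progeny_per_cross > 1:
            c = dc_replace(c, progeny_per_cross=c.progeny_per_cross - 1)
        while cycle_cost(c) > budget and c.n_parents_per_pool > 4:
            c = dc_replace(c, n_parents_per_pool=c.n_parents_per_pool - 2)
        if cycle_cost(c) > budget:
            raise ValueError(
                f"budget {budget} below minimal viable program for {cfg.strategy}"
            )
        out.append(c)
    return out


# ---------------------------------------------------------------------------
# the cycle-state machine


def _concat_pops(pops: list[Population], pool: str, cycle: int) -> Population:
    return Population(
        haplotypes=np.concatenate([p.haplotypes for p in pops], axis=0),
        ids=np.concatenate([p.ids for p in pops]),
        pedigree=np.concatenate([p.pedigree for p in pops], axis=0),
        pool=pool,
        cycle=cycle,
        family=np.concatenate([p.family for p in pops]),
    )


@dataclass
class CycleState:
    """Mutable per-scenario state carried between cycles."""

    parents: dict[str, Population]  # pool label -> recycled parents
    book: PedigreeBook
    window: est.TrainingWindow
    cycle: int = 0
    cost: float = 0.0
    cp_plans: dict[str, CrossPlan] | None = None  # OnePoolCP recycles crosses
    fit_bv: est.MarkerModelFit | None = None
    fit_gca: est.MarkerModelFit | None = None
    varcomp_cache: dict = field(default_factory=dict)


@dataclass
class CycleResult:
    """What one cycle produced, for response measurement."""

    cycle: int
    product: Population  # intra-pool candidates (one-pool) or hybrids (two-pool)
    intra: dict[str, Population] | None = None  # per-pool candidates (two-pool)
    product_phenotypes: np.ndarray | None = None


class ScenarioRunner:
    """Runs one scenario against one founder population and architecture."""

    def __init__(
        self,
        config: ScenarioConfig,
        genome_map: GenomeMap,
        arch: TraitArchitecture,
        initial: tuple[Population, ...],
        rng_seed: int | np.random.Generator = 0,
    ):
        if arch.ploidy != config.ploidy:
            raise ValueError("architecture ploidy does not match scenario ploidy")
        self.config = config
        self.map = genome_map
        self.arch = arch
        self.rng = np.random.default_rng(rng_seed)
        book = PedigreeBook()
        parents: dict[str, Population] = {}
        for pop in initial:
            book.register_founders(pop)
            parents[pop.pool] = pop
        if config.n_pools == 2 and set(parents) != {"A", "B"}:
            raise ValueError("two-pool scenarios need initial pools A and B")
        if config.n_pools == 1 and len(initial) != 1:
            raise ValueError("one-pool scenarios take a single initial population")
        self.state = CycleState(
            parents=parents,
            book=book,
            window=est.TrainingWindow(config.training_capacity),
        )
        # baseline marker frequencies for genomic inbreeding, per the
        # scenario's own initial population
        base = _concat_pops(list(parents.values()), "single", 0)
        self.base_marker_freq = base.allele_freq(genome_map.marker_index)
        gv0, _, _ = genetic_value(arch, base.dosages(arch.qtl_index))
        self.g0 = float(gv0.mean())

    # -- helpers -----------------------------------------------------------

    def _plan(self, parents: Population, y: int) -> CrossPlan:
        cfg = self.config
        if self.state.cycle == 0 or np.all(parents.family < 0):
            # founder generation: random non-self pairing into x crosses
            plan = random_plan(parents, y, self.rng)
            needed = cfg.n_crosses - len(plan)
            if needed > 0:  # fewer initial parents than recycled parents
                extra = []
                ids = parents.ids.copy()
                while len(extra) < needed:
                    perm = self.rng.permutation(ids)
                    for k in range(0, len(perm) - 1, 2):
                        if len(extra) < needed:
                            extra.append((int(perm[k]), int(perm[k + 1]), y))
                plan = CrossPlan(plan.crosses + extra, kind="random")
            return plan
        return max_avoidance_plan(parents, self.state.book, y, cfg.kinship_depth)

    def _true_bv(self, pop: Population) -> np.ndarray:
        dos = pop.dosages(self.arch.qtl_index)
        p = dos.mean(axis=0) / self.arch.ploidy
        return est.breeding_value(self.arch.a, self.arch.d, dos, p, self.arch.ploidy)

    def _bv_scores(self, pop: Population, phenos: np.ndarray | None) -> np.ndarray:
        cfg, st = self.config, self.state
        if cfg.estimation == "true":
            return self._true_bv(pop)
        if cfg.estimation == "phenotypic":
            if phenos is None:
                raise RuntimeError("phenotypic scoring without phenotypes")
            return phenos
        if st.fit_bv is None:  # no training data yet: uninformed ranking
            return self.rng.standard_normal(len(pop))
        return est.predict_rrblup_d(st.fit_bv, pop.dosages(self.map.marker_index))

    def _fit_models(self, need_gca: bool) -> None:
        """(Re)fit genomic models on the current training window."""
        cfg, st = self.config, self.state
        if cfg.estimation != "genomic" or len(st.window) < 10:
            return
        theta = st.varcomp_cache.get("bv") if cfg.freeze_varcomp else None
        st.fit_bv = est.fit_rrblup_d(st.window, cfg.ploidy, fixed_theta=theta)
        vc = st.fit_bv.varcomp
        st.varcomp_cache.setdefault(
            "bv", np.array([vc["s2_a"] / vc["s2_e"], vc["s2_d"] / vc["s2_e"]])
        )
        if need_gca:
            theta_g = st.varcomp_cache.get("gca") if cfg.freeze_varcomp else None
            st.fit_gca = est.fit_rrblup_gca(st.window, cfg.ploidy, fixed_theta=theta_g)
            vg = st.fit_gca.varcomp
            st.varcomp_cache.setdefault(
                "gca", np.array([vg["s2_m"] / vg["s2_e"], vg["s2_p"] / vg["s2_e"]])
            )

    # -- cycle drivers -----------------------------------------------------

    def run_cycle(self) -> CycleResult:
        cfg = self.config
        if cfg.strategy == "OnePoolBV":
            result = self._cycle_one_pool_bv()
        elif cfg.strategy == "OnePoolCP":
            result = self._cycle_one_pool_cp()
        else:
            result = self._cycle_two_pool()
        self.state.cost += cycle_cost(cfg)
        self.state.cycle += 1
        return result

    def run(self, n_cycles: int) -> list[CycleResult]:
        return [self.run_cycle() for _ in range(n_cycles)]

    def _evaluate(self, pop: Population) -> np.ndarray:
        """Phenotype a cohort (always done: GS training needs records too)."""
        return est.phenotype(pop, self.arch, self.rng)

    def _cycle_one_pool_bv(self) -> CycleResult:
        cfg, st = self.config, self.state
        parents = st.parents["single"]
        plan = self._plan(parents, cfg.progeny_per_cross)
        progeny = make_crosses(parents, plan, self.map, st.book, self.rng, cycle=st.cycle + 1)
        phenos = self._evaluate(progeny)
        if cfg.estimation == "genomic":
            st.window.add_population(progeny, phenos, self.map.marker_index)
            self._fit_models(need_gca=False)
        scores = self._bv_scores(progeny, phenos)
        st.parents["single"] = select_two_per_family(progeny, scores)
        return CycleResult(cycle=st.cycle + 1, product=progeny, product_phenotypes=phenos)

    def _cycle_one_pool_cp(self) -> CycleResult:
        cfg, st = self.config, self.state
        parents = st.parents["single"]
        if st.cp_plans and "single" in st.cp_plans:
            plan = st.cp_plans["single"]
        else:
            plan = self._plan(parents, cfg.progeny_per_cross)
        progeny = make_crosses(parents, plan, self.map, st.book, self.rng, cycle=st.cycle + 1)
        phenos = self._evaluate(progeny)
        if cfg.estimation == "genomic":
            st.window.add_population(progeny, phenos, self.map.marker_index)
            self._fit_models(need_gca=False)
        st.cp_plans = {"single": self._select_crosses(progeny)}
        # the individuals named in the selected crosses are next cycle's parents
        chosen = sorted({i for m, f, _ in st.cp_plans["single"].crosses for i in (m, f)})
        rows = np.where(np.isin(progeny.ids, chosen))[0]
        st.parents["single"] = progeny.subset(rows)
        return CycleResult(cycle=st.cycle + 1, product=progeny, product_phenotypes=phenos)

    def _select_crosses(self, progeny: Population) -> CrossPlan:
        """Best two disjoint-parent crosses within each max-avoidance family pair."""
        cfg, st = self.config, self.state
        fams = np.unique(progeny.family)
        # pair families by least kinship (families are full-sib, so any member
        # represents the family), walking in index order
        reps = {int(f): int(progeny.ids[np.argmax(progeny.family == f)]) for f in fams}
        unpaired = [int(f) for f in fams]
        pairs = []
        while unpaired:
            f1 = unpaired.pop(0)
            best, best_kin = None, np.inf
            for f2 in unpaired:
                kin = st.book.kinship(reps[f1], reps[f2], depth=cfg.kinship_depth)
                if kin < best_kin - 1e-12:
                    best, best_kin = f2, kin
            unpaired.remove(best)
            pairs.append((f1, best))
        use_genomic = cfg.estimation == "genomic" and st.fit_bv is not None
        loci = self.map.marker_index if use_genomic else self.arch.qtl_index
        dos = progeny.dosages(loci).astype(float)
        crosses = []
        for f1, f2 in pairs:
            r1 = np.where(progeny.family == f1)[0]
            r2 = np.where(progeny.family == f2)[0]
            scored = []
            for i in r1:
                for j in r2:
                    if use_genomic:
                        s = est.cross_performance_genomic(st.fit_bv, dos[i], dos[j])
                    else:
                        s = est.cross_performance(self.arch, dos[i], dos[j])
                    scored.append((s, int(progeny.ids[i]), int(progeny.ids[j])))
            scored.sort(key=lambda t: (-t[0], t[1], t[2]))
            top = scored[0]
            crosses.append((top[1], top[2], cfg.progeny_per_cross))
            used = {top[1], top[2]}
            for s, m, f in scored[1:]:
                if m not in used and f not in used:
                    crosses.append((m, f, cfg.progeny_per_cross))
                    break
        return CrossPlan(crosses, kind="max_avoidance")

    def _cycle_two_pool(self) -> CycleResult:
        cfg, st = self.config, self.state
        new_cycle = st.cycle + 1
        candidates: dict[str, Population] = {}
        cand_phenos: dict[str, np.ndarray | None] = {}
        for pool in ("A", "B"):
            plan = self._plan(st.parents[pool], cfg.progeny_per_cross)
            prog = make_crosses(
                st.parents[pool], plan, self.map, st.book, self.rng, pool=pool, cycle=new_cycle
            )
            if cfg.strategy in DH_STRATEGIES:
                prog = make_dh_population(prog, self.map, st.book, self.rng)
            candidates[pool] = prog
            cand_phenos[pool] = None
        if cfg.strategy in BVGCA_STRATEGIES:
            # intra-pool evaluation, then advance the top ~75% per family
            for pool in ("A", "B"):
                phen = (
                    self._evaluate(candidates[pool])
                    if cfg.estimation == "phenotypic"
                    else None
                )
                scores = self._bv_scores(candidates[pool], phen)
                candidates[pool] = advance_within_family(
                    candidates[pool], scores, cfg.advance_fraction
                )
        # two random testers per pool; every candidate meets the two
        # opposite-pool testers, one progeny per testcross
        testers = {
            pool: candidates[pool].subset(
                np.sort(self.rng.choice(len(candidates[pool]), size=2, replace=False))
            )
            for pool in ("A", "B")
        }
        hybrid_parts = []
        for pool, opp in (("A", "B"), ("B", "A")):
            tc = testcross_plan(candidates[pool], testers[opp])
            if pool == "A":
                crosses = tc.crosses  # mother from pool A
            else:
                crosses = [(t, c, n) for c, t, n in tc.crosses]  # keep A maternal
            merged = _concat_pops([candidates[pool], testers[opp]], pool, new_cycle)
            hyb = make_crosses(
                merged, CrossPlan(crosses, kind="testcross"), self.map, st.book, self.rng,
                pool="hybrid", cycle=new_cycle,
            )
            hybrid_parts.append(hyb)
        hybrids = _concat_pops(hybrid_parts, "hybrid", new_cycle)
        hyb_phenos = self._evaluate(hybrids)
        if cfg.estimation == "genomic":
            lookup = {}
            for pool in ("A", "B"):
                dos = candidates[pool].dosages(self.map.marker_index)
                for r, i in enumerate(candidates[pool].ids):
                    lookup[int(i)] = dos[r]
            st.window.add_population(hybrids, hyb_phenos, self.map.marker_index, lookup)
            self._fit_models(need_gca=cfg.strategy not in ("TwoPoolBV",))
        # selection within each pool
        for pool, opp in (("A", "B"), ("B", "A")):
            cand = candidates[pool]
            if cfg.strategy == "TwoPoolBV":
                phen = (
                    self._evaluate(cand) if cfg.estimation == "phenotypic" else None
                )
                scores = self._bv_scores(cand, phen)
            else:  # GCA selection
                scores = self._gca_scores(cand, candidates[opp], hybrids, hyb_phenos, pool)
            st.parents[pool] = select_two_per_family(cand, scores)
        return CycleResult(
            cycle=new_cycle,
            product=hybrids,
            intra=candidates,
            product_phenotypes=hyb_phenos,
        )

    def _gca_scores(
        self,
        cand: Population,
        opposite: Population,
        hybrids: Population,
        hyb_phenos: np.ndarray,
        pool: str,
    ) -> np.ndarray:
        cfg, st = self.config, self.state
        if cfg.estimation == "true":
            dos = cand.dosages(self.arch.qtl_index).astype(float)
            return np.array(
                [est.gca_true(self.arch, dos[i], opposite) for i in range(len(cand))]
            )
        if cfg.estimation == "phenotypic":
            # mean phenotype of the candidate's own testcross hybrids
            col = 0 if pool == "A" else 1  # A is always the maternal side
            parent = hybrids.pedigree[:, col]
            return np.array(
                [float(hyb_phenos[parent == i].mean()) for i in cand.ids]
            )
        if st.fit_gca is None:
            return self.rng.standard_normal(len(cand))
        role = "M" if pool == "A" else "P"
        return est.predict_gca_score(
            st.fit_gca, cand.dosages(self.map.marker_index), role
        )
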