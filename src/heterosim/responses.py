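"""Response metrics per cycle and the regression-on-H0 analysis.

All responses are standardized by the initial genetic SD sigma_G0 of the
founder population so that architectures on different trait scales are
comparable:

* genetic gain      dG   = (G_t - G_0) / sigma_G0, measured on the product
                    pool (intra-pool genotypes for one-pool strategies,
                    inter-pool hybrids for two-pool strategies);
* mean additive / dominance value, likewise standardized;
* inbreeding depression  P_ID = (P_I - P_HWE) / sigma_G0 — with positive
                    directional dominance this is negative, and at cycle 0
                    it equals -H0;
* panmictic heterosis  PH = (P_F1 - (P_A_HWE + P_B_HWE)/2) / sigma_G0,
                    defined only for two-pool strategies;
* genomic inbreeding f from the VanRaden method-1 relationship matrix at
                    the scenario's initial marker frequencies, via
                    mean diag(G) = 1 + (phi - 1) f.

The experiment-level analysis regresses each response at a timepoint on
scenario, H0 and their interaction (Y = mu + S + H + SH + e, replicate
error random) and locates pairwise crossover points
H0* = (intercept_B - intercept_A) / (slope_A - slope_B) with nonparametric
bootstrap confidence intervals over simulation replicates.
"""

from __future__ import annotations

import itertools
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .genomes import GenomeMap, Population, draw_and_split, make_genome_map, sample_qtl_and_markers, simulate_founder_haplotypes
from .strategies import CycleResult, ScenarioConfig, ScenarioRunner, years_to_cycles
from .traits import (
    TraitArchitecture,
    genetic_value,
    initial_heterosis,
    population_means_hwe_inbred,
    sample_architecture,
    scale_architecture,
)

__all__ = [
    "ResponseRecord",
    "RegressionResult",
    "delta_g",
    "inbreeding_depression",
    "panmictic_heterosis",
    "genomic_inbreeding",
    "measure_responses",
    "fit_response_regression",
    "regression_intersection",
    "run_experiment",
]


@dataclass
class ResponseRecord:
    scenario: str
    cycle: int
    delta_g: float
    additive: float
    dominance: float
    p_id: float
    ph: float | None  # None for one-pool scenarios, by definition
    genomic_f: float
    genetic_variance: float


def delta_g(product_mean_gv: float, g0: float, sigma_g0: float) -> float:
    """Standardized genetic gain (G_t - G_0) / sigma_G0."""
    if sigma_g0 == 0:
        raise ValueError("sigma_G0 is zero")
    return (product_mean_gv - g0) / sigma_g0


def inbreeding_depression(
    arch: TraitArchitecture, freqs: np.ndarray, sigma_g0: float
) -> float:
    """P_ID = (P_I - P_HWE) / sigma_G0 at the product pool's frequencies."""
    p_hwe, p_i = population_means_hwe_inbred(arch, freqs)
    return (p_i - p_hwe) / sigma_g0


def panmictic_heterosis(
    hybrid_mean_gv: float,
    freqs_a: np.ndarray,
    freqs_b: np.ndarray,
    arch: TraitArchitecture,
    sigma_g0: float,
) -> float:
    """PH = (P_F1 - (P_A_HWE + P_B_HWE)/2) / sigma_G0."""
    pa, _ = population_means_hwe_inbred(arch, freqs_a)
    pb, _ = population_means_hwe_inbred(arch, freqs_b)
    return (hybrid_mean_gv - 0.5 * (pa + pb)) / sigma_g0


def genomic_inbreeding(
    pop: Population, base_freqs: np.ndarray, marker_index: np.ndarray
) -> float:
    """Genomic f from mean diag(G) = 1 + (phi - 1) f, VanRaden method 1.

    G = M M' / sum_j phi p0_j (1 - p0_j) with M the marker dosages centred
    at phi p0; base frequencies come from the scenario's initial population.
    """
    p0 = np.asarray(base_freqs, dtype=float)
    denom = float(np.sum(pop.ploidy * p0 * (1.0 - p0)))
    if denom == 0:
        raise ValueError("all base frequencies fixed; G undefined")
    M = pop.dosages(marker_index) - pop.ploidy * p0
    diag = np.einsum("ij,ij->i", M, M) / denom
    return float((diag.mean() - 1.0) / (pop.ploidy - 1))


def measure_responses(
    scenario_id: str,
    result: CycleResult,
    arch: TraitArchitecture,
    g0: float,
    base_marker_freq: np.ndarray,
    genome_map: GenomeMap,
) -> ResponseRecord:
    """All standard responses for one cycle's product pool."""
    product = result.product
    gv, add, dom = genetic_value(arch, product.dosages(arch.qtl_index))
    s = arch.sigma_g0
    freqs = product.allele_freq(arch.qtl_index)
    ph = None
    if result.intra is not None:
        ph = panmictic_heterosis(
            float(gv.mean()),
            result.intra["A"].allele_freq(arch.qtl_index),
            result.intra["B"].allele_freq(arch.qtl_index),
            arch,
            s,
        )
    return ResponseRecord(
        scenario=scenario_id,
        cycle=result.cycle,
        delta_g=delta_g(float(gv.mean()), g0, s),
        additive=float(add.mean()) / s,
        dominance=float(dom.mean()) / s,
        p_id=inbreeding_depression(arch, freqs, s),
        ph=ph,
        genomic_f=genomic_inbreeding(product, base_marker_freq, genome_map.marker_index),
        genetic_variance=float(gv.var()),
    )


# ---------------------------------------------------------------------------
# regression on H0


@dataclass
class RegressionResult:
    """Per-scenario lines from Y ~ scenario * H0 with replicate error."""

    scenarios: list[str]
    intercepts: dict[str, float]
    slopes: dict[str, float]
    intercept_se: dict[str, float]
    slope_se: dict[str, float]
    r_squared: float
    model: object = field(repr=False, default=None)


def fit_response_regression(df: pd.DataFrame, response: str = "Y") -> RegressionResult:
    """OLS of a response on scenario, H0 and their interaction.

    ``df`` needs columns [response, 'scenario', 'H0'] with one row per
    simulation replicate. Returns per-scenario intercepts and slopes on H0
    with their standard errors.
    """
    scen = sorted(df["scenario"].unique())
    if len(scen) < 2 and df["H0"].nunique() < 3:
        raise ValueError("need >= 2 scenarios or >= 3 distinct H0 values")
    model = smf.ols(f"{response} ~ C(scenario) * H0", data=df).fit()
    if np.any(np.isnan(model.params)):
        aliased = [n for n, v in model.params.items() if np.isnan(v)]
        raise ValueError(f"rank-deficient design; aliased terms: {aliased}")
    base = scen[0]
    intercepts, slopes, i_se, s_se = {}, {}, {}, {}
    cov = model.cov_params()
    for s in scen:
        i_terms = ["Intercept"] + ([f"C(scenario)[T.{s}]"] if s != base else [])
        s_terms = ["H0"] + ([f"C(scenario)[T.{s}]:H0"] if s != base else [])
        intercepts[s] = float(sum(model.params[t] for t in i_terms))
        slopes[s] = float(sum(model.params[t] for t in s_terms))
        i_se[s] = float(np.sqrt(sum(cov.loc[a, b] for a in i_terms for b in i_terms)))
        s_se[s] = float(np.sqrt(sum(cov.loc[a, b] for a in s_terms for b in s_terms)))
    return RegressionResult(
        scenarios=scen,
        intercepts=intercepts,
        slopes=slopes,
        intercept_se=i_se,
        slope_se=s_se,
        r_squared=float(model.rsquared),
        model=model,
    )


def regression_intersection(
    df: pd.DataFrame,
    scenario_a: str,
    scenario_b: str,
    response: str = "Y",
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
    slope_tol: float = 1e-10,
) -> dict:
    """Crossover H0* of two scenario regressions, with a bootstrap CI.

    H0* = (intercept_B - intercept_A) / (slope_A - slope_B). The CI is a
    paired nonparametric bootstrap over replicate populations (rows sharing
    a 'population' label resample together; without that column, rows
    resample within scenario). Flags: 'parallel' when slopes coincide,
    'outside_range' when H0* falls outside the surveyed H0 values,
    'inestimable' when the CI half-width exceeds the surveyed H0 range.
    """
    rng = np.random.default_rng(rng)
    sub = df[df["scenario"].isin([scenario_a, scenario_b])]
    fit = fit_response_regression(sub, response)
    dslope = fit.slopes[scenario_a] - fit.slopes[scenario_b]
    if abs(dslope) < slope_tol:
        return {"h0_star": np.nan, "parallel": True, "ci": (np.nan, np.nan)}
    h0_star = (fit.intercepts[scenario_b] - fit.intercepts[scenario_a]) / dslope
    lo, hi = sub["H0"].min(), sub["H0"].max()
    boot = []
    paired = "population" in sub.columns
    if paired:
        units = [g for _, g in sub.groupby("population", sort=False)]
    else:
        units = [g for _, g in sub.groupby("scenario", sort=False)]
    for _ in range(n_boot):
        if paired:
            pick = rng.integers(0, len(units), size=len(units))
            bdf = pd.concat([units[k] for k in pick])
        else:
            bdf = pd.concat(
                [g.iloc[rng.integers(0, len(g), size=len(g))] for g in units]
            )
        try:
            bfit = fit_response_regression(bdf, response)
        except Exception:
            continue
        bd = bfit.slopes[scenario_a] - bfit.slopes[scenario_b]
        if abs(bd) > slope_tol:
            boot.append((bfit.intercepts[scenario_b] - bfit.intercepts[scenario_a]) / bd)
    if boot:
        ci = (float(np.percentile(boot, 2.5)), float(np.percentile(boot, 97.5)))
    else:
        ci = (np.nan, np.nan)
    half_width = (ci[1] - ci[0]) / 2.0 if np.isfinite(ci[0]) else np.inf
    return {
        "h0_star": float(h0_star),
        "parallel": False,
        "ci": ci,
        "outside_range": not (lo <= h0_star <= hi),
        "inestimable": half_width > (hi - lo),
    }


# ---------------------------------------------------------------------------
# the factorial experiment


PAPER_GRID = {
    "n_qtl_per_chr": (100, 1000, 5000),
    "mean_dd": (0.0, 0.5, 1.0, 1.5, 10.0),
    "var_dd": (0.0, 0.2, 1.0, 10.0),
    "ploidy": (2, 4, 6),
}


def enumerate_architectures(grid: dict | None = None) -> list[dict]:
    """The architecture factorial (paper grid: 3 x 5 x 4 x 3 = 180 cells)."""
    grid = dict(PAPER_GRID if grid is None else grid)
    keys = ("n_qtl_per_chr", "mean_dd", "var_dd", "ploidy")
    return [dict(zip(keys, combo)) for combo in itertools.product(*(grid[k] for k in keys))]


def run_experiment(
    scenarios: list[ScenarioConfig],
    n_cycles: int,
    rng_seed: int,
    out_dir: str | None = None,
    grid: dict | None = None,
    n_reps: int = 10,
    n_founders: int = 80,
    n_chromosomes: int = 10,
    n_loci_per_chr: int | None = None,
    n_markers_per_chr: int = 100,
    n_initial: int = 40,
    checkpoint_cycles: tuple[int, ...] | None = None,
) -> pd.DataFrame:
    """Run the architecture x scenario factorial and collect responses.

    Each grid cell is replicated ``n_reps`` times with fresh founders,
    architecture and initial draw; every valid scenario is applied to every
    replicate population. Returns the long-form response table (one row per
    scenario x population x recorded cycle) and optionally writes
    responses.csv plus a manifest of seeds and configurations.
    """
    cells = enumerate_architectures(grid)
    root = np.random.default_rng(rng_seed)
    rows = []
    manifest = {"seed": rng_seed, "n_reps": n_reps, "cells": len(cells), "runs": []}
    for cell in cells:
        for rep in range(n_reps):
            seeds = root.integers(0, 2**31 - 1, size=6)
            ploidy = cell["ploidy"]
            n_loci = n_loci_per_chr or max(cell["n_qtl_per_chr"], n_markers_per_chr)
            gmap = make_genome_map(n_chromosomes, n_loci, rng_seed=int(seeds[0]))
            gmap = sample_qtl_and_markers(
                gmap, cell["n_qtl_per_chr"], n_markers_per_chr, rng_seed=int(seeds[1])
            )
            founders = simulate_founder_haplotypes(
                n_founders, ploidy, gmap, rng_seed=int(seeds[2])
            )
            arch = sample_architecture(
                gmap, cell["mean_dd"], cell["var_dd"], ploidy, rng_seed=int(seeds[3])
            )
            arch = scale_architecture(arch, founders)
            h0 = initial_heterosis(arch, founders)
            pop_id = f"q{cell['n_qtl_per_chr']}_m{cell['mean_dd']}_v{cell['var_dd']}_p{ploidy}_r{rep}"
            for cfg in scenarios:
                if cfg.ploidy != ploidy:
                    continue
                pools = draw_and_split(
                    founders, n_initial, cfg.n_pools, rng_seed=int(seeds[4])
                )
                runner = ScenarioRunner(cfg, gmap, arch, pools, rng_seed=int(seeds[5]))
                scen_id = f"{cfg.strategy}|{cfg.estimation}|{cfg.intensity}|L{cfg.cycle_length}"
                manifest["runs"].append(
                    {"population": pop_id, "scenario": scen_id, "seeds": seeds.tolist()}
                )
                for _ in range(n_cycles):
                    res = runner.run_cycle()
                    if checkpoint_cycles and res.cycle not in checkpoint_cycles:
                        continue
                    rec = measure_responses(
                        scen_id, res, arch, runner.g0, runner.base_marker_freq, gmap
                    )
                    rows.append(
                        {
                            "population": pop_id,
                            "scenario": rec.scenario,
                            "rep": rep,
                            "H0": h0,
                            "cycle": rec.cycle,
                            "years": rec.cycle * cfg.cycle_length,
                            "delta_g": rec.delta_g,
                            "additive": rec.additive,
                            "dominance": rec.dominance,
                            "p_id": rec.p_id,
                            "ph": rec.ph,
                            "genomic_f": rec.genomic_f,
                            "genetic_variance": rec.genetic_variance,
                            "cost": runner.state.cost,
                            **cell,
                        }
                    )
    df = pd.DataFrame(rows)
    if out_dir:
        os.makedirs(out_dir, exist_ok=True)
        df.to_csv(os.path.join(out_dir, "responses.csv"), index=False)
        with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=1)
    return df


def select_timepoint(df: pd.DataFrame, years: float | None = None, cycle: int | None = None) -> pd.DataFrame:
    """Rows at the cycle closest to a year horizon (per scenario) or a fixed cycle."""
    if (years is None) == (cycle is None):
        raise ValueError("give exactly one of years or cycle")
    if cycle is not None:
        return df[df["cycle"] == cycle]
    parts = []
    for scen, g in df.groupby("scenario"):
        L = g["years"].iloc[0] / g["cycle"].iloc[0]
        target = years_to_cycles(years, int(round(L)))
        parts.append(g[g["cycle"] == target])
    return pd.concat(parts) if parts else df.iloc[:0]
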