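"""Full-scale strategy-crossover sweep, including autopolyploids.

This is the long-running version of the reduced experiment in the test
suite: genomic selection at high intensity, the four core strategies, a
dominance grid wide enough to span large H0, 25 cycles, and (optionally)
tetraploid and hexaploid populations whose 50-year crossovers occur at much
larger H0 than in diploids. Expect hours of runtime at the default sizes;
trim the grids for a quicker look.

    python examples/crossover_fullscale.py --ploidy 2 --out scratch/crossover2
"""

import argparse

import numpy as np

import heterosim as hs
from heterosim.responses import fit_response_regression, regression_intersection, run_experiment

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--ploidy", type=int, default=2, choices=[2, 4, 6])
parser.add_argument("--seed", type=int, default=11)
parser.add_argument("--reps", type=int, default=5)
parser.add_argument("--cycles", type=int, default=25)
parser.add_argument("--out", type=str, default=None)
args = parser.parse_args()

scenarios = [
    hs.ScenarioConfig(
        s, estimation="genomic", intensity="high", ploidy=args.ploidy,
        progeny_per_cross=40 if s.startswith("One") else 16,
        training_capacity=2000,
    )
    for s in ("OnePoolBV", "OnePoolCP", "TwoPoolBV", "TwoPoolGCA")
]

df = run_experiment(
    scenarios,
    n_cycles=args.cycles,
    rng_seed=args.seed,
    out_dir=args.out,
    grid={
        "n_qtl_per_chr": (100, 1000),
        "mean_dd": (0.0, 0.5, 1.0, 1.5, 3.0, 10.0),
        "var_dd": (0.2,),
        "ploidy": (args.ploidy,),
    },
    n_reps=args.reps,
    n_loci_per_chr=1100,
    n_markers_per_chr=100,
    checkpoint_cycles=(8, 25),
)
df["scenario"] = df["scenario"].str.split("|").str[0]

for cycle, label in ((8, "15 years"), (25, "50 years")):
    sub = df[df.cycle == cycle].rename(columns={"delta_g": "Y"})
    fit = fit_response_regression(sub)
    print(f"\n=== {label} (cycle {cycle}), ploidy {args.ploidy} ===")
    for s in fit.scenarios:
        print(f"  {s:12s} intercept {fit.intercepts[s]:6.2f}  slope {fit.slopes[s]:+.3f}")
    for one_pool in ("OnePoolBV", "OnePoolCP"):
        out = regression_intersection(sub, "TwoPoolGCA", one_pool, n_boot=500,
                                      rng=np.random.default_rng(args.seed))
        if out["parallel"]:
            print(f"  TwoPoolGCA vs {one_pool}: parallel regressions")
            continue
        lo, hi = out["ci"]
        flag = " (outside surveyed H0)" if out.get("outside_range") else ""
        print(f"  TwoPoolGCA overtakes {one_pool} at H0* = {out['h0_star']:.1f}"
              f" [CI {lo:.1f}, {hi:.1f}]{flag}")
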