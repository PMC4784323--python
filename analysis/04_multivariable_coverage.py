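"""Coverage when all seven predictors are fitted simultaneously.

Same base scenario and sigma_v sweep as the single-predictor study, with the
joint model (each conditional log OR = log 2).  Writes
results/coverage_multivariable.csv.
"""

import argparse
import pathlib

from crvecov.io import write_results
from crvecov.study import multivariable_sweep

OUT = pathlib.Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--reps", type=int, default=500)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--K", type=int, default=5)
    args = ap.parse_args()

    table = multivariable_sweep(K=args.K, reps=args.reps, seed=args.seed, progress=True)
    OUT.mkdir(exist_ok=True)
    write_results(table, OUT / "coverage_multivariable.csv")

    vil = table[table.ci_type == "vil"]
    print("\nVillage-adjusted coverage by coefficient (min over sweep):")
    summary = vil.groupby("coefficient").agg(
        rho_x=("rho_x_village", "first"), min_coverage=("coverage", "min")
    )
    print(summary.round(3).to_string())
    low = summary[summary.rho_x < 0.2]
    print(
        f"\nFor predictors with village-level ICC < 0.2 the village-adjusted "
        f"intervals keep coverage above {low.min_coverage.min():.3f} even with "
        f"K={args.K} villages; strongly clustered predictors (x3/x7, x4) fall below."
    )


if __name__ == "__main__":
    main()
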