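"""Exact marginal log odds ratios implied by the conditional model.

For the base scenario (conditional OR 2, household SD log 2) the exact
marginal slope is computed by quadrature + root-finding over the sigma_v
sweep, next to the closed-form attenuation approximation and the model-based
outcome ICCs.  Writes results/true_marginal.csv.
"""

import pathlib

import numpy as np
import pandas as pd

from crvecov import SimParams, build_design, marginal_truth, outcome_icc_model
from crvecov.coverage import SIGMA_V_SWEEP
from crvecov.study import FIG_BASE

OUT = pathlib.Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    d = build_design(5, 20, 5, ("x1",), seed=1)
    rows = []
    for sv in SIGMA_V_SWEEP:
        p = SimParams(
            alpha0=FIG_BASE["alpha0"],
            alpha=np.array([FIG_BASE["alpha1"]]),
            sigma_h=FIG_BASE["sigma_h"],
            sigma_v=float(sv),
            I=5, J=20, K=5,
        )
        t = marginal_truth(d, p)
        rows.append(
            {
                "sigma_v": sv,
                "alpha1": FIG_BASE["alpha1"],
                "beta_true": t.beta_true[1],
                "beta_zeger": t.beta_zeger[0],
                "zeger_rel_error": t.beta_zeger[0] / t.beta_true[1] - 1,
                "rho_y_village": outcome_icc_model(p, d, "village").value,
                "rho_y_household": outcome_icc_model(p, d, "household").value,
            }
        )
    table = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    table.to_csv(OUT / "true_marginal.csv", index=False)
    print(table.round(4).to_string(index=False))
    print(
        "\nThe marginal slope attenuates from the conditional log(2)="
        f"{FIG_BASE['alpha1']:.4f} as the village random-effect SD grows; the "
        "closed-form approximation tracks the exact value to within "
        f"{table.zeger_rel_error.abs().max():.1%}."
    )


if __name__ == "__main__":
    main()
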