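"""Plot coverage of the three interval types against village-level outcome ICC.

Reads results/coverage_single.csv (run 03_single_predictor_coverage.py
first); one panel per predictor layout x K, coverage on the y-axis and the
model-based village-level outcome ICC on the x-axis.  Writes
results/coverage_vs_icc.png.
"""

import pathlib

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

OUT = pathlib.Path(__file__).resolve().parents[1] / "results"

LABELS = {"un": "unadjusted", "hh": "household-adjusted", "vil": "village-adjusted"}


def main() -> None:
    table = pd.read_csv(OUT / "coverage_single.csv")
    layouts = sorted(table.coefficient.unique())
    ks = sorted(table.K.unique())
    fig, axes = plt.subplots(
        len(layouts), len(ks), figsize=(4 * len(ks), 2.6 * len(layouts)),
        sharex=True, sharey=True, squeeze=False,
    )
    for i, layout in enumerate(layouts):
        for j, K in enumerate(ks):
            ax = axes[i][j]
            cell = table[(table.coefficient == layout) & (table.K == K)]
            for ci_type, group in cell.groupby("ci_type"):
                g = group.sort_values("rho_y_village")
                ax.plot(g.rho_y_village, 100 * g.coverage, marker="o",
                        label=LABELS[ci_type])
            ax.axhline(95, color="grey", lw=0.8, ls="--")
            rho_x = cell.rho_x_village.iloc[0]
            ax.set_title(f"{layout} (rho_x={rho_x:.2f}), K={K}", fontsize=9)
            ax.set_ylim(40, 100)
    axes[0][0].legend(fontsize=8)
    for ax in axes[-1]:
        ax.set_xlabel("village-level outcome ICC")
    for row in axes:
        row[0].set_ylabel("coverage (%)")
    fig.tight_layout()
    fig.savefig(OUT / "coverage_vs_icc.png", dpi=150)
    print(f"wrote {OUT / 'coverage_vs_icc.png'}")


if __name__ == "__main__":
    main()
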