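"""Canonical study conditions for the coverage simulation.

The base scenario holds the conditional intercept at log(0.1/0.9) (10%
baseline prevalence), the conditional log odds ratio and household
random-effect SD at log(2), with I=5 individuals per household and J=20
households per village, and sweeps the village random-effect SD over
:data:`crvecov.coverage.SIGMA_V_SWEEP` (log 1.05 to log 5).  These functions
build and run the grids used throughout the analysis scripts and tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .coverage import SIGMA_V_SWEEP, run_grid
from .design import ALL_PREDICTORS

__all__ = ["FIG_BASE", "single_predictor_sweep", "multivariable_sweep"]

FIG_BASE = {
    "alpha0": float(np.log(0.1 / 0.9)),
    "alpha1": float(np.log(2.0)),
    "sigma_h": float(np.log(2.0)),
    "I": 5,
    "J": 20,
}

DEFAULT_REPS = 2000


def single_predictor_sweep(
    K: int,
    layouts: tuple[str, ...] | list[str],
    reps: int = DEFAULT_REPS,
    seed: int = 1,
    progress: bool = False,
) -> pd.DataFrame:
    """Coverage over the sigma_v sweep for single-predictor models."""
    config = {
        **FIG_BASE,
        "sigma_v": list(SIGMA_V_SWEEP),
        "K": K,
        "predictors": list(layouts),
        "reps": reps,
        "seed": seed,
    }
    return run_grid(config, progress=progress)


def multivariable_sweep(
    K: int,
    reps: int = DEFAULT_REPS,
    seed: int = 1,
    progress: bool = False,
) -> pd.DataFrame:
    """Coverage over the sigma_v sweep with all seven predictors fitted jointly."""
    config = {
        **FIG_BASE,
        "sigma_v": list(SIGMA_V_SWEEP),
        "K": K,
        "predictors": [list(ALL_PREDICTORS)],
        "reps": reps,
        "seed": seed,
    }
    return run_grid(config, progress=progress)
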