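"""Dataset and results readers/writers and config parsing.

Datasets are exchanged as comma-separated text with header
``village,household,individual,<predictors...>,y`` — one row per individual.
Reading validates the schema, binariness and the household-in-village
nesting, naming the first offending row.  Grid configurations are YAML.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .design import (
    ALL_PREDICTORS,
    HOUSEHOLD_PREDICTORS,
    ClusteredDataset,
    Design,
)

__all__ = ["read_dataset", "write_dataset", "write_results", "read_results", "load_config"]

ID_COLUMNS = ["village", "household", "individual"]


def write_dataset(dataset: ClusteredDataset, path: str | Path) -> None:
    d = dataset.design
    frame = pd.DataFrame(
        {
            "village": d.village_id,
            "household": d.household_id,
            "individual": d.individual_id,
            **{name: d.column(name) for name in d.predictor_names},
            "y": dataset.y,
        }
    )
    frame.to_csv(path, index=False)


def read_dataset(path: str | Path) -> ClusteredDataset:
    """Load a dataset written by :func:`write_dataset`; validates invariants."""
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty file, expected header {ID_COLUMNS + ['...', 'y']}")
    missing = [c for c in ID_COLUMNS + ["y"] if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    predictors = tuple(c for c in frame.columns if c not in ID_COLUMNS + ["y"])
    unknown = [c for c in predictors if c not in ALL_PREDICTORS]
    if unknown:
        raise ValueError(f"{path}: unexpected columns {unknown}")

    for col in list(predictors) + ["y"]:
        vals = frame[col].to_numpy()
        bad = np.nonzero(~np.isin(vals, (0, 1)))[0]
        if bad.size:
            raise ValueError(f"{path}: non-binary value in column {col!r} at row {bad[0]}")

    # nesting: each household under one village
    vid = frame["village"].to_numpy()
    hid = frame["household"].to_numpy()
    seen: dict[int, int] = {}
    for row, (h, v) in enumerate(zip(hid, vid)):
        if seen.setdefault(h, v) != v:
            raise ValueError(
                f"{path}: household {h} appears under villages {seen[h]} and {v} (row {row})"
            )

    hh_sizes = frame.groupby("household").size()
    vil_hh = frame.groupby("village")["household"].nunique()
    I = int(hh_sizes.iloc[0])
    J = int(vil_hh.iloc[0])
    K = int(frame["village"].nunique())
    X = frame[list(predictors)].to_numpy(dtype=np.int8) if predictors else np.zeros((len(frame), 0), dtype=np.int8)
    design = Design(
        village_id=vid,
        household_id=hid,
        individual_id=frame["individual"].to_numpy(),
        X=X,
        predictor_names=predictors,
        level_of={p: ("household" if p in HOUSEHOLD_PREDICTORS else "individual") for p in predictors},
        I=I,
        J=J,
        K=K,
    )
    return ClusteredDataset(design=design, y=frame["y"].to_numpy(dtype=np.int8))


RESULT_COLUMNS = [
    "alpha0", "sigma_h", "sigma_v", "I", "J", "K", "n_reps",
    "coefficient", "ci_type", "coverage", "mc_se", "coverage_all_reps",
    "n_converged", "n_attempted", "true_beta",
    "rho_y_village", "rho_y_household", "rho_x_village",
]


def write_results(results: pd.DataFrame, path: str | Path) -> None:
    """Write a coverage results table with stable column order and full precision."""
    if results.empty:
        raise ValueError("results table is empty")
    cols = [c for c in RESULT_COLUMNS if c in results.columns]
    cols += [c for c in results.columns if c not in cols]
    buf = _io.StringIO()
    results[cols].to_csv(buf, index=False, float_format="%.17g")
    Path(path).write_text(buf.getvalue())


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ValueError(f"{path}: config must be a mapping of grid keys")
    return config
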