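"""Nested village/household/individual designs and the conditional simulator.

The study population is a balanced two-level nested design: ``K`` villages,
each containing ``J`` households of ``I`` individuals.  Binary predictors are
laid out so that each village has an exact, pre-specified proportion of
positive individuals; household-level predictors (x1-x4) are constant within
a household, individual-level predictors (x5-x7) vary freely across a
village's members.  Outcomes are simulated from a conditional (random
effects) logistic model with independent Gaussian random intercepts for
village and household:

    logit P(Y=1 | x, u, z) = alpha0 + x' alpha + u_village + z_household,

    u ~ N(0, sigma_v^2),   z ~ N(0, sigma_h^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

__all__ = [
    "LAYOUTS",
    "HOUSEHOLD_PREDICTORS",
    "INDIVIDUAL_PREDICTORS",
    "ALL_PREDICTORS",
    "Design",
    "SimParams",
    "ClusteredDataset",
    "build_design",
    "simulate_outcomes",
]

# Per-predictor proportion of positive individuals in each of the five
# village profiles.  Designs with more than five villages replicate these
# profiles in whole sets.
LAYOUTS: dict[str, tuple[float, ...]] = {
    "x1": (0.2, 0.2, 0.2, 0.2, 0.2),
    "x2": (0.0, 0.1, 0.1, 0.3, 0.5),
    "x3": (0.0, 0.05, 0.1, 0.1, 0.75),
    "x4": (0.0, 0.0, 0.0, 1.0, 1.0),
    "x5": (0.2, 0.2, 0.2, 0.2, 0.2),
    "x6": (0.0, 0.1, 0.1, 0.3, 0.5),
    "x7": (0.0, 0.05, 0.1, 0.1, 0.75),
}

HOUSEHOLD_PREDICTORS = ("x1", "x2", "x3", "x4")
INDIVIDUAL_PREDICTORS = ("x5", "x6", "x7")
ALL_PREDICTORS = HOUSEHOLD_PREDICTORS + INDIVIDUAL_PREDICTORS

N_PROFILES = 5


@dataclass(frozen=True)
class Design:
    """A fixed nested layout with binary predictors.

    Attributes
    ----------
    village_id, household_id, individual_id
        Integer labels per unit; household ids are globally unique and
        strictly nested within villages.
    X
        Binary (0/1) predictor matrix, one column per entry of
        ``predictor_names``.
    predictor_names
        Column names of ``X`` (subset of x1..x7).
    level_of
        Maps each predictor name to "household" or "individual".
    I, J, K
        Individuals per household, households per village, villages.
    """

    village_id: np.ndarray
    household_id: np.ndarray
    individual_id: np.ndarray
    X: np.ndarray
    predictor_names: tuple[str, ...]
    level_of: dict[str, str] = field(repr=False)
    I: int = 0
    J: int = 0
    K: int = 0

    @property
    def n_units(self) -> int:
        return self.village_id.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.X[:, self.predictor_names.index(name)]

    def validate(self) -> None:
        """Check the nesting and balance invariants; raise ValueError on failure."""
        vid, hid = self.village_id, self.household_id
        # strict nesting: each household under exactly one village
        pairs = {}
        for h, v in zip(hid, vid):
            if pairs.setdefault(h, v) != v:
                raise ValueError(f"household {h} appears under villages {pairs[h]} and {v}")
        counts = np.bincount(np.unique(hid, return_inverse=True)[1])
        if not np.all(counts == self.I):
            raise ValueError("unequal household sizes")
        hh_per_village = {v: len({h for h, vv in pairs.items() if vv == v}) for v in set(pairs.values())}
        if set(hh_per_village.values()) != {self.J}:
            raise ValueError("unequal numbers of households per village")
        if not np.isin(self.X, (0, 1)).all():
            raise ValueError("predictors must be binary 0/1")


@dataclass(frozen=True)
class SimParams:
    """Conditional-model parameters and design sizes.

    ``alpha`` is the vector of conditional log odds ratios, aligned with the
    design's predictor columns.  ``sigma_h`` and ``sigma_v`` are the standard
    deviations (log-odds scale) of the household and village random effects.
    """

    alpha0: float
    alpha: np.ndarray
    sigma_h: float
    sigma_v: float
    I: int
    J: int
    K: int

    def __post_init__(self):
        object.__setattr__(self, "alpha", np.atleast_1d(np.asarray(self.alpha, dtype=float)))
        if self.sigma_h < 0 or self.sigma_v < 0:
            raise ValueError("random-effect standard deviations must be non-negative")
        if min(self.I, self.J, self.K) < 1:
            raise ValueError("I, J, K must be positive integers")

    @property
    def sigma_total_sq(self) -> float:
        return self.sigma_h**2 + self.sigma_v**2


@dataclass(frozen=True)
class ClusteredDataset:
    """A design with simulated binary outcomes attached."""

    design: Design
    y: np.ndarray

    def __post_init__(self):
        if self.y.shape[0] != self.design.n_units:
            raise ValueError("outcome length does not match design")
        if not np.isin(self.y, (0, 1)).all():
            raise ValueError("outcomes must be binary 0/1")


def _positive_count(n: int, proportion: float) -> int:
    k = int(round(n * proportion))
    return min(max(k, 0), n)


def build_design(
    I: int,
    J: int,
    K: int,
    predictors: tuple[str, ...] | list[str] = ALL_PREDICTORS,
    seed: int | np.random.SeedSequence = 0,
) -> Design:
    """Build a balanced nested design with exact village-level predictor proportions.

    Village profiles are defined in :data:`LAYOUTS` over five villages; for
    K a multiple of 5 the profiles are replicated in whole sets (e.g. K=20
    uses four identical sets).  Household-level predictors are assigned to
    ``round(J * proportion)`` whole households per village; individual-level
    predictors to ``round(J * I * proportion)`` individuals sampled across
    the village irrespective of household.  Which households/individuals are
    positive is randomized; the counts are deterministic.
    """
    if min(I, J, K) < 1:
        raise ValueError("I, J, K must be positive integers")
    if K % N_PROFILES != 0:
        raise ValueError(f"K must be a multiple of {N_PROFILES} (village profiles), got {K}")
    predictors = tuple(predictors)
    unknown = [p for p in predictors if p not in LAYOUTS]
    if unknown:
        raise ValueError(f"unknown predictors: {unknown}")

    rng = np.random.default_rng(seed)
    n_units = I * J * K
    village_id = np.repeat(np.arange(K), J * I)
    household_id = np.repeat(np.arange(K * J), I)
    individual_id = np.tile(np.arange(I), K * J)

    X = np.zeros((n_units, len(predictors)), dtype=np.int8)
    level_of = {}
    for c, name in enumerate(predictors):
        props = LAYOUTS[name]
        level = "household" if name in HOUSEHOLD_PREDICTORS else "individual"
        level_of[name] = level
        col = np.zeros(n_units, dtype=np.int8)
        for k in range(K):
            p = props[k % N_PROFILES]
            village_rows = slice(k * J * I, (k + 1) * J * I)
            if level == "household":
                n_pos = _positive_count(J, p)
                pos_households = rng.choice(J, size=n_pos, replace=False)
                block = np.zeros((J, I), dtype=np.int8)
                block[pos_households, :] = 1
                col[village_rows] = block.ravel()
            else:
                n_pos = _positive_count(J * I, p)
                pos_units = rng.choice(J * I, size=n_pos, replace=False)
                block = np.zeros(J * I, dtype=np.int8)
                block[pos_units] = 1
                col[village_rows] = block
        X[:, c] = col

    return Design(
        village_id=village_id,
        household_id=household_id,
        individual_id=individual_id,
        X=X,
        predictor_names=predictors,
        level_of=level_of,
        I=I,
        J=J,
        K=K,
    )


def simulate_outcomes(
    design: Design,
    params: SimParams,
    seed: int | np.random.SeedSequence | np.random.Generator,
) -> ClusteredDataset:
    """Simulate binary outcomes from the conditional logistic model.

    Draws one village effect u_k ~ N(0, sigma_v^2) per village and one
    household effect z_jk ~ N(0, sigma_h^2) per household, then samples
    y ~ Bernoulli(expit(alpha0 + x'alpha + u + z)).  A fixed seed yields a
    bit-reproducible dataset.
    """
    if params.alpha.shape[0] != design.X.shape[1]:
        raise ValueError(
            f"alpha has {params.alpha.shape[0]} entries but design has "
            f"{design.X.shape[1]} predictor columns"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_villages = design.village_id.max() + 1
    n_households = design.household_id.max() + 1
    u = rng.normal(0.0, params.sigma_v, size=n_villages)
    z = rng.normal(0.0, params.sigma_h, size=n_households)
    eta = (
        params.alpha0
        + design.X @ params.alpha
        + u[design.village_id]
        + z[design.household_id]
    )
    y = (rng.random(design.n_units) < expit(eta)).astype(np.int8)
    return ClusteredDataset(design=design, y=y)
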