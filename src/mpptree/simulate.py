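"""Synthetic-data generator for the Monte Carlo recovery study.

Generates item parameters, correlated latent traits, and 5-category Likert
responses with the statistical structure of the study design:

* discriminations per node from log-normal distributions with (location,
  scale) of (-0.5, 0.5) for the midpoint, (0.3, 0.2) for the agreement and
  (0.5, 0.5) for the extreme node — "location/scale" are the mean and sd of
  ``log(alpha)``, the ``rlnorm`` convention;
* difficulties per node from normals: midpoint N(-1, 0.5), agreement
  N(0, 1), extreme N(1, 0.5); intercepts are derived as ``d = alpha * b``;
* person traits from a trivariate standard normal with correlations
  r(M,A) = -0.10, r(A,E) = 0.10, r(M,E) = -0.50;
* a factorial design grid of sample sizes N in {500, 1000, 1500, 5000} by
  test lengths J in {10, 15, 20} with a configurable replicate count
  (2000 in the full study).

Seeding uses ``numpy.random.SeedSequence`` spawning keyed on (condition,
replicate) indices, so any single replicate is reproducible in isolation and
results do not depend on execution order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import (
    ItemParams,
    LatentTraits,
    LikertMatrix,
    MppValidationError,
    category_probability_array,
    validate_correlation_matrix,
)

#: Default trait correlation matrix, rows/cols ordered (M, A, E).
DEFAULT_TRAIT_CORR = np.array(
    [
        [1.0, -0.10, -0.50],
        [-0.10, 1.0, 0.10],
        [-0.50, 0.10, 1.0],
    ]
)


@dataclass
class NodeDistributionConfig:
    """Generating distributions for item parameters, one entry per node.

    ``alpha_loc``/``alpha_scale`` parameterize log-normals on the log scale;
    ``b_mean``/``b_sd`` parameterize normals for the difficulties.
    """

    alpha_loc: tuple[float, float, float] = (-0.5, 0.3, 0.5)
    alpha_scale: tuple[float, float, float] = (0.5, 0.2, 0.5)
    b_mean: tuple[float, float, float] = (-1.0, 0.0, 1.0)
    b_sd: tuple[float, float, float] = (0.5, 1.0, 0.5)

    def __post_init__(self) -> None:
        for name in ("alpha_scale", "b_sd"):
            vals = getattr(self, name)
            if any(v < 0 for v in vals):
                raise MppValidationError(f"{name} entries must be >= 0; got {vals}")

    @classmethod
    def from_dict(cls, d: dict) -> "NodeDistributionConfig":
        return cls(**{k: tuple(v) for k, v in d.items()})

    def to_dict(self) -> dict:
        return {
            "alpha_loc": list(self.alpha_loc),
            "alpha_scale": list(self.alpha_scale),
            "b_mean": list(self.b_mean),
            "b_sd": list(self.b_sd),
        }


@dataclass
class DesignGrid:
    """The factorial simulation design: sample sizes x test lengths."""

    sample_sizes: tuple[int, ...] = (500, 1000, 1500, 5000)
    test_lengths: tuple[int, ...] = (10, 15, 20)
    replicates: int = 2000
    base_seed: int = 0

    def __post_init__(self) -> None:
        if not self.sample_sizes or not self.test_lengths:
            raise MppValidationError("sample_sizes and test_lengths must be non-empty")
        if self.replicates < 1:
            raise MppValidationError("replicates must be >= 1")

    @classmethod
    def from_dict(cls, d: dict) -> "DesignGrid":
        d = dict(d)
        for k in ("sample_sizes", "test_lengths"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)

    def to_dict(self) -> dict:
        return {
            "sample_sizes": list(self.sample_sizes),
            "test_lengths": list(self.test_lengths),
            "replicates": self.replicates,
            "base_seed": self.base_seed,
        }


@dataclass
class Condition:
    """One design cell with per-replicate entropy for reproducible draws."""

    n_persons: int
    n_items: int
    index: int
    replicate_seeds: np.ndarray = field(repr=False)
    item_seed: int = 0

    @property
    def label(self) -> str:
        return f"N{self.n_persons}_J{self.n_items}"


def draw_item_params(
    J: int, config: NodeDistributionConfig | None = None, seed=None
) -> ItemParams:
    """Draw per-node item parameters for a J-item scale.

    Discriminations are i.i.d. log-normal and difficulties i.i.d. normal with
    the node's configured parameters; reproducible under a fixed seed.
    """
    if J < 1:
        raise MppValidationError(f"item count must be >= 1; got {J}")
    config = config or NodeDistributionConfig()
    rng = np.random.default_rng(seed)
    alpha = np.empty((3, J))
    b = np.empty((3, J))
    for k in range(3):
        alpha[k] = np.exp(rng.normal(config.alpha_loc[k], config.alpha_scale[k], size=J))
        b[k] = rng.normal(config.b_mean[k], config.b_sd[k], size=J)
    return ItemParams(alpha=alpha, b=b)


def draw_thetas(n: int, R: np.ndarray | None = None, seed=None) -> LatentTraits:
    """Draw n persons' traits from a trivariate normal with correlation R.

    Means are zero and variances one, so R is also the covariance matrix.
    """
    R = DEFAULT_TRAIT_CORR if R is None else np.asarray(R, dtype=float)
    validate_correlation_matrix(R)
    rng = np.random.default_rng(seed)
    theta = rng.multivariate_normal(np.zeros(3), R, size=n, method="cholesky")
    return LatentTraits(theta=theta, R=R)


def simulate_responses(params: ItemParams, traits: LatentTraits, seed=None) -> LikertMatrix:
    """Draw one Likert response per person x item from the MPP category
    probabilities.  Warns if fewer than five categories appear in the data."""
    probs = category_probability_array(params, traits)  # (n, J, 5)
    rng = np.random.default_rng(seed)
    cum = np.cumsum(probs, axis=-1)
    u = rng.random(cum.shape[:2])
    responses = (u[..., None] > cum).sum(axis=-1) + 1
    if len(np.unique(responses)) < 5:
        warnings.warn(
            "simulated data do not contain all five categories; "
            "parameters may be extreme or the sample very small",
            stacklevel=2,
        )
    return LikertMatrix(responses)


def build_design(grid: DesignGrid) -> list[Condition]:
    """Enumerate the design cells (cross product N x J) with stable seeds.

    Seeds derive from the grid's base seed by ``SeedSequence`` spawning keyed
    on the condition index and replicate index, never on execution order.
    Item parameters get one dedicated seed per test length so they are fixed
    across replicates and sample sizes within a test-length condition.
    """
    conditions = []
    idx = 0
    # one item-parameter stream per distinct test length
    item_seeds = {
        J: int(np.random.SeedSequence(grid.base_seed, spawn_key=(1, j)).generate_state(1)[0] % (2**31))
        for j, J in enumerate(grid.test_lengths)
    }
    for J in grid.test_lengths:
        for N in grid.sample_sizes:
            cell = np.random.SeedSequence(grid.base_seed, spawn_key=(2, idx))
            rep_seeds = cell.generate_state(grid.replicates, dtype=np.uint64)
            rep_seeds = (rep_seeds % (2**31)).astype(np.int64)
            conditions.append(
                Condition(
                    n_persons=N,
                    n_items=J,
                    index=idx,
                    replicate_seeds=rep_seeds,
                    item_seed=item_seeds[J],
                )
            )
            idx += 1
    return conditions
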