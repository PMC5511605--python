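"""The OptiMET design criterion.

A candidate design (subset of environments) is good for calibration when
the crop model maps distant parameter vectors to distant output vectors on
those environments.  The criterion quantifies this with a preposterior
argument: take m a-priori parameter vectors θ_u (by default a regular grid
over the expert bounds), compute the noise-free model outputs f(θ_u, E_j)
for every candidate environment, and form for a design d the likelihood of
θ_u given synthetic data generated from θ_v,

    L_uv = (4π σ_e²)^(−n_y/2) · exp(−Δ_uvᵀΔ_uv / (4σ_e²)),

with Δ_uv the vector of output differences over the design's environments
and n_y = Z·K observations per variety.  Columns of L are normalized into
a weight matrix W (each column sums to 1) and the criterion is

    OptiMET(d) = Σ_uv dist(θ_u, θ_v) · W_uv,

with dist the bounds-normalized Euclidean distance.  Small values mean the
design concentrates likelihood weight near the generating parameter
vector; the best design minimizes the criterion.  All likelihood algebra
is carried out in log space (per-column max subtraction) because the
exponent underflows for realistic output contrasts.
"""

from __future__ import annotations

import dataclasses
import itertools
from collections.abc import Sequence

import numpy as np

from .cgm import DEFAULT_CONSTANTS, ModelConstants, ParameterBounds, heading_batch, prepare_environment
from .environments import Environment

__all__ = [
    "ParameterGrid",
    "CandidateOutputs",
    "Design",
    "normalized_distance",
    "distance_matrix",
    "build_grid",
    "compute_candidate_outputs",
    "log_likelihood_matrix",
    "likelihood_matrix",
    "weight_matrix",
    "optimet_value",
    "OptimetCriterion",
]

DEFAULT_SIGMA_E = 2.0  # days; matches the observation-noise scale of heading notes


@dataclasses.dataclass(frozen=True)
class ParameterGrid:
    """m a-priori parameter vectors standing in for the variety distribution."""

    values: np.ndarray           # (m, p)
    bounds: ParameterBounds
    levels_per_param: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.atleast_2d(np.asarray(self.values, dtype=float)))
        if self.values.shape[1] != self.bounds.p:
            raise ValueError("grid width must match the number of parameters")
        if not np.all(self.bounds.contains(self.values)):
            raise ValueError("grid rows must lie within the parameter bounds")

    @property
    def m(self) -> int:
        return self.values.shape[0]


@dataclasses.dataclass(frozen=True)
class CandidateOutputs:
    """Noise-free model outputs f(θ_u, E_j): rows = grid index, cols = env."""

    outputs: np.ndarray          # (m, J), days
    env_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "outputs", np.atleast_2d(np.asarray(self.outputs, dtype=float)))
        if self.outputs.shape[1] != len(self.env_ids):
            raise ValueError("outputs must have one column per env_id")
        if not np.all(np.isfinite(self.outputs)):
            raise ValueError("outputs must be finite")

    @property
    def m(self) -> int:
        return self.outputs.shape[0]

    @property
    def n_candidates(self) -> int:
        return self.outputs.shape[1]


@dataclasses.dataclass(frozen=True)
class Design:
    """A size-Z subset of the candidate environments with K replications."""

    indices: tuple[int, ...]
    K: int = 1
    env_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        idx = tuple(int(i) for i in self.indices)
        object.__setattr__(self, "indices", idx)
        if len(set(idx)) != len(idx):
            raise ValueError("design indices must be distinct")
        if len(idx) < 1:
            raise ValueError("a design needs at least one environment")
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.env_ids is not None and len(self.env_ids) != len(idx):
            raise ValueError("env_ids must match indices")

    @property
    def Z(self) -> int:
        return len(self.indices)

    @property
    def n_y(self) -> int:
        return self.Z * self.K


def normalized_distance(
    theta_u: Sequence[float], theta_v: Sequence[float], bounds: ParameterBounds
) -> float:
    """Range-normalized Euclidean distance between two parameter vectors."""
    u = np.asarray(theta_u, dtype=float)
    v = np.asarray(theta_v, dtype=float)
    if u.shape != v.shape or u.shape != (bounds.p,):
        raise ValueError("vectors must both have length p matching the bounds")
    ranges = bounds.ranges
    if np.any(ranges <= 0):
        raise ValueError("bounds must have positive width")
    return float(np.sqrt(np.sum(((u - v) / ranges) ** 2)))


def distance_matrix(grid: ParameterGrid) -> np.ndarray:
    """All pairwise normalized distances of the grid rows, (m, m)."""
    scaled = grid.values / grid.bounds.ranges
    sq = np.sum(scaled**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * scaled @ scaled.T
    np.fill_diagonal(d2, 0.0)  # exact zeros; the expansion cancels imperfectly
    return np.sqrt(np.maximum(d2, 0.0))


def build_grid(bounds: ParameterBounds, levels: int) -> ParameterGrid:
    """Regular discretization: g levels per parameter (endpoints included)."""
    if levels < 2:
        raise ValueError("levels must be >= 2")
    axes = [np.linspace(lo, hi, levels) for lo, hi in zip(bounds.lower, bounds.upper)]
    values = np.array(list(itertools.product(*axes)))
    return ParameterGrid(values=values, bounds=bounds, levels_per_param=levels)


def compute_candidate_outputs(
    grid: ParameterGrid,
    envs: Sequence[Environment],
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> CandidateOutputs:
    """Evaluate the crop model on every (grid row, candidate environment)."""
    cols = []
    for env in envs:
        cache = prepare_environment(env, constants)
        cols.append(heading_batch(grid.values, cache, constants))
    return CandidateOutputs(
        outputs=np.column_stack(cols), env_ids=tuple(e.env_id for e in envs)
    )


def _design_sq_norms(outputs: CandidateOutputs, design: Design) -> np.ndarray:
    """ΔᵀΔ over the design's environments for all grid pairs, (m, m)."""
    sub = outputs.outputs[:, list(design.indices)]
    sq = np.sum(sub**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * sub @ sub.T
    np.fill_diagonal(d2, 0.0)
    return design.K * np.maximum(d2, 0.0)


def log_likelihood_matrix(
    outputs: CandidateOutputs, design: Design, sigma2_e: float
) -> np.ndarray:
    """log L_uv including the (4πσ²)^(−n_y/2) prefactor; symmetric."""
    if sigma2_e <= 0:
        raise ValueError("sigma2_e must be > 0")
    d2 = _design_sq_norms(outputs, design)
    return -0.5 * design.n_y * np.log(4.0 * np.pi * sigma2_e) - d2 / (4.0 * sigma2_e)


def likelihood_matrix(outputs: CandidateOutputs, design: Design, sigma2_e: float) -> np.ndarray:
    """The likelihood matrix L on the natural scale (may underflow for large Δ)."""
    return np.exp(log_likelihood_matrix(outputs, design, sigma2_e))


def weight_matrix(L: np.ndarray) -> np.ndarray:
    """Column-normalize L into the weight matrix W (columns sum to 1)."""
    L = np.asarray(L, dtype=float)
    sums = L.sum(axis=0)
    if np.any(sums <= 0):
        raise ValueError(
            "a column of L sums to zero (underflow); use a larger sigma2_e or "
            "the log-space path (optimet_value)"
        )
    return L / sums


def _weights_from_log(logL: np.ndarray) -> np.ndarray:
    """Column-wise softmax of log L; the n_y prefactor cancels."""
    shifted = logL - logL.max(axis=0, keepdims=True)
    expd = np.exp(shifted)
    return expd / expd.sum(axis=0, keepdims=True)


def optimet_value(
    design: Design,
    grid: ParameterGrid,
    outputs: CandidateOutputs,
    sigma2_e: float = DEFAULT_SIGMA_E**2,
) -> float:
    """OptiMET(d) = Σ_uv dist(θ_u, θ_v) · W_uv; smaller is better."""
    if grid.m != outputs.m:
        raise ValueError("grid and outputs disagree on m")
    W = _weights_from_log(log_likelihood_matrix(outputs, design, sigma2_e))
    return float(np.sum(distance_matrix(grid) * W))


class OptimetCriterion:
    """Reusable criterion evaluator caching the distance matrix and outputs.

    Calling the instance with a tuple of candidate indices returns the
    criterion value of that design; this is the ``criterion_fn`` interface
    the search module expects.
    """

    def __init__(
        self,
        grid: ParameterGrid,
        outputs: CandidateOutputs,
        sigma2_e: float = DEFAULT_SIGMA_E**2,
        K: int = 1,
    ):
        if grid.m != outputs.m:
            raise ValueError("grid and outputs disagree on m")
        if sigma2_e <= 0:
            raise ValueError("sigma2_e must be > 0")
        self.grid = grid
        self.outputs = outputs
        self.sigma2_e = float(sigma2_e)
        self.K = int(K)
        self._dist = distance_matrix(grid)

    @property
    def n_candidates(self) -> int:
        return self.outputs.n_candidates

    def __call__(self, indices: Sequence[int]) -> float:
        design = Design(indices=tuple(indices), K=self.K)
        logL = log_likelihood_matrix(self.outputs, design, self.sigma2_e)
        return float(np.sum(self._dist * _weights_from_log(logL)))
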