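"""Compact wheat phenology model: sowing to heading in three phases.

The model maps a variety's genetic parameters and an environment's daily
temperature / day-length series to a heading date (days after sowing):

1. Sowing → emergence: a fixed thermal-time duration ``tt_em`` (degree-days
   above a 0 °C base).
2. Emergence → flag leaf: leaves appear at one per ``Phyl`` degree-days.
   The final leaf number is ``FLN = l_base + SLDL · max(0, dl_sat − DL)``
   where DL is the day length on the day vernalization saturates (or the
   emergence day if that is later).  Vernalization accumulates daily at
   rate ``VBEE + VAI · T_eff`` from emergence (the seedling, not the dry
   seed, senses cold) until it reaches 1; the effective vernalizing
   temperature ``T_eff = max(0, min(T, t_ceiling − T, t_opt))`` is
   triangular — cool weather vernalizes best, warm autumn weather not at
   all, which is what stretches saturation dates across the season and
   lets field trials separate vernalization genotypes.
3. Flag leaf → heading: a further ``n_tail`` phyllochrons.

Heading therefore occurs when post-emergence thermal time reaches
``(FLN + n_tail) · Phyl``; sub-day resolution is obtained by linear
interpolation of thermal time within the heading day, which avoids
spurious ties between nearby parameter vectors.

The three genetic parameters are the ones with the largest documented
genetic variability for heading time: VAI (response of vernalization rate
to temperature, day⁻¹ °C⁻¹), SLDL (extra leaves per hour of day-length
deficit, leaves h⁻¹) and Phyl (phyllochron, °Cd leaf⁻¹).
"""

from __future__ import annotations

import dataclasses
from collections.abc import Sequence

import numpy as np
import pandas as pd

from .environments import Environment

__all__ = [
    "ModelConstants",
    "ParameterBounds",
    "DEFAULT_CONSTANTS",
    "DEFAULT_BOUNDS",
    "NoHeadingError",
    "prepare_environment",
    "heading_batch",
    "simulate_heading",
    "simulate_phenotypes",
]

PARAM_NAMES = ("VAI", "SLDL", "Phyl")


@dataclasses.dataclass(frozen=True)
class ModelConstants:
    """Non-genetic constants of the phenology model (one config block)."""

    tt_em: float = 150.0      # sowing→emergence thermal time, °Cd
    base_temp: float = 0.0    # base temperature for thermal time, °C
    vbee: float = 0.005       # baseline vernalization rate, day⁻¹
    vern_t_opt: float = 8.0   # most effective vernalizing temperature, °C
    vern_t_ceiling: float = 16.0  # no vernalization progress at or above, °C
    l_base: float = 8.0       # minimum final leaf number, leaves
    dl_sat: float = 15.0      # saturating day length, h
    n_tail: float = 2.0       # ligule→heading, phyllochrons


@dataclasses.dataclass(frozen=True)
class ParameterBounds:
    """Expert lower/upper bounds of the genetic parameters (uniform priors)."""

    names: tuple[str, ...] = PARAM_NAMES
    lower: tuple[float, ...] = (0.0, 0.0, 80.0)
    upper: tuple[float, ...] = (0.01, 1.0, 120.0)

    def __post_init__(self) -> None:
        if not (len(self.names) == len(self.lower) == len(self.upper)):
            raise ValueError("names, lower and upper must have equal length")
        for name, lo, hi in zip(self.names, self.lower, self.upper):
            if not lo < hi:
                raise ValueError(f"bounds for {name} must satisfy lower < upper")

    @property
    def p(self) -> int:
        return len(self.names)

    @property
    def ranges(self) -> np.ndarray:
        return np.asarray(self.upper) - np.asarray(self.lower)

    def contains(self, theta: np.ndarray) -> np.ndarray:
        """Row-wise within-bounds mask for a (n, p) or (p,) array."""
        t = np.atleast_2d(np.asarray(theta, dtype=float))
        return np.all((t >= np.asarray(self.lower)) & (t <= np.asarray(self.upper)), axis=1)


DEFAULT_CONSTANTS = ModelConstants()
DEFAULT_BOUNDS = ParameterBounds()


class NoHeadingError(RuntimeError):
    """The environment's horizon ended before heading was reached."""

    def __init__(self, phase: str, env_id: str, detail: str = ""):
        self.phase = phase
        self.env_id = env_id
        msg = f"no heading in environment {env_id!r}: horizon exhausted during {phase}"
        super().__init__(msg + (f" ({detail})" if detail else ""))


class _EnvCache:
    """Per-environment precomputations shared by all parameter vectors."""

    __slots__ = ("env_id", "cum_tt", "tt_inc", "cum_vern_t", "daylength", "t_em", "day_em")

    def __init__(self, env: Environment, constants: ModelConstants):
        self.env_id = env.env_id
        self.tt_inc = np.maximum(0.0, env.tmean_c - constants.base_temp)
        self.cum_tt = np.cumsum(self.tt_inc)
        # triangular vernalization effectiveness: rises with T to t_opt,
        # falls to zero at the ceiling (warm weather does not vernalize)
        t_eff = np.maximum(
            0.0,
            np.minimum(
                np.minimum(env.tmean_c, constants.vern_t_ceiling - env.tmean_c),
                constants.vern_t_opt,
            ),
        )
        self.cum_vern_t = np.cumsum(t_eff)
        self.daylength = env.daylength_h
        if constants.tt_em > self.cum_tt[-1]:
            raise NoHeadingError("emergence", env.env_id)
        self.t_em = _invert_cum_tt(self.cum_tt, self.tt_inc, np.array([constants.tt_em]))[0]
        self.day_em = int(self.t_em)


def _invert_cum_tt(cum_tt: np.ndarray, tt_inc: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Continuous-time inverse of the piecewise-linear thermal-time curve."""
    idx = np.searchsorted(cum_tt, targets, side="left")
    ok = idx < len(cum_tt)
    idx_c = np.minimum(idx, len(cum_tt) - 1)
    before = np.where(idx_c > 0, cum_tt[idx_c - 1], 0.0)
    inc = tt_inc[idx_c]
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(inc > 0, (targets - before) / inc, 0.0)
    t = idx_c + frac
    return np.where(ok, t, np.inf)


def prepare_environment(env: Environment, constants: ModelConstants = DEFAULT_CONSTANTS) -> _EnvCache:
    """Precompute thermal-time and vernalization accumulators for an environment."""
    return _EnvCache(env, constants)


def heading_batch(
    thetas: np.ndarray,
    env: Environment | _EnvCache,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> np.ndarray:
    """Heading dates (days after sowing) for a batch of parameter vectors.

    ``thetas`` is (n, 3) ordered (VAI, SLDL, Phyl).  Deterministic;
    raises :class:`NoHeadingError` if any vector fails to head within the
    environment's horizon.
    """
    cache = env if isinstance(env, _EnvCache) else _EnvCache(env, constants)
    t = np.atleast_2d(np.asarray(thetas, dtype=float))
    if t.shape[1] != 3:
        raise ValueError("thetas must have 3 columns (VAI, SLDL, Phyl)")
    vai, sldl, phyl = t[:, 0], t[:, 1], t[:, 2]

    n_days = len(cache.cum_tt)
    # vernalization accumulates from emergence; V(end of day d) is linear in VAI:
    # V = vbee·(days since emergence) + VAI·Σ_{emergence..d} clip(T, window)
    days_since_em = np.arange(1, n_days + 1) - cache.day_em
    cum_vern_from_em = cache.cum_vern_t - (cache.cum_vern_t[cache.day_em - 1] if cache.day_em > 0 else 0.0)
    vern = constants.vbee * days_since_em[None, :] + vai[:, None] * cum_vern_from_em[None, :]
    saturated = vern >= 1.0
    if not np.all(saturated[:, -1]):
        raise NoHeadingError("vernalization", cache.env_id)
    day_v = np.argmax(saturated, axis=1)

    dl_day = np.maximum(day_v, cache.day_em)
    dl = cache.daylength[dl_day]
    fln = constants.l_base + sldl * np.maximum(0.0, constants.dl_sat - dl)
    targets = constants.tt_em + (fln + constants.n_tail) * phyl
    heading = _invert_cum_tt(cache.cum_tt, cache.tt_inc, targets)
    if np.any(np.isinf(heading)):
        raise NoHeadingError(
            "leaf production",
            cache.env_id,
            f"{int(np.sum(np.isinf(heading)))} of {len(heading)} vectors",
        )
    return heading


def simulate_heading(
    theta: Sequence[float] | np.ndarray,
    env: Environment,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> float:
    """Heading date (real days after sowing) for one variety in one environment."""
    return float(heading_batch(np.asarray(theta, dtype=float)[None, :], env, constants)[0])


def simulate_phenotypes(
    thetas: pd.DataFrame,
    envs: Sequence[Environment],
    K: int = 1,
    noise_sd: float = 2.0,
    seed: int | None = 0,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> pd.DataFrame:
    """Simulate observed heading dates Y = f(θ, E) + ε across environments.

    ``thetas`` is a DataFrame indexed by genotype_id with columns
    (VAI, SLDL, Phyl).  Each genotype × environment combination is
    replicated ``K`` times with iid centered Gaussian noise of sd
    ``noise_sd`` days (the spread typical of field heading notes).
    Returns a long table (genotype_id, env_id, rep, heading_days).
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    theta_mat = thetas[list(PARAM_NAMES)].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    records = []
    for env in envs:
        try:
            f = heading_batch(theta_mat, env, constants)
        except NoHeadingError as err:
            raise NoHeadingError(err.phase, env.env_id, "during phenotype simulation") from err
        for k in range(1, K + 1):
            noise = rng.normal(0.0, noise_sd, size=len(f)) if noise_sd > 0 else 0.0
            records.append(
                pd.DataFrame(
                    {
                        "genotype_id": thetas.index,
                        "env_id": env.env_id,
                        "rep": k,
                        "heading_days": f + noise,
                    }
                )
            )
    return pd.concat(records, ignore_index=True)
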