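"""Design selection: exchange algorithm, exhaustive oracle and samplers.

The design space (all size-Z subsets of J candidate environments) is far
too large to enumerate at realistic J, so the optimal design is sought
with a greedy exchange algorithm: starting from a random subset, repeatedly
propose swapping one in-design environment (chosen uniformly) with one
out-of-design environment (uniformly) and accept iff the criterion strictly
decreases.  Several independent restarts guard against local optima.

For benchmarking, the module also samples comparison designs: purely
random, random with a fixed winter/spring sowing composition, and
"reasoned" designs that cover all sowing periods, plus a named
expert-knowledge fixture.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from collections.abc import Callable, Sequence

import numpy as np

from .criterion import Design
from .environments import Environment, Site

__all__ = [
    "ExchangeResult",
    "exchange_search",
    "exhaustive_search",
    "sample_designs",
    "WINTER_MONTHS",
    "SPRING_MONTHS",
    "DEFAULT_SOWING_PERIODS",
    "expert_met_sites",
    "expert_met_sowings",
]

#: Sowing-month classification used by the composition-constrained sampler.
WINTER_MONTHS = frozenset({9, 10, 11, 12})
SPRING_MONTHS = frozenset({1, 2, 3, 4, 5})

#: Sowing periods the "reasoned" strategy must all cover (months).
DEFAULT_SOWING_PERIODS: tuple[frozenset[int], ...] = (
    frozenset({10}),          # October
    frozenset({11, 12}),      # November/December
    frozenset({1, 2}),        # January/February
    frozenset({3, 4}),        # March/April
)


@dataclasses.dataclass(frozen=True)
class ExchangeResult:
    """Best design found, its criterion value, and per-restart traces."""

    design: Design
    value: float
    traces: tuple[tuple[float, ...], ...]
    n_evaluations: int


def _resolve_env_ids(candidates, indices: Sequence[int]) -> tuple[str, ...] | None:
    if candidates is None:
        return None
    ids = [c.env_id if isinstance(c, Environment) else str(c) for c in candidates]
    return tuple(ids[i] for i in indices)


def exchange_search(
    candidates: Sequence[Environment] | Sequence[str] | int,
    Z: int,
    criterion_fn: Callable[[tuple[int, ...]], float],
    n_iter: int = 3000,
    n_restarts: int = 4,
    seed: int | None = 0,
    K: int = 1,
) -> ExchangeResult:
    """Minimize a design criterion by random single-environment exchanges.

    ``criterion_fn`` maps a tuple of candidate indices to a scalar (smaller
    is better).  Per restart, a random initial Z-subset is refined over
    ``n_iter`` uniform swap proposals, accepting only strict decreases, so
    each trace is monotone non-increasing.  Ties are rejected.  Returns the
    best design across restarts.
    """
    if isinstance(candidates, int):
        J, cand_seq = candidates, None
    else:
        cand_seq = list(candidates)
        J = len(cand_seq)
    if not 1 <= Z <= J:
        raise ValueError(f"need 1 <= Z <= J, got Z={Z}, J={J}")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")

    rng = np.random.default_rng(seed)
    if Z == J:
        indices = tuple(range(J))
        value = float(criterion_fn(indices))
        design = Design(indices=indices, K=K, env_ids=_resolve_env_ids(cand_seq, indices))
        return ExchangeResult(design, value, ((value,),), 1)

    best_indices: tuple[int, ...] | None = None
    best_value = math.inf
    traces: list[tuple[float, ...]] = []
    n_eval = 0
    for _ in range(n_restarts):
        current = rng.choice(J, size=Z, replace=False).tolist()
        in_design = set(current)
        value = float(criterion_fn(tuple(sorted(current))))
        n_eval += 1
        trace = [value]
        out_pool = [j for j in range(J) if j not in in_design]
        for _ in range(n_iter):
            pos = rng.integers(Z)
            out_pos = rng.integers(J - Z)
            proposal = current.copy()
            proposal[pos], removed = out_pool[out_pos], current[pos]
            new_value = float(criterion_fn(tuple(sorted(proposal))))
            n_eval += 1
            if new_value < value:
                current = proposal
                out_pool[out_pos] = removed
                value = new_value
            trace.append(value)
        traces.append(tuple(trace))
        if value < best_value:
            best_value = value
            best_indices = tuple(sorted(current))

    design = Design(indices=best_indices, K=K, env_ids=_resolve_env_ids(cand_seq, best_indices))
    return ExchangeResult(design, best_value, tuple(traces), n_eval)


def exhaustive_search(
    candidates: Sequence[Environment] | Sequence[str] | int,
    Z: int,
    criterion_fn: Callable[[tuple[int, ...]], float],
    K: int = 1,
    max_subsets: int = 100_000,
) -> tuple[Design, float]:
    """Global minimizer by enumerating all C(J, Z) subsets (small J only).

    Ties are broken deterministically in favor of the lexicographically
    first subset by env_id (candidate order when ids are unavailable).
    """
    if isinstance(candidates, int):
        J, cand_seq = candidates, None
        order = list(range(J))
    else:
        cand_seq = list(candidates)
        J = len(cand_seq)
        ids = [c.env_id if isinstance(c, Environment) else str(c) for c in cand_seq]
        order = sorted(range(J), key=lambda i: ids[i])
    if not 1 <= Z <= J:
        raise ValueError(f"need 1 <= Z <= J, got Z={Z}, J={J}")
    n_subsets = math.comb(J, Z)
    if n_subsets > max_subsets:
        raise ValueError(
            f"C({J},{Z}) = {n_subsets} exceeds the cap {max_subsets}; "
            "use exchange_search instead"
        )
    best = None
    best_value = math.inf
    for combo in itertools.combinations(order, Z):
        value = float(criterion_fn(tuple(sorted(combo))))
        if value < best_value:
            best_value = value
            best = tuple(sorted(combo))
    design = Design(indices=best, K=K, env_ids=_resolve_env_ids(cand_seq, best))
    return design, best_value


def _sowing_month(env: Environment) -> int:
    return env.sowing_date.month


def is_winter_sowing(env: Environment) -> bool:
    return _sowing_month(env) in WINTER_MONTHS


def sample_designs(
    candidates: Sequence[Environment],
    Z: int,
    strategy: str,
    n_samples: int,
    seed: int | None = 0,
    n_winter: int | None = None,
    periods: Sequence[frozenset[int]] | None = None,
    K: int = 1,
    max_tries: int = 100_000,
) -> list[Design]:
    """Sample comparison designs uniformly within a constraint class.

    strategies:
      - ``"random"``: uniform Z-subsets.
      - ``"composition"``: uniform subsets with exactly ``n_winter`` winter
        sowings (months 9-12) and Z − n_winter spring sowings (months 1-5).
      - ``"reasoned"``: uniform subsets in which every sowing period
        (default: Oct; Nov/Dec; Jan/Feb; Mar/Apr) is represented.
    """
    J = len(candidates)
    if not 1 <= Z <= J:
        raise ValueError(f"need 1 <= Z <= J, got Z={Z}, J={J}")
    rng = np.random.default_rng(seed)
    designs: list[Design] = []

    if strategy == "random":
        for _ in range(n_samples):
            idx = tuple(sorted(rng.choice(J, size=Z, replace=False).tolist()))
            designs.append(Design(idx, K=K, env_ids=_resolve_env_ids(candidates, idx)))
        return designs

    if strategy == "composition":
        if n_winter is None or not 0 <= n_winter <= Z:
            raise ValueError("composition strategy needs 0 <= n_winter <= Z")
        winter = [j for j, e in enumerate(candidates) if is_winter_sowing(e)]
        spring = [j for j, e in enumerate(candidates) if _sowing_month(e) in SPRING_MONTHS]
        if len(winter) < n_winter:
            raise ValueError(f"winter class has only {len(winter)} candidates, need {n_winter}")
        if len(spring) < Z - n_winter:
            raise ValueError(f"spring class has only {len(spring)} candidates, need {Z - n_winter}")
        for _ in range(n_samples):
            idx = sorted(
                rng.choice(winter, size=n_winter, replace=False).tolist()
                + rng.choice(spring, size=Z - n_winter, replace=False).tolist()
            )
            designs.append(Design(tuple(idx), K=K, env_ids=_resolve_env_ids(candidates, idx)))
        return designs

    if strategy == "reasoned":
        periods = tuple(periods) if periods is not None else DEFAULT_SOWING_PERIODS
        if Z < len(periods):
            raise ValueError(f"Z={Z} cannot cover {len(periods)} sowing periods")
        members = [
            [j for j, e in enumerate(candidates) if _sowing_month(e) in per] for per in periods
        ]
        for per, mem in zip(periods, members):
            if not mem:
                months = "/".join(str(m) for m in sorted(per))
                raise ValueError(f"no candidate environment in sowing period months {months}")
        # rejection sampling keeps the distribution uniform within the class
        for _ in range(n_samples):
            for _try in range(max_tries):
                idx = sorted(rng.choice(J, size=Z, replace=False).tolist())
                chosen = set(idx)
                if all(chosen.intersection(mem) for mem in members):
                    designs.append(
                        Design(tuple(idx), K=K, env_ids=_resolve_env_ids(candidates, idx))
                    )
                    break
            else:
                raise RuntimeError("could not sample a period-covering design; constraint too tight")
        return designs

    raise ValueError(f"unknown strategy {strategy!r}")


def expert_met_sites() -> list[Site]:
    """The three sites of the expert-knowledge trial network (synthetic coords).

    A North–South latitude (hence photoperiod) gradient with a winter
    sowing at each site; the coordinates are approximate stand-ins.
    """
    return [
        Site("mons", "Mons-en-Chaussee (synthetic)", 49.88),
        Site("versailles", "Versailles (synthetic)", 48.80),
        Site("clermont", "Clermont-Ferrand (synthetic)", 45.78),
    ]


def expert_met_sowings() -> list[tuple[str, str]]:
    """(site_id, month-day) pairs of the expert design.

    Three winter sowings along the latitude gradient plus a spring sowing
    at the southern site, intended to decouple vernalization from
    photoperiod responses.
    """
    return [("mons", "11-15"), ("versailles", "11-15"), ("clermont", "11-15"), ("clermont", "03-15")]


def resolve_design(
    candidates: Sequence[Environment],
    site_date_pairs: Sequence[tuple[str, str]],
    K: int = 1,
) -> Design:
    """Turn (site_id, month-day) pairs into a Design over ``candidates``."""
    indices = []
    for site_id, monthday in site_date_pairs:
        matches = [
            j
            for j, e in enumerate(candidates)
            if e.site.site_id == site_id and e.sowing_date.strftime("%m-%d") == monthday
        ]
        if not matches:
            raise ValueError(f"no candidate environment for site {site_id!r} sown {monthday}")
        indices.append(matches[0])
    idx = tuple(sorted(indices))
    return Design(idx, K=K, env_ids=_resolve_env_ids(candidates, idx))
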