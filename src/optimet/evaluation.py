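"""Design- and estimator-quality metrics.

Two families of error measures, both normalized by a parameter range so
that parameters on very different scales (day⁻¹ °C⁻¹ vs degree-days) are
comparable and can be averaged:

* NRMSE against simulated truth, normalized by the prior (expert) bounds;
* NRMSE* and NPSE against full-data reference estimates, normalized by
  the observed range of the reference estimates themselves.  NPSE
  averages the squared error over the whole posterior (all retained MCMC
  draws), so it also reflects posterior spread, not just the point
  estimate.

Plus Pearson prediction accuracy and a long-format summarizer for
multi-design benchmark runs.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd

from .bayes import Chains

__all__ = [
    "ReferenceEstimates",
    "nrmse",
    "nrmse_star",
    "npse",
    "accuracy",
    "summarize_design_run",
]


@dataclasses.dataclass
class ReferenceEstimates:
    """Full-data parameter estimates used as references when truth is unknown.

    Ranges are the observed max − min of the reference estimates, not the
    prior bounds.
    """

    values: pd.DataFrame          # lines × parameters
    source: str = "full-data Bayesian estimates"

    @property
    def ranges(self) -> pd.Series:
        r = self.values.max() - self.values.min()
        if (r <= 0).any():
            raise ValueError("reference estimates have zero range for some parameter")
        return r


def _aligned(estimates: pd.DataFrame, truth: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    if set(estimates.index) != set(truth.index):
        raise ValueError("estimates and truth must cover the same lines")
    cols = [c for c in truth.columns if c in estimates.columns]
    if not cols:
        raise ValueError("estimates and truth share no parameter columns")
    return estimates.loc[truth.index, cols], truth[cols]


def nrmse(
    estimates: pd.DataFrame,
    truth: pd.DataFrame,
    ranges: Mapping[str, float] | pd.Series,
) -> pd.Series:
    """Per-parameter root-mean-square error normalized by a parameter range.

    NRMSE(θ_s) = sqrt( (1/I) Σ_i ((θ̂_is − θ_is) / R_s)² ).
    """
    est, tru = _aligned(estimates, truth)
    r = pd.Series(ranges).loc[est.columns].astype(float)
    if (r <= 0).any():
        raise ValueError("ranges must be positive")
    scaled = (est.to_numpy() - tru.to_numpy()) / r.to_numpy()
    return pd.Series(np.sqrt(np.mean(scaled**2, axis=0)), index=est.columns)


def nrmse_star(estimates: pd.DataFrame, reference: ReferenceEstimates) -> pd.Series:
    """NRMSE against full-data reference estimates, on their observed ranges."""
    return nrmse(estimates, reference.values, reference.ranges)


def npse(chains: Chains, reference: ReferenceEstimates) -> pd.Series:
    """Normalized posterior square error, averaged over all retained draws.

    NPSE(θ_s) = (1/I) Σ_i (1/K) Σ_k ((θ_isᵏ − θ*_is) / R*_s)², the
    posterior expectation of the normalized squared distance to the
    reference; it always exceeds the squared bias of the chain mean by
    the (normalized) posterior variance.
    """
    if chains.n_retained < 100:
        raise ValueError("need at least 100 retained draws")
    missing = set(chains.genotype_ids) - set(map(str, reference.values.index))
    if missing:
        raise ValueError(f"reference is missing lines present in the chains: {sorted(missing)[:5]}")
    params = [p for p in chains.param_names if p in reference.values.columns]
    theta = chains.retained_theta()          # (K, I, p)
    ref = reference.values.loc[list(chains.genotype_ids), list(chains.param_names)].to_numpy()
    ranges = reference.ranges.loc[list(chains.param_names)].to_numpy()
    scaled = (theta - ref[None, :, :]) / ranges[None, None, :]
    per_param = np.mean(scaled**2, axis=(0, 1))
    out = pd.Series(per_param, index=list(chains.param_names))
    return out.loc[params]


def accuracy(predicted: Sequence[float], observed: Sequence[float]) -> float:
    """Pearson correlation between predicted and observed values."""
    x = np.asarray(predicted, dtype=float)
    y = np.asarray(observed, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need at least 3 matched pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(np.corrcoef(x, y)[0, 1])


def summarize_design_run(records: pd.DataFrame) -> pd.DataFrame:
    """Tidy a benchmark run and append across-parameter means.

    ``records`` is long format with at least (design_id, strategy, year,
    parameter, metric, value).  Rows with parameter == "mean" are added:
    for each (design, strategy, year, metric) the mean of the metric over
    the parameters, which is how multi-parameter criteria are reported.
    """
    required = {"design_id", "strategy", "year", "parameter", "metric", "value"}
    if not required.issubset(records.columns):
        raise ValueError(f"records must have columns {sorted(required)}")
    if len(records) == 0:
        raise ValueError("records is empty")
    base = records.loc[records["parameter"] != "mean"].copy()
    means = (
        base.groupby(["design_id", "strategy", "year", "metric"], as_index=False)["value"]
        .mean()
        .assign(parameter="mean")
    )
    out = pd.concat([base, means], ignore_index=True)
    return out.sort_values(["metric", "design_id", "year", "parameter"]).reset_index(drop=True)
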