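"""Quantitative-genetics machinery for the simulation benchmark.

Synthetic inbred panels with map-structured linkage disequilibrium, trait
architectures of many small-effect QTL (geometric effect series), VanRaden
genomic kinship, G-BLUP genomic prediction with spectral REML, and a
kinship-corrected mixed-model association scan with the
variance-components-estimated-once (P3D) scheme.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .cgm import ParameterBounds

__all__ = [
    "GenotypeData",
    "TraitArchitecture",
    "simulate_genotypes",
    "assign_qtl",
    "vanraden_kinship",
    "gblup_predict",
    "mlm_scan",
    "detection_power",
]


@dataclasses.dataclass
class GenotypeData:
    """Inbred haplotype matrix ({0,1} coding) with a genetic map."""

    matrix: np.ndarray               # (n_lines, M) int8
    map: pd.DataFrame                # marker_id, chrom, pos_cM
    line_ids: tuple[str, ...]
    marker_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        if self.matrix.shape != (len(self.line_ids), len(self.marker_ids)):
            raise ValueError("matrix shape must be (n_lines, n_markers)")
        if list(self.map["marker_id"]) != list(self.marker_ids):
            raise ValueError("map rows must align with marker_ids")
        for _, grp in self.map.groupby("chrom", sort=False):
            if np.any(np.diff(grp["pos_cM"].to_numpy()) < 0):
                raise ValueError("pos_cM must be non-decreasing within a chromosome")

    @property
    def n_lines(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_markers(self) -> int:
        return self.matrix.shape[1]

    def subset_markers(self, keep: np.ndarray) -> "GenotypeData":
        keep = np.asarray(keep)
        return GenotypeData(
            matrix=self.matrix[:, keep],
            map=self.map.iloc[keep].reset_index(drop=True),
            line_ids=self.line_ids,
            marker_ids=tuple(np.asarray(self.marker_ids)[keep]),
        )


@dataclasses.dataclass
class TraitArchitecture:
    """Per-parameter QTL (markers, signed geometric effects) and true values."""

    qtl: dict[str, pd.DataFrame]     # parameter -> (marker_id, chrom, pos_cM, effect)
    true_values: pd.DataFrame        # lines × parameters, within bounds
    rescale: dict[str, tuple[float, float]]   # parameter -> (offset, slope)


def _haldane_recomb_fraction(d_cM: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cM, dtype=float) / 100.0))


def simulate_genotypes(
    n_lines: int,
    n_chrom: int = 7,
    markers_per_chrom: int = 150,
    chrom_length_cM: float = 150.0,
    founder_maf_range: tuple[float, float] = (0.1, 0.5),
    seed: int | None = 0,
) -> GenotypeData:
    """Simulate an inbred panel with distance-decaying LD along a genetic map.

    Each line's haplotype is a mosaic of ancestral segments: walking along
    the map, the allele at a marker copies the previous marker's segment
    with probability 1 − 2r (r the Haldane recombination fraction of the
    interval) and otherwise starts a fresh segment drawn at the marker's
    ancestral frequency (uniform in ``founder_maf_range``, orientation
    randomized).  Markers at zero distance are thus in complete LD and the
    squared allele correlation decays like e^(−4d) with map distance d in
    Morgans.  Monomorphic markers are filtered out.
    """
    if n_lines < 2 or n_chrom < 1 or markers_per_chrom < 2 or chrom_length_cM <= 0:
        raise ValueError("sizes must be positive (and >= 2 lines / markers)")
    lo, hi = founder_maf_range
    if not 0 < lo <= hi <= 0.5:
        raise ValueError("founder_maf_range must satisfy 0 < lo <= hi <= 0.5")
    rng = np.random.default_rng(seed)

    mats, maps, marker_ids = [], [], []
    for c in range(1, n_chrom + 1):
        pos = np.sort(rng.uniform(0.0, chrom_length_cM, size=markers_per_chrom))
        q = rng.uniform(lo, hi, size=markers_per_chrom)
        flip = rng.random(markers_per_chrom) < 0.5
        q = np.where(flip, 1.0 - q, q)

        r = _haldane_recomb_fraction(np.diff(pos))
        p_refresh = np.concatenate([[1.0], 2.0 * r])  # first marker always fresh
        refresh = rng.random((n_lines, markers_per_chrom)) < p_refresh[None, :]
        fresh = rng.random((n_lines, markers_per_chrom)) < q[None, :]
        idx = np.where(refresh, np.arange(markers_per_chrom)[None, :], -1)
        last = np.maximum.accumulate(idx, axis=1)
        mats.append(np.take_along_axis(fresh, last, axis=1).astype(np.int8))
        maps.append(pd.DataFrame({"chrom": c, "pos_cM": pos}))
        marker_ids.extend(f"c{c}m{k + 1}" for k in range(markers_per_chrom))

    matrix = np.concatenate(mats, axis=1)
    map_df = pd.concat(maps, ignore_index=True)
    map_df.insert(0, "marker_id", marker_ids)
    line_ids = tuple(f"L{i + 1:04d}" for i in range(n_lines))
    data = GenotypeData(matrix=matrix, map=map_df, line_ids=line_ids, marker_ids=tuple(marker_ids))

    freq = data.matrix.mean(axis=0)
    poly = (freq > 0) & (freq < 1)
    return data.subset_markers(np.flatnonzero(poly))


def assign_qtl(
    genos: GenotypeData,
    bounds: ParameterBounds,
    n_qtl: int = 25,
    ratio: float = 0.90,
    seed: int | None = 0,
    margin: float = 0.05,
    max_resample: int = 50,
) -> tuple[TraitArchitecture, GenotypeData]:
    """Assign QTL with geometric effect series and derive true parameter values.

    For each genetic parameter, ``n_qtl`` markers are sampled (disjoint
    across parameters) with |effect of the k-th QTL| ∝ ratio^k and random
    signs.  Raw scores X·β are affinely rescaled so the population spans
    [m_s + margin·R_s, M_s − margin·R_s], giving biologically plausible
    values strictly inside the expert bounds.  Returns the architecture
    and the analysis matrix with all QTL columns removed.
    """
    p = bounds.p
    if genos.n_markers <= (p + 1) * n_qtl:
        raise ValueError("need more markers than ~(p+1)·n_qtl to spare an analysis set")
    if not 0 < ratio <= 1:
        raise ValueError("ratio must lie in (0, 1]")
    rng = np.random.default_rng(seed)

    available = np.arange(genos.n_markers)
    qtl_frames: dict[str, pd.DataFrame] = {}
    true_cols = {}
    rescale = {}
    used: list[int] = []
    for s, name in enumerate(bounds.names):
        for _attempt in range(max_resample):
            pool = np.setdiff1d(available, np.array(used, dtype=int))
            chosen = rng.choice(pool, size=n_qtl, replace=False)
            effects = ratio ** np.arange(1, n_qtl + 1)
            effects *= rng.choice([-1.0, 1.0], size=n_qtl)
            raw = genos.matrix[:, chosen].astype(float) @ effects
            if np.ptp(raw) > 1e-12:
                break
        else:
            raise RuntimeError(f"could not find non-degenerate QTL set for {name}")
        used.extend(chosen.tolist())
        lo = bounds.lower[s] + margin * bounds.ranges[s]
        hi = bounds.upper[s] - margin * bounds.ranges[s]
        slope = (hi - lo) / np.ptp(raw)
        offset = lo - slope * raw.min()
        true_cols[name] = offset + slope * raw
        rescale[name] = (float(offset), float(slope))
        qtl_frames[name] = pd.DataFrame(
            {
                "marker_id": np.asarray(genos.marker_ids)[chosen],
                "chrom": genos.map["chrom"].to_numpy()[chosen],
                "pos_cM": genos.map["pos_cM"].to_numpy()[chosen],
                "effect": effects * slope,
            }
        )

    keep = np.setdiff1d(np.arange(genos.n_markers), np.array(used, dtype=int))
    truth = pd.DataFrame(true_cols, index=list(genos.line_ids))
    truth.index.name = "genotype_id"
    arch = TraitArchitecture(qtl=qtl_frames, true_values=truth, rescale=rescale)
    return arch, genos.subset_markers(keep)


def vanraden_kinship(genos: GenotypeData | np.ndarray) -> np.ndarray:
    """VanRaden genomic relationship matrix from 0/1 inbred haplotypes.

    Haplotypes are recoded to homozygote dosages X ∈ {0, 2} and
    G = (X − 2P)(X − 2P)ᵀ / (2 Σ p_l (1 − p_l)) with observed allele
    frequencies p_l.  For fully inbred lines the mean diagonal is ≈ 2
    relative to an outbred base (1 + f with f = 1).
    """
    m01 = genos.matrix if isinstance(genos, GenotypeData) else np.asarray(genos)
    X = 2.0 * m01.astype(float)
    p = X.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if poly.sum() < 2:
        raise ValueError("need at least 2 polymorphic markers for a kinship matrix")
    Xp = X[:, poly]
    pp = p[poly]
    S = Xp - 2.0 * pp
    denom = 2.0 * float(np.sum(pp * (1.0 - pp)))
    return (S @ S.T) / denom


def _reml_profile(d: np.ndarray, yt: np.ndarray, xt: np.ndarray):
    """Restricted log-likelihood of λ = σe²/σg² on the eigenbasis of G."""
    n = len(yt)

    def neg_reml(log_lambda: float) -> float:
        w = d + np.exp(log_lambda)
        sxx = np.sum(xt * xt / w)
        mu = np.sum(xt * yt / w) / sxx
        r = yt - mu * xt
        quad = np.sum(r * r / w)
        sigma_g2 = quad / (n - 1)
        ll = -0.5 * ((n - 1) * np.log(sigma_g2) + np.sum(np.log(w)) + np.log(sxx) + (n - 1))
        return -ll

    return neg_reml


def _fit_lambda(d: np.ndarray, yt: np.ndarray, xt: np.ndarray) -> float:
    neg = _reml_profile(d, yt, xt)
    res = optimize.minimize_scalar(
        neg, bounds=(np.log(1e-4), np.log(1e4)), method="bounded", options={"xatol": 1e-6}
    )
    return float(np.exp(res.x))


def gblup_predict(
    y_train: np.ndarray,
    G: np.ndarray,
    train_idx: Sequence[int],
    test_idx: Sequence[int],
    return_variance_ratio: bool = False,
):
    """G-BLUP predictions for test lines from a trained genomic mixed model.

    Model y = μ + g + e with g ~ N(0, G σg²): the variance ratio
    λ = σe²/σg² is fitted by restricted-likelihood maximization via a
    one-dimensional bounded search on the spectral decomposition of the
    training block, then predictions are
    μ̂ + G_test,train (G_train + λI)⁻¹ (y − μ̂).
    """
    y = np.asarray(y_train, dtype=float)
    train_idx = np.asarray(train_idx, dtype=int)
    test_idx = np.asarray(test_idx, dtype=int)
    if len(y) != len(train_idx):
        raise ValueError("y_train and train_idx must have equal length")
    G_tt = G[np.ix_(train_idx, train_idx)]
    if np.ptp(y) < 1e-14:
        preds = np.full(len(test_idx), y[0] if len(y) else 0.0)
        return (preds, np.inf) if return_variance_ratio else preds

    d, U = np.linalg.eigh(G_tt)
    d = np.maximum(d, 0.0)
    yt = U.T @ y
    xt = U.T @ np.ones(len(y))
    lam = _fit_lambda(d, yt, xt)

    w = d + lam
    sxx = np.sum(xt * xt / w)
    mu = float(np.sum(xt * yt / w) / sxx)
    alpha = U @ ((yt - mu * xt) / w)
    preds = mu + G[np.ix_(test_idx, train_idx)] @ alpha
    return (preds, lam) if return_variance_ratio else preds


def mlm_scan(y: np.ndarray, genos: GenotypeData, G: np.ndarray) -> pd.DataFrame:
    """Single-marker mixed-model association scan with a polygenic background.

    Tests each marker's fixed effect in y = μ + xβ + u + e with
    u ~ N(0, G σg²).  Variance components are estimated once under the
    null and reused for every marker (the population-parameters-
    previously-determined scheme); two-sided p-values come from the Wald
    statistic of β̂ in the variance-whitened regression.
    """
    y = np.asarray(y, dtype=float)
    n = genos.n_lines
    if len(y) != n:
        raise ValueError("y must have one value per line")
    d, U = np.linalg.eigh(G)
    d = np.maximum(d, 0.0)
    yt = U.T @ y
    ones_t = U.T @ np.ones(n)
    lam = _fit_lambda(d, yt, ones_t)
    w_inv_sqrt = 1.0 / np.sqrt(d + lam)

    ys = w_inv_sqrt * yt
    cs = w_inv_sqrt * ones_t
    Xs = (w_inv_sqrt[:, None]) * (U.T @ genos.matrix.astype(float))

    # per-marker OLS of ys on [cs, xs], closed form via 2x2 normal equations
    cc = float(cs @ cs)
    cy = float(cs @ ys)
    cx = cs @ Xs
    xx = np.einsum("ij,ij->j", Xs, Xs)
    xy = ys @ Xs
    det = cc * xx - cx**2
    constant = det <= 1e-10 * np.maximum(cc * xx, 1e-30)
    det_safe = np.where(constant, 1.0, det)
    beta = (cc * xy - cx * cy) / det_safe
    mu = (xx * cy - cx * xy) / det_safe

    rss = float(ys @ ys) - (mu * cy + beta * xy)
    dof = max(n - 2, 1)
    sigma2 = np.maximum(rss, 0.0) / dof
    var_beta = sigma2 * cc / det_safe
    with np.errstate(divide="ignore", invalid="ignore"):
        zstat = beta / np.sqrt(var_beta)
    pvals = 2.0 * stats.norm.sf(np.abs(zstat))
    pvals = np.where(constant, 1.0, pvals)
    beta = np.where(constant, 0.0, beta)

    out = genos.map.copy()
    out["beta"] = beta
    out["pvalue"] = pvals
    out["constant_marker"] = constant
    return out


def detection_power(
    pvalues: pd.DataFrame,
    qtl: pd.DataFrame,
    window_cM: float = 1.0,
    alpha: float = 0.05 / 25,
) -> float:
    """Fraction of simulated QTL with a significant marker within a map window.

    A QTL counts as detected if at least one tested marker on the same
    chromosome, strictly closer than ``window_cM``, has p < ``alpha``.
    QTL with no marker in the window are counted undetected.
    ``pvalues`` is an mlm_scan output; ``qtl`` needs chrom and pos_cM.
    """
    if len(qtl) == 0:
        raise ValueError("no QTL to evaluate")
    detected = 0
    sig = pvalues[pvalues["pvalue"] < alpha]
    for _, row in qtl.iterrows():
        near = sig[
            (sig["chrom"] == row["chrom"])
            & ((sig["pos_cM"] - row["pos_cM"]).abs() < window_cM)
        ]
        if len(near) > 0:
            detected += 1
    return detected / len(qtl)
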