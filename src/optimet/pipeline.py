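"""One-command benchmark of design strategies at desk scale.

The pipeline reproduces, on synthetic data, the full workflow used to
compare trial-network sampling strategies: simulate weather and an inbred
panel with QTL-driven genetic parameters; build candidate environments;
choose designs by criterion minimization, at random (with controlled
winter/spring composition), by a reasoned rule, and from the expert
fixture; phenotype the calibration lines in each design for each
evaluation season; re-estimate the parameters by MCMC; and score every
design by parameter NRMSE, QTL detection power, genomic prediction
accuracy of the validation lines, and heading-time prediction accuracy in
held-out validation environments.

Sizes default to values that keep a full run in the minutes range on one
CPU; every size is reachable from the YAML config, so full survey-scale
runs are a configuration choice, not a code change.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
import time
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import io as oio
from .bayes import MCMCSettings, PriorSpec, run_mcmc
from .cgm import DEFAULT_BOUNDS, DEFAULT_CONSTANTS, PARAM_NAMES, heading_batch, prepare_environment, simulate_phenotypes
from .criterion import Design, OptimetCriterion, build_grid, compute_candidate_outputs
from .environments import ClimateParams, Environment, Site, average_year, build_environments, concat_years, extend_cyclic, generate_synthetic_weather
from .evaluation import accuracy, nrmse, summarize_design_run
from .genetics import assign_qtl, detection_power, gblup_predict, mlm_scan, simulate_genotypes, vanraden_kinship
from .search import exchange_search, expert_met_sites, expert_met_sowings, resolve_design, sample_designs

__all__ = ["Config", "load_config", "save_config", "validate_config", "run_pipeline", "PipelineResult"]


class ConfigError(ValueError):
    pass


@dataclasses.dataclass
class WeatherConfig:
    n_sites: int = 10
    lat_min: float = 43.0
    lat_max: float = 50.5
    n_val_sites: int = 4
    n_avg_years: int = 6
    n_eval_seasons: int = 2
    start_year: int = 2001
    amplitude_c: float = 8.0
    noise_sd: float = 2.5
    rho: float = 0.7


@dataclasses.dataclass
class SowingConfig:
    winter: list[str] = dataclasses.field(default_factory=lambda: ["09-15", "10-15", "11-15"])
    spring: list[str] = dataclasses.field(default_factory=lambda: ["03-15"])
    validation: list[str] = dataclasses.field(default_factory=lambda: ["10-15", "11-15"])


@dataclasses.dataclass
class GenomeConfig:
    n_cal: int = 60
    n_val: int = 120
    n_chrom: int = 7
    markers_per_chrom: int = 150
    chrom_length_cM: float = 150.0
    n_qtl: int = 25
    geometric_ratio: float = 0.90


@dataclasses.dataclass
class CriterionConfig:
    # coarse grids can miss near-aliased parameter pairs and mislead the
    # design search; 8 levels is the smallest resolution we found reliable
    grid_levels: int = 8
    sigma_e: float = 2.0


@dataclasses.dataclass
class DesignConfig:
    Z: int = 4
    K: int = 1
    exchange_iters: int = 800
    exchange_restarts: int = 2
    n_random_per_class: int = 2
    include_expert: bool = True
    include_reasoned: bool = True


@dataclasses.dataclass
class MCMCConfig:
    n_iter: int = 2500
    burn_in: int = 500
    proposal_frac: float = 0.025
    variance_sampler: str = "mh"


@dataclasses.dataclass
class DetectionConfig:
    alpha: float = 0.05 / 25
    window_cM: float = 1.0


@dataclasses.dataclass
class Config:
    """Full pipeline configuration; every field has a runnable default."""

    seed: int = 0
    horizon_days: int = 300
    phenotype_noise_sd: float = 2.0
    weather: WeatherConfig = dataclasses.field(default_factory=WeatherConfig)
    sowings: SowingConfig = dataclasses.field(default_factory=SowingConfig)
    genome: GenomeConfig = dataclasses.field(default_factory=GenomeConfig)
    criterion: CriterionConfig = dataclasses.field(default_factory=CriterionConfig)
    design: DesignConfig = dataclasses.field(default_factory=DesignConfig)
    mcmc: MCMCConfig = dataclasses.field(default_factory=MCMCConfig)
    detection: DetectionConfig = dataclasses.field(default_factory=DetectionConfig)


_SECTIONS = {
    "weather": WeatherConfig,
    "sowings": SowingConfig,
    "genome": GenomeConfig,
    "criterion": CriterionConfig,
    "design": DesignConfig,
    "mcmc": MCMCConfig,
    "detection": DetectionConfig,
}


def _build_section(cls, data: dict[str, Any], prefix: str, errors: list[str]):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    for key in sorted(unknown):
        errors.append(f"unknown key {prefix}{key}")
    return cls(**{k: v for k, v in data.items() if k in known})


def config_from_dict(data: dict[str, Any] | None) -> Config:
    """Build a Config from a (possibly partial) plain dict; unknown keys rejected."""
    data = dict(data or {})
    errors: list[str] = []
    kwargs: dict[str, Any] = {}
    top_known = {f.name for f in dataclasses.fields(Config)}
    for key in sorted(set(data) - top_known):
        errors.append(f"unknown key {key}")
    for name, cls in _SECTIONS.items():
        section = data.get(name, {})
        if section is None:
            section = {}
        if not isinstance(section, dict):
            errors.append(f"section {name} must be a mapping")
            section = {}
        kwargs[name] = _build_section(cls, section, f"{name}.", errors)
    for name in ("seed", "horizon_days", "phenotype_noise_sd"):
        if name in data:
            kwargs[name] = data[name]
    if errors:
        raise ConfigError("invalid configuration: " + "; ".join(errors))
    cfg = Config(**kwargs)
    validate_config(cfg)
    return cfg


def validate_config(cfg: Config) -> Config:
    """Check cross-field consistency; raises ConfigError listing violations."""
    errors = []
    if cfg.weather.n_avg_years < 2:
        errors.append("weather.n_avg_years must be >= 2")
    if cfg.weather.n_eval_seasons < 1:
        errors.append("weather.n_eval_seasons must be >= 1")
    if cfg.horizon_days < 250:
        errors.append("horizon_days must be >= 250")
    n_specs = len(cfg.sowings.winter) + len(cfg.sowings.spring)
    if cfg.design.Z > cfg.weather.n_sites * n_specs:
        errors.append("design.Z exceeds the number of candidate environments")
    if cfg.genome.n_cal < 2 or cfg.genome.n_val < 2:
        errors.append("genome.n_cal and n_val must be >= 2")
    if not 0 < cfg.criterion.sigma_e:
        errors.append("criterion.sigma_e must be > 0")
    if cfg.mcmc.n_iter <= cfg.mcmc.burn_in:
        errors.append("mcmc.n_iter must exceed mcmc.burn_in")
    if errors:
        raise ConfigError("invalid configuration: " + "; ".join(errors))
    return cfg


def config_to_dict(cfg: Config) -> dict[str, Any]:
    return dataclasses.asdict(cfg)


def load_config(path: str | Path | None) -> Config:
    """Load a YAML config; an empty/missing body yields the full default config."""
    if path is None:
        return Config()
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return config_from_dict(data)


def save_config(cfg: Config, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=False)


# ---------------------------------------------------------------------------


def _season_dates(specs: list[str], season_year: int) -> list[dt.date]:
    """Month-day specs to concrete dates: months >= 7 sow in season_year, else +1."""
    out = []
    for spec in specs:
        month, day = map(int, spec.split("-"))
        out.append(dt.date(season_year if month >= 7 else season_year + 1, month, day))
    return out


def _candidate_sites(cfg: Config) -> tuple[list[Site], list[Site]]:
    """Candidate sites (expert trio + synthetic latitude fill) and validation sites."""
    sites = list(expert_met_sites())
    n_extra = max(cfg.weather.n_sites - len(sites), 0)
    lats = np.linspace(cfg.weather.lat_min, cfg.weather.lat_max, n_extra) if n_extra else []
    sites += [Site(f"s{i + 1:02d}", f"synthetic site {i + 1}", float(lat)) for i, lat in enumerate(lats)]
    sites = sites[: cfg.weather.n_sites]
    val_lats = np.linspace(cfg.weather.lat_min + 0.7, cfg.weather.lat_max - 0.7, cfg.weather.n_val_sites)
    val_sites = [Site(f"v{i + 1:02d}", f"validation site {i + 1}", float(lat)) for i, lat in enumerate(val_lats)]
    return sites, val_sites


@dataclasses.dataclass
class PipelineResult:
    report: pd.DataFrame
    designs: dict[str, Design]
    strategies: dict[str, str]
    out_dir: Path
    timings: dict[str, float]


def run_pipeline(
    config: Config | None = None,
    out_dir: str | Path = "optimet_run",
    seed: int | None = None,
    resume: bool = False,
) -> PipelineResult:
    """Run the full design-strategy benchmark; deterministic under seed.

    ``seed`` overrides ``config.seed``.  Artifacts land in ``out_dir``
    (weather/, genotypes/, designs/, chains/, report.tsv, log.txt).  With
    ``resume=True`` the per-design MCMC stage reuses estimate tables
    already present in chains/, making interrupted runs resumable at the
    expensive stage.
    """
    cfg = validate_config(config or Config())
    seed = cfg.seed if seed is None else int(seed)
    master = np.random.SeedSequence(seed)
    seeds = master.generate_state(6) % (2**31)
    out = Path(out_dir)
    for sub in ("weather", "genotypes", "designs", "chains"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    log_lines: list[str] = []

    def stage(name):
        t0 = time.perf_counter()

        def done():
            timings[name] = time.perf_counter() - t0
            log_lines.append(f"{name}: {timings[name]:.2f} s")

        return done

    # --- stage 1: sites and weather -------------------------------------
    end = stage("weather")
    sites, val_sites = _candidate_sites(cfg)
    wcfg = cfg.weather
    n_years_total = wcfg.n_avg_years + wcfg.n_eval_seasons + 2
    climate = ClimateParams(amplitude_c=wcfg.amplitude_c, noise_sd=wcfg.noise_sd, rho=wcfg.rho)
    all_series = generate_synthetic_weather(
        sites + val_sites, n_years_total, climate, seed=int(seeds[0]), start_year=wcfg.start_year
    )
    by_site: dict[str, list] = {}
    for s in all_series:
        by_site.setdefault(s.site_id, []).append(s)
    continuous = {sid: concat_years(lst) for sid, lst in by_site.items()}
    avg_by_site = {
        sid: extend_cyclic(average_year(lst[: wcfg.n_avg_years]), 2 * 366)
        for sid, lst in by_site.items()
    }
    oio.write_sites(sites + val_sites, out / "weather" / "sites.tsv")
    end()

    # --- stage 2: genotypes, QTL, calibration/validation split ----------
    end = stage("genetics")
    g = cfg.genome
    genos_full = simulate_genotypes(
        g.n_cal + g.n_val,
        n_chrom=g.n_chrom,
        markers_per_chrom=g.markers_per_chrom,
        chrom_length_cM=g.chrom_length_cM,
        seed=int(seeds[1]),
    )
    arch, genos = assign_qtl(
        genos_full, DEFAULT_BOUNDS, n_qtl=g.n_qtl, ratio=g.geometric_ratio, seed=int(seeds[2])
    )
    rng_split = np.random.default_rng(int(seeds[3]))
    perm = rng_split.permutation(genos.n_lines)
    cal_idx = np.sort(perm[: g.n_cal])
    val_idx = np.sort(perm[g.n_cal : g.n_cal + g.n_val])
    cal_ids = [genos.line_ids[i] for i in cal_idx]
    kinship = vanraden_kinship(genos)
    truth = arch.true_values
    oio.write_genotypes(genos, out / "genotypes" / "genotypes.tsv", out / "genotypes" / "map.tsv")
    truth.to_csv(out / "genotypes" / "true_parameters.tsv", sep="\t")
    end()

    # --- stage 3: candidate environments and design selection -----------
    end = stage("designs")
    sowing_specs = list(cfg.sowings.winter) + list(cfg.sowings.spring)
    avg_dates = _season_dates(sowing_specs, wcfg.start_year)
    avg_envs = build_environments(sites, avg_dates, avg_by_site, cfg.horizon_days)
    grid = build_grid(DEFAULT_BOUNDS, cfg.criterion.grid_levels)
    outputs = compute_candidate_outputs(grid, avg_envs)
    crit = OptimetCriterion(grid, outputs, sigma2_e=cfg.criterion.sigma_e**2, K=cfg.design.K)

    designs: dict[str, Design] = {}
    strategies: dict[str, str] = {}
    result = exchange_search(
        avg_envs,
        cfg.design.Z,
        crit,
        n_iter=cfg.design.exchange_iters,
        n_restarts=cfg.design.exchange_restarts,
        seed=int(seeds[4]),
        K=cfg.design.K,
    )
    designs["optimet"] = result.design
    strategies["optimet"] = "optimet"
    trace_rows = [
        {"restart": r, "iteration": i, "value": v}
        for r, tr in enumerate(result.traces)
        for i, v in enumerate(tr)
    ]
    pd.DataFrame(trace_rows).to_csv(out / "designs" / "exchange_trace.tsv", sep="\t", index=False)

    rng_designs = np.random.default_rng(int(seeds[5]))
    for n_winter in range(cfg.design.Z + 1):
        try:
            sampled = sample_designs(
                avg_envs,
                cfg.design.Z,
                "composition",
                cfg.design.n_random_per_class,
                seed=int(rng_designs.integers(2**31)),
                n_winter=n_winter,
                K=cfg.design.K,
            )
        except ValueError:
            continue  # class infeasible with this candidate composition
        for i, d in enumerate(sampled):
            designs[f"random_w{n_winter}_{i + 1}"] = d
            strategies[f"random_w{n_winter}_{i + 1}"] = "random"
    if cfg.design.include_reasoned:
        periods = [frozenset({int(spec.split("-")[0])}) for spec in sowing_specs]
        for i, d in enumerate(
            sample_designs(
                avg_envs,
                cfg.design.Z,
                "reasoned",
                1,
                seed=int(rng_designs.integers(2**31)),
                periods=periods,
                K=cfg.design.K,
            )
        ):
            designs["reasoned"] = d
            strategies["reasoned"] = "reasoned"
    if cfg.design.include_expert:
        try:
            designs["expert"] = resolve_design(avg_envs, expert_met_sowings(), K=cfg.design.K)
            strategies["expert"] = "expert"
        except ValueError:
            pass  # expert sites/sowings not among the candidates in this config
    with open(out / "designs" / "designs.json", "w") as fh:
        json.dump(
            {
                name: {"env_ids": list(d.env_ids), "K": d.K, "strategy": strategies[name]}
                for name, d in designs.items()
            },
            fh,
            indent=2,
        )
        fh.write("\n")
    end()

    # --- stage 4: per-season phenotyping, estimation and scoring --------
    end = stage("evaluation")
    records = []
    eval_rng = np.random.default_rng(int(master.generate_state(7)[-1] % (2**31)))
    prior = PriorSpec(bounds=DEFAULT_BOUNDS)
    theta_cal = truth.loc[cal_ids]
    for season_i in range(wcfg.n_eval_seasons):
        season_year = wcfg.start_year + wcfg.n_avg_years + season_i
        season_dates = _season_dates(sowing_specs, season_year)
        season_envs = build_environments(sites, season_dates, continuous, cfg.horizon_days)
        val_dates = _season_dates(list(cfg.sowings.validation), season_year)
        val_envs = build_environments(val_sites, val_dates, continuous, cfg.horizon_days)
        val_truth = _heading_table(truth.iloc[val_idx], val_envs)

        for name, design in designs.items():
            est_path = out / "chains" / f"estimates_{name}_y{season_year}.tsv"
            if resume and est_path.exists():
                estimates = pd.read_csv(est_path, sep="\t", index_col=0)
                estimates.index = estimates.index.astype(str)
            else:
                design_envs = [season_envs[j] for j in design.indices]
                phenos = simulate_phenotypes(
                    theta_cal,
                    design_envs,
                    K=design.K,
                    noise_sd=cfg.phenotype_noise_sd,
                    seed=int(eval_rng.integers(2**31)),
                )
                chains = run_mcmc(
                    phenos,
                    design_envs,
                    priors=prior,
                    settings=MCMCSettings(
                        n_iter=cfg.mcmc.n_iter,
                        burn_in=cfg.mcmc.burn_in,
                        proposal_frac=cfg.mcmc.proposal_frac,
                        variance_sampler=cfg.mcmc.variance_sampler,
                        seed=int(eval_rng.integers(2**31)),
                    ),
                )
                estimates = chains.estimates()
                estimates.to_csv(est_path, sep="\t")

            err = nrmse(estimates, theta_cal, dict(zip(DEFAULT_BOUNDS.names, DEFAULT_BOUNDS.ranges)))
            for param, value in err.items():
                records.append(_rec(name, strategies[name], season_year, param, "nrmse", value))

            # QTL detection and genomic prediction from the estimates
            for param in PARAM_NAMES:
                y_cal = estimates.loc[cal_ids, param].to_numpy()
                if np.ptp(y_cal) < 1e-12:
                    power = 0.0
                    acc_param = np.nan
                else:
                    scan = mlm_scan(
                        y_cal, _subset_lines(genos, cal_idx), kinship[np.ix_(cal_idx, cal_idx)]
                    )
                    power = detection_power(
                        scan, arch.qtl[param], window_cM=cfg.detection.window_cM, alpha=cfg.detection.alpha
                    )
                    preds = gblup_predict(y_cal, kinship, cal_idx, val_idx)
                    acc_param = accuracy(preds, truth.iloc[val_idx][param].to_numpy())
                records.append(_rec(name, strategies[name], season_year, param, "power", power))
                records.append(
                    _rec(name, strategies[name], season_year, param, "accuracy_param", acc_param)
                )

            # validation heading-time prediction through the crop model
            pred_params = pd.DataFrame(
                {
                    param: np.clip(
                        gblup_predict(estimates.loc[cal_ids, param].to_numpy(), kinship, cal_idx, val_idx)
                        if np.ptp(estimates.loc[cal_ids, param].to_numpy()) >= 1e-12
                        else np.full(len(val_idx), estimates.loc[cal_ids, param].mean()),
                        DEFAULT_BOUNDS.lower[s],
                        DEFAULT_BOUNDS.upper[s],
                    )
                    for s, param in enumerate(PARAM_NAMES)
                },
                index=[genos.line_ids[i] for i in val_idx],
            )
            val_pred = _heading_table(pred_params, val_envs)
            records.append(
                _rec(
                    name, strategies[name], season_year, "all", "heading_accuracy",
                    accuracy(val_pred.to_numpy().ravel(), val_truth.to_numpy().ravel()),
                )
            )
            records.append(
                _rec(
                    name, strategies[name], season_year, "all", "heading_rmse",
                    float(np.sqrt(np.mean((val_pred.to_numpy() - val_truth.to_numpy()) ** 2))),
                )
            )
    end()

    report = summarize_design_run(pd.DataFrame.from_records(records))
    report.to_csv(out / "report.tsv", sep="\t", index=False)
    (out / "log.txt").write_text("\n".join(log_lines) + "\n")
    return PipelineResult(report=report, designs=designs, strategies=strategies, out_dir=out, timings=timings)


def _rec(design_id, strategy, year, parameter, metric, value) -> dict[str, Any]:
    return {
        "design_id": design_id,
        "strategy": strategy,
        "year": year,
        "parameter": parameter,
        "metric": metric,
        "value": float(value) if value == value else np.nan,
    }


def _subset_lines(genos, line_idx):
    from .genetics import GenotypeData

    line_idx = np.asarray(line_idx, dtype=int)
    return GenotypeData(
        matrix=genos.matrix[line_idx],
        map=genos.map,
        line_ids=tuple(genos.line_ids[i] for i in line_idx),
        marker_ids=genos.marker_ids,
    )


def _heading_table(thetas: pd.DataFrame, envs: list[Environment]) -> pd.DataFrame:
    """Noise-free heading dates, lines × environments."""
    theta_mat = thetas[list(PARAM_NAMES)].to_numpy(dtype=float)
    cols = {}
    for env in envs:
        cache = prepare_environment(env, DEFAULT_CONSTANTS)
        cols[env.env_id] = heading_batch(theta_mat, cache)
    return pd.DataFrame(cols, index=thetas.index)
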