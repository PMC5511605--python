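"""Plain-text (TSV / JSON) readers and writers for the package's tables.

All tabular interchange is tab-separated UTF-8 with a header row and `.`
decimals; designs travel as small JSON objects.  Pandas does the actual
parsing.
"""

from __future__ import annotations

import datetime as dt
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .criterion import CandidateOutputs, Design, ParameterGrid
from .cgm import ParameterBounds
from .environments import Site, WeatherSeries
from .genetics import GenotypeData

__all__ = [
    "read_sites",
    "write_sites",
    "read_weather",
    "write_weather",
    "read_phenotypes",
    "write_phenotypes",
    "read_genotypes",
    "write_genotypes",
    "read_design",
    "write_design",
    "read_outputs",
    "write_outputs",
    "read_grid",
    "write_grid",
]


def read_sites(path: str | Path) -> list[Site]:
    df = pd.read_csv(path, sep="\t")
    return [
        Site(str(r.site_id), str(r.name), float(r.latitude_deg)) for r in df.itertuples(index=False)
    ]


def write_sites(sites, path: str | Path) -> None:
    pd.DataFrame(
        [{"site_id": s.site_id, "name": s.name, "latitude_deg": s.latitude_deg} for s in sites]
    ).to_csv(path, sep="\t", index=False)


def read_weather(path: str | Path) -> dict[str, WeatherSeries]:
    """Weather TSV (site_id, date, tmean_c) → one series per site."""
    df = pd.read_csv(path, sep="\t", parse_dates=["date"])
    out = {}
    for site_id, grp in df.groupby("site_id", sort=False):
        grp = grp.sort_values("date")
        out[str(site_id)] = WeatherSeries(
            str(site_id), pd.DatetimeIndex(grp["date"]), grp["tmean_c"].to_numpy(dtype=float)
        )
    return out


def write_weather(series_list, path: str | Path) -> None:
    frames = [
        pd.DataFrame({"site_id": s.site_id, "date": s.dates.strftime("%Y-%m-%d"), "tmean_c": s.tmean_c})
        for s in series_list
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"genotype_id": str})


def write_phenotypes(phenos: pd.DataFrame, path: str | Path) -> None:
    phenos.to_csv(path, sep="\t", index=False)


def read_genotypes(genotype_path: str | Path, map_path: str | Path) -> GenotypeData:
    """Genotype TSV (first column line_id, remaining columns markers) + map TSV."""
    geno = pd.read_csv(genotype_path, sep="\t", index_col=0)
    map_df = pd.read_csv(map_path, sep="\t")
    map_df = map_df.set_index("marker_id").loc[list(geno.columns)].reset_index()
    return GenotypeData(
        matrix=geno.to_numpy(dtype=np.int8),
        map=map_df,
        line_ids=tuple(map(str, geno.index)),
        marker_ids=tuple(map(str, geno.columns)),
    )


def write_genotypes(genos: GenotypeData, genotype_path: str | Path, map_path: str | Path) -> None:
    pd.DataFrame(genos.matrix, index=list(genos.line_ids), columns=list(genos.marker_ids)).to_csv(
        genotype_path, sep="\t", index_label="line_id"
    )
    genos.map.to_csv(map_path, sep="\t", index=False)


def read_design(path: str | Path, env_ids: list[str] | None = None) -> Design:
    """Design JSON {"env_ids": [...], "K": int}; indices resolved if a candidate list is given."""
    with open(path) as fh:
        obj = json.load(fh)
    ids = [str(e) for e in obj["env_ids"]]
    if env_ids is not None:
        lookup = {e: j for j, e in enumerate(env_ids)}
        missing = [e for e in ids if e not in lookup]
        if missing:
            raise ValueError(f"design references unknown environments: {missing[:5]}")
        indices = tuple(lookup[e] for e in ids)
    else:
        indices = tuple(range(len(ids)))
    return Design(indices=indices, K=int(obj.get("K", 1)), env_ids=tuple(ids))


def write_design(design: Design, path: str | Path) -> None:
    if design.env_ids is None:
        raise ValueError("design has no env_ids; resolve it against a candidate list first")
    with open(path, "w") as fh:
        json.dump({"env_ids": list(design.env_ids), "K": design.K}, fh, indent=2)
        fh.write("\n")


def read_outputs(path: str | Path) -> CandidateOutputs:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CandidateOutputs(outputs=df.to_numpy(dtype=float), env_ids=tuple(map(str, df.columns)))


def write_outputs(outputs: CandidateOutputs, path: str | Path) -> None:
    pd.DataFrame(outputs.outputs, columns=list(outputs.env_ids)).to_csv(
        path, sep="\t", index_label="grid_index"
    )


def read_grid(path: str | Path, bounds: ParameterBounds) -> ParameterGrid:
    df = pd.read_csv(path, sep="\t")
    return ParameterGrid(values=df[list(bounds.names)].to_numpy(dtype=float), bounds=bounds)


def write_grid(grid: ParameterGrid, path: str | Path) -> None:
    pd.DataFrame(grid.values, columns=list(grid.bounds.names)).to_csv(path, sep="\t", index=False)
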