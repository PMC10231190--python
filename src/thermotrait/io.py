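"""Readers, writers, run configuration and the end-to-end pipeline driver.

Rate tables are long-format CSV (``site_id, process, temperature_c, rate,
unit``); sites are one CSV row per site; ASV tables are TSV with ASV rows
and sample columns (an optional ``taxonomy`` column is split off).  Every
output file starts with a provenance comment carrying the package version,
the configuration hash and the seed, so identical configurations yield
identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .community import (AsvTable, asv_trait_screen, bray_curtis,
                        even_depth_transform, filter_asvs, fit_vector, nmds,
                        richness, shannon)
from .curves import PROCESS_UNITS, PROCESSES, RateCurve
from .simulate import (SurveyConfig, curves_from_table, generate_community,
                       generate_curves, generate_sites, generate_trait_params)
from .traits import fit_survey, regress_trait

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "read_rate_table", "read_sites", "read_asv_table",
           "write_with_provenance", "config_hash", "run_all"]

RATE_COLUMNS = ("site_id", "process", "temperature_c", "rate")


def read_rate_table(path) -> list[RateCurve]:
    """Read a long-format rate CSV into RateCurve objects.

    Validates the schema, flags duplicate (site, process, temperature) rows
    and non-numeric rates with their row numbers, warns on unit strings that
    do not match the process, and clamps small negative rates to zero.
    """
    df = pd.read_csv(path, comment="#")
    missing = [c for c in RATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    bad_proc = set(df["process"].unique()) - set(PROCESSES)
    if bad_proc:
        raise ValueError(f"{path}: unknown process(es) {sorted(bad_proc)}")
    rates = pd.to_numeric(df["rate"], errors="coerce")
    if rates.isna().any():
        row = int(df.index[rates.isna()][0]) + 2  # header + 1-based
        raise ValueError(f"{path}: non-numeric rate at row {row}")
    df["rate"] = rates
    dup = df.duplicated(subset=["site_id", "process", "temperature_c"])
    if dup.any():
        row = int(df.index[dup][0]) + 2
        raise ValueError(f"{path}: duplicate (site, process, temperature) at row {row}")
    if "unit" in df.columns:
        for process, grp in df.groupby("process", observed=True):
            expected = PROCESS_UNITS[str(process)]
            odd = set(grp["unit"].dropna().unique()) - {expected}
            if odd:
                warnings.warn(
                    f"{path}: unit {sorted(odd)} for process {process!r} "
                    f"(expected {expected!r})", UserWarning, stacklevel=2)
    return curves_from_table(df)


SITE_COLUMNS = ("site_id", "mat")


def read_sites(path) -> pd.DataFrame:
    """Read the site metadata CSV (site_id and MAT required)."""
    df = pd.read_csv(path, comment="#")
    missing = [c for c in SITE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    if df["site_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate site_id")
    return df


def read_asv_table(path, marker: str = "16S") -> AsvTable:
    """Read a TSV ASV table (ASV rows x sample columns, optional taxonomy)."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    taxonomy = None
    if "taxonomy" in df.columns:
        taxonomy = df.pop("taxonomy")
    counts = df.T  # samples x ASVs
    if not np.issubdtype(counts.to_numpy().dtype, np.number):
        raise ValueError(f"{path}: non-numeric counts")
    return AsvTable(counts, marker, taxonomy)


def config_hash(obj) -> str:
    """Stable short hash of a configuration mapping.

    The output directory is excluded: it determines where results go, not
    what they are, and equal hashes must imply identical outputs.
    """
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)
    if isinstance(obj, dict):
        obj = {k: v for k, v in obj.items() if k != "out_dir"}
    payload = json.dumps(obj, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def write_with_provenance(df: pd.DataFrame, path, cfg_hash: str, seed,
                          sep: str = ",", index: bool = False) -> None:
    """Write a table with a leading provenance comment line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# thermotrait {__version__} config_hash={cfg_hash} seed={seed}\n")
        df.to_csv(fh, sep=sep, index=index)


@dataclass
class RunConfig:
    """End-to-end run settings; round-trips losslessly through YAML."""

    out_dir: str
    seed: int = 1
    simulate: bool = True
    rates_path: str | None = None
    sites_path: str | None = None
    asv_paths: dict = field(default_factory=dict)  # marker -> path
    processes: tuple = PROCESSES
    q10_interval: tuple = (5.0, 15.0)
    n_permutations: int = 999
    community_stage: bool = True
    survey: dict = field(default_factory=dict)  # overrides for SurveyConfig

    def __post_init__(self):
        self.processes = tuple(self.processes)
        self.q10_interval = tuple(self.q10_interval)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        def plain(obj):
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            return obj

        with open(path, "w") as fh:
            yaml.safe_dump(plain(dataclasses.asdict(self)), fh, sort_keys=True)

    def survey_config(self) -> SurveyConfig:
        return SurveyConfig(seed=self.seed, **self.survey)


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


def run_all(config: RunConfig) -> dict:
    """simulate (optional) -> fit -> regress -> community, writing all outputs.

    Returns a dict of output paths.  Any stage failure aborts with a
    stage-labelled error.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    seed = config.seed
    paths: dict[str, Path] = {}

    if config.simulate:
        sites, curves, communities, truth = _simulate_stage(config, out, chash, paths)
    else:
        if not (config.rates_path and config.sites_path):
            raise RuntimeError("stage 'input' failed: rates_path and sites_path "
                               "are required when simulate is off")
        curves = read_rate_table(config.rates_path)
        sites = read_sites(config.sites_path)
        communities = {m: read_asv_table(p, m) for m, p in config.asv_paths.items()}
        truth = None

    indices = _fit_stage(config, curves)
    paths["fits"] = out / "fits.csv"
    write_with_provenance(indices, paths["fits"], chash, seed)

    stats_df = _regress_stage(config, indices, sites)
    paths["stats"] = out / "stats.csv"
    write_with_provenance(stats_df, paths["stats"], chash, seed)

    if config.community_stage:
        if not communities:
            raise RuntimeError("stage 'community' failed: no ASV table available")
        _community_stage(config, communities, indices, sites, out, chash, paths)

    provenance = {"version": __version__, "config_hash": chash, "seed": seed,
                  "outputs": {k: str(v) for k, v in paths.items()}}
    if truth is not None:
        provenance["truth"] = {m: t for m, t in truth.items()}
    with open(out / "run.json", "w") as fh:
        json.dump(provenance, fh, indent=2, default=str)
    paths["run"] = out / "run.json"
    return paths


@_stage("simulate")
def _simulate_stage(config, out, chash, paths):
    survey = config.survey_config()
    sites = generate_sites(survey)
    params = generate_trait_params(sites, survey)
    table = generate_curves(params, survey)
    paths["sites"] = out / "sites.csv"
    paths["rates"] = out / "rates.csv"
    paths["truth_params"] = out / "truth_params.csv"
    write_with_provenance(sites, paths["sites"], chash, config.seed)
    write_with_provenance(table, paths["rates"], chash, config.seed)
    write_with_provenance(params, paths["truth_params"], chash, config.seed)
    communities, truth = {}, {}
    if config.community_stage:
        for marker in ("16S", "ITS"):
            tab, tr = generate_community(sites, params, survey, marker=marker)
            communities[marker] = tab
            truth[marker] = tr
            p = out / f"asv_{marker.lower()}.tsv"
            paths[f"asv_{marker}"] = p
            write_with_provenance(tab.counts.T, p, chash, config.seed,
                                  sep="\t", index=True)
    return sites, curves_from_table(table), communities, truth


@_stage("fit")
def _fit_stage(config, curves):
    curves = [c for c in curves if c.process in config.processes]
    return fit_survey(curves, q10_interval=config.q10_interval)


@_stage("regress")
def _regress_stage(config, indices, sites):
    rows = []
    traits_by_process = {
        "bacterial_growth": ("t_min", "t_opt", "t_max", "q10"),
        "fungal_growth": ("t_min", "t_opt", "t_max", "q10"),
        "respiration": ("t_min", "q10"),
    }
    for process in config.processes:
        for trait in traits_by_process[process]:
            try:
                res = regress_trait(indices, sites, trait, process)
            except ValueError as exc:
                logger.warning("regression skipped (%s %s): %s", process, trait, exc)
                continue
            rows.append({"analysis": "trait_vs_mat", "process": process,
                         "trait": trait, "term": "mat", "estimate": res.slope,
                         "se": res.slope_se, "F": res.f_stat, "df1": res.df1,
                         "df2": res.df2, "p": res.p_value,
                         "r_squared": res.r_squared})
    return pd.DataFrame(rows)


@_stage("community")
def _community_stage(config, communities, indices, sites, out, chash, paths):
    marker_process = {"16S": "bacterial_growth", "ITS": "fungal_growth"}
    div_rows, vec_rows = [], []
    for marker, table in communities.items():
        for sample in table.sample_ids:
            counts = table.counts.loc[sample].to_numpy()
            div_rows.append({"marker": marker, "sample_id": sample,
                             "shannon": shannon(counts),
                             "richness": richness(counts)})
        filtered = even_depth_transform(filter_asvs(table))
        ord_res = nmds(bray_curtis(filtered), seed=config.seed)
        coords = ord_res.coordinates.reset_index(names="sample_id")
        coords.insert(0, "marker", marker)
        pkey = f"ordination_{marker}"
        paths[pkey] = out / f"{pkey.lower()}.csv"
        write_with_provenance(coords, paths[pkey], chash, config.seed)

        process = marker_process[marker]
        tmin = (indices[indices["process"] == process]
                .set_index("site_id")["t_min"]
                .reindex(table.sample_ids))
        variables = {"t_min": tmin.to_numpy(float),
                     "mat": sites.set_index("site_id")["mat"]
                                 .reindex(table.sample_ids).to_numpy(float),
                     "ph": sites.set_index("site_id")["ph"]
                                .reindex(table.sample_ids).to_numpy(float)}
        for name, vals in variables.items():
            if np.isnan(vals).any():
                continue
            vf = fit_vector(ord_res, vals, name=name,
                            n_perm=config.n_permutations, seed=config.seed)
            vec_rows.append({"marker": marker, "variable": name,
                             "r_squared": vf.r_squared, "p_perm": vf.p_perm,
                             "n_permutations": vf.n_permutations})
        if not tmin.isna().any():
            screen = asv_trait_screen(filtered, tmin.to_numpy(float))
            res = screen["results"].reset_index(names="asv_id")
            res.insert(0, "marker", marker)
            skey = f"screen_{marker}"
            paths[skey] = out / f"{skey.lower()}.csv"
            write_with_provenance(res, paths[skey], chash, config.seed)

    paths["diversity"] = out / "diversity.csv"
    write_with_provenance(pd.DataFrame(div_rows), paths["diversity"], chash,
                          config.seed)
    paths["vectors"] = out / "vectors.csv"
    write_with_provenance(pd.DataFrame(vec_rows), paths["vectors"], chash,
                          config.seed)
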