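"""Synthetic survey generator calibrated to the continental-gradient study design.

Emulates a 72-site survey spanning mean annual temperatures (MAT) from -3.1
to 18.3 degC, with square-root-model rate curves measured at 0-45 degC in
5 degC steps for three processes (bacterial growth, fungal growth,
respiration), trait-climate linear structure, an optional paired
summer/winter subset, and amplicon count tables whose composition turns
over along the Tmin and pH gradients.

Default trait-climate models (Tmin = beta0 + beta1 * MAT + noise):

==================  ======  ======  =====  =================
process             beta0   beta1   sigma  implied Tmin range
==================  ======  ======  =====  =================
bacterial_growth    -11.0    0.20    2.2   about -14 .. -5
fungal_growth        -8.0    0.07    1.8   about -11 .. -4
respiration          -5.8    0.10    1.1   about  -8 .. -2
==================  ======  ======  =====  =================

beta1 values are the field-survey coefficients; beta0 and sigma are
back-computed so that the Tmin ranges and the regression R^2 implied by the
survey's printed F statistics are reproduced (see docs/methods.md).
Measurement noise is added on the sqrt-rate scale, the scale on which the
model is fitted.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .community import AsvTable
from .curves import GROWTH_PROCESSES, PROCESS_UNITS, PROCESSES, RateCurve
from .ratkowsky import ratkowsky_sqrt_rate

__all__ = [
    "TraitClimateModel",
    "CommunityConfig",
    "SurveyConfig",
    "generate_sites",
    "generate_trait_params",
    "generate_curves",
    "generate_paired_subset",
    "generate_community",
    "curves_from_table",
]

# stage tags entering the per-stage seed streams
_STAGE = {"sites": 0, "traits": 1, "curves": 2, "paired": 3, "community": 4}


def _rng(seed: int, stage: str, extra: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STAGE[stage], extra]))


@dataclass
class TraitClimateModel:
    """Linear Tmin-climate model plus draw ranges for the remaining parameters."""

    intercept: float  # degC at MAT = 0
    slope: float      # degC Tmin per degC MAT
    sd: float         # residual scatter of Tmin, degC
    a_range: tuple = (0.02, 0.06)          # sqrt-rate per degC
    b_range: tuple | None = (0.08, 0.18)   # per degC; None = no optimum (Eq-2 only)
    t_max_range: tuple | None = (43.0, 51.0)


DEFAULT_TRAIT_MODELS = {
    "bacterial_growth": TraitClimateModel(-11.0, 0.20, 2.2,
                                          a_range=(0.02, 0.06),
                                          b_range=(0.08, 0.18),
                                          t_max_range=(43.0, 51.0)),
    "fungal_growth": TraitClimateModel(-8.0, 0.07, 1.8,
                                       a_range=(0.015, 0.05),
                                       b_range=(0.08, 0.30),
                                       t_max_range=(40.0, 52.0)),
    "respiration": TraitClimateModel(-5.8, 0.10, 1.1,
                                     a_range=(0.02, 0.06),
                                     b_range=None, t_max_range=None),
}


@dataclass
class CommunityConfig:
    """Settings for the synthetic ASV table.

    Planted warm/cold ASVs have log-abundance coupled positively/negatively
    to the site's Tmin z-score with strength ``coupling``; a further block is
    coupled to pH.  Counts are multinomial at ``depth`` reads per sample.
    """

    n_asvs: int = 400
    n_warm: int = 50
    n_cold: int = 50
    n_ph: int = 100
    coupling: float = 0.5
    ph_coupling: float = 0.5
    depth: int = 10_000
    base_sd: float = 1.0


@dataclass
class SurveyConfig:
    """Full configuration of one synthetic survey; ``seed`` drives every draw."""

    seed: int
    n_sites: int = 72
    mat_range: tuple = (-3.1, 18.3)
    seasonal_amplitude: float = 8.0   # degC half-amplitude of the annual cycle
    amplitude_jitter: float = 1.5     # site-to-site sd of the half-amplitude
    ph_range: tuple = (4.0, 8.0)
    som_range: tuple = (2.0, 80.0)    # % of dry mass, log-uniform
    map_range: tuple = (400.0, 1800.0)  # mm / yr, independent of MAT by default
    noise_sd: float = 0.02            # sqrt-rate measurement noise
    assay_temperatures: tuple = tuple(range(0, 50, 5))
    traits: dict = field(default_factory=lambda: {
        k: dataclasses.replace(v) for k, v in DEFAULT_TRAIT_MODELS.items()})

    community: CommunityConfig = field(default_factory=CommunityConfig)

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_sites < 3:
            raise ValueError("n_sites must be at least 3")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_LAND_USES = ("forest", "grassland", "arable", "heathland", "wetland")


def generate_sites(config: SurveyConfig) -> pd.DataFrame:
    """Site records: climate, soil and season covariates for each site.

    MAT uniform on the configured range; summer/winter monthly means are
    MAT +/- a jittered seasonal half-amplitude; pH uniform, SOM log-uniform,
    MAP uniform and independent of MAT; sampling season alternates.
    """
    rng = _rng(config.seed, "sites")
    n = config.n_sites
    mat = rng.uniform(*config.mat_range, size=n)
    amp = np.abs(config.seasonal_amplitude
                 + config.amplitude_jitter * rng.standard_normal(n))
    lo, hi = np.log10(config.som_range[0]), np.log10(config.som_range[1])
    return pd.DataFrame({
        "site_id": [f"S{i + 1:03d}" for i in range(n)],
        "latitude": np.clip(62.0 - 1.5 * mat + rng.normal(0, 1.5, n), 35.0, 71.0),
        "longitude": rng.uniform(-9.0, 30.0, n),
        "mat": mat,
        "map": rng.uniform(*config.map_range, size=n),
        "summer_temp": mat + amp,
        "winter_temp": mat - amp,
        "ph": rng.uniform(*config.ph_range, size=n),
        "som": 10 ** rng.uniform(lo, hi, size=n),
        "season": np.where(np.arange(n) % 2 == 0, "summer", "winter"),
        "land_use": [_LAND_USES[i % len(_LAND_USES)] for i in range(n)],
    })


def generate_trait_params(sites: pd.DataFrame, config: SurveyConfig) -> pd.DataFrame:
    """True per site x process curve parameters (a, b, t_min, t_max).

    Tmin follows the process's linear climate model; a, b and Tmax are drawn
    from fixed uniform ranges independent of MAT.  Respiration has no b or
    Tmax (its curve is the sub-optimal line throughout).  Draws with
    t_max - t_min < 30 degC are redrawn (bounded retries) to keep the niche
    realistic.
    """
    rng = _rng(config.seed, "traits")
    rows = []
    mat = sites["mat"].to_numpy(float)
    for process in PROCESSES:
        model = config.traits[process]
        t_min = model.intercept + model.slope * mat + rng.normal(0, model.sd, mat.size)
        a = rng.uniform(*model.a_range, size=mat.size)
        if model.b_range is None:
            b = np.full(mat.size, np.nan)
            t_max = np.full(mat.size, np.nan)
        else:
            b = rng.uniform(*model.b_range, size=mat.size)
            t_max = rng.uniform(*model.t_max_range, size=mat.size)
            for i in range(mat.size):
                for _ in range(100):
                    if t_max[i] - t_min[i] >= 30.0:
                        break
                    t_min[i] = (model.intercept + model.slope * mat[i]
                                + rng.normal(0, model.sd))
                    t_max[i] = rng.uniform(*model.t_max_range)
                else:
                    raise RuntimeError("could not draw t_min < t_max - 30")
        for i, site in enumerate(sites["site_id"]):
            rows.append({"site_id": site, "process": process, "a": a[i],
                         "b": b[i], "t_min": t_min[i], "t_max": t_max[i]})
    return pd.DataFrame(rows)


def _true_sqrt_rate(T, row):
    if np.isfinite(row["b"]):
        s = ratkowsky_sqrt_rate(T, row["a"], row["t_min"], row["b"], row["t_max"])
    else:
        s = row["a"] * (T - row["t_min"])
    return np.clip(s, 0.0, None)


def generate_curves(params: pd.DataFrame, config: SurveyConfig,
                    noise_sd: float | None = None, stage_extra: int = 0) -> pd.DataFrame:
    """Long-format rate table from true parameters plus sqrt-scale noise.

    Observed rate = max(sqrt_model(T) + e, 0)^2 with e ~ N(0, noise_sd^2):
    noise lives on the scale the estimator fits, and negative perturbed
    sqrt-rates floor at a zero rate.
    """
    rng = _rng(config.seed, "curves", stage_extra)
    noise = config.noise_sd if noise_sd is None else noise_sd
    T = np.asarray(config.assay_temperatures, dtype=float)
    frames = []
    for _, row in params.iterrows():
        s = _true_sqrt_rate(T, row)
        obs = np.clip(s + rng.normal(0.0, noise, T.size), 0.0, None) ** 2
        frames.append(pd.DataFrame({
            "site_id": row["site_id"], "process": row["process"],
            "temperature_c": T, "rate": obs,
            "unit": PROCESS_UNITS[row["process"]],
        }))
    return pd.concat(frames, ignore_index=True)


def generate_paired_subset(sites: pd.DataFrame, params: pd.DataFrame,
                           config: SurveyConfig, n_pairs: int = 10,
                           seasonal_offset: float = 0.0) -> pd.DataFrame:
    """Rate tables for a paired summer/winter resampling of ``n_pairs`` sites.

    Both seasons share the same true traits (the null of no seasonal effect)
    with independent measurement noise; ``seasonal_offset`` shifts the winter
    Tmin to inject a true effect for power checks.  Returns a long table with
    a ``season`` column.
    """
    chosen = sites["site_id"].iloc[:n_pairs]
    sub = params[params["site_id"].isin(chosen)].copy()
    out = []
    for k, season in enumerate(("summer", "winter")):
        p = sub.copy()
        if season == "winter" and seasonal_offset:
            p["t_min"] = p["t_min"] + seasonal_offset
        tab = generate_curves(p, config, stage_extra=100 + k)
        tab["season"] = season
        out.append(tab)
    return pd.concat(out, ignore_index=True)


def generate_community(sites: pd.DataFrame, params: pd.DataFrame,
                       config: SurveyConfig, marker: str = "16S"):
    """Synthetic ASV table whose composition turns over with Tmin and pH.

    Log-normal baseline abundances; ``n_warm``/``n_cold`` planted ASVs whose
    log-abundance increases/decreases with the site's true Tmin z-score for
    the marker's process (16S -> bacterial growth, ITS -> fungal growth);
    a further block tracks pH.  Counts are multinomial at the configured
    depth.  Returns (AsvTable, truth) where truth lists the planted ASV ids.
    """
    cc = config.community
    process = "bacterial_growth" if marker == "16S" else "fungal_growth"
    rng = _rng(config.seed, "community", 0 if marker == "16S" else 1)

    tmin = (params[params["process"] == process]
            .set_index("site_id")
            .loc[sites["site_id"], "t_min"]
            .to_numpy(float))
    z_t = (tmin - tmin.mean()) / tmin.std()
    ph = sites["ph"].to_numpy(float)
    z_ph = (ph - ph.mean()) / ph.std()

    n, p = len(sites), cc.n_asvs
    if cc.n_warm + cc.n_cold + cc.n_ph > p:
        raise ValueError("planted ASV blocks exceed n_asvs")
    base = rng.normal(0.0, cc.base_sd, size=p)
    logab = np.tile(base, (n, 1)) + rng.normal(0.0, 0.3, size=(n, p))
    warm = np.arange(cc.n_warm)
    cold = np.arange(cc.n_warm, cc.n_warm + cc.n_cold)
    phs = np.arange(cc.n_warm + cc.n_cold, cc.n_warm + cc.n_cold + cc.n_ph)
    logab[:, warm] += cc.coupling * z_t[:, None]
    logab[:, cold] -= cc.coupling * z_t[:, None]
    signs = rng.choice([-1.0, 1.0], size=phs.size)
    logab[:, phs] += cc.ph_coupling * z_ph[:, None] * signs

    probs = np.exp(logab)
    probs /= probs.sum(axis=1, keepdims=True)
    counts = np.vstack([rng.multinomial(cc.depth, probs[i]) for i in range(n)])
    prefix = "bASV" if marker == "16S" else "fASV"
    ids = [f"{prefix}{j + 1:04d}" for j in range(p)]
    frame = pd.DataFrame(counts, index=list(sites["site_id"]), columns=ids)
    truth = {
        "warm": [ids[j] for j in warm],
        "cold": [ids[j] for j in cold],
        "ph": [ids[j] for j in phs],
        "process": process,
    }
    return AsvTable(frame, marker), truth


def curves_from_table(table: pd.DataFrame) -> list[RateCurve]:
    """Group a long-format rate table into RateCurve objects."""
    curves = []
    for (site, process), grp in table.groupby(["site_id", "process"], sort=True,
                                              observed=True):
        grp = grp.sort_values("temperature_c")
        curves.append(RateCurve.from_raw(str(site), str(process),
                                         grp["temperature_c"].to_numpy(float),
                                         grp["rate"].to_numpy(float)))
    return curves
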