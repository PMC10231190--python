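"""Replicate-survey slope recovery: the package's end-to-end validation loop.

Generates many independent synthetic surveys, pushes each through the full
estimation pipeline (curves -> square-root model fits -> trait-climate
regression) and collects the recovered Tmin-vs-MAT and Q10-vs-MAT slopes.
The means over replicates estimate the slopes the pipeline would report for
a survey with the generator's trait-climate structure, and their spread
gives Monte-Carlo standard errors.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .curves import PROCESSES
from .simulate import SurveyConfig, curves_from_table, generate_curves, \
    generate_sites, generate_trait_params
from .traits import fit_survey, regress_trait

__all__ = ["replicate_slopes", "SlopeRecovery"]


@dataclasses.dataclass
class SlopeRecovery:
    process: str
    tmin_slopes: np.ndarray  # degC Tmin per degC MAT, one per replicate
    q10_slopes: np.ndarray   # Q10 units per degC MAT, one per replicate

    @property
    def n(self) -> int:
        return self.tmin_slopes.size

    def mean_se(self, which: str = "tmin"):
        x = self.tmin_slopes if which == "tmin" else self.q10_slopes
        return float(x.mean()), float(x.std(ddof=1) / np.sqrt(x.size))


def replicate_slopes(process: str, n_replicates: int = 500, base_seed: int = 1,
                     config_overrides: dict | None = None) -> SlopeRecovery:
    """Recovered trait-climate slopes over seeded replicate surveys.

    Each replicate draws a fresh default survey (72 sites, MAT uniform on
    [-3.1, 18.3] degC), simulates rate curves for ``process`` only, fits
    every curve (full model for growth, sub-optimal line for respiration),
    and regresses the fitted Tmin and Q10(5-15) on MAT.  Replicate seeds are
    spawned deterministically from ``base_seed``.
    """
    if process not in PROCESSES:
        raise ValueError(f"unknown process {process!r}")
    seeds = _replicate_seeds(base_seed, n_replicates)
    tmin_slopes = np.empty(n_replicates)
    q10_slopes = np.empty(n_replicates)
    for i, seed in enumerate(seeds):
        cfg = SurveyConfig(seed=int(seed), **(config_overrides or {}))
        sites = generate_sites(cfg)
        params = generate_trait_params(sites, cfg)
        params = params[params["process"] == process]
        table = generate_curves(params, cfg)
        indices = fit_survey(curves_from_table(table))
        tmin_slopes[i] = regress_trait(indices, sites, "t_min", process).slope
        q10_slopes[i] = regress_trait(indices, sites, "q10", process).slope
    return SlopeRecovery(process, tmin_slopes, q10_slopes)


def _replicate_seeds(base_seed: int, n: int) -> np.ndarray:
    """Deterministic child seeds below 2**31."""
    ss = np.random.SeedSequence(int(base_seed))
    return ss.generate_state(n, dtype=np.uint64) % np.uint64(2**31)
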