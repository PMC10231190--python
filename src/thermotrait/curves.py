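"""Rate-versus-temperature observations for one soil and one microbial process.

A :class:`RateCurve` holds the raw screening data behind every downstream
trait estimate: rates of bacterial growth (leucine incorporation), fungal
growth (acetate-in-ergosterol incorporation) or basal respiration, measured
in short assays across a ladder of incubation temperatures (by default
0-45 degC in 5 degC steps).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

PROCESSES = ("bacterial_growth", "fungal_growth", "respiration")
GROWTH_PROCESSES = ("bacterial_growth", "fungal_growth")

#: canonical unit string per process (used for read-time sanity warnings)
PROCESS_UNITS = {
    "bacterial_growth": "pmol leucine g-1 soil h-1",
    "fungal_growth": "pmol acetate g-1 soil h-1",
    "respiration": "ug CO2-C g-1 soil h-1",
}

#: fraction of the maximum rate below which a negative reading is treated as
#: blank-correction noise and clamped to zero instead of rejected
NEGATIVE_CLAMP_TOL = 0.05


@dataclass
class RateCurve:
    """One site x process set of (temperature, rate) observations.

    Temperatures are degC and must be strictly increasing; rates are
    non-negative in the process's own units.  ``excluded_mask`` marks points
    the analyst removed by hand; automatic outlier exclusion during fitting
    is tracked separately by the fit objects.
    """

    site_id: str
    process: str
    temperatures: np.ndarray
    rates: np.ndarray
    excluded_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.process not in PROCESSES:
            raise ValueError(
                f"unknown process {self.process!r}; expected one of {PROCESSES}"
            )
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if self.temperatures.ndim != 1 or self.temperatures.shape != self.rates.shape:
            raise ValueError("temperatures and rates must be 1-D and the same length")
        if np.any(np.diff(self.temperatures) <= 0):
            raise ValueError("temperatures must be strictly increasing")
        neg = np.where(self.rates < 0)[0]
        if neg.size:
            i = int(neg[0])
            raise ValueError(
                f"negative rate {self.rates[i]:g} at {self.temperatures[i]:g} degC "
                f"(site {self.site_id}, {self.process}); clamp or flag before construction"
            )
        if self.excluded_mask is None:
            self.excluded_mask = np.zeros(self.temperatures.size, dtype=bool)
        else:
            self.excluded_mask = np.asarray(self.excluded_mask, dtype=bool)
            if self.excluded_mask.shape != self.temperatures.shape:
                raise ValueError("excluded_mask must match the number of points")

    @classmethod
    def from_raw(cls, site_id, process, temperatures, rates, excluded_mask=None):
        """Build a curve from raw measurements, clamping small negative rates.

        Blank-corrected assays occasionally report slightly negative rates at
        the coldest temperatures.  Values within ``NEGATIVE_CLAMP_TOL`` of the
        curve maximum are clamped to 0 with a warning (preserving their
        leverage on Tmin); larger negatives are rejected.
        """
        rates = np.asarray(rates, dtype=float).copy()
        if np.any(rates < 0):
            scale = np.max(np.abs(rates)) or 1.0
            bad = rates < -NEGATIVE_CLAMP_TOL * scale
            if np.any(bad):
                i = int(np.where(bad)[0][0])
                raise ValueError(
                    f"negative rate {rates[i]:g} exceeds the clamp tolerance "
                    f"(site {site_id}, {process})"
                )
            warnings.warn(
                f"{int((rates < 0).sum())} small negative rate(s) clamped to 0 "
                f"for site {site_id} ({process})",
                UserWarning,
                stacklevel=2,
            )
            rates = np.clip(rates, 0.0, None)
        return cls(site_id, process, temperatures, rates, excluded_mask)

    @property
    def n_active(self) -> int:
        return int((~self.excluded_mask).sum())

    def active(self) -> tuple[np.ndarray, np.ndarray]:
        """Temperatures and rates of the non-excluded points."""
        keep = ~self.excluded_mask
        return self.temperatures[keep], self.rates[keep]


def sqrt_transform(curve: RateCurve) -> np.ndarray:
    """Element-wise square root of the observed rates (the model's fit scale)."""
    rates = np.asarray(curve.rates, dtype=float)
    neg = np.where(rates < 0)[0]
    if neg.size:
        i = int(neg[0])
        raise ValueError(
            f"negative rate {rates[i]:g} at {curve.temperatures[i]:g} degC"
        )
    return np.sqrt(rates)
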