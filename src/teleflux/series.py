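"""1-d time-series containers: teleconnection indices, winter means,
and regionally integrated annual flux anomalies."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

INDEX_NAMES = ("NAO", "EA")

#: Missing-value sentinel of the CPC monthly index text dialect.
CPC_SENTINEL = -99.9


@dataclass
class TeleconnectionSeries:
    """Standardized monthly teleconnection index (NAO or EA)."""

    name: str
    values: pd.Series  # PeriodIndex (monthly) -> float, NaN = masked

    def __post_init__(self):
        if self.name not in INDEX_NAMES:
            raise ValueError(f"index name must be one of {INDEX_NAMES}")
        idx = self.values.index
        if not isinstance(idx, pd.PeriodIndex) or idx.freqstr not in ("M", "ME"):
            raise ValueError("values must be indexed by monthly periods")
        if idx.has_duplicates:
            raise ValueError("duplicate months in index series")
        self.values = self.values.sort_index().astype(float)

    def month_value(self, year: int, month: int) -> float:
        p = pd.Period(f"{year:04d}-{month:02d}", freq="M")
        return float(self.values.get(p, np.nan))


@dataclass
class WinterIndexSeries:
    """Per-winter DJF means; winter ``y`` averages Dec(y-1), Jan(y), Feb(y).

    A winter value is present only when at least 2 of the 3 months are
    unmasked (NaN otherwise).
    """

    name: str
    values: pd.Series  # int winter_year -> float

    def __post_init__(self):
        self.values = self.values.sort_index().astype(float)
        if not self.values.index.is_unique:
            raise ValueError("duplicate winter years")

    @property
    def years(self) -> np.ndarray:
        return self.values.index.to_numpy()


@dataclass
class AnnualAnomalySeries:
    """Regionally integrated annual anomalies for one dataset.

    Units are PgC yr-1 for fluxes (positive = enhanced sink) or the
    native units for climate variables.
    """

    dataset: str
    region: str
    values: pd.Series  # int year -> float
    units: str = "PgC yr-1"

    def __post_init__(self):
        self.values = self.values.sort_index().astype(float)
        yrs = self.values.index.to_numpy()
        if yrs.size > 1 and not np.all(np.diff(yrs) == 1):
            raise ValueError("years must be consecutive within the dataset span")

    @property
    def years(self) -> np.ndarray:
        return self.values.index.to_numpy()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "dataset": self.dataset,
            "region": self.region,
            "year": self.values.index,
            "value": self.values.to_numpy(),
            "units": self.units,
        })
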