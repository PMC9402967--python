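"""Daily pollutant concentration panel container.

A :class:`PollutantPanel` holds six daily channels (PM2.5, PM10, SO2, NO2,
CO, O3) on a contiguous calendar index.  Concentrations are in ug/m3 except
CO, which is in mg/m3 (the convention of Chinese national reporting).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical channel order used throughout the package.
POLLUTANTS: tuple[str, ...] = ("PM25", "PM10", "SO2", "NO2", "CO", "O3")

#: Measurement unit per channel.
UNITS: dict[str, str] = {
    "PM25": "ug/m3",
    "PM10": "ug/m3",
    "SO2": "ug/m3",
    "NO2": "ug/m3",
    "CO": "mg/m3",
    "O3": "ug/m3",
}


@dataclass
class PollutantPanel:
    """Date-indexed daily concentrations for the six pollutant channels.

    Parameters
    ----------
    data
        DataFrame indexed by a contiguous daily ``DatetimeIndex`` with
        exactly the columns in :data:`POLLUTANTS` (any order accepted;
        stored in canonical order).
    units
        Unit label per channel; defaults to :data:`UNITS`.
    """

    data: pd.DataFrame
    units: dict[str, str] = field(default_factory=lambda: dict(UNITS))

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in POLLUTANTS if c not in df.columns]
        if missing:
            raise ValueError(f"panel is missing channels: {missing}")
        extra = [c for c in df.columns if c not in POLLUTANTS]
        if extra:
            raise ValueError(f"panel has unknown channels: {extra}")
        df = df.loc[:, list(POLLUTANTS)].sort_index()
        if not isinstance(df.index, pd.DatetimeIndex):
            raise TypeError("panel index must be a DatetimeIndex")
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique()
            raise ValueError(f"duplicate dates: {list(dupes[:5])}")
        if len(df) >= 2:
            deltas = np.diff(df.index.values).astype("timedelta64[D]")
            if not (deltas == np.timedelta64(1, "D")).all():
                gap_at = df.index[np.flatnonzero(deltas != np.timedelta64(1, "D"))[0]]
                raise ValueError(f"dates are not contiguous daily; first gap after {gap_at.date()}")
        if df.isna().any().any():
            bad = df.columns[df.isna().any()].tolist()
            raise ValueError(f"panel contains missing values in {bad}")
        self.data = df.astype(float)

    # -- convenience accessors -------------------------------------------------

    @property
    def dates(self) -> pd.DatetimeIndex:
        return self.data.index

    @property
    def values(self) -> np.ndarray:
        """n_days x 6 concentration matrix in canonical channel order."""
        return self.data.to_numpy()

    def __len__(self) -> int:
        return len(self.data)

    def series(self, pollutant: str) -> pd.Series:
        if pollutant not in POLLUTANTS:
            raise KeyError(f"unknown pollutant {pollutant!r}; expected one of {POLLUTANTS}")
        return self.data[pollutant]

    def covariates(self, target: str) -> pd.DataFrame:
        """The five channels other than *target*, in canonical order."""
        if target not in POLLUTANTS:
            raise KeyError(f"unknown pollutant {target!r}")
        return self.data[[c for c in POLLUTANTS if c != target]]

    def year_slice(self, year: int) -> pd.DataFrame:
        return self.data[self.data.index.year == year]
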