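"""Panel CSV interchange and run configuration files.

Panel CSV layout: header ``date,PM25,PM10,SO2,NO2,CO,O3`` (column order
free; common aliases like ``PM2.5`` accepted case-insensitively),
ISO-8601 dates, one row per day.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from .panel import POLLUTANTS, UNITS, PollutantPanel

logger = logging.getLogger(__name__)

_ALIASES = {
    "pm2.5": "PM25", "pm25": "PM25", "pm_25": "PM25",
    "pm10": "PM10", "pm_10": "PM10",
    "so2": "SO2", "no2": "NO2", "co": "CO", "o3": "O3",
    "date": "date",
}


def _canonical(col: str) -> str | None:
    return _ALIASES.get(col.strip().lower())


def read_panel_csv(path, forward_fill_gaps: bool = False) -> PollutantPanel:
    """Parse, validate and date-sort a panel CSV.

    Unparseable dates, non-numeric cells and duplicate dates raise with the
    offending row numbers.  Calendar gaps raise unless
    ``forward_fill_gaps`` is set, in which case missing days are filled
    from the previous day and the count is logged.
    """
    df = pd.read_csv(path)
    rename = {}
    for col in df.columns:
        canon = _canonical(str(col))
        if canon is None:
            raise ValueError(f"unrecognised column {col!r} in {path}")
        rename[col] = canon
    df = df.rename(columns=rename)
    if "date" not in df.columns:
        raise ValueError(f"no date column in {path}")

    dates = pd.to_datetime(df["date"], format="ISO8601", errors="coerce")
    bad = df.index[dates.isna()]
    if len(bad):
        raise ValueError(f"unparseable dates at CSV rows {[int(i) + 2 for i in bad[:5]]}")
    dupes = df.index[dates.duplicated()]
    if len(dupes):
        raise ValueError(f"duplicate dates at CSV rows {[int(i) + 2 for i in dupes[:5]]}")

    for col in POLLUTANTS:
        if col not in df.columns:
            raise ValueError(f"missing channel {col} in {path}")
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna() & df[col].notna()]
        if len(bad):
            raise ValueError(
                f"non-numeric {col} values at CSV rows {[int(i) + 2 for i in bad[:5]]}"
            )
        df[col] = vals

    df = df.set_index(pd.DatetimeIndex(dates)).sort_index()[list(POLLUTANTS)]
    if forward_fill_gaps and len(df) >= 2:
        full = pd.date_range(df.index[0], df.index[-1], freq="D")
        n_gaps = len(full) - len(df)
        if n_gaps:
            logger.info("forward-filling %d missing days", n_gaps)
            df = df.reindex(full).ffill()
    return PollutantPanel(df, dict(UNITS))


def write_panel_csv(panel: PollutantPanel, path) -> None:
    out = panel.data.copy()
    out.insert(0, "date", out.index.strftime("%Y-%m-%d"))
    out.to_csv(path, index=False)


def load_config_file(path) -> dict:
    """Read a JSON or YAML mapping (by extension; YAML otherwise)."""
    p = Path(path)
    text = p.read_text()
    if p.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return data
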