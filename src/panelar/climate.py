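"""Temperature summaries: Kira's warmth index and seasonal means.

The warmth index is an integrated temperature index for plant growth: months
with a mean temperature of at least 5 degC contribute (mean - 5) degC-months.
Winter temperature is the January-March mean, summer the April-October mean.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


class ClimateError(ValueError):
    pass


WARMTH_THRESHOLD = 5.0  # degC; months at or above this count toward growth


def warmth_index(monthly) -> float:
    """Sum of (monthly mean - 5) over months with mean >= 5 degC.

    ``monthly`` is the 12 monthly mean temperatures of one station-year, in
    any order.  Missing months are an error; no imputation.
    """
    m = np.asarray(list(monthly), dtype=float)
    if m.shape != (12,):
        raise ClimateError(f"need exactly 12 monthly values, got {m.shape}")
    if np.isnan(m).any():
        raise ClimateError("missing monthly temperature")
    excess = m - WARMTH_THRESHOLD
    return float(excess[excess >= 0].sum())


def seasonal_means(monthly_by_month: dict) -> tuple[float, float]:
    """(winter, summer) = (mean of months 1-3, mean of months 4-10)."""
    try:
        winter = float(np.mean([monthly_by_month[m] for m in (1, 2, 3)]))
        summer = float(np.mean([monthly_by_month[m] for m in range(4, 11)]))
    except KeyError as e:
        raise ClimateError(f"missing month {e.args[0]}") from None
    if np.isnan(winter) or np.isnan(summer):
        raise ClimateError("missing monthly temperature")
    return winter, summer


def station_year_summary(df: pd.DataFrame) -> pd.DataFrame:
    """Per station-year warmth index, winter, summer and annual means.

    Input columns: ``station, year, month, temp_c`` with months unique within
    a station-year.  Output: ``station, year, warmth_index, winter_c,
    summer_c, annual_c``.
    """
    required = {"station", "year", "month", "temp_c"}
    missing = required - set(df.columns)
    if missing:
        raise ClimateError(f"temperature table missing columns: {sorted(missing)}")
    if df.duplicated(subset=["station", "year", "month"]).any():
        raise ClimateError("duplicate station-year-month rows")
    rows = []
    for (station, year), sub in df.groupby(["station", "year"]):
        by_month = dict(zip(sub["month"], sub["temp_c"]))
        if set(by_month) != set(range(1, 13)):
            raise ClimateError(f"station {station!r} year {year}: incomplete months")
        winter, summer = seasonal_means(by_month)
        rows.append(
            {
                "station": station,
                "year": year,
                "warmth_index": warmth_index(by_month.values()),
                "winter_c": winter,
                "summer_c": summer,
                "annual_c": float(np.mean(list(by_month.values()))),
            }
        )
    return pd.DataFrame(rows)
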