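"""Climate covariates from sensor time series.

All operations here are deterministic aggregations of long-format sensor
data (location_id, sensor_id, timestamp, variable, value):

* growing-season start — days between the first date soil temperature rises
  above a threshold (default 2.5 C, evaluated on daily means) and the
  sampling date;
* winter vegetation temperature — multi-year mean canopy temperature over
  January-March;
* mean soil moisture — daily means, averaged over days, then years, then
  sensors (the hierarchical order matters with unbalanced coverage);
* circadian soil-moisture CV — coefficient of variation of the 24
  hour-of-day means pooled across years;
* sensor-failure exclusion — a year is dropped for a sensor when more than
  ``max_missing_months`` calendar months have no observations.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io_tables import ValidationError

logger = logging.getLogger(__name__)


def _select(series: pd.DataFrame, variable: str, location_id=None) -> pd.DataFrame:
    df = series[series["variable"] == variable]
    if location_id is not None:
        df = df[df["location_id"] == location_id]
    if df.empty:
        raise ValidationError(f"no observations for variable {variable!r}"
                              + (f" at location {location_id!r}" if location_id else ""))
    return df


def growing_season_start(
    soil_temp: pd.DataFrame,
    year: int,
    sampling_date,
    threshold_c: float = 2.5,
    location_id=None,
) -> int:
    """Days from the first daily-mean exceedance of ``threshold_c`` to sampling.

    Exceedance is strict (>).  If the series starts above the threshold the
    first observation date is used; an internal gap spanning the crossing
    only triggers a warning (first observed exceedance wins).
    """
    df = _select(soil_temp, "soil_temperature_C", location_id)
    sampling = pd.Timestamp(sampling_date)
    df = df[(df["timestamp"].dt.year == year) & (df["timestamp"] <= sampling)]
    if df.empty:
        raise ValidationError(f"no soil temperature data in {year} before sampling")
    daily = df.set_index("timestamp")["value"].resample("D").mean().dropna()
    above = daily[daily > threshold_c]
    if above.empty:
        raise ValidationError(
            f"soil temperature never exceeds {threshold_c} C before sampling")
    first = above.index[0]
    prev = daily.index[daily.index < first]
    if len(prev) and (first - prev[-1]).days > 1:
        logger.warning("gap spans the %.1f C crossing; first observed "
                       "exceedance used", threshold_c)
    days = (sampling.normalize() - first.normalize()).days
    if days < 0:
        raise ValidationError("threshold crossing after sampling date")
    return int(days)


def winter_vegetation_temperature(
    canopy: pd.DataFrame,
    years=None,
    months=(1, 2, 3),
    location_id=None,
) -> float:
    """Mean canopy temperature over the winter window across admitted years."""
    df = _select(canopy, "canopy_temperature_C", location_id)
    ts = df["timestamp"]
    mask = ts.dt.month.isin(list(months))
    if years is not None:
        mask &= ts.dt.year.isin(list(years))
    vals = df.loc[mask, "value"].dropna()
    if vals.empty:
        raise ValidationError("no canopy temperature data in the winter window")
    return float(vals.mean())


def mean_soil_moisture(
    moisture: pd.DataFrame,
    years=None,
    sensors=None,
    location_id=None,
) -> float:
    """Hierarchical mean moisture: daily means -> year means -> sensor means.

    Sensors without admissible data are dropped with a warning.  This order
    differs from the pooled observation mean whenever coverage is unbalanced.
    """
    df = _select(moisture, "soil_moisture_vol", location_id)
    if years is not None:
        df = df[df["timestamp"].dt.year.isin(list(years))]
    if sensors is not None:
        df = df[df["sensor_id"].isin(list(sensors))]
    df = df.dropna(subset=["value"])
    if df.empty:
        raise ValidationError("no admissible soil moisture data")
    per_sensor = []
    for sid, sub in df.groupby("sensor_id"):
        daily = (sub.set_index("timestamp")["value"]
                 .resample("D").mean().dropna())
        if daily.empty:
            logger.warning("sensor %s has no admissible data; dropped", sid)
            continue
        yearly = daily.groupby(daily.index.year).mean()
        per_sensor.append(float(yearly.mean()))
    if not per_sensor:
        raise ValidationError("all sensors dropped")
    return float(np.mean(per_sensor))


def circadian_cv(
    moisture: pd.DataFrame,
    years=None,
    location_id=None,
) -> float:
    """CV (population SD / mean) of the 24 hour-of-day moisture means."""
    df = _select(moisture, "soil_moisture_vol", location_id)
    if years is not None:
        df = df[df["timestamp"].dt.year.isin(list(years))]
    df = df.dropna(subset=["value"])
    hourly = df.groupby(df["timestamp"].dt.hour)["value"].mean()
    missing = sorted(set(range(24)) - set(hourly.index))
    if missing:
        raise ValidationError(f"empty hour-of-day bins: {missing}")
    vals = hourly.to_numpy()
    return float(vals.std(ddof=0) / vals.mean())


def exclude_failed_years(
    series: pd.DataFrame,
    max_missing_months: int = 5,
) -> pd.DataFrame:
    """Drop (location, sensor, variable, year) blocks with too many silent months.

    A calendar month counts as missing when it has zero observations; a year
    is excluded when strictly more than ``max_missing_months`` months are
    missing.
    """
    df = series.reset_index(drop=True)
    year = df["timestamp"].dt.year.to_numpy()
    month = df["timestamp"].dt.month.to_numpy()
    keep_mask = np.ones(len(df), dtype=bool)
    any_kept = False
    for (loc, sid, var), idx in df.groupby(
            ["location_id", "sensor_id", "variable"]).groups.items():
        pos = np.asarray(idx)
        sub_year = year[pos]
        sub_month = month[pos]
        for yr in np.unique(sub_year):
            in_year = sub_year == yr
            present = len(np.unique(sub_month[in_year]))
            if 12 - present > max_missing_months:
                keep_mask[pos[in_year]] = False
                logger.warning("excluding year %d for %s/%s/%s "
                               "(%d month(s) missing)", yr, loc, sid, var,
                               12 - present)
            else:
                any_kept = True
    if not any_kept:
        raise ValidationError("every year excluded by the failure rule")
    return df[keep_mask].reset_index(drop=True)
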