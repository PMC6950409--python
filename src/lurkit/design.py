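"""Station-month design matrix assembly.

The regression's unit of observation is a (station, month) pair: daily
PM2.5 and meteorology series are aggregated to monthly means, buffer
features are extracted at station coordinates, and season indicator
columns are added.  Every candidate predictor carries an a-priori
direction of effect (+1 / -1 / 0 = unconstrained) used later by the
supervised selection.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .features import extract_at, parse_feature_name
from .grid import FeatureRaster

__all__ = [
    "CandidateVariable",
    "DesignMatrix",
    "monthly_mean",
    "season_dummies",
    "assemble",
    "default_direction_prior",
    "SEASON_SCHEMES",
]

log = logging.getLogger("lurkit")

#: Named season partition schemes (month sets per season dummy).
SEASON_SCHEMES: dict[str, dict[str, frozenset[int]]] = {
    "northern_meteorological": {
        "spring": frozenset({3, 4, 5}),
        "fall": frozenset({9, 10, 11}),
    },
}

_VAR_CLASSES = (
    "land_use", "ndvi", "meteorology", "copollutant", "season", "distance",
)

# Keyword rules for default direction priors: built-environment /
# transport / industrial layers, co-pollutants, temperature and spring
# push PM2.5 up; greenness, humidity, rain, UV, fall and distance from
# airports push it down.  Anything unlisted is unconstrained.
_POSITIVE_KEYS = (
    "residential", "commercial", "industrial", "building", "built",
    "transport", "quarry", "road", "railway", "rail", "airport",
    "pm10", "no2", "so2", "temperature", "spring",
)
_NEGATIVE_KEYS = (
    "ndvi", "relative_humidity", "humidity", "rainfall", "uv", "fall",
)


@dataclass(frozen=True)
class CandidateVariable:
    """A candidate predictor: name, class, optional buffer radius, and
    a-priori direction of effect."""

    name: str
    var_class: str
    radius: float | None = None
    direction_prior: int = 0

    def __post_init__(self) -> None:
        if self.var_class not in _VAR_CLASSES:
            raise ValueError(f"unknown var_class {self.var_class!r}")
        if self.var_class in ("land_use", "ndvi") and self.radius is None:
            raise ValueError(f"{self.var_class} variable {self.name!r} needs a radius")
        if self.direction_prior not in (-1, 0, 1):
            raise ValueError("direction_prior must be -1, 0 or +1")


def default_direction_prior(name: str, var_class: str) -> int:
    """Default sign prior for a variable, by keyword."""
    low = name.lower()
    if var_class == "distance":
        return -1 if "airport" in low else 0
    for key in _NEGATIVE_KEYS:
        if key in low:
            return -1
    for key in _POSITIVE_KEYS:
        if key in low:
            return 1
    return 0


def monthly_mean(daily: pd.Series, min_completeness: float = 0.75) -> pd.Series:
    """Aggregate a daily series to monthly means.

    A month is emitted only when the fraction of its calendar days with a
    non-missing value is at least ``min_completeness``; the value is the
    arithmetic mean of the available days.
    """
    if not 0 < min_completeness <= 1:
        raise ValueError("min_completeness must be in (0, 1]")
    if len(daily) == 0:
        raise ValueError("daily series is empty")
    s = daily.copy()
    s.index = pd.DatetimeIndex(s.index)
    by_month = s.groupby(s.index.to_period("M"))
    counts = by_month.apply(lambda g: g.notna().sum())
    days = pd.Series({p: p.days_in_month for p in counts.index})
    means = by_month.mean()
    keep = counts / days >= min_completeness
    return means[keep]


def season_dummies(period, scheme: str | Mapping[str, frozenset[int]] =
                   "northern_meteorological") -> dict[str, int]:
    """0/1 season indicators for a (year, month) period.

    Under a partitioning scheme at most one indicator is active.
    """
    if isinstance(scheme, str):
        try:
            scheme = SEASON_SCHEMES[scheme]
        except KeyError:
            raise ValueError(f"unknown season scheme {scheme!r}") from None
    month = period.month if hasattr(period, "month") else int(period[1])
    if not 1 <= month <= 12:
        raise ValueError(f"month {month} not in 1..12")
    return {name: int(month in months) for name, months in scheme.items()}


@dataclass
class DesignMatrix:
    """Station-month observation table: response (pm25), candidate
    predictor columns, and station metadata.

    ``data`` is indexed by (station_id, period) with a ``pm25`` column
    plus one column per :class:`CandidateVariable`.
    """

    data: pd.DataFrame
    variables: list[CandidateVariable]
    coords: pd.DataFrame  # index station_id, columns x, y
    response: str = "pm25"

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            dupes = self.data.index[self.data.index.duplicated()].tolist()
            raise ValueError(f"duplicated (station, period) rows: {dupes[:5]}")
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise ValueError("duplicate candidate-variable names")
        missing = [n for n in names if n not in self.data.columns]
        if missing:
            raise ValueError(f"columns missing from data: {missing}")

    @property
    def X(self) -> pd.DataFrame:
        return self.data[[v.name for v in self.variables]]

    @property
    def y(self) -> pd.Series:
        return self.data[self.response]

    @property
    def n_obs(self) -> int:
        return len(self.data)

    @property
    def priors(self) -> dict[str, int]:
        return {v.name: v.direction_prior for v in self.variables}

    def variable(self, name: str) -> CandidateVariable:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    def dropna_response(self) -> "DesignMatrix":
        """Drop rows with a missing response, logging the count."""
        keep = self.data[self.response].notna()
        n_drop = int((~keep).sum())
        if n_drop:
            log.info("dropping %d rows with missing %s", n_drop, self.response)
        return DesignMatrix(self.data[keep].copy(), list(self.variables),
                            self.coords, self.response)

    # -- persistence: one CSV + a JSON sidecar of variable metadata -------
    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        self.data.to_csv(path, index_label=["station_id", "period"])
        meta = {
            "response": self.response,
            "variables": [
                {"name": v.name, "var_class": v.var_class, "radius": v.radius,
                 "direction_prior": v.direction_prior}
                for v in self.variables
            ],
            "coords": {
                str(s): [float(r["x"]), float(r["y"])]
                for s, r in self.coords.iterrows()
            },
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def from_csv(cls, path: str | Path) -> "DesignMatrix":
        path = Path(path)
        data = pd.read_csv(path, index_col=[0, 1])
        meta = json.loads(path.with_suffix(".json").read_text())
        variables = [CandidateVariable(**v) for v in meta["variables"]]
        coords = pd.DataFrame.from_dict(meta["coords"], orient="index",
                                        columns=["x", "y"])
        coords.index.name = "station_id"
        return cls(data, variables, coords, meta["response"])


def _infer_variable(name: str, var_class: str | None = None,
                    priors: Mapping[str, int] | None = None) -> CandidateVariable:
    parsed = parse_feature_name(name)
    if var_class is None:
        if parsed["kind"] == "distance":
            var_class = "distance"
        elif parsed["kind"] == "buffered":
            var_class = "ndvi" if parsed["layer"].upper() == "NDVI" else "land_use"
        else:
            var_class = "meteorology"
    prior = (priors or {}).get(name)
    if prior is None:
        prior = default_direction_prior(name, var_class)
    return CandidateVariable(name=name, var_class=var_class,
                             radius=parsed["radius"], direction_prior=prior)


def assemble(
    observations: pd.DataFrame,
    static_features: Mapping[str, FeatureRaster] | None = None,
    monthly_features: Mapping[str, Mapping[str, FeatureRaster]] | None = None,
    meteo: pd.DataFrame | None = None,
    copollutants: pd.DataFrame | None = None,
    season_scheme: str | Mapping[str, frozenset[int]] | None = "northern_meteorological",
    priors: Mapping[str, int] | None = None,
) -> DesignMatrix:
    """Assemble the station-month design matrix.

    Parameters
    ----------
    observations
        One row per (station_id, period) with columns ``station_id``,
        ``x``, ``y``, ``period`` (``YYYY-MM`` strings or Periods) and
        ``pm25``.
    static_features
        Buffer/distance rasters; extracted once per station and repeated
        across months.
    monthly_features
        Time-varying rasters (e.g. monthly NDVI composites): mapping
        ``name -> {period -> raster}``.
    meteo, copollutants
        Station-month tables with ``station_id``/``period`` columns plus
        one column per variable, already at monitor locations.
    priors
        Overrides for direction priors (name -> -1/0/+1); defaults come
        from :func:`default_direction_prior`.
    """
    obs = observations.reset_index(drop=True).copy()
    obs["period"] = obs["period"].astype(str)
    idx = pd.MultiIndex.from_frame(obs[["station_id", "period"]])
    if idx.duplicated().any():
        raise ValueError("duplicated (station, period) observations")
    data = pd.DataFrame({"pm25": obs["pm25"].to_numpy()}, index=idx)

    coords = (obs[["station_id", "x", "y"]]
              .drop_duplicates("station_id").set_index("station_id"))
    station_order = obs["station_id"].to_numpy()
    pts = coords.loc[station_order, ["x", "y"]].to_numpy()

    variables: list[CandidateVariable] = []

    for name in sorted(static_features or {}):
        rast = static_features[name]
        vals = extract_at(rast, pts, labels=list(station_order))
        data[name] = vals
        variables.append(_infer_variable(name, priors=priors))

    for name in sorted(monthly_features or {}):
        per_period = {str(k): v for k, v in monthly_features[name].items()}
        col = np.full(len(obs), np.nan)
        for period, sub in obs.groupby("period"):
            if period not in per_period:
                raise ValueError(f"no {name!r} raster for period {period}")
            rast = per_period[period]
            p = coords.loc[sub["station_id"], ["x", "y"]].to_numpy()
            col[sub.index.to_numpy()] = extract_at(
                rast, p, labels=list(sub["station_id"]))
        data[name] = col
        variables.append(_infer_variable(name, priors=priors))

    for table, var_class in ((meteo, "meteorology"), (copollutants, "copollutant")):
        if table is None:
            continue
        t = table.copy()
        t["period"] = t["period"].astype(str)
        t = t.set_index(["station_id", "period"])
        for name in sorted(c for c in t.columns):
            data[name] = t[name].reindex(data.index).to_numpy()
            variables.append(_infer_variable(name, var_class=var_class,
                                             priors=priors))

    if season_scheme is not None:
        months = pd.PeriodIndex(data.index.get_level_values("period"), freq="M")
        scheme = (SEASON_SCHEMES[season_scheme]
                  if isinstance(season_scheme, str) else season_scheme)
        for sname, smonths in scheme.items():
            data[sname] = np.isin(months.month, list(smonths)).astype(float)
            prior = (priors or {}).get(sname)
            if prior is None:
                prior = default_direction_prior(sname, "season")
            variables.append(CandidateVariable(sname, "season",
                                               direction_prior=prior))

    dm = DesignMatrix(data, variables, coords)
    return dm.dropna_response()
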