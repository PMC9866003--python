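"""Conditional probability function (CPF) wind-sector source localization.

For a pollution source with per-sample contribution c and wind records
(direction theta, speed v), the CPF of compass sector dtheta is

    CPF(dtheta) = m(dtheta) / n(dtheta)

where n counts non-calm winds blowing from the sector and m counts those
among them whose paired contribution exceeds a high percentile threshold
(conventionally the 80th).  Sectors with elevated CPF point toward the
source.  Calm winds (speed <= 1 m/s by default) carry unreliable
directions and are excluded from both counts.

Contributions are 24-h filter values while winds are sub-daily, so each
wind record inherits the contribution of its calendar day; when two
co-located samplers yield duplicate dates, the day's values are averaged.

The compass is split into ``n_sectors`` equal sectors (default 16 of
22.5 deg), north-centered, clockwise, half-open: sector k covers
[center - width/2, center + width/2) with center k * (360/n_sectors).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class WindRecord:
    """A single wind observation (direction in degrees, speed in m/s)."""

    timestamp: pd.Timestamp
    direction: float
    speed: float

    def __post_init__(self):
        if not np.isfinite(self.direction):
            raise ValueError("wind direction must be finite")
        self.direction = float(self.direction) % 360.0
        if self.speed < 0:
            raise ValueError("wind speed must be >= 0")


@dataclass
class CPFResult:
    """Per-sector conditional probabilities for one source."""

    sector_centers: np.ndarray
    m_counts: np.ndarray
    n_counts: np.ndarray
    cpf: np.ndarray
    threshold_value: float
    percentile: float
    calm_cutoff: float
    n_calm_excluded: int = 0
    n_unmatched: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "sector_center_deg": self.sector_centers,
            "n": self.n_counts,
            "m": self.m_counts,
            "cpf": self.cpf,
        })

    @property
    def argmax_sector(self) -> int:
        """Index of the sector with the highest defined CPF."""
        vals = np.where(np.isnan(self.cpf), -np.inf, self.cpf)
        return int(np.argmax(vals))


def sectorize(direction, n_sectors: int = 16):
    """Map wind directions (degrees) to compass-sector indices.

    North-centered, clockwise, half-open sectors; e.g. with 16 sectors,
    [348.75, 11.25) -> 0 (N), [11.25, 33.75) -> 1 (NNE), ...  Directions
    are normalized modulo 360; non-finite input is an error.
    """
    if n_sectors < 1:
        raise ValueError("n_sectors must be >= 1")
    arr = np.asarray(direction, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("wind directions must be finite")
    width = 360.0 / n_sectors
    idx = np.floor(((arr % 360.0) + width / 2.0) / width).astype(int) % n_sectors
    if np.isscalar(direction) or arr.ndim == 0:
        return int(idx)
    return idx


def sector_centers(n_sectors: int = 16) -> np.ndarray:
    return np.arange(n_sectors) * (360.0 / n_sectors)


def _pair_daily(contributions, winds: pd.DataFrame):
    """Attach the calendar day's contribution to each wind record."""
    if isinstance(contributions, pd.Series):
        series = contributions
    else:
        raise TypeError(
            "contributions must be a pandas Series indexed by sample date"
        )
    idx = pd.DatetimeIndex(series.index).normalize()
    daily = series.groupby(idx).mean()  # duplicate dates (two sites) averaged
    wind_days = pd.DatetimeIndex(winds["timestamp"]).normalize()
    mapped = daily.reindex(wind_days).to_numpy()
    return mapped


def cpf_compute(
    contributions: pd.Series,
    winds: pd.DataFrame,
    percentile: float = 0.80,
    calm_cutoff: float = 1.0,
    n_sectors: int = 16,
) -> CPFResult:
    """Conditional probability per wind sector for one source.

    contributions : per-sample series indexed by sample date (ug/m3).
    winds : DataFrame with columns ``timestamp``, ``wd_deg``, ``ws_ms``.
    percentile : threshold quantile of the paired non-calm contribution
        values (linear-interpolation empirical quantile).
    calm_cutoff : winds with speed <= this (m/s) are excluded everywhere.

    Exceedance is strict (> threshold).  Sectors never visited by usable
    winds get CPF = NaN, not 0/0.  A constant contribution series makes
    the threshold equal that constant, hence all CPF = 0, with a warning.
    """
    if not 0.0 < percentile < 1.0:
        raise ValueError("percentile must lie in (0, 1)")
    for col in ("timestamp", "wd_deg", "ws_ms"):
        if col not in winds.columns:
            raise ValueError(f"winds table lacks column {col!r}")
    values = _pair_daily(contributions, winds)
    matched = np.isfinite(values)
    n_unmatched = int((~matched).sum())
    speed = winds["ws_ms"].to_numpy(dtype=float)
    if np.any(speed < 0):
        raise ValueError("wind speeds must be >= 0")
    usable = matched & (speed > calm_cutoff)
    n_calm = int((matched & ~(speed > calm_cutoff)).sum())
    if not usable.any():
        raise ValueError("no usable wind records (all calm or unmatched)")
    vals = values[usable]
    dirs = winds["wd_deg"].to_numpy(dtype=float)[usable]
    threshold = float(np.quantile(vals, percentile))
    exceed = vals > threshold
    if vals.max() == vals.min():
        warnings.warn(
            "constant contribution series: threshold equals the constant, "
            "all CPF values are 0",
            stacklevel=2,
        )
    sectors = sectorize(dirs, n_sectors)
    n_counts = np.bincount(sectors, minlength=n_sectors)
    m_counts = np.bincount(sectors, weights=exceed.astype(float),
                           minlength=n_sectors).astype(int)
    with np.errstate(invalid="ignore"):
        cpf = np.where(n_counts > 0, m_counts / np.maximum(n_counts, 1), np.nan)
    return CPFResult(
        sector_centers=sector_centers(n_sectors),
        m_counts=m_counts,
        n_counts=n_counts,
        cpf=cpf,
        threshold_value=threshold,
        percentile=percentile,
        calm_cutoff=calm_cutoff,
        n_calm_excluded=n_calm,
        n_unmatched=n_unmatched,
    )
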