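"""Aggregation of mass-scaled source contributions into reporting tables.

Once the G matrix is scaled to ug/m3 of PM2.5 mass per factor, the
standard reporting surfaces are the mean contribution and percentage share
per source, overall and stratified by calendar month and by
weekday/weekend.  Percentages are always computed from unrounded means;
rounding is presentation-only and must never feed back into computation
(published tables routinely carry +-0.02 rounding inconsistencies for
exactly this reason).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

WEEKDAY = "weekday"
WEEKEND = "weekend"


def percentage_shares(means) -> np.ndarray:
    """Percentage share of each source: 100 * mean_k / sum(means).

    All means must be >= 0 and not all zero.  Shares sum to exactly 100
    before any presentation rounding.
    """
    means = np.asarray(means, dtype=float)
    if np.any(means < 0):
        raise ValueError("contribution means must be nonnegative")
    total = means.sum()
    if total <= 0:
        raise ValueError("cannot compute shares of an all-zero contribution")
    return 100.0 * means / total


@dataclass
class ContributionTable:
    """Mean contributions and shares for one stratum of samples."""

    stratum: str
    sources: list
    per_source_mean: np.ndarray
    per_source_pct: np.ndarray
    n_samples: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "stratum": self.stratum,
            "source": list(self.sources),
            "mean_ugm3": self.per_source_mean,
            "pct": self.per_source_pct,
            "n": self.n_samples,
        })

    @property
    def total(self) -> float:
        return float(np.nansum(self.per_source_mean)) if self.n_samples else float("nan")


def _strata(dates: pd.DatetimeIndex, stratifier: str):
    """Map each sample to its stratum label; list all expected labels."""
    if stratifier == "overall":
        return np.asarray(["overall"] * len(dates)), ["overall"]
    if stratifier == "month":
        labels = dates.to_period("M").astype(str)
        expected = [
            str(p) for p in pd.period_range(dates.min(), dates.max(), freq="M")
        ]
        return np.asarray(labels), expected
    if stratifier == "weekpart":
        labels = np.where(dates.dayofweek < 5, WEEKDAY, WEEKEND)
        return labels, [WEEKDAY, WEEKEND]
    raise ValueError(
        f"unknown stratifier {stratifier!r}; use overall, month or weekpart"
    )


def aggregate(
    scaled_G, dates, stratifier: str = "overall", labels=None
) -> list[ContributionTable]:
    """Mean contribution and share per source within each stratum.

    scaled_G : n x p mass-scaled contributions (ug/m3).
    dates : per-sample calendar dates.
    stratifier : "overall", "month" (every calendar month between the first
        and last sample date appears, possibly empty), or "weekpart"
        (ISO weekday 1-5 vs 6-7).
    labels : source names; defaults to "factor_1" ... "factor_p".

    Empty strata are emitted with ``n_samples = 0`` and NaN means so the
    caller sees the gap instead of a silently absent row.
    """
    G = np.asarray(scaled_G, dtype=float)
    dates = pd.DatetimeIndex(dates)
    if G.ndim != 2 or len(dates) != G.shape[0]:
        raise ValueError("scaled_G must be n x p with one date per row")
    p = G.shape[1]
    if labels is None:
        labels = [f"factor_{k + 1}" for k in range(p)]
    if len(labels) != p:
        raise ValueError("one label per factor required")
    sample_labels, expected = _strata(dates, stratifier)
    tables = []
    for stratum in expected:
        mask = sample_labels == stratum
        n = int(mask.sum())
        if n == 0:
            means = np.full(p, np.nan)
            pct = np.full(p, np.nan)
        else:
            means = G[mask].mean(axis=0)
            try:
                pct = percentage_shares(means)
            except ValueError:
                pct = np.full(p, np.nan)
        tables.append(ContributionTable(
            stratum=str(stratum),
            sources=list(labels),
            per_source_mean=means,
            per_source_pct=pct,
            n_samples=n,
        ))
    return tables


def contribution_frame(scaled_G, dates, labels=None) -> pd.DataFrame:
    """Long-format table over all three stratifiers, ready for CSV export."""
    frames = []
    for strat in ("overall", "month", "weekpart"):
        for table in aggregate(scaled_G, dates, strat, labels=labels):
            frames.append(table.to_frame())
    return pd.concat(frames, ignore_index=True)
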