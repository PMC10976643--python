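"""Ensemble statistics for chemical-shift series.

Per-nucleus distribution summaries, rolling averages of shift time series,
deviation tables against experimental values (per-nucleus
|delta_calc - delta_exp| with the row average P-bar), and detection of the
peak order on the ppm axis (most downfield first).
"""

from __future__ import annotations

import dataclasses
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .shielding import ShiftSeries
from .structures import STATE_NUCLEI

__all__ = [
    "RollingConfig",
    "EnsembleSummary",
    "DeviationRow",
    "ensemble_summary",
    "rolling_average",
    "deviation_table",
    "deviation_frame",
    "peak_order",
    "round_half_away",
]

#: canonical ordering of nucleus labels for tie-breaks
CANONICAL_ORDER = ("P_alpha", "P_beta", "P_gamma", "P_i")


@dataclasses.dataclass(frozen=True)
class RollingConfig:
    """Rolling-average window (snapshots) and centering mode.

    The default is a trailing (causal) window of 20 snapshots, with the
    first window-1 entries averaged over the available prefix; ``centered``
    switches to a symmetric window.
    """

    window: int = 20
    mode: str = "trailing"

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.mode not in ("trailing", "centered"):
            raise ValueError("mode must be 'trailing' or 'centered'")


@dataclasses.dataclass
class EnsembleSummary:
    """Per-nucleus mean, spread (max - min) and histogram of delta."""

    table: pd.DataFrame  # index nucleus, columns mean/spread/min/max
    histograms: dict[str, tuple[np.ndarray, np.ndarray]]


def ensemble_summary(series: ShiftSeries, bins: int = 40) -> EnsembleSummary:
    rows = {}
    hists = {}
    for nuc in series.nuclei:
        v = series.delta[nuc]
        if v.size == 0:
            raise ValueError(f"empty series for {nuc}")
        rows[nuc] = {
            "mean": float(np.mean(v)),
            "spread": float(np.max(v) - np.min(v)),
            "min": float(np.min(v)),
            "max": float(np.max(v)),
            "n": int(v.size),
        }
        hists[nuc] = np.histogram(v, bins=bins)
    table = pd.DataFrame(rows).T
    table.index.name = "nucleus"
    return EnsembleSummary(table=table, histograms=hists)


def rolling_average(
    values: Sequence[float], config: RollingConfig = RollingConfig()
) -> np.ndarray:
    """Rolling mean of a series.

    Trailing mode is causal with prefix shortening (entry k averages the
    last ``window`` values up to and including k); centered mode uses a
    symmetric window shortened at both edges. Window 1 is the identity.
    """
    s = pd.Series(np.asarray(values, float))
    if s.empty:
        raise ValueError("rolling_average requires a nonempty series")
    center = config.mode == "centered"
    return (
        s.rolling(config.window, min_periods=1, center=center)
        .mean()
        .to_numpy()
    )


def round_half_away(x: float, decimals: int = 2) -> float:
    """Round half away from zero (the convention of printed shift tables;
    numpy rounds half to even)."""
    q = Decimal(1).scaleb(-decimals)
    d = Decimal(repr(float(x)))
    sign = -1 if d < 0 else 1
    return float(sign * (abs(d).quantize(q, rounding=ROUND_HALF_UP)))


@dataclasses.dataclass
class DeviationRow:
    """One deviation-table row: per-nucleus |delta_calc - delta_exp| (ppm,
    rounded half away from zero to 2 decimals) and the row average P-bar
    computed from the unrounded deviations, then rounded."""

    deviations: dict[str, float]
    p_bar: float

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.deviations.values()):
            raise ValueError("deviations must be non-negative")


def deviation_table(
    calc_means: Mapping[str, float],
    experimental: Mapping[str, float],
    decimals: int = 2,
) -> DeviationRow:
    """Per-nucleus absolute deviation and its row average P-bar.

    Only nuclei present in both inputs contribute; P-bar is the arithmetic
    mean of the unrounded deviations, rounded last. Symmetric under
    swapping calculated and experimental values.
    """
    common = [n for n in calc_means if n in experimental]
    if not common:
        raise ValueError("no nucleus common to calculated and experimental sets")
    raw = {n: abs(float(calc_means[n]) - float(experimental[n])) for n in common}
    p_bar = float(np.mean(list(raw.values())))
    return DeviationRow(
        deviations={n: round_half_away(v, decimals) for n, v in raw.items()},
        p_bar=round_half_away(p_bar, decimals),
    )


def deviation_frame(
    rows: Mapping[tuple[str, str], DeviationRow]
) -> pd.DataFrame:
    """Assemble rows keyed by (state, geometry regime) into a printed-table
    shaped DataFrame with columns P_alpha..P_i and P_bar."""
    nuclei = [n for n in CANONICAL_ORDER
              if any(n in r.deviations for r in rows.values())]
    data = {}
    for (state, regime), row in rows.items():
        rec = {n: row.deviations.get(n, np.nan) for n in nuclei}
        rec["P_bar"] = row.p_bar
        data[(state, regime)] = rec
    df = pd.DataFrame(data).T
    df.index.names = ["state", "regime"]
    return df


def peak_order(series: ShiftSeries) -> tuple[list[str], bool]:
    """Nucleus labels ordered by mean delta, most downfield (largest ppm)
    first. Ties are broken by canonical label order and flagged."""
    means = series.means()
    if len(means) < 2:
        raise ValueError("peak_order requires at least two nuclei")
    canon = {n: i for i, n in enumerate(CANONICAL_ORDER)}
    ordered = sorted(
        means, key=lambda n: (-means[n], canon.get(n, len(canon)))
    )
    vals = sorted(means.values(), reverse=True)
    tie = any(abs(a - b) < 1e-12 for a, b in zip(vals, vals[1:]))
    return ordered, tie
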