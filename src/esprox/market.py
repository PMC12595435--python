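"""Market collapse/recovery rates and baseline ES proximity from prices.

For one market index P(t) with a known recession window, the crash episode
is anchored at t1 (maximal price within the window) and t2 (minimal price
after t1).  Over an evaluation span of alpha trading days,

    R1 = [P(t1) - P(t1 + alpha)] / [P(t1) - P(t2)]   (collapse rate)
    R2 = [P(t2 + alpha) - P(t2)] / [P(t1) - P(t2)]   (recovery rate)

and the response and recovery times are ln(1/R1) and ln(1/R2): a market
that completes its fall (rebound) within alpha days has R = 1 and time 0;
slower moves give positive times.  Both rates are price-scale invariant.

Baseline (pre-crisis) ES proximity is the kurtosis of moving-window lagged
ACF values of a daily synchronization proxy: either the cross-sectional
phase (or sign) coherence of constituent-stock log-returns (panel mode) or
the index's own log-return series (single-series mode).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .metrics import windowed_acf
from .signals import EsProximityReport

__all__ = [
    "MarketEpisode",
    "MarketTiming",
    "locate_extrema",
    "collapse_recovery_rates",
    "market_es_proximity",
    "analyze_markets",
]

DEFAULT_ALPHA = 100          # trading days
DEFAULT_MARKET_LAG = 2       # trading days
DEFAULT_MARKET_WINDOW = 60.0  # trading days
DEFAULT_MARKET_STEP = 5.0    # trading days
MIN_BASELINE_DAYS = 150


def _as_price_series(prices) -> pd.Series:
    s = pd.Series(prices) if not isinstance(prices, pd.Series) else prices.copy()
    s = s.dropna()
    if (s <= 0).any():
        raise ValueError("prices must be positive")
    return s


def locate_extrema(prices: pd.Series, recession_window) -> tuple:
    """(t_max, t_min): in-window price maximum, then the minimum after it.

    Ties break toward the earlier date.  Raises if the window is empty;
    a window whose minimum precedes its maximum marks a non-crash episode,
    which :class:`MarketEpisode` flags rather than errors on.
    """
    s = _as_price_series(prices)
    start, end = recession_window
    win = s.loc[start:end]
    if win.empty:
        raise ValueError("recession window contains no price data")
    t_max = win.idxmax()   # first occurrence on ties
    after = win.loc[t_max:]
    t_min = after.idxmin() if len(after) > 1 else win.idxmin()
    return t_max, t_min


@dataclass
class MarketEpisode:
    """One market's crash episode: prices, recession window, alpha span."""

    prices: pd.Series
    recession_window: tuple
    alpha: int = DEFAULT_ALPHA

    def __post_init__(self) -> None:
        self.prices = _as_price_series(self.prices)
        if self.alpha < 1:
            raise ValueError("alpha must be >= 1 trading day")
        start, end = self.recession_window
        win = self.prices.loc[start:end]
        if win.empty:
            raise ValueError("recession window contains no price data")
        # global extrema in the window; non-crash if the minimum comes first
        self.t_max = win.idxmax()
        self.t_min = win.idxmin()
        self.is_crash = self.t_max < self.t_min
        if self.is_crash:
            self.t_max, self.t_min = locate_extrema(self.prices, self.recession_window)

    def _pos(self, ts) -> int:
        return int(self.prices.index.get_loc(ts))


@dataclass
class MarketTiming:
    """Normalized collapse/recovery rates and their log-inverse times."""

    r1: float
    r2: float
    response_time: float = math.nan   # ln(1/R1); NaN when R1 <= 0
    recovery_time: float = math.nan   # ln(1/R2); NaN when R2 <= 0
    flags: tuple = ()


def collapse_recovery_rates(episode: MarketEpisode) -> MarketTiming:
    """R1, R2 and the response/recovery times for one crash episode.

    Alpha counts trading days (rows of the price series), not calendar
    days.  Rates <= 0 (price above the pre-crash maximum at t1 + alpha, or
    below the trough at t2 + alpha) are retained, but the corresponding
    log-inverse time is flagged missing rather than clamped.
    """
    p = episode.prices
    flags = [] if episode.is_crash else ["non_crash"]
    i1 = episode._pos(episode.t_max)
    i2 = episode._pos(episode.t_min)
    if i1 + episode.alpha >= len(p) or i2 + episode.alpha >= len(p):
        raise ValueError("alpha overruns the end of the price series")
    p1, p2 = float(p.iloc[i1]), float(p.iloc[i2])
    if p1 == p2:
        raise ValueError("flat market: P(t1) equals P(t2)")
    drop = p1 - p2
    r1 = (p1 - float(p.iloc[i1 + episode.alpha])) / drop
    r2 = (float(p.iloc[i2 + episode.alpha]) - p2) / drop
    timing = MarketTiming(r1=r1, r2=r2)
    if r1 > 0:
        timing.response_time = math.log(1.0 / r1)
    else:
        flags.append("nonpositive_r1")
    if r2 > 0:
        timing.recovery_time = math.log(1.0 / r2)
    else:
        flags.append("nonpositive_r2")
    timing.flags = tuple(flags)
    return timing


def _phase_coherence(returns: pd.DataFrame, method: str) -> np.ndarray:
    """Daily cross-sectional coherence of per-stock return series.

    ``phase``: Hilbert-transform phases of each (demeaned) return series,
    combined into a Kuramoto order parameter per day.  ``sign``: fraction
    by which up-moves outweigh down-moves, |mean_j sign(ret_jt)|.
    """
    x = returns.to_numpy(dtype=float).T  # stocks x days
    if method == "phase":
        x = x - x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1)
        x = x[sd > 0]
        phases = np.angle(sps.hilbert(x, axis=1))
        return np.abs(np.exp(1j * phases).mean(axis=0))
    if method == "sign":
        return np.abs(np.sign(x).mean(axis=0))
    raise ValueError(f"unknown panel method {method!r}")


def market_es_proximity(
    prices,
    lag: int = DEFAULT_MARKET_LAG,
    window: float = DEFAULT_MARKET_WINDOW,
    step: float = DEFAULT_MARKET_STEP,
    method: str = "phase",
) -> EsProximityReport:
    """Baseline ES proximity of a market from daily data.

    ``prices`` is either a single index-price series (single-series mode:
    the windowed ACF is taken on daily log-returns) or a date x ticker
    DataFrame of constituent prices (panel mode, preferred: the windowed
    ACF is taken on a daily cross-sectional coherence series built from
    per-stock log-returns; ``method`` picks the phase or sign construction).
    Defaults: lag 2 trading days, 60-day windows advancing by 5 days.
    """
    if lag < 1:
        raise ValueError("lag must be >= 1 trading day (lag 0 is degenerate)")
    if isinstance(prices, pd.DataFrame) and prices.shape[1] > 1:
        rets = np.log(prices).diff().dropna(how="all")
        if len(rets) < MIN_BASELINE_DAYS:
            raise ValueError(f"baseline needs >= {MIN_BASELINE_DAYS} trading days")
        series = _phase_coherence(rets, method)
        mode = f"panel_{method}"
    else:
        s = _as_price_series(
            prices.iloc[:, 0] if isinstance(prices, pd.DataFrame) else prices
        )
        if len(s) < MIN_BASELINE_DAYS:
            raise ValueError(f"baseline needs >= {MIN_BASELINE_DAYS} trading days")
        series = np.log(s).diff().dropna().to_numpy()
        mode = "index_returns"
    if np.allclose(series, series[0]):
        raise ValueError("constant series: ES proximity undefined")
    wacf = windowed_acf(series, window_length=window, step=step, lag=lag,
                        sampling_rate=1.0)
    report = EsProximityReport(
        kurtosis=wacf.kurtosis,
        n_windows=int(wacf.valid_values.size),
        band=(math.nan, math.nan),
        lag=lag,
        window_length=window,
        step=step,
        per_window_acf=wacf.acf_values,
        n_missing=wacf.n_missing,
        low_confidence=wacf.low_confidence,
        mode=mode,
    )
    return report


def analyze_markets(
    panel: pd.DataFrame,
    recession_window,
    baseline_window,
    alpha: int = DEFAULT_ALPHA,
    lag: int = DEFAULT_MARKET_LAG,
    method: str = "phase",
) -> pd.DataFrame:
    """Per-market R1, R2, response/recovery times and baseline kurtosis.

    ``panel`` is tidy daily data with columns ``date``, ``market_id``,
    ``price`` and optionally ``ticker`` (constituent prices; when present
    the baseline kurtosis uses panel mode, and the market index is the
    equal-weight mean constituent price).  Recession and baseline windows
    are (start, end) date pairs applied to every market.
    """
    df = panel.copy()
    df["date"] = pd.to_datetime(df["date"])
    has_tickers = "ticker" in df.columns and df["ticker"].notna().any()
    rows = []
    for market, g in df.groupby("market_id"):
        if has_tickers:
            wide = g.pivot_table(index="date", columns="ticker", values="price")
            index_prices = wide.mean(axis=1)
        else:
            wide = None
            index_prices = g.set_index("date")["price"].sort_index()
        episode = MarketEpisode(index_prices, recession_window, alpha)
        timing = collapse_recovery_rates(episode)
        b0, b1 = baseline_window
        baseline = (
            wide.loc[b0:b1] if wide is not None else index_prices.loc[b0:b1]
        )
        report = market_es_proximity(baseline, lag=lag, method=method)
        rows.append({
            "market_id": market,
            "r1": timing.r1,
            "r2": timing.r2,
            "response_time": timing.response_time,
            "recovery_time": timing.recovery_time,
            "kurtosis": report.kurtosis,
            "mode": report.mode,
            "flags": ";".join(timing.flags),
        })
    return pd.DataFrame(rows).set_index("market_id")
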