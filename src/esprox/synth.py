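"""Seeded generators for surrogate recordings and synthetic market panels.

Surrogate multichannel recordings come from the mechanistic simulator
itself — each channel is one oscillator's real part, simulated at the
network's own critical coupling for a chosen feedback exponent — so
estimator validation is a genuine round trip through the model rather
than through phenomenological noise.  Market panels are geometric random
walks with a controlled crash/rebound segment and a two-state Markov
regime switch in cross-sectional coherence during the baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .model import SimulationConfig, generate_topology, simulate
from .perturbation import locate_critical_coupling
from .signals import MultichannelSignal

__all__ = [
    "SurrogateSpec",
    "MarketPanelSpec",
    "make_surrogate_recording",
    "make_market_panel",
]

# S* searches are expensive; one population (topology + frequencies) is
# shared across surrogate draws so each (z, population) pair is solved once
_CRITICAL_CACHE: dict = {}


@dataclass
class SurrogateSpec:
    """Surrogate multichannel recording emulating resting-state EEG."""

    n_channels: int = 32
    sampling_rate: float = 500.0     # Hz
    duration: float = 180.0          # s
    z_truth: float = 0.0             # feedback exponent used for generation
    noise_snr: float = 20.0          # dB sensor noise; inf = noiseless
    seed: int = 0
    population_seed: int = 0         # fixes topology + frequencies
    links_per_node: int = 4
    # near-bifurcation regime: weak limit cycles with strong relative noise
    # give graded, alpha-band-like collective dynamics whose windowed-ACF
    # tails survive the bandpass/Hilbert estimation pipeline
    config: SimulationConfig = field(
        default_factory=lambda: SimulationConfig(lam=0.25))

    def __post_init__(self) -> None:
        if self.n_channels < 2:
            raise ValueError("need at least 2 channels")
        if self.duration < 30.0:
            raise ValueError("duration too short for any windowed statistic")
        steps_per_sample = 1.0 / (self.config.dt * self.sampling_rate)
        if abs(steps_per_sample - round(steps_per_sample)) > 1e-9:
            raise ValueError("sampling_rate must divide the integration rate")


def _population(spec: SurrogateSpec):
    """Topology, frequency configuration and critical coupling for one
    (z_truth, population) pair, cached across draws."""
    key = (spec.n_channels, spec.links_per_node, spec.population_seed,
           float(spec.z_truth), spec.config.lam if np.isscalar(spec.config.lam) else None)
    if key in _CRITICAL_CACHE:
        return _CRITICAL_CACHE[key]
    top = generate_topology("random", spec.n_channels,
                            spec.links_per_node * spec.n_channels,
                            seed=spec.population_seed)
    rng = np.random.default_rng(np.random.SeedSequence((spec.population_seed, 1)))
    omega = rng.normal(spec.config.omega_mean, spec.config.omega_sd, spec.n_channels)
    cfg = replace(spec.config, feedback_exponent=float(spec.z_truth),
                  omega=omega, seed=int(rng.integers(2**31)))
    cp = locate_critical_coupling(top, cfg, fine_duration=120.0)
    out = (top, omega, cp.s_critical)
    _CRITICAL_CACHE[key] = out
    return out


def make_surrogate_recording(spec: SurrogateSpec):
    """Simulate a surrogate recording; returns (signal, sidecar).

    The network runs at its own peak-PCF critical coupling for
    ``spec.z_truth``; node real parts become channels, downsampled to
    ``spec.sampling_rate`` and overlaid with white sensor noise at
    ``spec.noise_snr`` dB (per channel, relative to that channel's power).
    The sidecar records the full ground truth.
    """
    top, omega, s_star = _population(spec)
    cfg = replace(
        spec.config, coupling=s_star, feedback_exponent=float(spec.z_truth),
        omega=omega, duration=spec.config.transient + spec.duration,
        seed=spec.seed, store_state=True,
    )
    traj = simulate(top, cfg)
    stride = int(round(1.0 / (cfg.dt * spec.sampling_rate)))
    data = traj.state[::stride].real.T.copy()   # channels x samples
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 2)))
    if np.isfinite(spec.noise_snr):
        power = np.mean(data**2, axis=1, keepdims=True)
        noise_sd = np.sqrt(power / 10.0 ** (spec.noise_snr / 10.0))
        data = data + noise_sd * rng.standard_normal(data.shape)
    signal = MultichannelSignal(data, spec.sampling_rate)
    sidecar = {
        "z_truth": float(spec.z_truth),
        "s_critical": float(s_star),
        "seed": spec.seed,
        "population_seed": spec.population_seed,
        "n_channels": spec.n_channels,
        "sampling_rate": spec.sampling_rate,
        "duration_s": spec.duration,
        "noise_snr_db": spec.noise_snr,
    }
    return signal, sidecar


@dataclass
class MarketPanelSpec:
    """Synthetic daily price panel with a controlled crash and rebound.

    ``crash_speed`` and ``rebound_speed`` are log-price drifts per trading
    day during the fall and rise; ``crash_depth`` is the total log drop, so
    the time to trough is crash_depth / crash_speed days.
    ``coherence_bistability`` is the daily regime-switch probability of the
    baseline two-state (high/low cross-sectional coherence) Markov chain —
    the ground-truth ES proximity the baseline statistic should recover.
    """

    n_markets: int = 20
    n_days: int = 1200
    n_stocks: int = 20
    crash_day: int = 600
    crash_speed: float | np.ndarray = 0.007    # log-price drop per day
    rebound_speed: float | np.ndarray = 0.002  # log-price rise per day
    coherence_bistability: float | np.ndarray = 0.05  # switch prob / day
    crash_depth: float = 0.7                   # total log drop at trough
    base_volatility: float = 0.01              # idiosyncratic daily sd
    coherent_loading: float = 0.9              # common-factor share, high regime
    incoherent_loading: float = 0.1            # common-factor share, low regime
    start: str = "2005-01-03"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.crash_day < self.n_days):
            raise ValueError("crash_day must be interior to the series")
        for name in ("crash_speed", "rebound_speed", "coherence_bistability"):
            v = np.broadcast_to(np.asarray(getattr(self, name), float),
                                (self.n_markets,)).copy()
            if name != "coherence_bistability" and np.any(v <= 0):
                raise ValueError(f"{name} must be positive")
            setattr(self, name, v)
        if self.base_volatility < 0:
            raise ValueError("base_volatility must be nonnegative")


def make_market_panel(spec: MarketPanelSpec):
    """Generate a tidy (date, market_id, ticker, price) panel + sidecar.

    Per market: stock log-returns share a common factor whose loading
    alternates between coherent and incoherent regimes (two-state Markov
    chain, switch probability ``coherence_bistability`` per day) up to the
    crash; from ``crash_day`` all stocks drift down by ``crash_speed`` per
    day until the cumulative drop reaches ``crash_depth``, then drift up by
    ``rebound_speed``.  The sidecar stores trough dates and all speeds.
    """
    dates = pd.bdate_range(spec.start, periods=spec.n_days)
    rng = np.random.default_rng(spec.seed)
    frames = []
    truth = {}
    for m in range(spec.n_markets):
        mid = f"M{m:02d}"
        q = float(spec.coherence_bistability[m])
        down = float(spec.crash_speed[m])
        up = float(spec.rebound_speed[m])
        days_down = int(np.ceil(spec.crash_depth / down))
        trough = min(spec.crash_day + days_down, spec.n_days - 1)

        # baseline regime chain: 1 = coherent, 0 = incoherent
        flips = rng.random(spec.n_days) < q
        regime = np.bitwise_xor.accumulate(flips).astype(int)
        factor = rng.standard_normal(spec.n_days) * spec.base_volatility
        loading = np.where(regime == 1, spec.coherent_loading,
                           spec.incoherent_loading)
        drift = np.zeros(spec.n_days)
        drift[spec.crash_day:trough] = -down
        drift[trough:] = up
        eps = rng.standard_normal((spec.n_stocks, spec.n_days))
        rets = (
            drift[None, :]
            + loading[None, :] * factor[None, :]
            + np.sqrt(1.0 - loading[None, :] ** 2) * spec.base_volatility * eps
        )
        prices = 100.0 * np.exp(np.cumsum(rets, axis=1))
        df = pd.DataFrame({
            "date": np.repeat(dates.values, spec.n_stocks),
            "market_id": mid,
            "ticker": np.tile([f"{mid}S{j:02d}" for j in range(spec.n_stocks)],
                              spec.n_days),
            "price": prices.T.ravel(),
        })
        frames.append(df)
        truth[mid] = {
            "crash_speed": down,
            "rebound_speed": up,
            "coherence_bistability": q,
            "crash_day": str(dates[spec.crash_day].date()),
            "trough_day": str(dates[trough].date()),
            "days_to_trough": days_down,
        }
    panel = pd.concat(frames, ignore_index=True)
    sidecar = {"spec_seed": spec.seed, "markets": truth,
               "crash_depth": spec.crash_depth}
    return panel, sidecar
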