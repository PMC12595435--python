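"""Perturbation protocol at the critical point: loss and recovery timing.

A network sitting at its peak-PCF critical coupling is driven by a global
square pulse u(t).  The baseline state is summarized by the moving-window
ACF of the order parameter before the pulse; the baseline zone is the
baseline mean +/- 3 SD of those windowed-ACF values.  Loss time is the
delay from pulse onset until the windowed ACF first leaves the zone;
recovery time is the delay from pulse offset until it sustainably returns.
Across networks of increasing ES proximity (feedback exponent Z), the
baseline ACF kurtosis rises while loss accelerates and recovery slows,
yielding a negative kurtosis/loss-time and positive kurtosis/recovery-time
rank correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import metrics
from .metrics import WindowedACF, windowed_acf
from .model import (
    NetworkTopology,
    PerturbationProtocol,
    SimulationConfig,
    SimulationBlowUpError,
    simulate,
    sweep_coupling,
)

__all__ = [
    "BaselineZone",
    "ResponseTiming",
    "CriticalPointResult",
    "ExperimentRow",
    "ExperimentResult",
    "baseline_zone",
    "measure_response",
    "locate_critical_coupling",
    "run_es_experiment",
]

#: default Z grid: seven ES proximities from non-ES to strongly explosive
DEFAULT_Z_GRID = (0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0)


@dataclass
class BaselineZone:
    """Baseline windowed-ACF mean +/- ``n_sd`` standard deviations."""

    mean: float
    half_width: float
    n_windows: int = 0

    @property
    def lower(self) -> float:
        return self.mean - self.half_width

    @property
    def upper(self) -> float:
        return self.mean + self.half_width

    def contains(self, value: float) -> bool:
        """NaN (undefined ACF) counts as outside the baseline zone."""
        return bool(np.isfinite(value) and self.lower <= value <= self.upper)


@dataclass
class ResponseTiming:
    """Times to leave and to sustainably re-enter the baseline zone, s."""

    loss_time: float = math.nan       # from pulse onset to first exit
    recovery_time: float = math.nan   # from pulse offset to sustained return
    loss_censored: bool = False       # never left the zone within the horizon
    recovery_censored: bool = False   # never returned within the horizon


@dataclass
class CriticalPointResult:
    """Outcome of the two-stage peak-PCF critical-coupling search."""

    s_critical: float
    coarse_sweep: metrics.CouplingSweep
    fine_sweep: metrics.CouplingSweep
    endpoint_peak: bool = False


@dataclass
class ExperimentRow:
    z: float
    realization: int
    seed: int
    s_critical: float
    baseline_kurtosis: float
    timing: ResponseTiming
    baseline_mean_r: float = math.nan
    baseline_pinned: bool = False  # baseline sat on the synchronized branch
    baseline_acf: np.ndarray | None = None  # finite baseline window ACFs


@dataclass
class ExperimentResult:
    rows: list[ExperimentRow]
    summary: dict | None = None          # per-realization baseline kurtosis
    summary_pooled: dict | None = None   # kurtosis of per-Z pooled ACF values
    failures: list = field(default_factory=list)


def baseline_zone(baseline_acf: WindowedACF, n_sd: float = 3.0) -> BaselineZone:
    """Zone of normal critical-state variability: mean +/- 3 SD of the
    baseline windowed-ACF values."""
    vals = baseline_acf.valid_values
    if vals.size < 10:
        raise ValueError(f"need >= 10 baseline windows, got {vals.size}")
    sd = float(np.std(vals))
    if sd == 0.0:
        raise ValueError("degenerate baseline: zero SD of windowed ACF")
    return BaselineZone(mean=float(np.mean(vals)), half_width=n_sd * sd,
                        n_windows=int(vals.size))


def measure_response(
    acf_timeline: WindowedACF,
    zone: BaselineZone,
    protocol: PerturbationProtocol,
    dwell: int = 3,
) -> ResponseTiming:
    """Loss/recovery clock readings from a windowed-ACF timeline.

    Times are referenced to window centers: loss to pulse onset, recovery
    to pulse offset.  Recovery requires ``dwell`` consecutive in-zone
    windows (dwell=1 reproduces the literal 3-SD return rule).  If the ACF
    never leaves the zone, loss is censored and the recovery time is 0 by
    convention.  Window timestamps and the protocol must share the same
    clock (time since the start of the analyzed series).
    """
    centers = acf_timeline.window_centers
    values = acf_timeline.acf_values
    if centers.size == 0 or protocol.onset > centers[-1] or protocol.onset < centers[0]:
        raise ValueError("perturbation onset lies outside the ACF timeline")
    if dwell < 1:
        raise ValueError("dwell must be >= 1")
    in_zone = np.array([zone.contains(v) for v in values])

    timing = ResponseTiming()
    post_onset = np.nonzero(centers > protocol.onset)[0]
    exited = post_onset[~in_zone[post_onset]]
    if exited.size == 0:
        timing.loss_censored = True
        timing.recovery_time = 0.0
        return timing
    loss_idx = int(exited[0])
    timing.loss_time = float(centers[loss_idx] - protocol.onset)

    # the return clock runs from pulse offset, but a return can only begin
    # once the ACF has actually crossed out of the zone
    candidates = np.nonzero((centers > protocol.offset)
                            & (np.arange(centers.size) > loss_idx))[0]
    timing.recovery_censored = True
    for pos, i in enumerate(candidates):
        run = candidates[pos : pos + dwell]
        if run.size < dwell:
            break
        if in_zone[run].all():
            timing.recovery_time = float(centers[i] - protocol.offset)
            timing.recovery_censored = False
            break
    if timing.recovery_censored:
        timing.recovery_time = math.nan
    return timing


def locate_critical_coupling(
    topology: NetworkTopology,
    config_template: SimulationConfig,
    coarse_grid: np.ndarray | None = None,
    n_coarse: int = 2,
    n_fine: int = 3,
    fine_points: int = 10,
    fine_duration: float = 300.0,
    acf_kwargs: dict | None = None,
) -> CriticalPointResult:
    """Two-stage peak-PCF search for the critical coupling S*.

    A coarse ascending sweep brackets the synchronization transition (the
    first grid interval where the mean order parameter crosses 0.5 or, if
    it never does, the coarse peak-PCF neighbourhood); a finer, longer
    sweep inside the bracket then locates the PCF maximum.  The two-stage
    form is needed because high-Z (explosive) networks jump within a
    narrow coupling window that a single coarse grid usually misses.
    """
    if coarse_grid is None:
        coarse_grid = np.geomspace(0.5, 80.0, 18)
    coarse = sweep_coupling(topology, config_template, coarse_grid,
                            n_realizations=n_coarse, acf_kwargs=acf_kwargs)
    r = np.nan_to_num(coarse.mean_r, nan=0.0)
    crossed = r > 0.5
    if crossed.any():
        j = int(np.argmax(crossed))
        lo = coarse_grid[max(j - 1, 0)]
        hi = coarse_grid[j]
    else:
        j = int(np.nanargmax(coarse.pcf_values))
        lo = coarse_grid[max(j - 1, 0)]
        hi = coarse_grid[min(j + 1, coarse_grid.size - 1)]
    fine_grid = np.linspace(lo, hi, fine_points)
    fine_template = replace(config_template, duration=fine_duration,
                            seed=config_template.seed + 1)
    fine = sweep_coupling(topology, fine_template, fine_grid,
                          n_realizations=n_fine, acf_kwargs=acf_kwargs)
    # the critical point separates the incoherent and synchronized branches:
    # restrict the peak-PCF pick to grid points whose mean order parameter is
    # genuinely intermediate (co-existence / fluctuation region); points deep
    # on either branch can still show large transient PCF from one-way
    # nucleation inside the sweep window.  The lower bound tracks the
    # finite-size incoherent floor r ~ N^(-1/2).
    lo_r = max(0.15, 1.5 / np.sqrt(topology.n_nodes))
    mid = (fine.mean_r >= lo_r) & (fine.mean_r <= 0.85)
    if mid.sum() >= 3:
        sub = metrics.CouplingSweep(
            s_values=fine.s_values[mid], pcf_values=fine.pcf_values[mid],
            mean_r=fine.mean_r[mid], mean_acf=fine.mean_acf[mid],
            direction=fine.direction)
        try:
            s_star = metrics.find_critical_point(sub, smooth=True)
            fine.critical_s = s_star
            fine.endpoint_peak = sub.endpoint_peak
        except ValueError:
            s_star = metrics.find_critical_point(fine, smooth=True)
    else:
        # 3-point smoothing suppresses single-grid-point flukes of the
        # noisy PCF estimate inside the narrow bistable window
        s_star = metrics.find_critical_point(fine, smooth=True)
    return CriticalPointResult(
        s_critical=s_star,
        coarse_sweep=coarse,
        fine_sweep=fine,
        endpoint_peak=fine.endpoint_peak,
    )


def run_es_experiment(
    topology: NetworkTopology,
    z_grid=DEFAULT_Z_GRID,
    n_realizations: int = 25,
    pulse_strength: float = 10.0,
    pulse_duration: float = 5.0,
    baseline: float = 120.0,
    horizon: float = 300.0,
    config_template: SimulationConfig | None = None,
    dwell: int = 3,
    seed: int = 0,
    critical_couplings: dict | None = None,
    window_length: float = 10.0,
    step: float = 5.0,
    timeline_step: float = 1.0,
    lag: int | None = None,
    search_kwargs: dict | None = None,
    min_summary_rows: int = 10,
) -> ExperimentResult:
    """Z-sweep experiment behind the kurtosis vs loss/recovery correlations.

    For each feedback exponent Z: find (or look up) the peak-PCF critical
    coupling, then run ``n_realizations`` seeded simulations at that
    coupling consisting of a discarded transient, a baseline segment, a
    global pulse of ``pulse_strength`` lasting ``pulse_duration`` seconds,
    and a post-pulse horizon.  Each row records the baseline windowed-ACF
    kurtosis and the loss/recovery timing against the baseline 3-SD zone.
    The summary holds Spearman correlations of kurtosis with both times
    across all uncensored rows (requires >= ``min_summary_rows``).

    ``critical_couplings`` maps Z -> S* and doubles as a cache: entries are
    used when present and filled in otherwise.
    """
    template = config_template or SimulationConfig()
    if critical_couplings is None:
        critical_couplings = {}
    master = np.random.SeedSequence(seed)
    if template.omega is None:
        # one frequency configuration per experiment: realizations then vary
        # only in initial conditions and noise, so the located critical
        # coupling stays valid for every row
        omega_rng = np.random.default_rng(master.spawn(1)[0])
        omega = omega_rng.normal(template.omega_mean, template.omega_sd,
                                 topology.n_nodes)
        template = replace(template, omega=omega)
    z_seeds = master.spawn(len(list(z_grid)))
    rows: list[ExperimentRow] = []
    failures = []
    duration = template.transient + baseline + pulse_duration + horizon
    protocol_run = None
    for z, zss in zip(z_grid, z_seeds):
        zrng = np.random.default_rng(zss)
        if z not in critical_couplings:
            search_cfg = replace(template, feedback_exponent=float(z),
                                 seed=int(zrng.integers(2**31)))
            critical_couplings[z] = locate_critical_coupling(
                topology, search_cfg, **(search_kwargs or {})).s_critical
        s_star = critical_couplings[z]
        for k in range(n_realizations):
            run_seed = int(zrng.integers(2**31))
            cfg = replace(
                template, coupling=float(s_star), feedback_exponent=float(z),
                duration=duration, seed=run_seed, store_state=False,
            )
            protocol_run = PerturbationProtocol(
                strength=pulse_strength,
                onset=template.transient + baseline,
                offset=template.transient + baseline + pulse_duration,
            )
            try:
                traj = simulate(topology, cfg, perturbation=protocol_run)
            except SimulationBlowUpError as exc:
                failures.append((float(z), k, str(exc)))
                continue
            # clock of the analyzed series starts at the end of the transient
            onset = baseline
            offset = baseline + pulse_duration
            # baseline statistic on the standard (non-overlapping-heavy)
            # stride; a finer-stride timeline gives timing resolution
            wacf = windowed_acf(traj.order_parameter, window_length, step,
                                lag=lag)
            timeline = windowed_acf(traj.order_parameter, window_length,
                                    timeline_step, lag=lag)
            pre = wacf.window_centers + window_length / 2.0 <= onset
            base_vals = wacf.acf_values[pre]
            base_finite = base_vals[np.isfinite(base_vals)]
            try:
                zone = baseline_zone(
                    WindowedACF(window_length, step, wacf.lag, base_vals,
                                wacf.window_centers[pre], math.nan)
                )
                b_kurt = metrics.kurtosis(base_finite)
            except ValueError as exc:
                failures.append((float(z), k, f"degenerate baseline: {exc}"))
                continue
            timing = measure_response(
                timeline, zone,
                PerturbationProtocol(pulse_strength, onset, offset),
                dwell=dwell,
            )
            r_vals = traj.order_parameter.values
            n_base = int(onset * traj.order_parameter.sampling_rate)
            base_r = float(r_vals[:n_base].mean())
            rows.append(ExperimentRow(
                float(z), k, run_seed, float(s_star), float(b_kurt), timing,
                baseline_mean_r=base_r,
                # a baseline locked on the synchronized branch is not a
                # critical-state trial; flagged and excluded from summaries
                baseline_pinned=base_r > 0.9,
                baseline_acf=base_finite,
            ))
    result = ExperimentResult(rows=rows, failures=failures)
    result.summary = _summarize(rows, min_summary_rows)
    result.summary_pooled = _summarize(rows, min_summary_rows, pooled=True)
    return result


def _summarize(rows: list[ExperimentRow], min_rows: int,
               pooled: bool = False) -> dict | None:
    """Rank correlations of baseline kurtosis vs loss/recovery times.

    ``pooled`` replaces each row's own kurtosis with the kurtosis of the
    baseline ACF values pooled across that Z level's (non-pinned) rows —
    the per-Z distribution view; per-realization kurtosis from a ~2-min
    baseline rests on few windows and is noisy."""
    n_pinned = sum(r.baseline_pinned for r in rows)
    rows = [r for r in rows if not r.baseline_pinned]
    if pooled:
        pool: dict[float, list] = {}
        for r in rows:
            if r.baseline_acf is not None:
                pool.setdefault(r.z, []).append(r.baseline_acf)
        z_kurt = {}
        for z, chunks in pool.items():
            vals = np.concatenate(chunks)
            if vals.size >= 4 and np.var(vals) > 0:
                z_kurt[z] = metrics.kurtosis(vals)
        rows = [r for r in rows if r.z in z_kurt]
        kurt = np.array([z_kurt[r.z] for r in rows])
    else:
        kurt = np.array([r.baseline_kurtosis for r in rows])
    loss = np.array([r.timing.loss_time for r in rows])
    rec = np.array([r.timing.recovery_time for r in rows])
    ok_loss = np.isfinite(loss) & np.isfinite(kurt)
    ok_rec = np.isfinite(rec) & np.isfinite(kurt)
    if ok_loss.sum() < min_rows or ok_rec.sum() < min_rows:
        return None
    try:
        rho_l, p_l = metrics.rank_correlation(kurt[ok_loss], loss[ok_loss])
        rho_r, p_r = metrics.rank_correlation(kurt[ok_rec], rec[ok_rec])
    except ValueError:
        return None  # degenerate (constant) kurtosis or time vector
    return {
        "rho_kurtosis_loss": rho_l,
        "p_kurtosis_loss": p_l,
        "n_loss": int(ok_loss.sum()),
        "rho_kurtosis_recovery": rho_r,
        "p_kurtosis_recovery": p_r,
        "n_recovery": int(ok_rec.sum()),
        "n_pinned_baseline_excluded": int(n_pinned),
    }
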