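"""Feedback-modified Stuart-Landau oscillator networks.

Each node is a complex variable z_j = r_j e^{i theta_j} evolving under

    dz_j/dt = (lambda_j + i omega_j - |z_j|^2) z_j
              + S R(t)^Z sum_k A_jk (z_k(t - tau_jk) - z_j(t))
              + beta xi_j(t) + u(t)

where R(t) is the instantaneous global order-parameter magnitude.  The
feedback factor R^Z makes the effective coupling state-dependent: weak
global synchrony suppresses local coupling and strong synchrony sustains
it, which introduces internal resistance to state change, hysteresis, and
— as Z grows — a shift of the synchronization transition from a gradual
second-order form toward the abrupt, explosive (first-order) limit.
u(t) is a global pulsatile perturbation applied identically to all nodes.

Integration is Euler-Maruyama with a ring-buffer delay history; the noise
term is an independent complex Gaussian increment of standard deviation
beta * sqrt(dt) on each of the real and imaginary parts.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import networkx as nx
import numpy as np

from ._integrator import BLOWUP_GUARD, advance_chunk
from .metrics import CouplingSweep, OrderParameterSeries, pcf, windowed_acf

__all__ = [
    "NetworkTopology",
    "SimulationConfig",
    "PerturbationProtocol",
    "TrajectoryResult",
    "SimulationBlowUpError",
    "generate_topology",
    "simulate",
    "sweep_coupling",
]

TOPOLOGY_KINDS = ("random", "scale_free", "small_world", "custom")


class SimulationBlowUpError(RuntimeError):
    """Raised when a node amplitude exceeds the numerical guard threshold."""


@dataclass
class NetworkTopology:
    """Undirected, connected, unweighted coupling graph."""

    n_nodes: int
    adjacency: np.ndarray       # symmetric 0/1, zero diagonal
    kind: str
    n_links: int
    seed: int | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.shape != (self.n_nodes, self.n_nodes):
            raise ValueError("adjacency shape does not match n_nodes")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency diagonal must be zero")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency must be binary")
        links = int(a.sum()) // 2
        if links != self.n_links:
            raise ValueError(f"n_links={self.n_links} but adjacency has {links} edges")
        if self.kind not in TOPOLOGY_KINDS:
            raise ValueError(f"unknown topology kind {self.kind!r}")
        if not nx.is_connected(nx.from_numpy_array(a)):
            raise ValueError("graph must be connected")
        self.adjacency = a.astype(np.int8)

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(np.int64)

    @classmethod
    def from_adjacency(cls, adjacency: np.ndarray, seed: int | None = None) -> "NetworkTopology":
        a = np.asarray(adjacency)
        return cls(a.shape[0], a, "custom", int(a.sum()) // 2, seed)


def generate_topology(
    kind: str,
    n_nodes: int,
    n_links: int,
    seed: int,
    rewire_prob: float = 0.1,
    max_tries: int = 200,
) -> NetworkTopology:
    """Generate a connected topology with (approximately) ``n_links`` edges.

    random       Erdos-Renyi G(n, m), regenerated until connected.
    scale_free   Barabasi-Albert preferential attachment with m chosen so
                 the edge count is as close to ``n_links`` as the attachment
                 scheme allows (attained count recorded in ``n_links``).
    small_world  Watts-Strogatz ring lattice of even degree
                 2 * n_links / n_nodes, rewired with ``rewire_prob``.

    Deterministic under a fixed seed.
    """
    if n_links < n_nodes - 1:
        raise ValueError("n_links must be at least n_nodes - 1 for connectivity")
    if n_links > n_nodes * (n_nodes - 1) // 2:
        raise ValueError("n_links exceeds the complete-graph edge count")
    rng = np.random.default_rng(seed)
    if kind == "random":
        for _ in range(max_tries):
            g = nx.gnm_random_graph(n_nodes, n_links, seed=int(rng.integers(2**31)))
            if nx.is_connected(g):
                break
        else:
            raise RuntimeError("could not draw a connected G(n, m) graph")
    elif kind == "scale_free":
        m = max(1, round(n_links / n_nodes))
        g = nx.barabasi_albert_graph(n_nodes, m, seed=int(rng.integers(2**31)))
        # BA graphs on a connected seed star are connected by construction
    elif kind == "small_world":
        k = 2 * n_links / n_nodes
        if abs(k - round(k)) > 1e-9 or round(k) % 2 != 0:
            raise ValueError(
                "small_world needs 2 * n_links / n_nodes to be an even integer"
            )
        g = nx.connected_watts_strogatz_graph(
            n_nodes, int(round(k)), rewire_prob, tries=max_tries,
            seed=int(rng.integers(2**31)),
        )
    else:
        raise ValueError(f"unknown topology kind {kind!r}")
    a = nx.to_numpy_array(g, dtype=np.int8)
    return NetworkTopology(n_nodes, a, kind, g.number_of_edges(), seed)


@dataclass
class PerturbationProtocol:
    """Global square pulse u(t) = strength for onset < t < offset, else 0."""

    strength: float             # p, same units as dz/dt forcing
    onset: float                # t1, s (relative to the start of the run)
    offset: float               # t2, s

    def __post_init__(self) -> None:
        if self.offset <= self.onset:
            raise ValueError("offset must exceed onset")
        if self.strength < 0:
            raise ValueError("strength must be nonnegative")

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass
class SimulationConfig:
    """All model parameters for one integration run.

    ``omega`` defaults to i.i.d. Gaussian angular frequencies with mean
    2*pi*10 rad/s and SD 2*pi*1 rad/s (an alpha-band surrogate); ``delay``
    is a homogeneous per-link delay in seconds or a full (n, n) matrix.
    """

    coupling: float = 0.0               # S
    feedback_exponent: float = 0.0      # Z >= 0
    duration: float = 60.0              # total simulated time, s
    transient: float = 20.0             # discarded settling time, s
    dt: float = 1e-3                    # s
    noise_scale: float = 0.05           # beta
    # 2 ms keeps the phase lag omega*tau small; delays of ~10 ms at alpha-band
    # frequencies push the diffusively coupled network into amplitude death
    delay: float | np.ndarray = 0.002   # tau_jk, s
    omega: np.ndarray | None = None     # rad/s, per node; None -> drawn
    omega_mean: float = 2 * np.pi * 10.0
    omega_sd: float = 2 * np.pi * 1.0
    lam: float | np.ndarray = 1.0       # lambda_j, 1/s
    diffusive: bool = True              # subtract degree * z_j in coupling
    store_state: bool = True            # keep full z_j(t); r(t) is always kept
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not (self.duration > self.transient >= 0):
            raise ValueError("need duration > transient >= 0")
        if self.noise_scale < 0 or self.feedback_exponent < 0:
            raise ValueError("noise_scale and feedback_exponent must be >= 0")


@dataclass
class TrajectoryResult:
    """Post-transient trajectory and derived series of one simulation."""

    times: np.ndarray                       # s, absolute simulation time
    order_parameter: OrderParameterSeries   # r(t), always present
    state: np.ndarray | None = None         # (n_samples, n) complex z_j(t)
    phases: np.ndarray | None = None        # (n, n_samples), in (-pi, pi]
    amplitudes: np.ndarray | None = None    # (n, n_samples), >= 0
    final_state: np.ndarray | None = None   # z at the last step (pre-trim)
    final_history: np.ndarray | None = None
    final_head: int = 0
    config: SimulationConfig | None = None


def _edge_arrays(topology: NetworkTopology, delay, dt: float):
    """CSR adjacency plus per-directed-edge delay steps."""
    a = topology.adjacency
    n = topology.n_nodes
    indptr = np.zeros(n + 1, dtype=np.int64)
    cols = []
    for j in range(n):
        nbrs = np.nonzero(a[j])[0]
        cols.append(nbrs)
        indptr[j + 1] = indptr[j] + nbrs.size
    indices = np.concatenate(cols).astype(np.int64) if cols else np.zeros(0, np.int64)
    if np.isscalar(delay):
        tau = np.full(indices.size, float(delay))
    else:
        dmat = np.asarray(delay, dtype=float)
        if dmat.shape != (n, n):
            raise ValueError("delay matrix must be (n_nodes, n_nodes)")
        tau = np.concatenate([dmat[j, cols[j]] for j in range(n)])
    steps = tau / dt
    rounded = np.rint(steps)
    if np.any(np.abs(steps - rounded) > 1e-6):
        raise ValueError("every delay must be an integer multiple of dt")
    return indptr, indices, rounded.astype(np.int64)


def _resolve_per_node(value, n: int) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        return np.full(n, float(arr))
    if arr.shape != (n,):
        raise ValueError("per-node parameter has wrong length")
    return arr.copy()


def simulate(
    topology: NetworkTopology,
    config: SimulationConfig,
    perturbation: PerturbationProtocol | None = None,
    initial_state: np.ndarray | None = None,
    _chunk_steps: int = 20_000,
) -> TrajectoryResult:
    """Integrate the network and return the post-transient trajectory.

    The initial condition (unless ``initial_state`` carries one over from a
    previous run, as in hysteresis sweeps) has uniform random phases on
    (-pi, pi] and amplitude 0.5 for every node; the delay history is the
    initial state held constant.  Bit-reproducible under a fixed seed.
    """
    n = topology.n_nodes
    dt = config.dt
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    omega = (
        np.asarray(config.omega, dtype=float)
        if config.omega is not None
        else rng.normal(config.omega_mean, config.omega_sd, n)
    )
    if omega.shape != (n,):
        raise ValueError("omega has wrong length")
    lam = _resolve_per_node(config.lam, n)
    indptr, indices, edge_delay = _edge_arrays(topology, config.delay, dt)
    max_delay = int(edge_delay.max()) if edge_delay.size else 0

    if initial_state is not None:
        z = np.asarray(initial_state, dtype=np.complex128).copy()
        if z.shape != (n,):
            raise ValueError("initial_state has wrong length")
    else:
        theta0 = rng.uniform(-np.pi, np.pi, n)
        z = (0.5 * np.exp(1j * theta0)).astype(np.complex128)
    hist = np.tile(z, (max_delay + 1, 1))
    head = 0

    n_steps = int(round(config.duration / dt))
    if perturbation is not None:
        if not (0 <= perturbation.onset < perturbation.offset <= config.duration):
            raise ValueError("perturbation window must lie within the run")
    beta_step = config.noise_scale * np.sqrt(dt)
    rot = np.exp(1j * omega * dt)

    r_all = np.empty(n_steps)
    keep_state = config.store_state
    state_all = np.empty((n_steps, n), dtype=np.complex128) if keep_state else None

    done = 0
    while done < n_steps:
        m = min(_chunk_steps, n_steps - done)
        if config.noise_scale > 0:
            # adjacent float64 pairs reinterpreted as (real, imag)
            noise = rng.standard_normal((m, 2 * n)).view(np.complex128)
            noise *= beta_step
        else:
            noise = np.zeros((m, n), dtype=np.complex128)
        t_chunk = (done + np.arange(m)) * dt
        u_chunk = np.zeros(m)
        if perturbation is not None:
            mask = (t_chunk > perturbation.onset) & (t_chunk < perturbation.offset)
            u_chunk[mask] = perturbation.strength
        r_chunk = np.empty(m)
        state_chunk = (
            state_all[done : done + m]
            if keep_state
            else np.empty((0, n), dtype=np.complex128)
        )
        head, blow = advance_chunk(
            z, hist, head, rot, lam, config.coupling,
            config.feedback_exponent, config.diffusive, indptr, indices,
            edge_delay, noise, u_chunk, dt, r_chunk, state_chunk,
        )
        if blow >= 0:
            t_blow = (done + blow) * dt
            raise SimulationBlowUpError(
                f"|z| exceeded {BLOWUP_GUARD:g} at t={t_blow:.3f}s "
                f"(S={config.coupling}, Z={config.feedback_exponent})"
            )
        r_all[done : done + m] = r_chunk
        done += m

    skip = int(round(config.transient / dt))
    times = np.arange(skip, n_steps) * dt
    ops = OrderParameterSeries(np.clip(r_all[skip:], 0.0, 1.0), 1.0 / dt, n)
    result = TrajectoryResult(
        times=times,
        order_parameter=ops,
        final_state=z.copy(),
        final_history=hist.copy(),
        final_head=head,
        config=config,
    )
    if keep_state:
        kept = state_all[skip:]
        result.state = kept
        result.phases = np.angle(kept.T)
        result.amplitudes = np.abs(kept.T)
    return result


def sweep_coupling(
    topology: NetworkTopology,
    config_template: SimulationConfig,
    s_grid: np.ndarray,
    n_realizations: int = 1,
    direction: str = "up",
    carry_state: bool | None = None,
    acf_kwargs: dict | None = None,
):
    """Mean order parameter, PCF and mean windowed ACF along a coupling grid.

    ``direction='up'`` runs the ascending grid with an independent random
    initial condition at every grid point (the protocol behind peak-PCF
    critical-point identification).  ``'down'`` runs the grid descending
    with the state carried over between points (adiabatic hysteresis
    protocol); ``'both'`` returns an (up, down) pair of sweeps, both with
    carry-over, the down-pass continuing from the up-pass's final state.
    Realizations use seeds spawned from ``config_template.seed``.
    """
    s_grid = np.asarray(s_grid, dtype=float)
    if s_grid.size == 0 or np.any(np.diff(s_grid) < 0):
        raise ValueError("s_grid must be nonempty and ascending")
    if n_realizations < 1:
        raise ValueError("n_realizations must be >= 1")
    if direction not in ("up", "down", "both"):
        raise ValueError("direction must be 'up', 'down' or 'both'")
    if direction == "both":
        up = _one_direction_sweep(topology, config_template, s_grid,
                                  n_realizations, "up", True, acf_kwargs,
                                  return_final=True)
        down = _one_direction_sweep(topology, config_template, s_grid,
                                    n_realizations, "down", True, acf_kwargs,
                                    start_states=up.pop("final_states"))
        return _assemble(s_grid, up, "up", n_realizations), _assemble(
            s_grid[::-1], down, "down", n_realizations)
    carry = carry_state if carry_state is not None else (direction == "down")
    res = _one_direction_sweep(topology, config_template, s_grid,
                               n_realizations, direction, carry, acf_kwargs)
    grid = s_grid if direction == "up" else s_grid[::-1]
    return _assemble(grid, res, direction, n_realizations)


def _one_direction_sweep(topology, template, s_grid, n_realizations, direction,
                         carry, acf_kwargs, start_states=None, return_final=False):
    acf_kwargs = acf_kwargs or {}
    grid = s_grid if direction == "up" else s_grid[::-1]
    shape = (grid.size, n_realizations)
    mean_r = np.full(shape, np.nan)
    pcf_v = np.full(shape, np.nan)
    macf = np.full(shape, np.nan)
    failures = []
    final_states = []
    seeds = np.random.SeedSequence(template.seed).spawn(n_realizations)
    for k, ss in enumerate(seeds):
        child = np.random.default_rng(ss)
        state = None if start_states is None else start_states[k]
        for i, s in enumerate(grid):
            cfg = replace(template, coupling=float(s), store_state=False,
                          seed=int(child.integers(2**31)))
            try:
                traj = simulate(topology, cfg, initial_state=state)
            except SimulationBlowUpError as exc:
                failures.append((float(s), k, str(exc)))
                if carry:
                    state = None
                continue
            r = traj.order_parameter
            mean_r[i, k] = r.values.mean()
            pcf_v[i, k] = pcf(r)
            try:
                macf[i, k] = np.nanmean(windowed_acf(r, **acf_kwargs).acf_values)
            except ValueError:
                pass  # run shorter than two windows; ACF column stays NaN
            if carry:
                state = traj.final_state
        final_states.append(state)
    out = {
        "mean_r": np.nanmean(mean_r, axis=1),
        "pcf": np.nanmean(pcf_v, axis=1),
        "macf": np.nanmean(macf, axis=1),
        "failures": failures,
    }
    if return_final:
        out["final_states"] = final_states
    return out


def _assemble(grid, res, direction, n_realizations) -> CouplingSweep:
    return CouplingSweep(
        s_values=np.asarray(grid, dtype=float),
        pcf_values=res["pcf"],
        mean_r=res["mean_r"],
        mean_acf=res["macf"],
        direction=direction,
        n_realizations=n_realizations,
        failures=res["failures"],
    )
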