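"""Integration core for the delayed Stuart-Landau network.

The local (stiff, rotational) part (lambda_j + i omega_j - |z_j|^2) z_j is
advanced with an exponential step — exact for the frozen-coefficient linear
part, so an uncoupled node relaxes to amplitude sqrt(lambda) without the
spurious energy injection a plain Euler step suffers at oscillatory
frequencies — while coupling, forcing and noise enter as Euler-Maruyama
increments.  The Python driver in :mod:`esprox.model` feeds pre-generated
noise in chunks so all randomness flows through one seeded
:class:`numpy.random.Generator`.
"""

import math

import numba
import numpy as np

# guard threshold on |z| beyond which the integration aborts
BLOWUP_GUARD = 1.0e3


@numba.njit(cache=True, fastmath=True)
def advance_chunk(
    z,            # (n,) complex128, current state; updated in place
    hist,         # (L, n) complex128 ring buffer of past states; hist[head] == z
    head,         # int, ring-buffer position of the current state
    rot,          # (n,) complex128 per-step rotation exp(i omega_j dt)
    lam,          # (n,) float64 bifurcation parameters, 1/s
    coupling,     # float, global coupling strength S
    zexp,         # float, feedback exponent Z
    diffusive,    # bool: subtract degree*z_j (diffusive) or not (direct sum)
    indptr,       # (n+1,) int64 CSR row pointers of the adjacency
    indices,      # (E,) int64 CSR column indices
    edge_delay,   # (E,) int64 per-edge delay in integration steps (< L)
    noise,        # (m, n) complex128 pre-scaled noise increments (beta*sqrt(dt))
    u_chunk,      # (m,) float64 global forcing u(t) per step
    dt,           # float, step size in s
    r_out,        # (m,) float64 order-parameter magnitude at each step start
    state_out,    # (m, n) complex128 post-step states (ignored when 0 rows)
):
    """Advance ``m`` steps.  Returns (new_head, blowup_step) with
    blowup_step == -1 when no state exceeded the guard threshold."""
    m = noise.shape[0]
    n = z.shape[0]
    L = hist.shape[0]
    record = state_out.shape[0] > 0
    for t in range(m):
        # instantaneous global order parameter from the current phases
        sr = 0.0
        si = 0.0
        for j in range(n):
            a = abs(z[j])
            if a > 1e-12:
                sr += z[j].real / a
                si += z[j].imag / a
        big_r = np.sqrt(sr * sr + si * si) / n
        r_out[t] = big_r
        gain = coupling * big_r ** zexp if coupling != 0.0 else 0.0

        u = u_chunk[t]
        nxt = head + 1
        if nxt == L:
            nxt = 0
        for j in range(n):
            acc = 0.0 + 0.0j
            deg = 0.0
            for e in range(indptr[j], indptr[j + 1]):
                idx = head - edge_delay[e]
                if idx < 0:
                    idx += L
                acc += hist[idx, indices[e]]
                deg += 1.0
            if diffusive:
                acc -= deg * z[j]
            zj = z[j]
            a2 = zj.real * zj.real + zj.imag * zj.imag
            # exponential step for the frozen local part, Euler for the rest
            znew = (
                rot[j] * (math.exp((lam[j] - a2) * dt) * zj
                          + dt * (gain * acc + u))
                + noise[t, j]
            )
            if znew.real * znew.real + znew.imag * znew.imag > BLOWUP_GUARD**2:
                return head, t
            hist[nxt, j] = znew
        head = nxt
        for j in range(n):
            z[j] = hist[head, j]
        if record:
            for j in range(n):
                state_out[t, j] = z[j]
    return head, -1
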