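# Methods

## The model

Each network node is a Stuart–Landau oscillator written as a complex
variable z_j = r_j e^{iθ_j}:

    dz_j/dt = (λ_j + iω_j − |z_j|²) z_j
              + S · R(t)^Z · Σ_k A_jk (z_k(t − τ_jk) − z_j(t))
              + β ξ_j(t) + u(t)

- λ_j (1/s) sets the distance from the Hopf bifurcation; an uncoupled,
  noiseless node settles on a limit cycle of amplitude √λ.
- ω_j (rad/s) are natural frequencies, drawn i.i.d. N(2π·10, (2π·1)²) —
  an alpha-band surrogate.
- A_jk is a binary, symmetric, connected coupling graph; S is the global
  coupling strength; τ_jk are per-link delays.
- R(t) = |N⁻¹ Σ_j e^{iθ_j(t)}| is the instantaneous Kuramoto order
  parameter.  The feedback factor R^Z makes the effective coupling
  state-dependent: weak global synchrony suppresses local coupling and
  strong synchrony sustains it.  Z = 0 recovers conventional diffusive
  coupling; increasing Z adds internal resistance to state change,
  widening the hysteresis loop and shifting the synchronization
  transition from a gradual (second-order) form toward the explosive
  (first-order) limit.  Z is therefore the ground-truth "ES proximity"
  dial.
- u(t) is a global square pulse (strength p between onset and offset,
  zero otherwise), applied identically to every node as a real additive
  forcing.
- ξ_j(t) is complex white noise: each Euler increment adds independent
  N(0, (β√dt)²) to the real and imaginary parts, with β = 0.05.

Defaults: λ = 1, τ = 2 ms on every link, dt = 1 ms, initial phases
uniform on (−π, π], initial amplitudes 0.5, delay history held at the
initial state.  A delay of ~10 ms was rejected: at ωτ ≈ 0.6 the
diffusively coupled heterogeneous network sits in delay-induced
amplitude death and never synchronizes, at any coupling we tested.

### Integration

The stiff local part (λ_j + iω_j − |z_j|²) z_j is advanced with an
exponential (ETD1) step — exact for the frozen-coefficient linear part —
while coupling, forcing and noise enter as Euler–Maruyama increments
rotated into the same frame.  A plain Euler step at dt = 1 ms visibly
inflates amplitudes (the rotation adds energy ∝ (ω dt)²/dt per unit
time; equilibrium amplitude ≈ 1.72 instead of 1 at λ = 1).  The ETD
form restores √λ to machine precision and keeps dt = 1 ms affordable.
Delays use a ring buffer; every τ_jk must be an integer multiple of dt.
The run aborts if any |z_j| exceeds 10³.  All noise flows from one
seeded `numpy.random.Generator`, so runs are bit-reproducible.

## Statistics

- Order parameter r(t): magnitude of the mean phase vector, recorded at
  every integration step (1 kHz by default).
- PCF = N · Var_t[r(t)], the N-scaled temporal variance; it peaks at the
  critical coupling.
- Windowed ACF: within 10-s windows advancing by 5 s, the biased
  (1/n-normalized) Pearson autocorrelation of r(t) at a single lag,
  default lag = round(f_s/10) samples (≈ one 10-Hz cycle; 50 samples at
  500 Hz).  Zero-variance windows are recorded as missing and excluded.
- ES proximity = Pearson (non-excess) kurtosis m₄/m₂² of the windowed
  ACF values.  Gaussian reference 3; heavier tails — produced by the
  intermittent, bistable dynamics near an explosive critical point —
  push it above 3.  Reported kurtoses from fewer than 30 windows are
  flagged low-confidence.
- Comparators: DFA-1 Hurst exponent (log-spaced boxes from 4 to n/4,
  linear detrend, log–log slope) and Spearman rank correlation (exact
  permutation p for untied n ≤ 9, t-approximation otherwise).

## Critical-point identification

S* is the coupling at the (3-point-smoothed) peak of the PCF curve.
Because high-Z networks jump within a narrow coupling window that a
single coarse grid misses, the search is two-stage: a coarse ascending
geometric sweep (independent random initial conditions per point)
brackets the first crossing of mean r = 0.5; a finer, longer,
multi-realization sweep inside the bracket then locates the PCF peak,
restricted to grid points whose mean order parameter is intermediate
(0.15–0.85) so that transient one-way nucleation deep on a branch is not
mistaken for criticality.  Fine-stage runs last 300 s by default: in an
activated-switching system the operationally observed variance peak
depends on observation time, so the search horizon is matched to the
experiment baseline.  Endpoint peaks are flagged "sweep too narrow".
The frequency configuration is drawn once per experiment and shared by
the search and all realizations; S* depends on the draw, so redrawing
ω_j per realization would invalidate it.

## Perturbation experiment

For each Z: simulate at S*(Z) with a 20-s discarded transient, a 120-s
baseline, a 5-s global pulse of strength p = 10, and a post-pulse
horizon (default 300–420 s).  The baseline zone is the mean ± 3 SD of
the baseline windowed-ACF values (10/5 windows fully before onset;
≥ 10 windows required).  Timing uses the same 10-s windows at a 1-s
stride — the 5-s stride would quantize every loss/recovery time to 5 s.
Loss time: first window center after onset whose ACF falls outside the
zone (undefined ACF counts as outside), minus onset.  Recovery time:
first post-offset window center that both follows the loss crossing and
starts a run of `dwell` consecutive in-zone windows (dwell = 5 timeline
windows ≈ the spec's 3 windows at the 5-s stride), minus offset.  A run
whose ACF never leaves the zone has censored loss and recovery 0 by
convention.  Rows whose baseline mean r exceeds 0.9 are flagged
`baseline_pinned` — the network spent its baseline locked on the
synchronized branch rather than at criticality — and are excluded from
summary correlations (the count is reported).

Summaries give Spearman correlations of baseline kurtosis with loss and
recovery times in two variants: per-realization kurtosis (each row's own
~23 windows; noisy) and pooled kurtosis (ACF values pooled across a Z
level's rows before taking kurtosis — the per-Z distribution view, which
is how the heavy-tail signature is normally displayed and is far more
stable at desk scale).

## Pipelines

EEG-style: per channel, zero-phase 4th-order Butterworth band-pass
(8–13 Hz, forward–backward), Hilbert-transform instantaneous phase with
3/(low Hz)-cycle edge trims per side, channels-as-oscillators order
parameter, windowed ACF (10 s / 5 s, lag 50 at 500 Hz, rescaled as
round(f_s/10) at other rates), kurtosis.  Recordings shorter than 3 min
are processed but flagged.

Market: crash episodes are anchored at the in-recession price maximum
t1 and subsequent minimum t2.  Over α trading days (default 100),
R1 = [P(t1) − P(t1+α)]/[P(t1) − P(t2)] and
R2 = [P(t2+α) − P(t2)]/[P(t1) − P(t2)]; response and recovery times are
ln(1/R1) and ln(1/R2).  α counts rows (trading days).  Nonpositive
rates are kept but their times flagged missing.  Baseline ES proximity
comes from a daily coherence proxy: in panel mode (preferred) the
cross-sectional Hilbert-phase (or sign) coherence of constituent
log-returns; in single-series mode the index's own log-returns.  The
windowed ACF uses lag 2 trading days, 60-day windows, 5-day steps.

## Synthetic data

Surrogate recordings re-use the mechanistic simulator: n_channels
oscillators at the generating Z's own critical coupling, node real
parts as channels, downsampled to 500 Hz, plus white sensor noise at a
per-channel SNR (default 20 dB).  The surrogate config uses λ = 0.25:
near the bifurcation the collective dynamics are graded and noisy
(alpha-band-like bursts) and the windowed-ACF tail structure survives
the band-pass/Hilbert estimation pipeline; at λ = 1 a 32-node critical
network pins to one branch for whole recordings and the reconstruction
noise whitens pinned windows, flattening the statistic.  What the
surrogates do not emulate: volume conduction and sensor mixing,
electrode geometry, non-stationary artifacts, 1/f background — so
passing round-trip tests shows estimator consistency with the model
class, not performance on real EEG.

Market panels are geometric random walks (20 stocks per market, daily
idiosyncratic volatility 1%) sharing a common factor whose loading
switches between a coherent (0.9) and an incoherent (0.1) regime as a
two-state Markov chain with per-day switch probability
`coherence_bistability` — the simplest mechanism producing fat-tailed
windowed-ACF distributions.  From `crash_day` all stocks drift down by
`crash_speed` per day until the cumulative log drop reaches
`crash_depth` (default 0.7), then up by `rebound_speed`.  The
generator-vs-estimate rank correlation is monotone for switch
probabilities in ≈ [0.004, 0.05]/day; above that every 60-day window
contains many switches and the tails saturate.  Crash speeds that
complete the fall faster than α days saturate R1 at 1, so monotonicity
holds for crash_speed ≲ crash_depth/α.

## Problem sizes

Desk-scale defaults used by the test suite and the acceptance script:
networks of N = 100 nodes and 400 links (the canonical density of 4
links per node); kurtosis measurements use the empirical recipe's
3-minute epoch (~35 windows per estimate, so the estimator's
window-count-dependent tail bias matches across simulated and recorded
data), 12–30 realizations per condition; two-stage searches with
200–300-s fine sweeps; robustness analogues run at N ∈ {25, 50, 100}
with 4–6 realizations.  The
experiment CLI exposes flags to scale any of these up (e.g. N = 1000,
4000 links, 100 realizations per Z).

## Known limitations

- At N = 100 the critical state is dominated by whole-network branch
  switching; per-realization kurtosis from a 2-min baseline is noisy,
  and for Z ≥ 2 a realization may spend its entire baseline on one
  branch.  The pooled summary and the pinned-baseline flag exist for
  exactly this reason.
- The located S* inherits Monte-Carlo error from the PCF estimates; at
  high Z a few percent of coupling shift changes the switching rate
  substantially.
- The market panel-mode coherence construction (Hilbert phases of daily
  returns) is one of several defensible choices; the sign-coherence
  variant is provided and the mode is recorded in every report.
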