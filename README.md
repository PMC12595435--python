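# esprox

Estimate how close a complex network's synchronization transition is to
the explosive (first-order) limit — its **ES proximity** — from time
series alone, and use it to predict whether the network will collapse
fast and recover slowly under perturbation.

Many systems that matter (cortical networks under anesthesia, stock
markets in a crisis) normally operate near a critical point. How they
leave that state under a shock, and how they come back, depends on the
*type* of their phase transition: networks near the explosive limit are
hypersensitive at criticality and internally resistant to change
(hysteresis), so they collapse abruptly and recover slowly. This package
implements the full computational framework around that idea:

- a **feedback-modified Stuart–Landau network simulator**
  (`esprox.model`): N coupled oscillators
  `dz_j/dt = (λ_j + iω_j − |z_j|²) z_j + S·R^Z·Σ_k A_jk (z_k(t−τ) − z_j) + β ξ_j + u(t)`,
  where the global order parameter R feeds back into the coupling with
  exponent Z — the ES-proximity control dial — and u(t) is a global
  pulse perturbation;
- **criticality metrics** (`esprox.metrics`): order parameter r(t), the
  pair correlation function PCF = N·Var[r] whose peak marks the critical
  coupling, moving-window lagged autocorrelations of r(t), and the
  **kurtosis of the windowed-ACF distribution** — the ES-proximity
  statistic (≈ 3 for networks far from the explosive limit, > 3 near
  it), plus DFA Hurst and Spearman comparators;
- a **perturbation-response experiment** (`esprox.perturbation`):
  baseline ± 3 SD zone of windowed ACF values, time-to-loss and
  time-to-recovery of the baseline critical state, and the headline
  correlations (kurtosis vs loss time negative, vs recovery time
  positive);
- an **EEG-style pipeline** (`esprox.signals`): alpha band-pass →
  Hilbert phases → channel order parameter → windowed ACF (lag 50 at
  500 Hz, 10-s/5-s windows) → kurtosis;
- a **market pipeline** (`esprox.market`): collapse/recovery rates
  R1 = [P(t1)−P(t1+α)]/[P(t1)−P(t2)], R2 = [P(t2+α)−P(t2)]/[P(t1)−P(t2)]
  over α trading days, response/recovery times ln(1/R1), ln(1/R2), and
  baseline ES proximity from daily return coherence (ACF lag 2 days);
- **seeded synthetic-data generators** (`esprox.synth`) for surrogate
  multichannel recordings with known ground-truth Z and market panels
  with controlled crash/rebound speeds and baseline coherence
  bistability.

## Worked example

Generate 3-minute, 32-channel surrogate recordings from the mechanistic
simulator — each network running at its own peak-PCF critical coupling —
and estimate their ES proximity blind, through the full signal pipeline
(band-pass, Hilbert phases, order parameter, windowed ACF, kurtosis):

```python
import numpy as np
from esprox.synth import SurrogateSpec, make_surrogate_recording
from esprox.signals import es_proximity

for z in (0.0, 3.0):
    kurts = []
    for k in range(8):
        spec = SurrogateSpec(z_truth=z, seed=200 + k, population_seed=3)
        signal, truth = make_surrogate_recording(spec)
        kurts.append(es_proximity(signal).kurtosis)
    print(f"Z={z}: S*={truth['s_critical']:.2f}  "
          f"median estimated ACF kurtosis={np.median(kurts):.2f}")
```

Output:

```
Z=0.0: S*=3.00  median estimated ACF kurtosis=2.55
Z=3.0: S*=9.33  median estimated ACF kurtosis=8.60
```

The feedback network needs a three-fold stronger coupling to reach its
critical point — that is the internal resistance of a near-explosive
network — and its windowed-ACF distribution grows heavy tails
(kurtosis ≫ 3) because its critical dynamics are intermittent and
bistable, while the conventional (Z = 0) network stays near the
Gaussian reference 3. That single number, computable from any
sufficiently long multichannel recording or synchronization proxy —
simulated, EEG-derived, or built from daily stock returns — is the
ES-proximity estimate.

The same machinery is available from the shell:

```sh
esprox sweep --n-nodes 100 --n-links 400 -z 2 --out out/sweep
esprox experiment --z-grid 0,1,2,3 --realizations 25 --seed 7 --out out/exp
esprox synth market --markets 20 --out out/panel
esprox market out/panel/panel.csv --alpha 100 \
    --recession-start 2007-04-01 --recession-end 2008-03-31 \
    --baseline-start 2005-01-03 --baseline-end 2006-12-29 --out out/mkt
```

Every subcommand writes a `manifest.json` with the resolved
configuration and seeds; rerunning with the same manifest reproduces the
outputs bit for bit.

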