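# gmnsim — gastric motility network simulator

`gmnsim` simulates a one-dimensional chain of gastric pacemaker/muscle
oscillator units and quantifies how the chain entrains into a single
propagating slow wave.

Each **oscillator unit (OU)** pairs

- an **ICC pacemaker cell** (interstitial cell of Cajal): a 23-state
  conductance-based model whose rhythm is set by an intracellular
  IP₃/Ca²⁺ oscillator (IP₃-receptor Ca²⁺ release from the ER, SERCA
  reuptake, mitochondrial and plasma-membrane fluxes) coupled to a full
  complement of voltage-gated membrane currents, and
- a **smooth-muscle (SM) cell**: a 14-state conductance-based follower
  driven by the ICC through a gap-junction conductance.

42 units are placed along a 6-cm rostro-caudal axis. An innervation
parameter β (the baseline IP₃ synthesis rate, mM/s) decreases linearly
from rostral to caudal, so uncoupled units oscillate from ≈3.6 cpm down
to ≈2.1 cpm. Neighbouring ICCs are coupled three ways:

1. **electrical** gap-junction conductance (nS),
2. diffusive **Ca²⁺ exchange** (s⁻¹),
3. diffusive **IP₃ exchange** (s⁻¹),

and neighbouring SM cells by a (weak) electrical conductance. Each
mechanism can be disabled independently for ablation studies, and the
per-junction strengths can be drawn from seeded uniform distributions to
study robustness to coupling variability.

## Quick start (Python)

```python
from gmnsim import NetworkConfig, integrate, compute_metrics

cfg = NetworkConfig()                      # 42 units, defaults
res = integrate(cfg, duration_s=900.0)     # stiff LSODA, banded Jacobian
m = compute_metrics(res.time, res.v_sm, length_cm=cfg.length_cm)
print(m.entrainment_range, m.total_lag_mean, m.velocity_cm_s)
```

`compute_metrics` returns per-cell slow-wave periods, peak-to-peak lags
relative to cell 1, an entrained/not-entrained classification per cell,
the contiguous entrained prefix length, total rostro-caudal lag, and the
propagation velocity when the whole chain is locked.

## Command line

```bash
gmnsim simulate --n-cells 42 --duration 900 --out run.h5
gmnsim analyze run.h5 --out metrics.csv
gmnsim sweep --parameter g_icc_icc --out sweep/
gmnsim reproduce ablation --out results/
gmnsim intrinsic-freq --out intrinsic.csv
```

`gmnsim reproduce <name>` runs a named experiment: `default`,
`ablation` (electrical-only / messenger-only / both), `g_sweep`,
`pip3_sweep`, `pca_sweep`, `gcoup_sweep`, `variability`, `intrinsic`.

## Layout

- `src/gmnsim/icc.py`, `sm.py` — single-cell models (currents, Ca²⁺
  handling, IP₃ dynamics) with YAML-serializable parameter sets.
- `src/gmnsim/network.py` — chain assembly: β gradient, coupling
  operators, state packing, variability sampling.
- `src/gmnsim/_kernel.py` — optional numba-compiled right-hand side.
- `src/gmnsim/simulate.py` — integration, trajectory containers
  (HDF5/CSV), physiological initial conditions.
- `src/gmnsim/analysis.py` — peak detection, periods, lags, entrainment
  classification, frequency/lag curve fits.
- `src/gmnsim/experiments.py`, `cli.py` — scripted experiments and CLI.
- `src/gmnsim/data/*.yaml` — shipped default parameter files.
- `docs/methods.md` — model equations, units and numerical methods.

## Tests

```bash
python -m pytest -q tests/
```

The suite mixes fast unit/property tests (coupling-flux conservation,
compiled-vs-reference derivative oracles, constructed-signal analysis
checks) with a slow suite that integrates full 42-cell, 900-s networks
once per session and asserts the headline physiological quantities.
`scripts/acceptance.py --seed 0 --out acceptance.json` recomputes those
headline quantities standalone.
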