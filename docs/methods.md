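# Methods

## Units and conventions

| Quantity | Unit |
| --- | --- |
| time | s (gating time constants stated in s) |
| membrane potential | mV |
| current | pA |
| conductance | nS |
| capacitance | pF |
| concentration | mM |
| coupling permeability | s⁻¹ |

Membrane equation: `dV/dt = −(ΣI_ionic + I_junction) / C_m × 1e3`
(pA/pF = mV/ms, and the factor 1e3 converts to mV/s so the whole system
evolves on a seconds clock).

## ICC pacemaker cell (23 states)

States: `V`, six compartment concentrations (`Ca_i` cytosolic, `Ca_SS`
subspace, `Ca_ER`, `Ca_MT` mitochondrial, `IP3`, IP₃-receptor
inactivation `h`), and 16 Hodgkin–Huxley gates.

**Membrane currents** (all of the form `g·(gates)·(V−E)` unless noted):
L-type Ca²⁺ (`d_ltype·f_ltype·f_ca_ltype`, with a Ca²⁺-dependent
inactivation gate relaxing to `K_fca/(K_fca+Ca_SS)`…), voltage-dependent
dihydropyridine-resistant Ca²⁺ (VDDR), T-type (LVA) Ca²⁺, Na⁺, delayed
rectifier Kv, slow Kr, A-type, ERG, Ca²⁺-activated K⁺
(`g_bk·Ca_i/(Ca_i+K_bk)`), background K⁺ and Cl⁻, and a
Ca²⁺-inhibited nonselective cation current
`g_nscc /(1+(Ca_i/K_nscc)^n_nscc)·(V−E_nscc)` that provides the
depolarizing drive during the intracellular Ca²⁺ trough.

Gates follow `dx/dt = (x_∞(V) − x)/τ_x` with Boltzmann
`x_∞ = 1/(1+exp(∓(V−V_h)/k))`.

**Ca²⁺ handling.** The subspace/ER pair forms the oscillator core:
IP₃-receptor release with open probability
`(IP3/(IP3+d1))³ (Ca_SS/(Ca_SS+d5))³ h³` and inactivation
`dh/dt = a2 (d2·(IP3+d1)/(IP3+d3)·(1−h) − Ca_SS·h)`, ER leak, and a
saturating SERCA pump `v_serca·Ca²/(k²+Ca²)`. Subspace Ca²⁺ drains to
the cytosol (linear leak), which exchanges with mitochondria (uniporter
in, Na⁺/Ca²⁺ exchanger out) and extrudes via a plasma-membrane pump.
Membrane Ca²⁺ currents feed their compartments with `1/(2·F·vol)`
scaling and a cytosolic buffering factor `f_c`.

**IP₃ dynamics** (the slow clock):

```
dIP3/dt = P_MV·(1 − V⁸/(k_V⁸ + V⁸)) + β − η·IP3
          − V_m4·IP3⁴/(k_4⁴ + IP3⁴) + J_IP3_exchange
```

Voltage-gated synthesis shuts off during the depolarized plateau, so
IP₃ ramps during the inter-wave interval and resets on each wave; the
innervation parameter β sets the ramp rate and hence the intrinsic
frequency.

## Smooth-muscle cell (14 states)

States: `V`, cytosolic `Ca_i`, 12 gates. Currents: L-type and T-type
Ca²⁺ (L-type with Ca²⁺-dependent inactivation gate), Na⁺, delayed
rectifier (two gates), A-type (two gates), Ca²⁺-activated K⁺,
background K⁺, background nonselective, and a ligand-operated
nonselective cation current
`g_nscc·m_nscc·r_lig / (1+(Ca_i/K_nscc_ca)^4)·(V−E_nscc)`.
Ca²⁺ balance: influx through the Ca²⁺ currents minus a saturating
extrusion `v_ex·Ca²/(k_ex²+Ca²)`, with buffering `f_c`. An isolated SM
cell is quiescent near −54 mV; it oscillates only when driven by its
ICC.

## Network

`N = 42` units span `L = 6` cm (7 cells/cm). β decreases linearly from
`β₁ = 2.650e−5` to `β₄₂ = 1.336e−5` mM/s, calibrated so the uncoupled
endpoint frequencies are ≈3.6 and ≈2.1 cpm.

Coupling (nearest neighbour, chain ends open):

- ICC–ICC electrical: `I_i ← G·(V_i − V_{i+1})` into cell *i*, the
  negative into cell *i+1* (conserves charge; default `G = 0.7` nS).
- ICC–ICC Ca²⁺ and IP₃ exchange: `J = P·(C_i − C_{i+1})` removed from
  the higher side and added to the lower (defaults `P_ca = 0.8`,
  `P_ip3 = 8` s⁻¹, applied to `Ca_i` and `IP3`).
- ICC→SM within a unit: `I_coup = g_coup·(V_ICC − V_SM)` into the SM
  cell (default 0.5 nS).
- SM–SM electrical: default 0.2 nS.

Per-junction values may be scalars or length-`N−1` vectors; variability
level `v ∈ [0,1]` draws each junction's `G` (and `P_ip3` when IP₃
exchange is enabled) from `U[default·(1−v), default·(1+v)]` with a
seeded generator.

**State packing** is unit-major: 37 consecutive entries per unit (23 ICC
then 14 SM), so the Jacobian is banded with bandwidth 37 and the chain
coupling stays block-tridiagonal.

## Numerics

`scipy.integrate.solve_ivp` with LSODA, `rtol = 1e−6`, `atol = 1e−9`,
`lband = uband = 37`. Halving the tolerances changes last-7-cycle
period estimates by <0.1 % (tested). Initial conditions tile a
pre-settled single-unit trough state (600-s relaxation at the
mid-gradient β, sampled at the voltage minimum), which removes most of
the startup transient. The right-hand side has a numba-compiled kernel
and a pure-numpy reference; both agree to 1e−12 relative (oracle test).

## Entrainment analysis

- **Peaks**: local maxima of `V_SM` with ≥5 mV prominence and ≥5 s
  separation, refined by quadratic interpolation through the three
  samples around each maximum.
- **Periods**: mean/s.d. of the last 7 inter-peak intervals per cell
  (20 for classification).
- **Lags**: each cycle of cell 1 is matched to the nearest subsequent
  peak of cell *i* within one period; unmatched cycles are discarded
  and counted. Relative lag is reported per cell; total lag is cell 42
  minus cell 1.
- **Entrained** cell *i*: period CV < 0.5 %, period within 1 % of cell
  1, relative-lag s.d. < 2 % of the period. The **entrainment range**
  is the longest entrained prefix starting at cell 1. Velocity
  `L / total lag` is reported only when the whole chain is entrained.
- **Fits**: ordinary least squares for frequency vs β (slope,
  intercept, R²); a double exponential
  `a₁·exp(−x/b₁) + a₂·exp(−x/b₂)` with multi-start least squares for
  total lag vs coupling strength.
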