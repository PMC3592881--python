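# betacell

Kinetic models of glucose- and L-alanine-stimulated insulin secretion in
pancreatic β-cells, for systems biologists studying stimulus–secretion
coupling in clonal β-cell lines.

Nutrients trigger insulin secretion through a well-defined chain: fuel
metabolism raises ATP, ATP closes the K⁺_ATP channel, the membrane
depolarises, voltage-gated Ca²⁺ channels open, and bulk intracellular
Ca²⁺ rises. L-alanine additionally enters the cell by electrogenic
Na⁺ co-transport, depolarising the membrane *independently* of
metabolism. `betacell` implements this picture as two coupled ODE models:

* **Model 1 — core metabolism.** An 18-state single-compartment network
  (glycolysis, lactate dehydrogenase, condensed TCA cycle, transamination,
  respiratory chain, proton leak, ATP synthase) with conserved adenine and
  pyridine pools and the mitochondrial membrane potential ΔΨ_m:
  `dx/dt = S·v(x)`, with respiration saturating in NADH and cutting off
  above a ΔΨ threshold, and `dΔΨ/dt = (10·v_resp − 3·v_syn − v_leak)/C`.
  Inputs are the glucose and alanine influxes `J_GLC`, `J_ALA`; 41
  adjustable parameters; exactly five reactions carry L-alanine.
* **Model 2 — membrane electrophysiology.** A Hodgkin–Huxley current
  balance `C_m·dV/dt = −ΣI` over nine currents (K_Dr, K_ATP, K_Ca, CaV,
  Ca pump, NaV, Na/K pump, Na/Ca exchanger, and the ohmic Na⁺/alanine
  co-transport current `I_NaAla = g_NaAla·(V − E_Na)`), with dynamic
  intracellular Ca²⁺/Na⁺/K⁺ and a cytosolic ATP balance whose production
  constant `k_ATP` is the metabolic input.

Around the models: steady-state dose–response scans, one-at-a-time
sensitivity scans, limit-cycle time-averaging, a bounded least-squares
ATP calibration, a simplex fit of the three Ca²⁺→insulin scaling
constants (insulin ∝ mean Ca²⁺; `k_ATP` linear in nutrient dose;
`g_NaAla` linear in alanine), and a synthetic-data generator reproducing
the experimental condition grid. See `docs/methods.md` for the science.

## Worked example

```python
import numpy as np
from betacell import (MetabolicParameters, dose_response_scan,
                      ElectroParameters, simulate_electro, oscillation_summary,
                      K_ATP_STIM, G_NAALA_10MM)

# model 1: steady-state dose–response at the influxes mapping to
# 1.1, 5, 16.7 and 30 mmol/l D-glucose
tab = dose_response_scan("J_GLC", [0.015, 0.066, 0.222, 0.399])
print(tab[["J_GLC", "ATP", "LAC", "GLU"]].round(3).to_string(index=False))

# model 2: bursting at stimulatory ATP production with the co-transport
# conductance standing for 10 mmol/l L-alanine
p = ElectroParameters(); p["k_ATP"] = K_ATP_STIM; p["g_NaAla"] = G_NAALA_10MM
tc = simulate_electro(p, t_end=480000.0)
s = oscillation_summary(tc["t"].to_numpy(), tc["V"].to_numpy(), burn_in=0.5)
print(f"V oscillatory: {s['oscillatory']}, peak-to-peak {s['amplitude']:.1f} mV, "
      f"period {s['period']/1000:.2f} s")
t = tc["t"].to_numpy(); sel = t >= 0.5*t[-1]; tt = t[sel]
ca = float(np.trapezoid(tc["Ca_i"].to_numpy()[sel], tt)/(tt[-1]-tt[0]))
print(f"mean Ca_i over the limit cycle: {ca:.3f} umol/l")
```

prints

```
 J_GLC   ATP   LAC   GLU
 0.015 0.123 0.000 0.000
 0.066 0.659 0.002 0.002
 0.222 1.972 0.022 0.022
 0.399 2.995 0.073 0.192
V oscillatory: True, peak-to-peak 79.7 mV, period 1.04 s
mean Ca_i over the limit cycle: 0.641 umol/l
```

Reading it: steady-state ATP (mmol/l) rises monotonically and begins to
saturate across the physiological glucose range, lactate export grows
with glycolytic flux, and glutamate accumulates only at high input. In
model 2, stimulatory ATP production closes K_ATP and produces ~1 s
bursting with a sub-micromolar mean Ca²⁺; the co-transport conductance
raises mean Na⁺ and Ca²⁺ above the glucose-only case — the model's
account of why alanine secretes more insulin than its ATP contribution
alone would predict.

A CLI mirrors the library (`betacell steady | scan | sensitivity |
simulate | oscillate | fit-atp | fit-ca | synth | recover`); outputs are
CSV tables with `.meta` provenance sidecars.

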