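# Methods

`betacell` implements two coupled deterministic ODE models of nutrient-
stimulated insulin secretion in a clonal pancreatic β-cell line, plus the
scan and calibration machinery around them. This note records the models,
their assumptions, the numerical choices, and what the synthetic-data
pipeline does and does not establish.

## Model 1 — core metabolic network

A single-compartment kinetic network of ATP production with D-glucose
and/or L-alanine input. Eighteen quantities are integrated: fifteen
metabolite concentrations (GLC, F6P, FBP, GAP, DPG, PEP, PYR, LAC, AcCoA,
OAA, CTT, aKG, GLU, ASP, ALA), free ATP, free NADH, and the mitochondrial
membrane potential ΔΨ_m. ADP and NAD⁺ are conserved-pair complements
(`ADP = A_tot − ATP`, `NAD = N_tot − NADH`), so the adenine and pyridine
pools are conserved *by construction*; the tests verify the bookkeeping
rather than an integrator property.

Twenty-four reactions (glycolysis, lactate dehydrogenase and export, a
condensed TCA cycle, transamination, respiration, proton leak, ATP
synthase, and a lumped ATP-translocation/consumption step) plus two input
fluxes `J_GLC`, `J_ALA` define the stoichiometry; five of them (the
alanine input flux and reactions 17–20: alanine dehydrogenase, glutamate
dehydrogenase, and the two transaminases) exist only to carry L-alanine.

Rate-law shapes:

- mass action for glycolytic and TCA steps; the five alanine-linked
  reactions and the aldolase step are net reversible mass-action rates
  `k_f·(Π reactants − Π products/K_eq)`;
- Michaelis saturation in pyruvate for pyruvate dehydrogenase and
  pyruvate carboxylase (the latter prevents an unbounded ATP drain when
  alanine floods the pyruvate pool);
- respiration `k23 · NADH/(K_resp+NADH) · 1/(1+exp(a_resp·(ΔΨ−ΔΨ*)))`:
  saturating in NADH, roughly linear in ΔΨ below the threshold ΔΨ*, and
  falling rapidly to zero above it;
- ATP synthase `k24 · 1/(1+exp(a_syn·(ΔΨ_syn−ΔΨ))) · (ADP·Pi − ATP/Keq24)`:
  ΔΨ-activated and reversible in the adenine pool; 10 protons are pumped
  per NADH oxidised and 3 re-enter per ATP synthesised;
- proton leak linear in ΔΨ; `dΔΨ/dt = (10·v23 − 3·v24 − v_leak)/C_mito`.

Units are mmol/l and minutes (mV for ΔΨ_m). The adjustable-parameter
registry enumerates exactly 41 entries: 24 forward rate constants, 7
equilibrium constants, 3 saturation constants, 4 respiratory/synthase
shape constants, the two pools `A_tot`/`N_tot`, and `C_mito`. Inorganic
phosphate and the two input fluxes are held outside the registry.

Default values are this package's own calibration of the reconstructed
rate laws, chosen once so that the default model exhibits the qualitative
phenotype of the system it describes: steady-state ATP monotone and
saturating in glucose influx; a uniform upward shift of the ATP, lactate
and glutamate curves when a 10 mmol/l-equivalent alanine flux is added; a
high lactate-dehydrogenase flux typical of clonal β-cell lines; and the
expected one-at-a-time sensitivity directions (raising the LDH constant
k8 lowers the ATP saturation level and slows its rise; raising the
ATP-translocation constant k21 or the proton-leak constant k22 depresses
steady-state ATP; raising k10, k23, k24 raises it).

Deliberate exclusions: no cytosol/matrix compartmentalisation, no NADH
shuttles, no Ca²⁺ activation of dehydrogenases, no cooperativity, no pH
state (intermembrane protons enter only through ΔΨ_m), no SBML I/O.

Stimulus mapping: nutrient concentrations map linearly to input fluxes
(`J_GLC = 0.0133·[glucose]`, `J_ALA = 0.047·[alanine]`, both mmol/l/min
per mmol/l). The glucose slope places the 1.1–30 mmol/l experimental
range on the rising-to-saturating part of the dose–response; the alanine
slope is set so that 10 mmol/l alanine alone yields steady-state ATP
comparable to 16.7 mmol/l glucose, which is the experimentally observed
equivalence.

## Model 2 — membrane electrophysiology and Ca²⁺ handling

A Hodgkin–Huxley current-balance model with six states: membrane
potential V, delayed-rectifier activation n, bulk intracellular Ca²⁺
(µmol/l), Na⁺, K⁺ and cytosolic ATP (mmol/l). Nine currents are carried
(outward positive): I_KDr, I_KATP, I_KCa, I_CaV, I_CaPump, I_NaV, I_NaK,
I_NaCa, and the ohmic Na⁺/L-alanine co-transport current
`I_NaAla = g_NaAla·(V − E_Na)`. Nernst potentials use the fixed
extracellular bath (Na 140, K 5.4, Ca 2.6 mmol/l — consistent with a
Krebs-Ringer bicarbonate buffer). Key functional forms:

- K_ATP open probability `1/(1+(ATP/K_katp)^2)` — the ATP sensor;
- K_Ca activation is Hill-4 in Ca²⁺; I_CaV has instantaneous voltage
  activation and Ca²⁺-dependent inactivation `1/(1+(Ca/K_CaInact)²)`,
  which bounds Ca²⁺ excursions under strong drive;
- the Na/K pump moves 3 Na⁺ out : 2 K⁺ in per cycle (net +1 charge out),
  the Na/Ca exchanger imports 3 Na⁺ per Ca²⁺ extruded (net +1 charge in);
  both ion balances use exactly the currents that appear in the voltage
  equation, scaled by 1/(zF·Vol) and, for Ca²⁺, the free fraction f_i;
- cytosolic ATP: `dATP/dt = k_ATP − k_hyd·ATP − (I_NaK + I_CaPump/2)/(F·Vol)`;
  a Na⁺ load therefore directly accelerates ATP consumption through the
  pump term. Both ATP-driven pumps carry a saturating factor
  `ATP/(ATP+K_pump_atp)` so they stall as ATP depletes.

`k_ATP` is the metabolic input knob (basal 4·10⁻⁵, stimulatory 1.8·10⁻⁴
mmol/l/ms); `g_NaAla` is the alanine-coupling knob (50 pS ≡ 10 mmol/l
alanine). At stimulatory `k_ATP` the model settles on a bursting limit
cycle (V amplitude > 70 mV, burst period ~1–2 s); switching `g_NaAla`
from 0 to 50 raises mean Na⁺ and Ca²⁺, slightly lowers K⁺ (the pump
works against the Na⁺ load), strengthens the Ca²⁺-activated K⁺ current,
and shortens the burst period. K⁺ can be frozen (`electro.dynamic_K = 0`)
to reproduce the five-equation reading of the system; only E_K, E_Na and
E_Ca are implemented — no further reversal potential is needed by any
current in the set.

The slow pools (Na⁺, K⁺, ATP) relax over tens of seconds, so stationary
time-averages use 480 s simulations with 50% burn-in (90% for the Na/K
ripple statistics). ER Ca²⁺ sequestration, IP₃ signalling, stochastic
gating and explicit vesicle exocytosis are out of scope.

## Steady states, scans, summaries

Steady states are found by stiff integration (LSODA, rtol 1e-9) in chunks
until the scaled residual `max_i |dy_i|/max(1,|y_i|)` falls below 1e-8,
then polished by a Newton root solve (the polish is discarded if it
leaves the integrated point's neighbourhood or its non-negativity).
Timeouts return a flagged, non-converged result. Dose–response scans
warm-start each grid point from the previous one; non-converged rows are
flagged and the scan continues. Some parameter scalings (e.g. a large
ATP-consumption constant at low glucose influx) place the network on a
glycolytic-type limit cycle where no steady state exists — those points
are reported as non-converged, and the bounded ATP fit substitutes a
large penalty there so the optimiser steers back to the steady regime.

Sensitivity scans are strictly one-at-a-time with symmetric log-spaced
default factors {1/5, 1/2, 2, 5}. Limit-cycle summaries report the
trapezoidal time mean, extrema, and the mean peak-to-peak period; peak
detection runs on a linearly detrended window with a 5%-of-range
prominence filter so the small periodic ripple of the slowly relaxing
ion pools is not masked by their residual drift, and signals with fewer
than two prominent peaks get period = NaN rather than an error.

## Calibration

**ATP fit.** The objective is the sum of squared *observation-normalised*
residuals, `Σ((sim−obs)/obs)²`, over the stimulus conditions of the
10-condition ATP design; the stimulus-free basal row is excluded (9
fitted observations) because the network models nutrient-driven, not
basal, turnover. Zero observations fall back to SD normalisation
(configurable). Minimisation is bounded local search (L-BFGS-B) with
default box bounds ×0.2–×5 of the start values; the default fitted
subset is the 10 parameters whose ×½/×2 scaling most displaces the ATP
curve, computed from the sensitivity ranking. Solutions pinned at a
bound are flagged.

**Ca²⁺→insulin scaling fit.** Three constants link model 2 to insulin
observations: insulin-per-Ca, the glucose→k_ATP slope, and the
alanine→g_NaAla slope. The alanine k_ATP slope is tied to the glucose
slope by the 10 mmol/l-alanine ≡ 16.7 mmol/l-glucose equipotency, AIB
contributes conductance but no k_ATP, and oligomycin/FCCP clamp k_ATP at
basal. The fit is an unconstrained Nelder–Mead simplex over the logs of
the three positive constants against the 11-condition insulin design
(1 stimulus-free + 5 glucose-only + 5 alanine-only), minimising the
unweighted squared difference between observed insulin and scaled mean
limit-cycle Ca²⁺.

Because each mean-Ca²⁺ evaluation is a long simulation, the fit evaluates
a once-tabulated response surface: mean Ca²⁺ on an 8×5 (k_ATP, g_NaAla)
grid, bilinearly interpolated and linearly extrapolated outside the grid
(extrapolation, not clipping, keeps the objective curved there so the
conductance slope remains identifiable). Observation generation and
fitting share this surface, so the zero-noise self-fit recovers the
generating constants exactly; what the surrogate does *not* establish is
the interpolation error against direct simulation, which is why a direct
`mean_ca` callable can be supplied instead.

## Synthetic data

The generator reproduces the experimental design: 20-min endpoint
observations on the condition grid of D-glucose {1.1, 5, 16.7, 30} and
L-alanine {0.5, 1, 2, 5, 10} mmol/l, alone and in the printed
combinations, plus AIB (10 mmol/l), oligomycin, FCCP and DMGLU (5 mmol/l)
conditions. Noise is multiplicative Gaussian with default cv = 0.10,
standing in for the scatter of triplicate assays; the insulin design uses
glucose {1.1, 5, 10, 16.7, 30} so the dose–response series has five
points. Everything is reproducible from an explicit seed; there is no
hidden global state.

What passing tests show — and do not. The recovery study demonstrates
that the fitting machinery is unbiased and precise *under the generator's
assumptions* (multiplicative Gaussian noise, a correctly specified
model, conditions mapped exactly as assumed). It does not establish
identifiability against real measurements, where the model is
misspecified and the noise is not proportional. At cv = 0.05 the
insulin-per-Ca and glucose-slope constants recover to a few percent
(median over 20 replicates), while the alanine-conductance slope is the
weakest-identified of the three (median ≈ 9–23% depending on the seed
block): along the alanine series the metabolic (k_ATP) and co-transport
(g_NaAla) routes to Ca²⁺ elevation partially trade off. Replicates with
errors above 50% are labelled weakly identifiable in the report rather
than asserted recovered.

## Numerical choices and problem sizes

- LSODA everywhere; metabolic runs rtol 1e-9/atol 1e-10, membrane runs
  rtol 1e-6 with per-variable atol matched to each quantity's scale and a
  50 ms step cap so no burst is skipped.
- Steady-state tolerance 1e-8 (scaled residual); halving it moves outputs
  by < 1e-4 relative. Burst periods are stable to well under 1% when the
  integration tolerance is halved.
- Scans and fits in the test suite use compact grids (6–7 point influx
  grids, 3–5 condition fits, the 8×5 surrogate grid, 480 s membrane
  horizons); these sizes were chosen as the smallest on which the
  qualitative claims are stable.
- Ties and degeneracies: reversible reactions are evaluated as net rates
  without clipping; a constant signal has period NaN, not an error; a
  non-converged scan row is flagged, not fatal.

## Known limitations

- All rate laws and defaults are reconstructions in the base-model
  families; no claim is made that they match any particular published
  parameter table, and absolute concentrations are model-scale rather
  than assay-calibrated.
- The combined glucose+alanine insulin response is deliberately not
  fitted: mean Ca²⁺ alone under-predicts secretion when both stimuli act
  together, so the scaling fit is restricted to the single-stimulus
  series.
- The glucose→flux and alanine→flux maps are linear; saturation of
  nutrient uptake at supra-physiological doses is not modelled.
- The metabolic model can oscillate in corners of parameter space; the
  steady-state machinery reports rather than resolves such regimes (no
  bifurcation analysis).
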