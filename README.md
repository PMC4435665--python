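# vbephys

Patch-clamp sweep analysis and conductance-based simulation of thalamic
ventrobasal (VB) relay neurons.

VB relay neurons fire low-threshold calcium-channel-driven rebound bursts on
release from hyperpolarization, a behaviour central to thalamocortical
rhythms and absence epilepsy.  In the GAERS rat model of absence epilepsy,
VB neurons need substantially more hyperpolarizing current to reach
burst-firing threshold than non-epileptic controls (NEC); mechanistically
this traces to an enlarged HCN current (I_h), which lowers input resistance
and opposes the membrane hyperpolarization that de-inactivates T-type
calcium channels, while the bursts themselves are unchanged.  `vbephys`
packages the complete electrophysiological analysis of that phenotype —
current-clamp burst metrics, voltage-clamp current-separation pipelines,
group statistics, and liquid-junction-potential corrections — together with
a single-compartment VB neuron simulator that stands in for the patch-clamp
recordings, so every analysis stage is verifiable by parameter recovery and
oracle equivalence without any recorded data.

## The model and the analyses

The simulator integrates (fixed-step RK4, 0.025 ms)

```
Cm dV/dt = −[ g_L(V−E_L) + g_T m²h(V−E_Ca) + g_h r(V−E_h)
            + g_HVA q²(V−E_Ca) + g_Na m³h(V−E_Na) + g_K n⁴(V−E_K) ] + I_inj
```

with thalamocortical T-type kinetics (inactivation recovery of hundreds of
ms below −80 mV), Boltzmann HCN activation r∞(V) = 1/(1+exp((V−V₅₀)/k))
with V₅₀ = −86 mV and k = 4.2 mV, and pharmacology as conductance scaling
(`block_h` ≙ ZD7288, `block_T` ≙ Z944).  Strain presets (`NEC`, `GAERS`,
`P7P9_*`, `*_ZD`, `*_Z944`) differ only in conductance densities.

The analysis modules implement the standard measurements:

- burst criterion: ≥ 3 action potentials within 100 ms; rebound-burst
  threshold scanned over −110…+200 pA ladders in 10-pA steps;
- passive properties (RMP, input resistance from the maximal deflection,
  sag, maximum hyperpolarization), burst morphology (inflection/deflection
  points, latencies, afterhyperpolarization), tonic f–I curves;
- whole-cell capacitance from the integral of the 5-mV step transient,
  offline linear leak correction, −50 mV/100-ms prepulse separation of
  T-type vs high-voltage-activated calcium currents, blocker-sensitive
  current subtraction, tail-current activation curves with Boltzmann
  (V₅₀, k) fits, and Hill EC₅₀ dose–response fits;
- pooled-variance Student's t comparisons with mean ± SEM summaries;
- the generalized Henderson equation for liquid-junction potentials (LJP),
  with a literature ion-mobility table and the four bundled recording
  solutions.

## Worked example

```python
from vbephys import model
from vbephys.currentclamp import rebound_burst_threshold, threshold_metric_row
from vbephys.traces import make_step_protocol

params = model.preset("NEC")
ladder = make_step_protocol(0.0, 200.0, 1000.0, 400.0, -110.0, 0.0, 10.0,
                            0.05, "current_clamp")
sim = model.simulate_ladder(params, ladder, model.ClampConfig.cc(seed=1))
res = rebound_burst_threshold(sim)
print(f"rebound-burst threshold: {res.threshold_pA:+.0f} pA "
      f"({res.aps_per_burst} APs per burst)")
for k, v in threshold_metric_row(res).items():
    print(f"  {k:38s} {v:8.2f}")
```

prints

```
rebound-burst threshold: -70 pA (3 APs per burst)
  Threshold current (pA)                   -70.00
  APs per burst                              3.00
  Burst inflection point (mV)              -70.61
  Burst deflection point (mV)              -46.11
  Maximum hyperpolarization (mV)           -86.54
  Pre-Burst Membrane Potential (mV)        -80.48
  Sag (mV)                                   6.06
  Latency to inflection (ms)                19.80
  Latency to AP (ms)                        56.85
  Latency inflection to AP (ms)             37.05
  Latency to deflection point (ms)         107.85
  Inflect to deflect latency (ms)           88.05
  Afterhyperpolarization (mV)              -77.23
  AHP - Vrest (mV)                          -2.26
  Resting membrane potential (mV)          -74.97
  Input resistance (MOhm)                  165.20
```

i.e. this control-preset cell rests near −75 mV, needs −70 pA of injected
current for 1,000 ms to de-inactivate enough T-type current, and on release
fires a 3-spike burst riding a low-threshold spike whose regenerative
depolarization begins at −70.6 mV.  The GAERS preset run the same way needs
about 20 pA more.  `vbephys.study.cohort_study` runs the full two-strain
comparison (thresholds at both step durations, APs/burst, RMP, R_in, I_h
tail density, and the ZD7288/Z944 drug conditions) on jittered cohorts.

A command-line interface mirrors the library:

```
vbephys simulate --preset NEC --protocol cc1000 --out sweeps.txt --seed 7
vbephys analyze-cc sweeps.txt --report table1.csv
vbephys analyze-vc --task cm cm_sweeps.txt --out cm.csv
vbephys cohort --preset-a NEC --preset-b GAERS --n 15 --seed 11 --out cmp.csv
vbephys ljp --pipette pip.txt --bath bath.txt --temp-c 34
```

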