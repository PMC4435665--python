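# Methods

This note documents the models, estimators and numerical choices behind
`vbephys`: what the synthetic-data generator does and does not emulate, the
defaults that matter, and the known limitations.

## 1. The single-compartment VB neuron

The simulator integrates one isopotential compartment,

    Cm dV/dt = −(I_leak + I_T + I_h + I_HVA + I_Na + I_K) + I_inj,

in the patch-clamp unit system (mV, ms, pA, nS, pF; note pA = nS·mV and
mV/ms = pA/pF).  Gates follow first-order kinetics
dx/dt = (x∞(V) − x)/τ(V) with Boltzmann steady states
x∞ = 1/(1+exp((V½−V)/s)); the sign of the slope s selects activation
(s > 0) or inactivation/hyperpolarization-activation (s < 0).

**T-type calcium current** I_T = g_T·m²h·(V−E_Ca), E_Ca = +120 mV (ohmic
driving force).  Activation: V½ = −58.5 mV, s = 6.2 mV, τ_m ≈ 1–2 ms
(reciprocal double-exponential form).  Inactivation: V½ = −83 mV,
s = −4 mV; τ_h is piecewise exponential with recovery ≈ 290 ms at −90 mV
and decay ≈ 20–30 ms at depolarized potentials.  The slow hyperpolarized
recovery is the mechanism that separates 200-ms from 1,000-ms conditioning
steps: a 1,000-ms step at the threshold trough recruits roughly twice the
de-inactivated T-current pool of a 200-ms step.

**HCN current** I_h = g_h·r·(V−E_h), E_h = −43 mV.  r∞ is a Boltzmann with
V½ = −86 mV and slope 4.2 mV — the values the tail-current analysis is
expected to recover.  τ_r is bell-shaped, peaking at 250 ms near −95 mV and
falling to tens of ms above −75 mV.  The asymmetry is deliberate: the slow
hyperpolarized branch lets a 1,000-ms conditioning step settle (≥ 4 time
constants everywhere on the activation protocol), while fast deactivation
above −75 mV confines the current's influence to the hyperpolarized trough.
With slow deactivation instead, I_h boosts the post-release overshoot so
strongly that extra g_h *facilitates* bursting, inverting the strain
phenotype; with the fast branch, threshold current is monotone
non-decreasing in g_h, as observed.

**HVA calcium** I_HVA = g_HVA·q²(V−E_Ca), V½ = −25 mV, s = 5 mV,
τ = 1.5 ms, non-inactivating — a deliberately minimal high-threshold
current whose I–V peaks near −5 mV, clearly separated from the T peak.

**Spikes** use Hodgkin–Huxley Na/K rate functions threshold-shifted to
V_T = −47 mV, with the delayed-rectifier rates scaled by φ_n = 0.3.
g_Na = 1,400 nS is set low enough that burst spike counts saturate
(a stronger low-threshold spike does not recruit ever more sodium spikes)
and tonic firing within the ±200-pA ladder stays below ~20 Hz, so a
T-blocked (tonic-only) cell never meets the 3-APs-in-100-ms burst
criterion.

**Integration** is fixed-step RK4 at ≤ 0.025 ms internal step (command
samples are subdivided as needed); results are deterministic and
solver-independent at the accuracy the analyses need.  The initial state is
the resting fixed point (found by bracketed root solving on the
steady-state current) polished by a 500-ms relaxation; ladder sweeps share
one relaxed state.  Voltage clamp drives the membrane through the residual
series resistance (1−compensation)·R_series (default 10 MΩ at 70 %
compensation, floored at 0.5 MΩ for numerical stability), so recorded
currents contain realistic capacitive transients, leak, and voltage-escape
artifacts.  Noise is additive Gaussian on the response only, applied after
integration and seeded, keeping the dynamics deterministic.  Pharmacology
is conductance scaling (`block_h`, `block_T`), not state-dependent block.

## 2. Strain presets and what they emulate

Adult presets share Cm = 67 pF, g_leak = 5 nS, E_leak = −80 mV and differ
only in the two conductances the biology implicates: NEC g_T = 79 nS,
g_h = 8 nS; GAERS g_T = 77 nS, g_h = 18 nS (plus a modestly larger g_HVA).
These magnitudes are package choices tuned once so that burst thresholds
land in the tens-of-pA range on the standard −110…+200 pA / 10 pA ladder
and the strain contrast reproduces the qualitative phenotype: the larger
GAERS I_h clamps the achievable hyperpolarization, so ~20 pA more current
is needed to de-inactivate T channels, input resistance is lower, the tail
density roughly doubles, resting potential moves ≤ 2 mV, and full HCN block
hyperpolarizes the cell and converts burst polarity from
hyperpolarization-released to depolarization-evoked, while full T-type
block abolishes bursting entirely.  P7–P9 presets model the
calcium-current voltage-clamp condition in younger animals: Cm = 40 pF,
~25 % lower T density in the epileptic strain, and spike/HCN conductances
zero because the Cs/TEA/4-AP recording solutions silence them; their g_T
and g_HVA are scaled so that peak current densities come out at the
tens-of-pA/pF magnitudes these recordings report.

`generate_cohort` draws cells log-normally around a preset (conductances
and Cm, CV 0.2 by default, means preserved) with additive Gaussian jitter
of E_leak (SD 1.2 mV) spreading resting potentials, and an optional
log-normal scale on the T-inactivation τ (off by default).  The study
pipeline additionally assigns each cell a recording offset (SD 2.5–3 mV)
added to reported potentials only — the residual electrode/junction offset
of real recordings — which spreads measured RMPs without touching the
dynamics.  These spreads were chosen so group SEMs sit at the scale real
cohort tables report while a 15-cell-per-strain comparison retains power
for the threshold contrast.

What the generator does **not** emulate: dendrites and space-clamp error
(single compartment), GHK rectification of calcium currents (the linear
driving force pushes the T-type I–V peak to ≈ −25 mV instead of the
−50…−40 mV seen with GHK fluxes; peak *separation* from HVA is preserved),
membrane bistability under HCN block, temperature dependence,
state-dependent drug action, and channel noise.  Passing tests therefore
demonstrate correctness of the analysis chain and internal consistency of
the model — not that the model is a quantitative digital twin of a VB
neuron.

## 3. Current-clamp analyses

Spikes are upward crossings of −20 mV followed by a downward crossing, the
spike time at the intervening maximum, peaks closer than 1 ms merged.  A
burst is ≥ 3 spikes inside a sliding 100-ms window; window starts anchored
at spike times are sufficient and are checked against an exhaustive grid
search in the tests.  Rebound bursts are searched within 300 ms after step
offset (observed latencies reach ~270 ms); depolarization-evoked bursts
within the step.  The threshold scan walks hyperpolarizing amplitudes from
smallest to largest magnitude and returns the first qualifying sweep;
"no burst anywhere" is a value, not an error, because full T-type block
legitimately produces it.  `aps_per_burst` counts the whole spike cluster
of the threshold burst (consecutive intervals < 100 ms), which can exceed
the best single-window count by a trailing spike.

Passive metrics at the threshold sweep: RMP = mean of the last 50 ms before
the step; maximum hyperpolarization = minimum V in the step; pre-burst
potential = mean of the last 10 ms of the step; sag = pre-burst − minimum
(positive for the depolarizing I_h relaxation; reported sign conventions in
the literature are inconsistent between age groups, and this package always
reports depolarizing sag as positive).  Input resistance = |maximal
deflection| / |injected current|; the cohort study evaluates it on the
largest (−110 pA) step, where the HCN conductance difference is most
visible.

Inflection/deflection points: spikes are clipped (linear interpolation
across ±2 ms), the trace smoothed with a 1-ms boxcar, and dV/dt analyzed.
A plain k·SD derivative threshold (k = 3 against the pre-offset derivative
SD) triggers on the *passive* rebound in low-noise recordings, so the
detector is made scale-free: when the pre-spike derivative decelerates and
then re-accelerates (the passive-then-regenerative shape of a rebound
low-threshold spike), the inflection is the deceleration minimum — the
point where the exponential depolarization begins; for monotone shapes the
first sustained (≥ 2 ms) crossing of max(k·SD, 25 % of the segment's
maximal slope) is used.  The deflection is the first sustained negative
crossing after the post-spike crest.  On the control preset this places the
inflection near −70 mV, the expected scale.  The afterhyperpolarization is
the minimum V within 200 ms after the deflection.  These are surrogates for
an integration-based manual procedure that is not algorithmically specified
anywhere; they are validated on constructed fixtures with known onsets and
should not be presented as identical to hand-scored values.

Tonic frequency uses the 500–1,000-ms window after step onset (avoiding
onset bursts); input–output curves report rebound-cluster frequency for
hyperpolarizing steps and tonic frequency for depolarizing ones, optionally
normalized so the threshold amplitude maps to zero.

## 4. Voltage-clamp pipelines

**Capacitance**: Cm = ∫(I − I_ss)dt / ΔV over a 5-mV step from −90 mV.
The steady-state is a line fitted to the post-transient segment (removing
slow gating drift) and the integral runs over the first 8 ms.  A
series-resistance correction divides by (1 − g_app·R_s)², with R_s read
off the instantaneous current jump and g_app the apparent steady-state
conductance — both measured from the sweep itself.  This keeps the
estimate within 2 % of truth across a 10× leak range and under doubled
series resistance; the uncorrected textbook integral is biased by
≈ 2·g_leak·R_s.

**Leak correction** fits I = g(V−E) to steady-state currents of calibration
steps at or below −80 mV (from the analyzed ladder or a dedicated
small-step family) and subtracts g·(V_cmd(t)−E) pointwise.  It is
idempotent and exact for ohmic cells.  Caveat: any conductance open near
−90 mV (HCN, unless blocked) contaminates the fitted line and the
extrapolation to test potentials — one reason the calcium presets model
Cs-blocked HCN.

**Prepulse separation**: the −50 mV/100-ms prepulse (10-ms interpulse
interval) inactivates T below 1 % of control; subtracting the prepulse
family from the no-prepulse family sweep-wise yields the T component, the
prepulse family itself the HVA component.  Peaks are signed extrema toward
the expected (inward) direction after a 2-ms blank.  Residual error comes
from T-current recovery during the 10-ms gap (~4 %) and series-resistance
voltage escape; under a well-compensated clamp both components recover
direct channel-off simulations within 5 % at the peak.  At 70 %
compensation with large currents the separation degrades substantially
(tens of %), because the voltage escape differs between total and prepulse
sweeps exactly where the HVA activation curve is steep — the in-silico
version of why poorly clamped cells are discarded.

**Tail-current activation**: conditioning steps (1,000 ms, −110…−60 mV in
5-mV increments from a −60 mV holding) are followed by a 200-ms tail step
to −110 mV; analysis uses the blocker-subtracted family.  The tail
amplitude is the inward extremum in a short window 2–3.5 ms after the tail
step (the blank excludes the capacitive transient; the short window keeps
re-activation at −110 mV — τ ≈ 100 ms — below 0.04 of full scale), minus
the pre-step baseline, normalized to the −110 mV conditioning value.  On
noiseless simulations the normalized curve tracks r∞ within 0.05
everywhere.

**Fits**: the Boltzmann f(V) = 1/(1+exp((V−V₅₀)/k)) and Hill
f(c) = cⁿ/(cⁿ+EC₅₀ⁿ) are fitted by bounded least squares from a fixed
coarse grid of starts (deterministic multi-start; the grid covers the data
span in V₅₀/EC₅₀ and half-decade steps in slope/cooperativity), matching a
2-D lattice search oracle in the tests.  At noise SD 0.03 with 11 points
the Boltzmann estimator recovers (V₅₀, k) with mean absolute errors well
under (1 mV, 0.5).

## 5. Statistics

Group rows report mean ± SEM (SD/√n).  The default two-sample test is the
pooled-variance Student t, two-sided (Welch available via flag); paired
comparisons use the paired t.  Zero variance in both groups with equal
means returns (0, 1); with unequal means the statistic is undefined and
returned as NaN.  No multiplicity correction is applied across metric rows,
matching common reporting practice in this literature — interpret per-row
p values accordingly.  The empirical type-I error at α = 0.05 under the
null is verified to lie in [0.04, 0.06] over 10⁴ replicates.

A caveat the simulated study exposes: "APs per burst at threshold" is an
integer pinned from below at the 3-AP criterion, and the GAERS preset's
strong I_h clamp makes *every* threshold burst minimal (exactly 3 APs, zero
group variance), while control thresholds overshoot by ~0.4 AP through the
10-pA ladder grid.  A pooled t test on a zero-variance group is
hypersensitive, so this comparison can flag a 0.4-AP difference as
significant at n = 15 — a discreteness artifact of the criterion plus
model, not evidence of a real burst-morphology difference.

## 6. Junction potentials

The generalized Henderson equation

    V = (RT/F)·[Σ z_i u_i Δc_i / Σ z_i² u_i Δc_i]·ln(Σ z_i² u_i c_i^pip / Σ z_i² u_i c_i^bath)

is evaluated with relative mobilities (K⁺ ≡ 1) from limiting molar
conductivities (packaged table with per-entry provenance), at 307 K by
default, with the pipette-minus-bath sign convention (a K-gluconate
pipette in NaCl bath is positive, and the true membrane potential is the
reading minus the LJP).  Solutions are entered as nominal recipe ions:
strong salts dissociate fully; HEPES carries −0.33 charge at pH 7.2
(pKa 7.5) and 4-AP +0.99 (pKa 9.2); EGTA enters as the di-anion; chelated
nucleotides and neutral osmolytes are excluded; the small pH-titration
cation is not added by default (matching the entry convention of the
junction-potential calculators the table follows), though
`dissociate(..., ph_adjust_cation=...)` can balance charge explicitly.
Charged species without a mobility entry raise an error above 1 mM and are
dropped (with an audit trail) below it.  The two-ion limit matches the
closed-form bi-ionic potential to 0.01 mV and the computation is exactly
antisymmetric under pipette/bath exchange.  Activity coefficients and full
electro-diffusion are out of scope; agreement with any particular reference
calculator beyond ~1 mV should not be expected.

## 7. Problem sizes and determinism

Default analyses run at 0.05-ms sampling (current-clamp protocols can use
0.02 ms); the cohort study uses 15 cells per strain, each analyzed over
two current-step ladders, two drug conditions and a two-condition
tail-current protocol.  All randomness (cohort draws, noise, offsets,
restarts) flows from explicit integer seeds; repeated runs are bit-identical.
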