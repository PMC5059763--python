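# Methods

## Model

The device is treated as four layers in series: bulk solution (B), the
supported lipid bilayer with its channel population, the isolation layer
(IL) — the nanometre-thick aqueous film trapped between bilayer and
contact — and the Pd/PdHx contact. Two state variables evolve in time:
the IL pH and the areal hydride inventory Q_H of the contact. Everything
else is algebraic.

**Membrane flux.** H⁺ current through the membrane follows the
Goldman–Hodgkin–Katz constant-field solution of the Nernst–Planck
equation, parameterized by a single effective permeability. The full
membrane potential drop is taken equal to the applied voltage V (Pd vs
Ag/AgCl): the bulk electrolyte resistance (~kΩ) is negligible against
the membrane's (~GΩ), so essentially all of V falls across the bilayer.
Sign convention: j > 0 is H⁺ flow from IL to bulk.

**Units of the permeability.** Device permeabilities are quoted on the
scale conventionally printed in s⁻¹ (0.006 bare bilayer, 0.58 with gA,
0.74 with ALM). Dimensional analysis of the GHK current equation with
concentrations in mol m⁻³ requires m s⁻¹ for the result to be a current
density in A m⁻²; and indeed plugging the printed numbers in directly
(as m s⁻¹) reproduces the measured device currents (−4.3 vs measured
−4.5 mA cm⁻² for gA; −5.52 vs −5.5 for ALM). We therefore treat the
printed values as the canonical device-scale permeability and insert
them into the SI GHK equation unchanged, rather than rescaling by the
IL thickness; the discrepancy is one of notation, not of physics.

**Electrode kinetics.** The contact current uses the two-branch
Butler–Volmer form i = i0[a·e^{αfη} − e^{−(1−α)fη}] rather than the
one-branch Tafel law, because the exchange current density i0 is defined
by equal forward and reverse currents at zero net current — a definition
that only the symmetric form honours; the Tafel law is recovered at
large |η|. The overpotential is η = V − V₀ − V_N with V_N the Nernst
potential of the IL/bulk concentration ratio: acidification of the IL
raises V_N and favours reduction. Oxidation (a = 1) requires hydride in
the film: a freshly prepared Pd contact holds no H, so its anodic branch
is off until reduction has loaded the film. In the dynamics the
availability `a` ramps linearly over a regularization scale of
1e−10 mol m⁻² as Q_H → 0, which keeps the right-hand side continuous
and resolves the otherwise-chattering depletion boundary (the net effect
is the physical one: at depletion, oxidation proceeds exactly as fast as
reduction supplies H).

**Buffering.** The IL is a single well-mixed compartment. The net areal
proton source r = (i − j)/F changes its pH as dpH/dt = −r/(β·D_IL),
with β the standard Van Slyke buffer capacity
β = ln10·([H⁺] + Kw/[H⁺] + Σ C·Ka·[H⁺]/(Ka+[H⁺])²) evaluated at the
current IL pH. The IL concentration [H⁺]_IL is always recomputed exactly
from the pH (1000·10^(−pH) mol m⁻³), never incremented separately, so
no linearization error can accumulate. The titratable proton content
T(pH) = [H⁺] − Kw/[H⁺] + Σ C·[H⁺]/(Ka+[H⁺]) is the closed-form
antiderivative of −β and is used to audit mass balance without numerical
quadrature.

## Parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| f = F/RT | 38.66 | V⁻¹ | conventional device value (T ≈ 300.2 K) |
| pH_B | 7.0 | — | working buffer; [H⁺]_B = 1e-4 mol m⁻³ |
| buffer | 5 mol m⁻³ phosphate, pKa 7.21 | — | the 5 mM K-phosphate working buffer; β(pH 7) ≈ 2.72 mol m⁻³/pH |
| P_base / P_gA / P_ALM | 0.006 / 0.58 / 0.74 | device scale (s⁻¹) | fitted device permeabilities |
| ALM thresholds | ±0.06 | V | gating onset of alamethicin; hard step by default, sigmoid width configurable |
| D_IL | 0.5e-9 | m | IL thickness used by the fits (force-displacement estimates run up to ~1 nm; configurable) |
| i0 | 10 | A m⁻² | calibration choice (see below) |
| α | 0.5 | — | symmetric barrier; calibration choice |
| V0 | −0.22233 (library) / 0.0 (presets) | V | see below |
| Pd film | 50e-9 m, x_max 0.6 | — | nominal PdHx capacity diagnostic |

**Electrode calibration (i0, α, V0).** The measured Pd Tafel parameters
are not available at desk scale, so the synthetic presets use a
calibration: i0 = 10 A m⁻², α = 0.5. With these, reduction at −200 mV
initially outpaces membrane transport (|i| > |j|), the IL alkalizes, and
the two currents converge to the membrane-limited value — the regime the
model is meant to exhibit. The nominal Pd/Ag-AgCl offset V0 = −0.22233 V
remains the library default, but at −200 mV and pH 7 it yields a weakly
*positive* overpotential, i.e. oxidation where reduction is observed —
the sign convention that would reconcile it is not recoverable. The
presets therefore override V0 = 0 V so that η < 0 at −200 mV/pH 7.
Nothing in the permeability workflow depends on this choice: the steady
currents are membrane-limited, and the fits estimate P, not V0.

## Numerics

With the physical reservoir β·D_IL ≈ 1.4e−9 mol m⁻² per pH unit and
currents of order 10 A m⁻², the IL pH relaxes on microseconds while
protocols run for tens of minutes: the ODE system is stiff by roughly
eight orders of magnitude. Each constant-voltage protocol segment is
therefore integrated with a stiffness-switching solver (LSODA,
rtol = 1e-8, per-state atol down to 1e-18) restarted at every voltage
step; explicit time stepping would either ring at the quasi-equilibrium
or require ~1e8 sub-steps. Three states are co-integrated: pH_IL, Q_H,
and the cumulative net proton source ∫(i−j)/F dt. The last is redundant
at the ODE level — it must equal D_IL·ΔT(pH) exactly — so comparing the
two routes audits the solver; the residual is ~1e-8 relative, and a
10×-tighter-tolerance rerun moves the result by less than 1e-6.
Consequences of the stiffness worth knowing:

* at any practical sampling interval (≥ 1 s) the traces show the IL pH
  already at its quasi-steady plateau; the plateau value, not the
  transient, is the observable;
* the t = 0 sample reports the pre-relaxation state (pH_IL = pH_B),
  giving a single large kinetic spike at the start of each trace.

Other numerical choices: GHK is evaluated via `expm1` with the
overflow-safe form for either field sign, switching to a second-order
series for |fV| < 1e-6 (branch mismatch ~1e-15 relative); all
exponential arguments are clamped to ±50; the Nernst potential is
computed as a difference of logs so its antisymmetry is exact; the
permeability search runs in log10 P with Brent's bounded minimizer
(relative tolerance 1e-6, bounds [1e-4, 10]); an estimate within 0.1%
of a bound is flagged `at_bound` and not converged; (i0, α) are
recovered by trust-region least squares with i0 in log space and α
bounded to (0, 1).

The hydride inventory is tracked but **not clamped** at the nominal
PdHx capacity: sustaining the observed ~4–5 mA cm⁻² for ten minutes
requires ~50× the 50-nm film's nominal x = 0.6 capacity, a tension the
four-layer model does not resolve. A warning reports the peak hydride
ratio; an explicit `hydride_capacity` can be set to study capacity
effects.

## Synthetic data

The generator emulates stepped-voltage chronoamperometry for the five
device conditions (bare SLB; +gA; +gA with Ca²⁺ block; +ALM; +ALM with
urea disruption): 10-minute steps at −200/0 mV (gA family) or
−200/0/+100 mV (ALM family), 1 s sampling by default, currents of order
0.1–10 mA cm⁻². Noise is additive i.i.d. Gaussian on the measured
current only (specified absolutely or as a fraction of max |i|), seeded
and reproducible; pH and membrane-flux columns stay clean. Blocked
variants set the channel block factor to zero, reducing the membrane to
the bare bilayer.

What the generator does *not* emulate — and hence what passing tests do
not establish about real data: baseline drift and electrode fouling,
the minutes-scale current growth seen in measured traces (a slow process
outside the four-layer model), device-to-device geometry variability,
parallel cathodic pathways (H₂ evolution), ALM's rectifying behaviour at
positive bias, and lateral transport within the IL. Recovery statistics
on synthetic traces demonstrate that the estimation workflow is
correct and well-conditioned for the modelled physics, not that the
model captures every feature of a measured trace.

At 5%-of-maximum noise (≈2.4 mA cm⁻², the maximum being the kinetic
spike at t = 0) the bare bilayer's steady signal (~0.045 mA cm⁻²) is
far below the noise floor, so its permeability is unidentifiable from a
single noisy trace; the channel devices are recovered with ~1.4% median
error, and the ordering P_SLB < P_gA < P_ALM survives in every seeded
replicate because the channel/bare contrast is two orders of magnitude.

## Known limitations

* The printed V0 is inconsistent with the observed current sign at
  −200 mV under this formulation (see calibration note); it is exposed
  as configuration rather than resolved.
* The relaxation to the pH plateau is microseconds here versus minutes
  in measured traces; only plateau values and switching logic, not time
  constants, should be compared against experiments.
* The alamethicin relaxation time constant is marginally *longer* than
  gramicidin's under the presets (the larger buffer capacity at its
  lower plateau outweighs its steeper current response), although both
  are far faster than the bare bilayer's.
* Single-channel conductances, channel densities, electric-double-layer
  electrostatics and non-proton ion transport are out of scope; the
  permeabilities are device-scale quantities.
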