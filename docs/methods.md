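# Methods

## Scope and model structure

`nitropath` computes three related things for anammox-based nitrogen removal
from low-strength wastewater: (i) closed stoichiometric combinations of
nitrogen-cycle half-reactions and their theoretical oxygen/organic demands,
(ii) two-point cycle mass balances that apportion nitrogen removal among
microbial pathways, and (iii) a forward kinetic simulation of a sequencing
batch reactor (SBR) cycle that produces data with known per-pathway ground
truth. Nothing is fitted: (i) and (ii) are exact algebra, (iii) is an
initial-value ODE problem.

## Reaction algebra and closure

Reactions are signed molar coefficient vectors over a small species registry
(NH3, O2, NO2−, NO3−, N2, H2O, H+, CH3COO−, HCO3−, CO2), reactants negative.
Combination, normalisation and closure are plain linear algebra on these
vectors; the closure system {net NO2− = 0, net NO3− = 0, NH3 consumed = 1}
is solved with `numpy.linalg.solve` and rejected when singular or when any
weight is negative (an infeasible route, e.g. two oxidisers with no
reducer).

The five built-in half-reactions are exactly element- and charge-balanced
except anammox, whose conventional biomass-free equation (NH3 + 1.32 NO2− +
H+ → 1.02 N2 + 0.26 NO3− + 2 H2O) carries known residuals (N −0.02, O +0.14,
charge +0.06 mol per mol NH3) because cell synthesis is omitted. Rather than
loosening the global balance tolerance (1e-9 mol), the reaction is flagged
`empirical` and exempted; the residuals themselves are asserted in the test
suite so a silent regression of the vector would be caught. The anammox NO2
and NO3 coefficients are configurable; every derived quantity (case weights,
demands, the PN/A nitrate leak) responds consistently.

### Demands and the rounded-coefficient convention

Theoretical oxygen demand of organics uses the electron-equivalent formula
ThOD = 8·(4C + H − 2O − charge) g O2/mol, floored at zero; only C/H/O(±)
species are accepted because acetate is the only organic in scope and a
nitrogenous-ThOD model is deliberately out of scope. Demands per mg NH3-N
divide by 14 g N/mol.

`DemandSummary` carries full-precision values and a *table* variant that
recomputes each demand from the molar coefficient rounded to two decimals.
Printed summary tables in this field derive their demand columns from the
rounded total-reaction coefficients, and the two routes genuinely differ in
the second decimal for Case I (0.8534 mol O2 → 1.95 full-precision but
0.85 × 32/14 = 1.94 table convention). Comparisons against published
tables use the table variant; everything else uses full precision.

## Apportionment equations and their constants

The two-point balances use only react-phase start/end bulk concentrations.
"Initial" means immediately after feed mixing (the `mix_feed` convexity
identity: ratio × influent + (1 − ratio) × residual); "final" means the end
of the anoxic react phase, with settling/decant assumed reaction-free.

Two anammox coupling constants coexist in practice: the conventional
2.04 mg TN per mg NH4-N (used by the field's balance equations, and the
default here, `consistency_mode="paper"`), and the strictly reaction-closed
1 + 1.32 − 0.26 = 2.06 (`consistency_mode="closed"`). The package keeps
both on purpose: the conventional constant preserves comparability with
published balances, while the closed constant makes apportionment exactly
consistent with simulation driven by the same reaction vector — applying
the conventional constant to endpoints generated by exact 1.32/0.26
stoichiometry leaves a small spurious negative AOB term (−0.098 mg N/L per
10 mg NH4-N), which the test suite demonstrates.

The product-form equation "NH4_initial − NH4_final × 2.04" is implemented
as (NH4_initial − NH4_final) × 2.04 throughout; the literal precedence
yields negative nonsense for any realistic cycle.

Negative apportioned components are returned as computed with a warning
flag (optional clamp-to-zero). Negativity is the diagnostic that the
phase's neglected pathway was not actually negligible; clamping silently
would destroy exactly that signal. By construction TN_denitritation is
defined as ΔN − TN_anammox, so the phase-II identity TN_anammox +
TN_denitritation = ΔN is exact at machine level in its defining form.

The nitrate-to-nitrite transformation ratio (NTR) of batch denitrification
tests is accumulated NO2-N over reduced NO3-N, evaluated only where the
nitrate drawdown exceeds ε = 0.1 mg N/L — typical analytical precision —
to prevent 0/0 blow-up at trace start; the reported maximum scans the whole
series so transient nitrite peaks of complete-denitrification traces are
captured. NTR is invariant under uniform concentration scaling.

Campaign summary statistics use the sample (n−1) standard deviation.
Nitrogen-removal efficiency is offered both as efficiency-of-means and as
per-day efficiencies (via the campaign frame); the averaging order of
published campaign figures is generally unstated, so neither variant is
privileged.

## The cycle simulator

### What it emulates

A 10-L-scale SBR operated at 3 cycles/day: 10 min feed at 50 % volume
exchange, 360 min anoxic react, 30 min settle, 10 min decant, 70 min idle.
Influent analytes are drawn per cycle from zero-truncated normals; the two
built-in operating points are the low-strength ammonium+nitrite feed
(14.3 ± 2.5 / 14.1 ± 2.4 / 1.2 ± 0.8 mg N/L, no rbCOD, DO 0.07 mg/L) and
the acetate-amended feed (12.5 ± 1.8 / 12.3 ± 1.4 / 2.0 ± 0.6 mg N/L plus
24.2 mg/L acetate COD, DO 0.03 mg/L). The acetate dose is modelled as fixed
(sd 0) because it is a controlled addition rather than a measured influent
property. Feed is treated as instantaneous (10 min ≪ 360 min), which makes
cycle endpoints exactly the two-point balance the apportionment assumes.

### Rate laws and parameters

Each guild g converts its key substrate at μmax,g · Xg · Π s/(Ks+s), with
aerobic guilds (AOB, NOB, aerobic heterotrophs) multiplied by DO/(K_O2+DO)
and anoxic guilds (anammox, both denitrification steps) by the
non-competitive inhibition K_O2/(K_O2+DO). Biomass is 4.9 g VSS/L total
(a freshly inoculated reactor) split by configurable guild fractions;
biomass is otherwise static, with an optional linear per-day drift for
long-campaign scenarios.

No kinetic constants are available for the emulated system, so the defaults
are order-of-magnitude literature-typical values for mainstream conditions,
chosen once so that the default no-rbCOD cycle removes most of its
ammonium/nitrite within the react phase:

| guild | μmax (mg N or COD g VSS⁻¹ h⁻¹) | K_s (mg/L) | K_O2 (mg/L) | fraction |
|---|---|---|---|---|
| anammox | 4 | NH4 0.5, NO2 0.5 | 0.2 (inh.) | 0.10 |
| AOB | 20 | NH4 0.5 | 0.3 | 0.01 |
| NOB | 30 | NO2 0.3 | 0.15 | 0.01 |
| denitratation | 10 | NO3 0.5, COD 5 | 0.2 (inh.) | 0.15 |
| denitritation | 4 | NO2 0.5, COD 5 | 0.2 (inh.) | 0.15 |
| aerobic COD | 30 | COD 5 | 0.2 | 0.15 |

These are illustrative, not fitted; quantitative conclusions should never be
read off the defaults. The NOB oxygen affinity is set high (low K_O2)
because high-affinity nitrite oxidisers are precisely the failure mode of
mainstream anammox operation, and denitritation is slower than
denitratation so nitrite accumulates during carbon-fed nitrate reduction
(the partial-denitrification character the batch fixtures display).

Species updates come from the same reaction vectors as the closure algebra.
With `closed_stoichiometry=True` (default) the anammox N2 yield is set to
close the nitrogen balance exactly (2.06 N per NH3-N); with the empirical
vector the 0.02 mol N shortfall is tracked explicitly as "incorporated"
nitrogen so the closure invariant holds in both modes.

### Integration and numerical choices

`scipy.integrate.solve_ivp` with LSODA, rtol 1e-8 / atol 1e-10, over the
6-h react phase; profiles are sampled at 5-min resolution. Monod saturation
makes all rates vanish smoothly as substrates approach zero, so
concentrations stay non-negative without event handling and the system is
non-stiff at the defaults (LSODA covers stiff parameter choices). Pathway
ground-truth integrals are carried as extra quadrature states of the same
ODE, so they share the integrator's error control; per-cycle nitrogen and
COD closure hold to ~1e-14 relative, far inside the 1e-6 target.

All campaign randomness flows from one `numpy.random.SeedSequence` split
into per-cycle streams, so any sub-run is reproducible in isolation and
identical seeds give byte-identical outputs. Daily effluent records are the
last cycle's react endpoint (recorded in the output metadata); measurement
noise, when enabled, is Normal(0, σ_abs + σ_rel·value) truncated at zero.

### What the generator does and does not capture

It emulates the operating schedule, influent statistics, DO regimes,
guild-resolved nitrogen conversions and analytical noise. It does **not**
model granule/biofilm diffusion limitation, settling and selective washout,
microbial growth dynamics and community shifts, temperature dependence, pH
or free-ammonia/free-nitrous-acid inhibition, N2O side-paths, DNRA, or the
endogenous carbon-storage route of partial denitrifiers (the generator uses
direct acetate-driven denitrification only). Tests passing on these
synthetic data therefore validate the *balance algebra and its assumptions*
— e.g. that endpoint apportionment recovers true pathway fluxes when its
neglected-pathway assumption holds, and is biased in a definite direction
when it does not — not the kinetics of any real reactor.

## Validation strategy

Worked numerical examples are hand-derived and frozen in the tests;
closure, monotonicity, additivity, scale-invariance and determinism are
property-based (hypothesis, bounded concentration domains). Oracle-recovery
tests run the full loop: simulate an acetate-amended cycle with nitrifiers
disabled and the closed vector, apportion its endpoints, and compare each
pathway estimate with the simulator's ground-truth integral — exact to
integrator precision noise-free, and with median relative error across
pathways well under 10 % when every endpoint reading carries 0.2 mg/L
noise (100 seeded replicates). Problem sizes (single cycles, 100
replicates, ≤ 20-day campaigns) keep the whole suite around ten seconds
while leaving the statistics conclusive.

## Known limitations

* The demand table's rounded-coefficient convention means full-precision
  demands can differ by one unit in the second decimal from the table
  variant; both are exposed, and which one a comparison uses is explicit.
* The conventional 2.04 constant and the reaction vector's 2.06 are not
  reconcilable without a biomass-explicit stoichiometry (out of scope);
  mixed use (e.g. closed simulator + conventional apportionment) introduces
  a ~1 % systematic on anammox shares, visible in the tests.
* Effluent figures of a simulated campaign are react-endpoint grabs, not
  composites; compare accordingly.
* The kinetic defaults reproduce qualitative regime behaviour (nitrate
  accumulation without rbCOD, nitrate polishing and nitrite accumulation
  with it), not any particular reactor's magnitudes.
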