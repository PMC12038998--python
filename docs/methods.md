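# Methods

`cysmca` implements an *in-vivo* metabolic control analysis (MCA) workflow
for an engineered *E. coli* L-cysteine production process, together with
the bioprocess calculations (cell-specific rates, exporter selectivity,
off-gas balancing, carbon molar balances) that frame it. This note records
the models, the assumptions behind them, the numerical choices, and the
limits of what the synthetic validation can show.

## The reduced network

The packaged model (`cysmca.model.build_reduced_model`) covers glycolysis,
the pentose phosphate pathway, the citrate cycle and the
L-cysteine/O-acetylserine (OAS) branch in a single cytosolic compartment:
37 reactions over 53 species. Species are labelled BiGG-style. Three
species are extracellular boundary pools (medium glucose and the two
exported products); water and the currency/cofactor pools (adenylates,
NAD(H), NADP(H), quinones, Pi/PPi, CO2, the sulfur species and glutamate)
are clamped. That leaves 33 balanced intermediates; the acyl-carrier trio
CoA/acetyl-CoA/succinyl-CoA forms the single conserved moiety, handled
throughout by link decomposition. Clamping currency pairs is the standard
reduced-model MCA convention: it prevents spurious conserved pools and
keeps the enzyme-level sensitivities in focus. The designation is a
configuration list (`MetabolicModel.with_internal_set`), not a hard-coded
assumption.

Carbon bookkeeping uses the transferred-moiety convention (CoA counts 0
carbons, acetyl-CoA the 2 acetyl carbons), under which every chemical
reaction in the model is carbon balanced; the lumped respiratory steps
(NADH5, ATPS) and the coupled exporter (YdeD) are flagged as
pseudo/transport steps and exempted.

**Exporter coupling.** The YdeD step co-exports OAS and L-cysteine 1:1.
This coupling is kept as the default because it reproduces the measured
selectivity almost exactly: at a cysteine export of 24.6 mg g⁻¹ h⁻¹ the
coupled OAS co-export is 0.203 mmol g⁻¹ h⁻¹ × 147.13 g mol⁻¹ =
29.9 mg g⁻¹ h⁻¹, against 30.1 measured (OAS and its extracellular isomer
N-acetylserine have equal molar mass, so mass rates are interchangeable).

**Default augmentations.** With every arrow irreversible and glutamate
clamped, the printed network cannot carry a positive serine/cysteine flux
at steady state: the 2-oxoglutarate released by phosphoserine
transaminase has no sink, which forces the anaplerotic PPC flux negative.
Genome-scale models close this loop through nitrogen assimilation. The
default augmentation therefore adds, via the ordinary `augment_model`
mechanism:

- `GDH` — glutamate dehydrogenase, recycling 2-oxoglutarate into the
  clamped glutamate pool;
- `BIOMASS` — a lumped biomass-precursor drain with the classic *E. coli*
  precursor demands (flux unit: specific growth rate, h⁻¹);
- `ACEex` — an acetate overflow export (reference flux
  0.05 mmol g⁻¹ h⁻¹); without an acetate exit, carbon-source
  perturbations have no overflow route and trace pools collapse;
- `GLCfeed`, `PYRup`, `SUCCup` — boundary feeds used by the perturbation
  design.

## Reference state

The reference state represents the production phase of the fed-batch
process: glucose uptake 2.2 mmol g⁻¹ h⁻¹, coupled OAS/cysteine export
0.203 mmol g⁻¹ h⁻¹, specific growth rate ≈ 0.19 h⁻¹, cultivation
temperature 305.15 K. Reference intracellular concentrations are typical
glucose-fed *E. coli* pools, with a deliberately scarce OAS pool
(0.04 mM) reflecting the exporter-driven precursor drain of the producer
strain. The full reference flux distribution is obtained once, as the
closest point to pathway-level target fluxes that satisfies every
balanced-species constraint exactly (weighted least squares with the
measured uptake and export pinned).

## The synthetic kinetic model

Each reaction carries one of three rate laws:

- **Thermokinetic affinity** (17 near-equilibrium enzymes):
  v = V_f (1 − Γ), Γ = exp(ΔG_r / RT). The scaled elasticity w.r.t. a
  participant is −s·Γ/(1−Γ): it diverges approaching equilibrium and
  vanishes in the saturated forward limit. Reference ΔG_r is drawn
  uniformly in (−2.5, −0.5) kJ mol⁻¹ — close enough to equilibrium that
  these elasticities stay O(1); further out (e.g. −9 kJ mol⁻¹) the
  elasticities drop to ~0.03 and the network can no longer re-balance
  after perturbations.
- **Lin-log** (far-from-equilibrium enzymes, 20 in the core model plus
  the augmented drains): v = e·J_ref (1 + Σ ε_j ln(c_j/c_ref)).
  Elasticities are drawn from a generalized-mass-action prior:
  ε_ij = −s_ij · g_i · (1 + U(−0.3, 0.3)) with reaction gain
  g_i ~ U(0.5, 1.4) (biomass drain: U(0.1, 0.25)). The sign-symmetric
  backbone makes the steady-state Jacobian approximately −N W Nᵀ with W
  positive diagonal, i.e. the network is dynamically stable by
  construction. Independent per-entry draws (signs from stoichiometry,
  magnitudes uniform) routinely produce a near-singular Jacobian — a
  weakly controllable mode spread over the sugar-phosphate pool — and the
  perturbed steady states then fold and disappear at feed increments
  below 2%.
- **Feed** (boundary supplies): constant flux.

Far-reaction reference ΔG_r values are drawn in (−35, −12) kJ mol⁻¹, and
ΔG°′ values are back-computed from the reference concentrations so that
thermodynamic classification on the generated data reproduces the
near/far split exactly.

All rate laws return J_ref exactly at the reference state, and the model
is fully deterministic given a seed.

## Perturbation experiment emulation

The design mirrors four parallel short-term reactors (glucose; pyruvate;
glucose+pyruvate; glucose+succinate), each with three 7-minute feeding
stages (30/60/90 mL h⁻¹), giving 12 perturbed steady states plus the
reference. Enzyme levels are held at reference throughout — on the
minutes time scale expression does not change, which is exactly the
identifying assumption of the lin-log regression.

Pyruvate and succinate feeds are boundary fluxes into the internal
pyruvate and succinate nodes (0.06/0.12/0.18 and 0.04/0.08/0.12
mmol g⁻¹ h⁻¹). Glucose feeding is represented as a change of the clamped
*medium glucose concentration* (×1.25/1.50/1.75; mixed regimes
×1.15/1.30/1.45) to which the PTS responds kinetically. A fixed-flux
glucose boundary was rejected after analysis: it pins the PTS flux
exactly, and the kinetic steady state then fold-bifurcates at roughly +2%
feed for essentially every elasticity draw. On the 7-minute stage time
scale, the concentration of glucose in the medium is in fact the quantity
the feed controls. Feed magnitudes were chosen so that all 12 states
exist (lie inside the kinetic model's basin) across many elasticity
draws — a validity requirement of the generator, not a tuning target.

Steady states are solved in log-concentration space by a Newton method
(hybrid Powell) started from the linearized response, with automatic
continuation in the boundary setting when a direct solve fails, and with
the conserved CoA pool pinned to its reference total. Consecutive feed
stages of one reactor warm-start from the previous stage, as in the
physical experiment. Mass-balance residuals are required to be below
1e-8 relative.

Measurement noise is multiplicative log-normal (default CV 10%, mean
preserved), applied independently to every concentration and rate;
CV = 0 returns exact model output.

## Flux analysis

FBA and FVA are linear programs on the HiGHS solver; the loopless FVA
variant uses the standard binary/potential MILP formulation with the
cycle basis restricted to purely internal, two-sided reactions. TFA
couples each reaction's direction to the sign of
ΔG_r = ΔG°′ + RT Σ s_j ln c_j through paired binary use-variables
(big-M 1000 kJ mol⁻¹, strictness margin 1e-3 kJ mol⁻¹) and reports
ranges for fluxes, Gibbs energies and log-concentrations. Concentration
bounds default to 10 nM–50 mM and are narrowed to ±20% around measured
values. Equilibrium classification: ΔG_r ∈ [−10, 0] kJ mol⁻¹ is "near"
(the −10 boundary inclusive), below −10 "far", positive or missing
"unclassified".

Per-state flux distributions in the pipeline come from weighted
least-squares reconciliation of the measured rates onto N v = 0
(null-space projection). For noise-free consistent data this returns the
input exactly; under noise it is the minimal consistent adjustment.

## Elasticities and control coefficients

Near-equilibrium rows of the elasticity matrix use the thermokinetic
closed form at the representative (midpoint) ΔG_r from TFA; far rows are
regressed per reaction from v_k/J_ref − 1 against ln(c_k/c_ref) over the
12 perturbation states, with effectors defaulting to the reaction's
internal reactants and products (plus the measured medium glucose for
the PTS). Ridge shrinkage is off by default and switched on automatically
(λ = 1e-3) when the design's condition number exceeds 1e6.

Control coefficients follow the classical steady-state sensitivity
algebra with link decomposition for the conserved moiety:
C_S^u = −L M⁻¹ N_R with M = N_R (dv/dc) L, C_J^u = I + (dv/dc) C_S^u,
scaled by reference fluxes and concentrations. The summation theorems
hold exactly whenever the reference flux vector satisfies N J = 0 — the
pipeline guarantees this by reconciling the (re)sampled reference rates
on the feed-free subnetwork before every evaluation. Reactions with
|J| < 1e-9 are excluded from scaling (scaled coefficients undefined);
a reduced Jacobian with condition number above 1e12 raises rather than
returning garbage.

Monte Carlo uncertainty propagation resamples every concentration and
rate from a truncated normal (at zero), re-reconciles, re-assembles the
elasticity matrix and recomputes the coefficients; summaries are medians,
2.5/97.5 percentiles and sign-stability fractions. The Monte Carlo path
always applies a small ridge (λ = 1e-3): without it, designs that noise
lifts just past the rank-deficiency threshold acquire arbitrary
null-space components that swamp the summaries. Iterations with singular
Jacobians are dropped and counted; more than 50% dropped is an error.

## Fed-batch generator and bioprocess calculations

The fed-batch simulator books glucose carbon explicitly into biomass,
products and CO2 at every Euler step (default Δt = 0.02 h), so the
generated series closes its carbon balance by construction and the CO2
evolution rate is defined as the carbon not fixed elsewhere. It
reproduces the reference process layout: 10 L initial volume, 10 g L⁻¹
batch glucose, exponential growth at 0.21 h⁻¹, automatic feed start at
glucose depletion, dual 670 g L⁻¹ glucose / 320 g L⁻¹ thiosulfate
feeding, growth to a 35 g L⁻¹ stationary ceiling, and export rates of
24.6 (cysteine) / 30.1 (OAS-as-NAS) mg g⁻¹ h⁻¹ during production.
Off-gas fractions are generated by inverting the same inert-gas (N2)
balance the estimator uses.

Cell-specific rates are computed from total-amount differences
(V·C) with explicit feed correction, divided by the trapezoid integral
of biomass; volume changes make concentration-derivative formulas wrong
in fed-batch. Biomass carbon content defaults to 0.474 g C per g CDW
(CH₁.₇₇O₀.₄₉N₀.₂₄). The carbon balance reports each sink as percent of
the glucose carbon supplied (batch charge + feed), with residual medium
glucose itemized and the remainder as "unaccounted".

## Known limitations

- **Weak flux excitation.** The basin-limited feed increments move
  concentrations strongly (up to e² typically, e⁵ for trace pools in the
  harshest pyruvate stage) but fluxes only by a few percent. At 10%
  measurement noise the lin-log regression response is therefore noise
  dominated (SNR ≈ 0.2) and elasticity recovery is poor regardless of
  estimator; the shipped identifiability smoke test documents that the
  error shrinks with the noise level and reaches ≤30% (median) once the
  noise is well below the flux excitation (~0.1% CV). Consequently the
  Monte Carlo sign-stabilities at 10% CV are moderate (~0.6–0.8) for most
  enzymes — an honest statement about what this experiment layout can
  identify.
- **Rank-deficient designs in the cysteine branch.** The branch is an
  all-lin-log (hence linear) subnetwork driven by only three boundary
  degrees of freedom, so the 12-state design is exactly collinear for
  reactions with ≥4 effectors (SERAT, CYSS, SLCYSS, and the biomass
  drain). Their elasticities are not identifiable from this design; the
  regression falls back to ridge and flags the condition number. All
  full-rank rows are recovered to machine precision on noise-free data.
- The generator emulates neither LC–MS measurement physics, quenching
  losses, nor within-stage transients; states are exact steady states.
- Lin-log rate laws are local approximations; the harshest perturbation
  stages drive some trace metabolites far from the reference, where
  lin-log kinetics (and hence the generated "truth") should be read as a
  stress test for the estimators, not as metabolite physiology.
- Group-contribution estimation of formation energies is out of scope;
  standard Gibbs energies are inputs (the generator supplies consistent
  synthetic values).
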