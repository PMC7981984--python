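# Methods

This note documents the models, numerical choices and limitations behind
`kinequiv`. Everything quantitative stated here is computed by the test
suite or `scripts/acceptance.py`.

## Thermodynamic model

Reactions annotated with a standard Gibbs energy ΔG° (kJ/mol) are coupled to
log-concentration variables ln x (ln mol/L) through
ΔG_r = ΔG° + RT·Σ_j n_ij ln x_j. Water and protons are treated at fixed
activity and excluded from the concentration term (`excluded_species`,
configurable). RT defaults to 2.4789 kJ/mol (298.15 K). Concentration data
arriving in log10(mM) — the usual measurement convention — is converted at
the boundary (`log_mM_to_ln_molar`).

Direction coupling uses per-reaction binaries b⁺/b⁻ with big-M constants:
M = max(|LB|,|UB|) for flux couplings (falling back to `big_m_flux` = 1000
when bounds are open) and `big_m_energy` = 1000 kJ/mol for the energy
couplings — the tightest safe values for the bounded problems this package
builds. Strict inequalities are realised as closed ones offset by the
tolerance, since MILP solvers operate on closed sets.

**Equilibrium exclusion.** A reaction at Γ = 1 has equal forward and
backward rates, zero net flux, and divergent elasticities, so active
reactions must satisfy |ln Γ| ≥ δ. δ is not a measured quantity; the default
δ = 0.01 is small enough not to distort TVA ranges (it shifts each bound by
at most RT·δ ≈ 0.025 kJ/mol of driving force) while bounding the elasticity
term Γ/(1−Γ) ≈ 100 at the band edge.

**Minimum activity.** The workflow's purpose requires every reaction of the
kinetic model to carry net flux (a zero-flux reaction leaves its expansion
metabolites without dynamics and the Jacobian singular). With
`min_net_flux` set, every thermodynamically treated reaction must choose a
direction (b⁺ + b⁻ = 1) and carry at least that magnitude. The workflow
default is 1e-4 mmol/gDW/h: negligible against core fluxes of order 1, but
two orders of magnitude above the MILP solver's feasibility tolerance, so
the constraint cannot be satisfied "at tolerance" by a numerically zero
flux. The option is off in the plain `ThermoParams` so that TFA/TVA can also
be used for ordinary feasibility analysis where zero flux is legitimate.

All LPs and MILPs run on scipy's HiGHS backend, which is deterministic for a
fixed model; no solver seed exists or is needed.

## Sampling and representative states

With direction binaries fixed (to the pattern of a feasibility solve —
required, because hit-and-run needs a convex set), the TFA feasible set is a
polytope. Sampling works in the null space of the equality constraints:
equalities (mass balance, ΔG definitions, fixed variables) are eliminated
exactly via an orthonormal basis, inequality rows that are constant over
that affine hull are checked once and dropped (they would otherwise pin the
interior-point slack at zero), and an interior point maximises the
normalised slack. The walk is artificial-centering hit-and-run: directions
are drawn toward randomly chosen previous iterates relative to the running
center (Gaussian directions during warm-up), the step is uniform on the
feasible chord. Defaults: 1000 warm-up steps, thinning 10, both
configurable. These are mixing heuristics, not guarantees; the test suite
checks uniform marginals on boxes (Kolmogorov–Smirnov) and exact moment
matches on segments.

The representative state is chosen by PCA: samples are standardised
(constant columns dropped), components retained until cumulative explained
variance reaches `variance_coverage` (default 0.9 — a generalisation of
retaining a fixed component count, which is pool-specific), and the pool
member closest to the projected pool mean is returned, ties broken by lowest
sample index. The representative is always an actual sample, never an
average, so it satisfies every constraint exactly.

## Steady-state transfer

Bands are F_i = ref_i ± relaxation·max(|ref_i|, floor). The floor matters
because 1% of a zero reference is a point: near-zero fluxes get an absolute
floor of 1e-6 mmol/gDW/h. Concentration bands act on the ln x variables
(keeping the MILP linear) with a floor of 0.01 ln-units, i.e. about a 1%
concentration change, for log-concentrations near zero. Percent deviations
are reported against the small-model reference value.

The transfer MILP retains the full TFA constraint set of the receiving
model, not only mass balance — the receiving models are TFA models, and a
transferred state must remain thermodynamically admissible; a caller who
wants the purely stoichiometric variant can build the receiving problem
without thermodynamic data. With all z = 1 the bands vanish, so the MILP is
feasible whenever the receiving TFA problem is; the reported optimum is the
minimum violation count, and the violated set is reported as found (HiGHS is
deterministic; `enumerate_minimum_violation_sets` lists all minimum-
cardinality sets on small models, where alternative optima are a real
concern). Achieved values for *violated* reactions are one optimal solution
among possibly many and should be read as "outside the band", not as a
unique prediction.

## Kinetic ensembles

Kinetic instances are represented at the elasticity level: a steady state
plus a scaled elasticity matrix determines stability and all control
coefficients, which are the workflow's outputs, without committing to rate
constants. Each mechanism's binding elasticity is documented in
`kinetics.py` and verified against a central-difference oracle built from an
explicit rate law (binding factor ρⁿ/(1+ρ)ⁿ per site times the displacement
factor 1−Γ): convenience kinetics |n|(1−σ) for substrates and −|n|σ for
products (the default for enzymatic and lumped reactions), reversible Hill
h(1−σ)/−hσ, mass action |n|/0 (the default for transport and exchange
steps), competitive inhibitors −σ and activators +(1−σ). Saturations are
sampled uniformly on (1e-6, 1−1e-6); the open interval keeps rate-law
back-solves well-posed. Literature Km values can be injected as fixed
σ = x/(Km+x) at the reference concentration.

Reactions are oriented along their net flux before applying the
displacement term (Γ < 1 in the oriented frame); scaled elasticities are
invariant to this orientation, which the tests verify. Reactions without
thermodynamic data use their binding terms only (irreversible limit).

**Stability and control.** Conserved moieties are removed exactly: the
independent rows of S are found by rational row reduction (sympy) and the
link matrix solves S = L·N_R exactly. An instance is stable iff the reduced
Jacobian has no eigenvalue with real part above 1e-9 ("not positive": zero
is admitted). Control coefficients come from the linearised steady-state
response; because fluxes in one model can span many orders of magnitude
(core fluxes ~1, basal expansion fluxes ~1e-4), the linear solve is
row-equilibrated — rows of J and of N_R·diag(v) share the same flux prefix,
so the scaling cancels exactly and the summation theorems hold to ~1e-11
in practice. Instances whose equilibrated Jacobian is still singular (by
condition number) are discarded and counted separately; singularity there
means the linearised response is genuinely undefined. Only the eigenvalue
test filters instances; a hook for additional user-defined consistency
filters is the `stability_check` callable of `stratified_resample`.

**Stratified resampling.** Shared enzyme–metabolite pairs (including lumped
reactions present in both models — the default reading of "shared") are
copied bit-exactly; expansion-specific σ are redrawn up to `max_tries`
(default 10) until the instance is stable, and instances exhausting the
budget are dropped and counted, yielding the retained-fraction accounting.

## Deviation reports

DI defaults to the DI of the population-mean FCC matrix; the per-instance DI
distribution is always attached, since either aggregation is defensible and
they can differ. Only enzymatic and lumped reactions count as enzymes when
building shared sets across models; summing over *all* reaction columns
recovers DI = 0 identically (the summation-theorem null that the acceptance
checks enforce). Percentile classes use the empirical 25th/75th DI
percentiles with ties taking the lower class, for determinism. Rankings
order enzymes by |mean FCC| with ties broken by enzyme id.

## Synthetic families

The generator emulates the output structure of systematic GEM reduction: a
linear catabolic backbone with fixed substrate uptake (default 1.0
mmol/gDW/h), an ATP/ADP-style conserved pair (investment step plus a
gradient-driven recharge reaction), a small secretion branch, and a lumped
biomass reaction capped at 10% of the core flux, mirroring the
biomass-dilution scale. Each nesting level adds two-reaction parallel routes
around the highest-degree backbone metabolites (branch-point creation — the
mechanism that redistributes control in real families) plus one alternative
lumped biomass route, so lumped sets differ across levels.

ΔG° values are generated from per-metabolite formation energies (backbone
steps drop 8–20 kJ/mol; the cofactor couple is split by 30 kJ/mol), so ΔG°
sums to zero around every stoichiometric cycle — randomly drawn per-reaction
ΔG° would create thermodynamically inconsistent loops. Reference physiology
emulates fluxomics/metabolomics data: bounds of ±20% around a strictly
feasible interior point for a seeded half of the fluxes and
log-concentrations, guaranteed to remain feasible at any tightening.

What the toys do *not* emulate: genome-scale topology and redundancy,
realistic compound energetics, measurement noise in the physiology,
cofactor-coupled transport, and isoenzymes. Passing tests therefore
demonstrate the correctness of the machinery and its invariants
(summation, DI identities, bit-exact sharing, oracle agreement), not that
any particular biological conclusion transfers to real networks.

## Problem sizes

The standard test family has 12/17/22 reactions over three levels; the
acceptance run uses 300 flux samples per polytope and 200 stable kinetic
instances per level, stratified across levels, which reproduces every
invariant headroom-free (summation residuals ~1e-11) in a few seconds.
Library defaults follow the larger study conditions (10,000 samples per
polytope); all counts are plain arguments.

## Known limitations

- Sampling assumes fixed directionalities; the union of direction patterns
  is not sampled, and uniformity over the polytope is approximate
  (hit-and-run mixing).
- ΔG° values are accepted as given: no group-contribution estimation and no
  pH/ionic-strength adjustment.
- Exchange fluxes are not banded during transfer (they encode the imposed
  physiology), and multi-reference or weighted-violation transfer is out of
  scope.
- The MAT-container reader expects COBRA-style structs (`rxns`, `mets`,
  `S`, `lb`, `ub`, optional `subSystems`); thermodynamic annotations must be
  supplied separately through the TSV/physiology tables.
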