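"""Metabolic control analysis around a sampled steady state.

Conserved moieties (e.g. an ATP + ADP pool) make rows of S linearly
dependent; the system is first reduced to independent metabolites via the
link matrix L (S = L N_R, exact over rationals).  For a kinetic instance with
elasticity matrix E at steady state (v, x), the independent-space Jacobian is

    J = N_R diag(v) E diag(x)^-1 L

and local stability requires no eigenvalue with positive real part.  For
stable instances, scaled control coefficients follow from implicit
differentiation of N_R v(x(e)) = 0, with one enzyme per reaction and rates
proportional to enzyme level:

    CCC_full = -diag(x)^-1 L J^-1 N_R diag(v)     (d ln x / d ln e)
    FCC      = I + E CCC_full                     (d ln v / d ln e)

At steady state N_R v = 0, so FCC rows sum to 1 and CCC rows to 0 (the
summation theorems) by construction up to round-off; the test suite verifies
both to 1e-6 and cross-checks the coefficients against finite-difference
perturbation of explicit ODE models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd
import sympy

from .errors import SolverError
from .kinetics import (
    ElasticityMatrix,
    MechanismSpec,
    SaturationSample,
    elasticities_from_saturations,
    sample_saturations,
)
from .model_io import StoichiometricModel
from .sampling import SteadyState

DEFAULT_CONC = 1e-3  # mol/L stand-in for metabolites without concentration data
STABILITY_TOL = 1e-9


@dataclass
class ReducedSystem:
    """S = L N_R with N_R the independent-metabolite rows (exact over rationals)."""

    N_R: np.ndarray  # (n_independent x n_reactions)
    L: np.ndarray  # (n_metabolites x n_independent)
    independent_ids: list[str]
    dependent_ids: list[str]
    metabolite_ids: list[str]  # full ordering matching L rows
    reaction_ids: list[str]


def reduce_system(model: StoichiometricModel) -> ReducedSystem:
    """Select independent metabolite rows and build the link matrix exactly."""
    S_exact = model.stoichiometric_matrix(exact=True)
    m, n = S_exact.shape
    M = sympy.Matrix(
        m, n, lambda i, j: sympy.Rational(S_exact[i, j].numerator, S_exact[i, j].denominator)
    )
    # pivot columns of S^T = independent rows of S
    _, pivots = M.T.rref()
    ind = list(pivots)
    dep = [i for i in range(m) if i not in set(ind)]
    N_R = M[ind, :]
    if dep:
        # each row of S is an exact combination of the independent rows:
        # L^T solves N_R N_R^T L^T_col = N_R S^T_col (N_R has full row rank)
        G = N_R * N_R.T
        L_exact = (G.LUsolve(N_R * M.T)).T
    else:
        L_exact = sympy.eye(m)
    met_ids = model.metabolite_ids
    return ReducedSystem(
        N_R=np.array(N_R.tolist(), dtype=float),
        L=np.array(L_exact.tolist(), dtype=float),
        independent_ids=[met_ids[i] for i in ind],
        dependent_ids=[met_ids[i] for i in dep],
        metabolite_ids=met_ids,
        reaction_ids=model.reaction_ids,
    )


def _state_vectors(
    reduced: ReducedSystem, state: SteadyState, default_conc: float = DEFAULT_CONC
) -> tuple[np.ndarray, np.ndarray]:
    """(v, x_full) aligned to the reduced system's orderings."""
    v = np.array([float(state.nf.get(r, 0.0)) for r in reduced.reaction_ids])
    x = np.array(
        [
            float(np.exp(state.ln_x[m])) if m in state.ln_x.index else default_conc
            for m in reduced.metabolite_ids
        ]
    )
    if np.any(x <= 0):
        raise ValueError("zero or negative concentration: cannot scale elasticities")
    return v, x


def jacobian_reduced(
    reduced: ReducedSystem,
    state: SteadyState,
    E: ElasticityMatrix,
    default_conc: float = DEFAULT_CONC,
) -> np.ndarray:
    """Independent-space Jacobian of dx/dt = N_R v(x)."""
    v, x = _state_vectors(reduced, state, default_conc)
    # reorder E rows/cols if needed
    Em = E.to_frame().loc[reduced.reaction_ids, reduced.metabolite_ids].to_numpy()
    return reduced.N_R @ (v[:, None] * Em) @ (reduced.L / x[:, None])


@dataclass
class StabilityReport:
    eigenvalues: np.ndarray
    max_real_part: float
    stable: bool
    tolerance: float = STABILITY_TOL


def check_stability(J: np.ndarray, tol: float = STABILITY_TOL) -> StabilityReport:
    """Stable iff no eigenvalue has real part above ``tol`` (zero admitted)."""
    if not np.all(np.isfinite(J)):
        raise ValueError("Jacobian contains non-finite entries")
    eig = np.linalg.eigvals(J)
    max_re = float(eig.real.max()) if eig.size else 0.0
    return StabilityReport(
        eigenvalues=eig, max_real_part=max_re, stable=max_re <= tol, tolerance=tol
    )


@dataclass
class ControlMatrices:
    """Scaled flux and concentration control coefficients.

    Enzymes are identified with reactions (one enzyme per reaction, rate
    proportional to enzyme level), so both matrices have reaction columns.
    """

    FCC: pd.DataFrame  # fluxes x enzymes
    CCC: pd.DataFrame  # independent metabolites x enzymes
    CCC_full: pd.DataFrame  # all metabolites x enzymes

    def fcc_to_tsv(self, path) -> None:
        self.FCC.to_csv(path, sep="\t")


def control_coefficients(
    reduced: ReducedSystem,
    state: SteadyState,
    E: ElasticityMatrix,
    default_conc: float = DEFAULT_CONC,
    rcond: float = 1e-12,
) -> ControlMatrices:
    """Scaled FCC/CCC matrices from the linearised steady-state response."""
    v, x = _state_vectors(reduced, state, default_conc)
    Em = E.to_frame().loc[reduced.reaction_ids, reduced.metabolite_ids].to_numpy()
    J = reduced.N_R @ (v[:, None] * Em) @ (reduced.L / x[:, None])
    RHS = reduced.N_R * v[None, :]  # N_R diag(v)
    # rows of J and RHS share the N_R diag(v) prefix, so row equilibration
    # removes the (large) flux-scale disparity exactly from the solve
    scale = np.abs(J).max(axis=1)
    if np.any(scale == 0):
        raise SolverError("singular Jacobian: control coefficients undefined")
    Js = J / scale[:, None]
    if np.linalg.cond(Js) > 1.0 / rcond:
        raise SolverError("singular Jacobian: control coefficients undefined")
    ccc_full = -(reduced.L / x[:, None]) @ np.linalg.solve(Js, RHS / scale[:, None])
    fcc = np.eye(len(v)) + Em @ ccc_full
    rxns = reduced.reaction_ids
    mets = reduced.metabolite_ids
    ind = reduced.independent_ids
    ccc_full_df = pd.DataFrame(ccc_full, index=mets, columns=rxns)
    return ControlMatrices(
        FCC=pd.DataFrame(fcc, index=rxns, columns=rxns),
        CCC=ccc_full_df.loc[ind],
        CCC_full=ccc_full_df,
    )


# ---------------------------------------------------------------------------
# Ensembles
# ---------------------------------------------------------------------------


@dataclass
class EnsembleInstance:
    sample: SaturationSample
    elasticity: ElasticityMatrix
    stability: StabilityReport
    control: ControlMatrices | None  # None for unstable / singular instances


@dataclass
class KineticEnsemble:
    """Population of kinetic-model instances around one steady state."""

    model_name: str
    state: SteadyState
    instances: list[EnsembleInstance] = field(default_factory=list)
    n_sampled: int = 0
    n_stable: int = 0
    n_singular: int = 0

    @property
    def stable_instances(self) -> list[EnsembleInstance]:
        return [i for i in self.instances if i.control is not None]

    @property
    def stable_samples(self) -> list[SaturationSample]:
        return [i.sample for i in self.stable_instances]

    def fcc_stack(self) -> np.ndarray:
        """(n_stable, fluxes, enzymes) array of FCCs of stable instances."""
        return np.stack([i.control.FCC.to_numpy() for i in self.stable_instances])

    def mean_fcc(self) -> pd.DataFrame:
        inst = self.stable_instances
        if not inst:
            raise ValueError("ensemble has no stable instances")
        ref = inst[0].control.FCC
        return pd.DataFrame(
            self.fcc_stack().mean(axis=0), index=ref.index, columns=ref.columns
        )


def make_stability_check(
    specs: list[MechanismSpec],
    state: SteadyState,
    model: StoichiometricModel,
    reduced: ReducedSystem | None = None,
    tol: float = STABILITY_TOL,
):
    """Callable sample -> bool used by stratified resampling."""
    reduced = reduced or reduce_system(model)

    def check(sample: SaturationSample) -> bool:
        E = elasticities_from_saturations(sample, specs, state, model)
        J = jacobian_reduced(reduced, state, E)
        return check_stability(J, tol).stable

    return check


def _instance_from_sample(
    sample: SaturationSample,
    specs: list[MechanismSpec],
    state: SteadyState,
    model: StoichiometricModel,
    reduced: ReducedSystem,
    tol: float,
) -> tuple[EnsembleInstance, bool]:
    """Build one instance; second return flags a singular-Jacobian discard."""
    E = elasticities_from_saturations(sample, specs, state, model)
    J = jacobian_reduced(reduced, state, E)
    report = check_stability(J, tol)
    control = None
    singular = False
    if report.stable:
        try:
            control = control_coefficients(reduced, state, E)
        except SolverError:
            singular = True
    return EnsembleInstance(sample, E, report, control), singular


def build_ensemble(
    model: StoichiometricModel,
    state: SteadyState,
    specs: list[MechanismSpec],
    n_stable: int,
    seed: int,
    reduced: ReducedSystem | None = None,
    max_draws: int | None = None,
    tol: float = STABILITY_TOL,
    keep_unstable: bool = False,
) -> KineticEnsemble:
    """Sample saturation states until ``n_stable`` stable instances are found.

    Each stable instance carries its control matrices; unstable draws are
    counted (and optionally kept without controls).  ``max_draws`` caps the
    total number of draws (default ``50 * n_stable``).
    """
    reduced = reduced or reduce_system(model)
    max_draws = max_draws or 50 * n_stable
    ens = KineticEnsemble(model_name=model.name, state=state)
    batch = max(n_stable, 16)
    draw_seed = 0
    while ens.n_stable < n_stable and ens.n_sampled < max_draws:
        take = min(batch, max_draws - ens.n_sampled)
        samples = sample_saturations(
            specs, model, n=take, seed=int(np.random.default_rng([seed, draw_seed]).integers(2**31))
        )
        draw_seed += 1
        for sample in samples:
            if ens.n_stable >= n_stable:
                break
            inst, singular = _instance_from_sample(
                sample, specs, state, model, reduced, tol
            )
            ens.n_sampled += 1
            if singular:
                ens.n_singular += 1
            if inst.control is not None:
                ens.n_stable += 1
                ens.instances.append(inst)
            elif keep_unstable:
                ens.instances.append(inst)
    return ens


def ensemble_from_samples(
    samples: list[SaturationSample],
    model: StoichiometricModel,
    state: SteadyState,
    specs: list[MechanismSpec],
    reduced: ReducedSystem | None = None,
    tol: float = STABILITY_TOL,
) -> KineticEnsemble:
    """Build an ensemble from pre-drawn samples (e.g. stratified transfers)."""
    reduced = reduced or reduce_system(model)
    ens = KineticEnsemble(model_name=model.name, state=state)
    for sample in samples:
        inst, singular = _instance_from_sample(sample, specs, state, model, reduced, tol)
        ens.n_sampled += 1
        if singular:
            ens.n_singular += 1
        if inst.control is not None:
            ens.n_stable += 1
            ens.instances.append(inst)
    return ens
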