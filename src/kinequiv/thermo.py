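"""Thermodynamics-based flux analysis (TFA) with equilibrium exclusion, and TVA.

TFA couples net flux directions to reaction Gibbs energies through a MILP:
for every reaction with a standard Gibbs energy, binary direction indicators
force flux to run down the thermodynamic gradient,

    NF = v+ - v-,   v+ <= M b+,   v- <= M b-,   b+ + b- <= 1,
    dG_r = dG0_r + RT * sum_j n_ij ln x_j,
    dG_r <= -RT*delta + M_G (1 - b+),
    dG_r >= +RT*delta - M_G (1 - b-),

so a reaction may carry forward flux only while dG_r <= -RT*delta, i.e. while
its displacement Gamma = exp(dG_r / RT) stays at least a factor exp(delta)
away from equilibrium.  The exclusion band delta keeps downstream elasticities
finite (a reaction at Gamma = 1 has equal forward and backward rates and no
net flux).  Water and protons are treated at fixed activity and excluded from
the concentration term.

Thermodynamic variability analysis (TVA) minimises and maximises each selected
variable under the full constraint set; reactions whose net-flux range crosses
zero in both directions are classified bidirectional.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InfeasibleProblemError, SolverError
from .milp import INF, LinearModel, Solution
from .model_io import StoichiometricModel

#: RT in kJ/mol at 298.15 K.
RT_DEFAULT = 2.4789

LN10 = math.log(10.0)

#: metabolite ids treated at fixed activity (no concentration variable)
DEFAULT_EXCLUDED_SPECIES = ("h2o", "h2o_c", "h2o_e", "h2o_p", "h", "h_c", "h_e", "h_p")


def log_mM_to_ln_molar(log_mM: float) -> float:
    """Convert a log10(mM) value (measurement convention) to ln(mol/L)."""
    return log_mM * LN10 + math.log(1e-3)


def ln_molar_to_log_mM(ln_molar: float) -> float:
    return (ln_molar - math.log(1e-3)) / LN10


def compute_gamma(delta_g_r: float | np.ndarray, RT: float = RT_DEFAULT):
    """Thermodynamic displacement Gamma = exp(dG_r / RT); 1 at equilibrium."""
    if RT <= 0:
        raise ValueError("RT must be positive")
    return np.exp(np.asarray(delta_g_r, dtype=float) / RT)[()]


@dataclass
class ThermoParams:
    """Units: energies kJ/mol, concentrations ln(mol/L), fluxes mmol/gDW/h."""

    RT: float = RT_DEFAULT
    gamma_exclusion: float = 0.01  # minimum |ln Gamma| for active reactions
    #: when set, every thermodynamically treated reaction must choose a
    #: direction (b+ + b- = 1) and carry at least this net flux magnitude, so
    #: no reaction in the system sits at zero net flux
    min_net_flux: float | None = None
    conc_bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    default_conc_lb: float = math.log(1e-8)
    default_conc_ub: float = math.log(0.05)
    big_m_flux: float = 1000.0
    big_m_energy: float = 1000.0
    excluded_species: tuple[str, ...] = DEFAULT_EXCLUDED_SPECIES

    def __post_init__(self) -> None:
        if self.RT <= 0 or self.gamma_exclusion <= 0:
            raise ValueError("RT and gamma_exclusion must be positive")
        for m, (lo, hi) in self.conc_bounds.items():
            if lo > hi:
                raise ValueError(f"conc bounds for {m!r}: lb > ub")


@dataclass
class TVAResult:
    ranges: pd.DataFrame  # index: variable name, columns: min, max
    tolerance: float

    @property
    def bidirectional_flags(self) -> pd.Series:
        return (self.ranges["min"] < -self.tolerance) & (
            self.ranges["max"] > self.tolerance
        )

    def to_json(self) -> str:
        return self.ranges.assign(bidirectional=self.bidirectional_flags).to_json(
            orient="index", indent=2
        )


class TFAProblem:
    """MILP over (NF, v+, v-, ln x, dG, b+, b-) for one stoichiometric model."""

    def __init__(self, model: StoichiometricModel, params: ThermoParams):
        self.model = model
        self.params = params
        self.lm = LinearModel()
        self.nf: dict[str, int] = {}
        self.vp: dict[str, int] = {}
        self.vn: dict[str, int] = {}
        self.bp: dict[str, int] = {}
        self.bn: dict[str, int] = {}
        self.lnx: dict[str, int] = {}
        self.dg: dict[str, int] = {}
        self.thermo_reactions: list[str] = []
        self.applied_physiology: list[str] = []
        self._build()

    # -- construction ------------------------------------------------------
    def _build(self) -> None:
        p = self.params
        model = self.model
        for r in model.reactions:
            self.nf[r.id] = self.lm.add_variable(
                f"NF_{r.id}", r.lower_bound, r.upper_bound
            )
        # concentration variables for metabolites of thermo-treated reactions
        thermo_rxns = [r for r in model.reactions if r.delta_g0 is not None]
        conc_mets: list[str] = []
        seen = set()
        for r in thermo_rxns:
            for m in r.stoichiometry:
                if m not in seen and m not in p.excluded_species:
                    seen.add(m)
                    conc_mets.append(m)
        for m in conc_mets:
            lo, hi = p.conc_bounds.get(m, (p.default_conc_lb, p.default_conc_ub))
            self.lnx[m] = self.lm.add_variable(f"LNX_{m}", lo, hi)
        # mass balance S.NF = 0
        rows: dict[str, dict[int, float]] = {m.id: {} for m in model.metabolites}
        for r in model.reactions:
            for m, c in r.stoichiometry.items():
                rows[m][self.nf[r.id]] = float(c)
        for mid, coeffs in rows.items():
            if coeffs:
                self.lm.add_constraint(f"mb_{mid}", coeffs, 0.0, 0.0)
        # thermodynamic coupling
        for r in thermo_rxns:
            rid = r.id
            self.thermo_reactions.append(rid)
            M = max(abs(r.lower_bound), abs(r.upper_bound))
            if not np.isfinite(M) or M == 0:
                M = p.big_m_flux
            self.vp[rid] = self.lm.add_variable(f"VP_{rid}", 0.0, max(r.upper_bound, 0.0))
            self.vn[rid] = self.lm.add_variable(f"VN_{rid}", 0.0, max(-r.lower_bound, 0.0))
            self.bp[rid] = self.lm.add_variable(f"BP_{rid}", 0, 1, integer=True)
            self.bn[rid] = self.lm.add_variable(f"BN_{rid}", 0, 1, integer=True)
            self.dg[rid] = self.lm.add_variable(
                f"DG_{rid}", -p.big_m_energy, p.big_m_energy
            )
            self.lm.add_constraint(
                f"nf_split_{rid}",
                {self.nf[rid]: 1.0, self.vp[rid]: -1.0, self.vn[rid]: 1.0},
                0.0,
                0.0,
            )
            self.lm.add_constraint(
                f"fwd_use_{rid}", {self.vp[rid]: 1.0, self.bp[rid]: -M}, -INF, 0.0
            )
            self.lm.add_constraint(
                f"bwd_use_{rid}", {self.vn[rid]: 1.0, self.bn[rid]: -M}, -INF, 0.0
            )
            if p.min_net_flux is not None:
                self.lm.add_constraint(
                    f"one_dir_{rid}", {self.bp[rid]: 1.0, self.bn[rid]: 1.0}, 1.0, 1.0
                )
                self.lm.add_constraint(
                    f"fwd_min_{rid}",
                    {self.vp[rid]: 1.0, self.bp[rid]: -p.min_net_flux},
                    0.0,
                    INF,
                )
                self.lm.add_constraint(
                    f"bwd_min_{rid}",
                    {self.vn[rid]: 1.0, self.bn[rid]: -p.min_net_flux},
                    0.0,
                    INF,
                )
            else:
                self.lm.add_constraint(
                    f"one_dir_{rid}", {self.bp[rid]: 1.0, self.bn[rid]: 1.0}, -INF, 1.0
                )
            # dG definition
            coeffs = {self.dg[rid]: 1.0}
            for m, c in r.stoichiometry.items():
                if m in self.lnx:
                    coeffs[self.lnx[m]] = coeffs.get(self.lnx[m], 0.0) - p.RT * float(c)
            self.lm.add_constraint(f"dg_def_{rid}", coeffs, r.delta_g0, r.delta_g0)
            # equilibrium exclusion, both directions
            MG = p.big_m_energy
            margin = p.RT * p.gamma_exclusion
            self.lm.add_constraint(
                f"dg_fwd_{rid}",
                {self.dg[rid]: 1.0, self.bp[rid]: MG},
                -INF,
                -margin + MG,
            )
            self.lm.add_constraint(
                f"dg_bwd_{rid}",
                {self.dg[rid]: 1.0, self.bn[rid]: -MG},
                margin - MG,
                INF,
            )

    def apply_physiology(self, physiology: pd.DataFrame | None) -> None:
        """Tighten bounds from a physiology table.

        Expected columns: ``id``, ``variable`` in {"flux", "log_conc"},
        ``lb``, ``ub``; fluxes in mmol/gDW/h, concentrations in log10(mM)
        (converted to ln mol/L internally).  Rows referencing unknown ids
        raise a configuration error.
        """
        if physiology is None:
            return
        for _, row in physiology.iterrows():
            vid, kind = str(row["id"]), str(row["variable"])
            lo, hi = float(row["lb"]), float(row["ub"])
            if kind == "flux":
                if vid not in self.nf:
                    raise ConfigurationError(f"physiology flux id {vid!r} unknown")
                idx = self.nf[vid]
            elif kind == "log_conc":
                if vid not in self.lnx:
                    raise ConfigurationError(
                        f"physiology concentration id {vid!r} has no concentration "
                        f"variable (no thermodynamic data uses it)"
                    )
                idx = self.lnx[vid]
                lo, hi = log_mM_to_ln_molar(lo), log_mM_to_ln_molar(hi)
            else:
                raise ConfigurationError(f"physiology variable kind {kind!r} unknown")
            new_lo = max(self.lm.lb[idx], lo)
            new_hi = min(self.lm.ub[idx], hi)
            if new_lo > new_hi:
                raise InfeasibleProblemError(
                    f"physiology bounds on {vid!r} contradict model bounds"
                )
            self.lm.set_bounds(idx, new_lo, new_hi)
            self.applied_physiology.append(f"{kind}:{vid}=[{lo:g},{hi:g}]")

    # -- solving -----------------------------------------------------------
    def solve_feasibility(self) -> Solution:
        return self.lm.solve(objective=None)

    def fix_directionality(self, sol: Solution | None = None) -> Solution:
        """Fix direction binaries to the pattern of a feasible solution.

        Required before sampling: with binaries fixed the feasible set is a
        convex polytope.  Returns the solution whose pattern was used.
        """
        if sol is None:
            sol = self.solve_feasibility()
        for rid in self.thermo_reactions:
            b_plus = round(float(sol.x[self.bp[rid]]))
            b_minus = round(float(sol.x[self.bn[rid]]))
            self.lm.fix(self.bp[rid], b_plus)
            self.lm.fix(self.bn[rid], b_minus)
            # closed directions become explicit equalities so the sampling
            # polytope is full-dimensional within its affine hull
            if b_plus == 0:
                self.lm.fix(self.vp[rid], 0.0)
            if b_minus == 0:
                self.lm.fix(self.vn[rid], 0.0)
        return sol

    def copy(self) -> "TFAProblem":
        import copy as _copy

        return _copy.deepcopy(self)

    # -- extraction --------------------------------------------------------
    def nf_values(self, x: np.ndarray) -> pd.Series:
        return pd.Series({rid: float(x[i]) for rid, i in self.nf.items()}, name="NF")

    def lnx_values(self, x: np.ndarray) -> pd.Series:
        return pd.Series({m: float(x[i]) for m, i in self.lnx.items()}, name="ln_x")

    def dg_values(self, x: np.ndarray) -> pd.Series:
        return pd.Series({r: float(x[i]) for r, i in self.dg.items()}, name="dG")

    def gamma_values(self, x: np.ndarray) -> pd.Series:
        dg = self.dg_values(x)
        return pd.Series(compute_gamma(dg.values, self.params.RT), index=dg.index, name="gamma")


def build_tfa_problem(
    model: StoichiometricModel,
    params: ThermoParams | None = None,
    physiology: pd.DataFrame | None = None,
) -> TFAProblem:
    """Assemble the TFA MILP for ``model`` and apply physiology bounds."""
    problem = TFAProblem(model, params or ThermoParams())
    problem.apply_physiology(physiology)
    return problem


def run_tva(
    problem: TFAProblem,
    variables: list[str] | None = None,
    tol: float = 1e-9,
) -> TVAResult:
    """Min/max each selected variable (default: every net flux) under TFA.

    Variables are referred to by their LinearModel names (``NF_<rxn>``,
    ``LNX_<met>``, ``DG_<rxn>``); bare reaction ids select net fluxes.
    Solver failures on individual variables are recorded as NaN rather than
    aborting the scan.
    """
    if variables is None:
        names = [f"NF_{rid}" for rid in problem.model.reaction_ids]
    else:
        names = [v if "_" in v and v.split("_")[0] in ("NF", "LNX", "DG") else f"NF_{v}"
                 for v in variables]
    records = {}
    for name in names:
        idx = problem.lm.index(name)
        vals = []
        for sense in ("min", "max"):
            try:
                sol = problem.lm.solve(objective={idx: 1.0}, sense=sense)
                vals.append(sol.fun)
            except (SolverError, InfeasibleProblemError):
                vals.append(np.nan)
        records[name] = vals
    df = pd.DataFrame.from_dict(records, orient="index", columns=["min", "max"])
    return TVAResult(ranges=df, tolerance=tol)


def classify_bidirectional(result: TVAResult, tol: float = 1e-9) -> set[str]:
    """Reaction ids whose TVA net-flux range strictly straddles zero."""
    flags = (result.ranges["min"] < -tol) & (result.ranges["max"] > tol)
    return {
        name.removeprefix("NF_")
        for name, flag in flags.items()
        if flag and name.startswith("NF_")
    }
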