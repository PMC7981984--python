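"""Deterministic nested toy-model families for end-to-end testing.

The generator emulates the structure that systematic GEM reduction produces:
a shared catabolic core (linear backbone with an energy-cofactor couple, a
secretion branch and a lumped biomass reaction), expanded level by level with
two-reaction parallel routes around hub metabolites — exactly the
branch-point-creating expansions that redistribute flux control in real
reduced-model families.  Each level strictly contains the previous one, so
the family passes nesting validation by construction.

Standard Gibbs energies are not drawn per reaction: each metabolite gets a
formation energy decreasing along the backbone and every reaction's dG0 is
the stoichiometric combination of formation energies.  This makes the toy
thermodynamics internally consistent (dG0 sums to zero around any
stoichiometric cycle) and guarantees a feasible, away-from-equilibrium flux
state with nonzero uptake at every level.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd

from .errors import GenerationError, InfeasibleProblemError
from .model_io import (
    Metabolite,
    NestedMapping,
    Reaction,
    StoichiometricModel,
    build_nested_mapping,
)
from .sampling import interior_point, polytope_from_linear_model
from .thermo import ThermoParams, build_tfa_problem, ln_molar_to_log_mM

ATP_DROP = 30.0  # formation-energy gap of the cofactor couple, kJ/mol


@dataclass
class ToyFamilySpec:
    """Conditions for one nested family.

    ``core_size`` counts the reactions of the smallest model (>= 8);
    expansions add ``2 * expansions_per_level + 1`` reactions per level
    (two-reaction parallel paths around hubs plus one alternative lumped
    biomass route).  ``forced_branch_lb`` forces flux through the first
    expansion branch of each level, which is how tests provoke transfer-band
    violations.
    """

    core_size: int = 12
    n_levels: int = 3
    expansions_per_level: int = 2
    include_moiety: bool = True
    seed: int = 0
    uptake: float = 1.0  # mmol/gDW/h
    chain_drop_range: tuple[float, float] = (8.0, 20.0)  # kJ/mol per step
    forced_branch_lb: float = 0.0

    def __post_init__(self) -> None:
        if self.core_size < 8:
            raise GenerationError("core_size must be >= 8")
        if self.n_levels < 1:
            raise GenerationError("n_levels must be >= 1")


def _chain_met(i: int) -> str:
    return f"M{i:02d}"


def generate_nested_toys(
    spec: ToyFamilySpec,
) -> tuple[list[StoichiometricModel], list[NestedMapping], pd.DataFrame]:
    """Build the family, validate nesting and TFA feasibility of every level.

    Returns (models smallest-to-largest, consecutive nested mappings,
    reference physiology table generated from the smallest model).
    """
    rng = np.random.default_rng(spec.seed)
    # core inventory: uptake, chain, SEC, EX_sec, LMPD_bio, EX_bio, EX_prod
    # (+ a standalone cofactor-regeneration reaction when the moiety is on)
    n_chain = spec.core_size - (7 if spec.include_moiety else 6)
    n_mets = n_chain + 1
    formation: dict[str, float] = {}
    level = 0.0
    drops = rng.uniform(*spec.chain_drop_range, size=n_chain)
    for i in range(n_mets):
        formation[_chain_met(i + 1)] = level
        if i < n_chain:
            level -= drops[i]

    metabolites = [Metabolite(id=_chain_met(i + 1)) for i in range(n_mets)]
    hub_sec = _chain_met(max(2, (n_mets + 1) // 2))
    formation["SECM"] = formation[hub_sec] - rng.uniform(*spec.chain_drop_range)
    last = _chain_met(n_mets)
    formation["BIOMASS"] = formation[last] - 20.0
    metabolites += [
        Metabolite(id="SECM"),
        Metabolite(id="BIOMASS", is_biomass_building_block=True),
    ]
    if spec.include_moiety:
        formation["ADP"] = -5.0
        formation["ATP"] = formation["ADP"] + ATP_DROP
        metabolites += [Metabolite(id="ATP"), Metabolite(id="ADP")]

    def dg0(stoich: dict[str, Fraction]) -> float:
        return float(sum(float(c) * formation[m] for m, c in stoich.items()))

    def rxn(rid, stoich, lb, ub, subsystem, kind="enzymatic", thermo=True):
        stoich = {m: Fraction(c) for m, c in stoich.items()}
        return Reaction(
            id=rid,
            stoichiometry=stoich,
            lower_bound=lb,
            upper_bound=ub,
            subsystem=subsystem,
            kind=kind,
            delta_g0=dg0(stoich) if thermo else None,
        )

    big = 50.0 * spec.uptake
    reactions = [
        rxn("EX_upt", {_chain_met(1): 1}, spec.uptake, spec.uptake, "exchange",
            kind="exchange", thermo=False)
    ]
    half = n_chain // 2
    for i in range(n_chain):
        stoich = {_chain_met(i + 1): -1, _chain_met(i + 2): 1}
        if spec.include_moiety and i == 0:
            stoich.update({"ATP": -1, "ADP": 1})  # energy-investment step
        sub = "upper core" if i < half else "lower core"
        reactions.append(rxn(f"R{i + 1:02d}", stoich, -big, big, sub))
    if spec.include_moiety:
        # concentration-gradient-driven cofactor recharge closes the ATP/ADP
        # pool without tying it to the backbone flux
        reactions.append(rxn("REGEN", {"ADP": -1, "ATP": 1}, 0.0, big, "energy"))
    reactions += [
        rxn("SEC", {hub_sec: -1, "SECM": 1}, 0.0, 0.2 * spec.uptake, "secretion"),
        rxn("EX_sec", {"SECM": -1}, 0.0, big, "exchange", kind="exchange", thermo=False),
        rxn(
            "LMPD_bio",
            {last: -1, "BIOMASS": 1, **({"ATP": Fraction(-1, 20), "ADP": Fraction(1, 20)}
                                        if spec.include_moiety else {})},
            0.05 * spec.uptake,
            0.1 * spec.uptake,
            "biomass",
            kind="lumped",
        ),
        rxn("EX_bio", {"BIOMASS": -1}, 0.0, big, "exchange", kind="exchange", thermo=False),
        rxn("EX_prod", {last: -1}, 0.0, big, "exchange", kind="exchange", thermo=False),
    ]
    core = StoichiometricModel(name="T1", metabolites=metabolites, reactions=reactions)
    _validate_level(core)
    models = [core]

    chain_ids = [_chain_met(i + 1) for i in range(n_mets)]
    for lvl in range(2, spec.n_levels + 1):
        prev = models[-1]
        mets = [m for m in prev.copy().metabolites]
        rxns = [r for r in prev.copy().reactions]
        model_tmp = StoichiometricModel(name=f"T{lvl}", metabolites=mets, reactions=rxns)
        used_hubs: set[str] = set()
        for e in range(spec.expansions_per_level):
            hub = _pick_hub(model_tmp, chain_ids, used_hubs)
            used_hubs.add(hub)
            pos = chain_ids.index(hub)
            target = chain_ids[min(pos + 2, n_mets - 1)]
            if target == hub:
                target = chain_ids[-1]
            xid = f"X{lvl}{e + 1}"
            formation[xid] = 0.5 * (formation[hub] + formation[target]) + rng.uniform(
                -1.0, 1.0
            )
            mets.append(Metabolite(id=xid))
            ea = rxn(f"EA{lvl}{e + 1}", {hub: -1, xid: 1}, -big, big, f"expansion L{lvl}")
            eb = rxn(f"EB{lvl}{e + 1}", {xid: -1, target: 1}, -big, big, f"expansion L{lvl}")
            if e == 0 and spec.forced_branch_lb > 0:
                ea.lower_bound = spec.forced_branch_lb
                eb.lower_bound = spec.forced_branch_lb
            rxns += [ea, eb]
            model_tmp = StoichiometricModel(name=f"T{lvl}", metabolites=mets, reactions=rxns)
        # an alternative lumped biomass route through the first expansion met
        alt_src = f"X{lvl}1"
        rxns.append(
            rxn(
                f"LMPD_alt{lvl}",
                {alt_src: -1, "BIOMASS": 1},
                0.0,
                0.05 * spec.uptake,
                "biomass",
                kind="lumped",
            )
        )
        model = StoichiometricModel(name=f"T{lvl}", metabolites=mets, reactions=rxns)
        _validate_level(model)
        models.append(model)

    mappings = [
        build_nested_mapping(models[i], models[i + 1]) for i in range(len(models) - 1)
    ]
    physiology = generate_reference_physiology(models[0], seed=spec.seed)
    return models, mappings, physiology


def _pick_hub(
    model: StoichiometricModel, chain_ids: list[str], used: set[str]
) -> str:
    """Highest-degree backbone metabolite not yet expanded (ties by id)."""
    candidates = [m for m in chain_ids[:-1] if m not in used]
    if not candidates:
        raise GenerationError("no hub candidates left for expansion")
    degree = {m: 0 for m in candidates}
    for r in model.reactions:
        for m in r.stoichiometry:
            if m in degree:
                degree[m] += 1
    return max(candidates, key=lambda m: (degree[m], m))


def _validate_level(model: StoichiometricModel) -> None:
    try:
        problem = build_tfa_problem(model, ThermoParams(min_net_flux=1e-4))
        problem.solve_feasibility()
    except InfeasibleProblemError as exc:
        raise GenerationError(
            f"generated level {model.name!r} has an infeasible TFA problem: {exc}"
        )


def generate_reference_physiology(
    model: StoichiometricModel,
    seed: int,
    tighten: float = 0.2,
    fraction: float = 0.5,
    params: ThermoParams | None = None,
) -> pd.DataFrame:
    """Emulate measured physiology: bounds around a feasible interior point.

    A strictly feasible TFA point is computed, then a seeded subset of fluxes
    and log-concentrations is bounded around it with +/- ``tighten`` relative
    half-width (floors keep near-zero values bounded too).  The interior point
    itself always satisfies the emitted table, so applying it to the model
    preserves feasibility, including at ``tighten = 0``.
    """
    rng = np.random.default_rng(seed)
    if params is None:
        params = ThermoParams(min_net_flux=1e-4)
    problem = build_tfa_problem(model, params)
    problem.fix_directionality()
    x0 = interior_point(polytope_from_linear_model(problem.lm))
    records = []
    flux_ids = [
        rid for rid in model.reaction_ids if model.reaction(rid).kind != "exchange"
    ]
    chosen_flux = sorted(
        rng.choice(flux_ids, size=max(1, int(fraction * len(flux_ids))), replace=False)
    )
    for rid in chosen_flux:
        v = float(x0[problem.nf[rid]])
        w = tighten * max(abs(v), 0.1)
        records.append({"id": rid, "variable": "flux", "lb": v - w, "ub": v + w})
    conc_ids = sorted(problem.lnx)
    chosen_conc = sorted(
        rng.choice(conc_ids, size=max(1, int(fraction * len(conc_ids))), replace=False)
    )
    for mid in chosen_conc:
        p = ln_molar_to_log_mM(float(x0[problem.lnx[mid]]))
        w = tighten * max(abs(p), 0.2)
        records.append({"id": mid, "variable": "log_conc", "lb": p - w, "ub": p + w})
    return pd.DataFrame.from_records(records, columns=["id", "variable", "lb", "ub"])
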