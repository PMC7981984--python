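"""Carrying a reference steady state into a larger nested model.

Topological differences make it impossible for a larger model to reproduce a
smaller model's steady state exactly, so each shared intracellular variable is
given a relaxation band around its reference value and a binary ``z`` that,
when set to 1, deactivates the band:

    NF_i + (F_ub_i - UB_i) * z_i <= F_ub_i
    NF_i + (F_lb_i - LB_i) * z_i >= F_lb_i

(z=0 confines NF_i to [F_lb, F_ub]; z=1 recovers the model bounds [LB, UB]).
Minimising sum(z) yields the maximum number of shared variables that can be
pinned to the reference; bands that survive are imposed permanently before
re-sampling the larger model.  The same machinery applies to the flux profile
(bands on net fluxes) and to the concentration vector (bands on ln x).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InfeasibleProblemError
from .model_io import NestedMapping
from .sampling import (
    SteadyState,
    assemble_steady_state,
    sample_concentration_space,
    sample_flux_space,
    select_representative,
)
from .thermo import TFAProblem

FLUX_FLOOR = 1e-6  # mmol/gDW/h: band half-width floor for near-zero references
LNX_FLOOR = 0.01  # ln-units: band floor for near-zero log concentrations


@dataclass
class Band:
    var_name: str
    reference: float
    f_lb: float
    f_ub: float
    z_index: int


@dataclass
class TransferProblem:
    problem: TFAProblem  # large-model TFA problem with bands added
    mapping: NestedMapping
    relaxation: float
    phase: str  # "flux" | "concentration"
    bands: dict[str, Band] = field(default_factory=dict)  # keyed by shared id


@dataclass
class TransferReport:
    objective: int
    violated_ids: list[str]
    table: pd.DataFrame  # id, reference, achieved, percent_deviation, violated
    phase: str

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _half_width(ref: float, relaxation: float, floor: float) -> float:
    return relaxation * max(abs(ref), floor)


def build_transfer_milp(
    large: TFAProblem,
    mapping: NestedMapping,
    reference: SteadyState,
    relaxation: float = 0.01,
    floor: float = FLUX_FLOOR,
    phase: str = "flux",
) -> TransferProblem:
    """Add relaxation bands with violation binaries to a copy of ``large``.

    ``phase='flux'`` puts bands on the net fluxes of shared intracellular
    reactions; ``phase='concentration'`` on the log-concentrations of shared
    metabolites (floors :data:`FLUX_FLOOR` / :data:`LNX_FLOOR` respectively).
    """
    prob = large.copy()
    tp = TransferProblem(problem=prob, mapping=mapping, relaxation=relaxation, phase=phase)
    if phase == "flux":
        pairs = [
            (sid, lid)
            for sid, lid in mapping.shared_reactions
            if prob.model.reaction(lid).kind != "exchange"
        ]
        var_index, ref_values = prob.nf, reference.nf
        prefix = "NF"
    elif phase == "concentration":
        pairs = [(sm, lm_) for sm, lm_ in mapping.shared_metabolites if lm_ in prob.lnx]
        var_index, ref_values = prob.lnx, reference.ln_x
        if floor == FLUX_FLOOR:
            floor = LNX_FLOOR
        prefix = "LNX"
    else:
        raise ValueError(f"unknown phase {phase!r}")
    for sid, lid in pairs:
        if sid not in ref_values.index:
            continue
        idx = var_index[lid]
        lb, ub = prob.lm.lb[idx], prob.lm.ub[idx]
        if not (np.isfinite(lb) and np.isfinite(ub)):
            raise ConfigurationError(
                f"shared variable {lid!r} has unbounded model bounds; "
                "transfer bands require finite LB/UB"
            )
        ref = float(ref_values[sid])
        hw = _half_width(ref, relaxation, floor)
        f_lb, f_ub = ref - hw, ref + hw
        z = prob.lm.add_variable(f"Z_{prefix}_{lid}", 0, 1, integer=True)
        prob.lm.add_constraint(
            f"band_ub_{prefix}_{lid}", {idx: 1.0, z: f_ub - ub}, -np.inf, f_ub
        )
        prob.lm.add_constraint(
            f"band_lb_{prefix}_{lid}", {idx: 1.0, z: f_lb - lb}, f_lb, np.inf
        )
        tp.bands[lid] = Band(
            var_name=f"{prefix}_{lid}", reference=ref, f_lb=f_lb, f_ub=f_ub, z_index=z
        )
    return tp


def minimize_violations(tp: TransferProblem, floor: float | None = None) -> TransferReport:
    """Solve the band MILP: minimum number of shared variables outside bands."""
    if floor is None:
        floor = FLUX_FLOOR if tp.phase == "flux" else LNX_FLOOR
    objective = {band.z_index: 1.0 for band in tp.bands.values()}
    sol = tp.problem.lm.solve(objective=objective, sense="min")
    violated, records = [], []
    for lid, band in tp.bands.items():
        z_val = round(float(sol.x[band.z_index]))
        achieved = float(sol.x[tp.problem.lm.index(band.var_name)])
        pct = 100.0 * (achieved - band.reference) / max(abs(band.reference), floor)
        if z_val == 1:
            violated.append(lid)
        records.append(
            {
                "id": lid,
                "reference": band.reference,
                "achieved": achieved,
                "percent_deviation": pct,
                "violated": bool(z_val),
            }
        )
    table = pd.DataFrame.from_records(
        records, columns=["id", "reference", "achieved", "percent_deviation", "violated"]
    )
    return TransferReport(
        objective=int(round(sol.fun)),
        violated_ids=violated,
        table=table,
        phase=tp.phase,
    )


def impose_bands(tp: TransferProblem, report: TransferReport) -> TFAProblem:
    """Permanently clamp non-violated shared variables into their bands.

    Returns the large model's TFA problem with band bounds intersected into the
    variable bounds (violated reactions keep their original model bounds) and
    without the transfer binaries, ready for sampling.
    """
    prob = tp.problem
    base = prob.copy()
    keep = [
        (name, coeffs, lo, hi)
        for name, coeffs, lo, hi in base.lm.constraints
        if not name.startswith("band_")
    ]
    base.lm.constraints = keep
    violated = set(report.violated_ids)
    for lid, band in tp.bands.items():
        z_idx = base.lm.index(f"Z_{band.var_name.split('_', 1)[0]}_{lid}")
        if lid in violated:
            base.lm.fix(z_idx, 1.0)
            continue
        base.lm.fix(z_idx, 0.0)
        idx = base.lm.index(band.var_name)
        lo = max(base.lm.lb[idx], band.f_lb)
        hi = min(base.lm.ub[idx], band.f_ub)
        base.lm.set_bounds(idx, lo, hi)
    return base


def transfer_steady_state(
    large: TFAProblem,
    mapping: NestedMapping,
    reference: SteadyState,
    n: int = 10000,
    seed: int = 0,
    relaxation: float = 0.01,
    variance_coverage: float = 0.9,
    warmup: int = 1000,
    thin: int = 10,
) -> tuple[SteadyState, TransferReport, TransferReport]:
    """Full two-phase transfer: flux bands, then concentration bands.

    Orchestrates: minimise flux-band violations -> impose surviving bands ->
    sample the flux space -> PCA representative -> fix that flux profile ->
    minimise concentration-band violations -> impose -> sample ln x -> PCA
    representative.  Returns the large model's representative steady state and
    the two violation reports.
    """
    # flux phase
    tp_flux = build_transfer_milp(large, mapping, reference, relaxation, phase="flux")
    flux_report = minimize_violations(tp_flux)
    banded = impose_bands(tp_flux, flux_report)
    banded.fix_directionality()
    flux_pool = sample_flux_space(banded, n=n, seed=seed, warmup=warmup, thin=thin)
    flux_idx, flux_row = select_representative(flux_pool, variance_coverage)
    nf = flux_row.copy()
    nf.index = [i.removeprefix("NF_") for i in nf.index]

    # concentration phase: fix the flux profile, then band shared ln x
    fixed = banded.copy()
    for rid, idx in fixed.nf.items():
        v = float(nf[rid])
        fixed.lm.fix(idx, v)
        if rid in fixed.vp:
            b_plus = round(fixed.lm.lb[fixed.bp[rid]])
            if b_plus == 1:
                fixed.lm.fix(fixed.vp[rid], v)
            b_minus = round(fixed.lm.lb[fixed.bn[rid]])
            if b_minus == 1:
                fixed.lm.fix(fixed.vn[rid], -v)
    tp_conc = build_transfer_milp(
        fixed, mapping, reference, relaxation, phase="concentration"
    )
    conc_report = minimize_violations(tp_conc)
    banded_conc = impose_bands(tp_conc, conc_report)
    conc_pool = sample_concentration_space(
        banded_conc, fixed_flux=nf, n=n, seed=seed + 1, warmup=warmup, thin=thin
    )
    conc_idx, conc_row = select_representative(conc_pool, variance_coverage)
    state = assemble_steady_state(
        banded_conc,
        nf=nf,
        ln_x=conc_row,
        provenance={
            "method": "transfer",
            "source_model": mapping.small_name,
            "seed": seed,
            "relaxation": relaxation,
            "flux_sample_index": flux_idx,
            "conc_sample_index": conc_idx,
            "flux_violations": flux_report.violated_ids,
            "conc_violations": conc_report.violated_ids,
        },
    )
    return state, flux_report, conc_report


def enumerate_minimum_violation_sets(
    tp: TransferProblem, max_bands: int = 12
) -> list[frozenset[str]]:
    """All minimum-cardinality violation sets, by exhaustive z enumeration.

    Intended for small models (at most ``max_bands`` shared bands): every
    0/1 assignment of the violation binaries is checked for LP feasibility.
    """
    ids = list(tp.bands)
    if len(ids) > max_bands:
        raise ValueError(f"too many bands ({len(ids)}) for exhaustive enumeration")
    best: list[frozenset[str]] = []
    best_count = len(ids) + 1
    for assignment in itertools.product((0, 1), repeat=len(ids)):
        count = sum(assignment)
        if count > best_count:
            continue
        lm = tp.problem.lm.copy()
        for lid, z_val in zip(ids, assignment):
            lm.fix(tp.bands[lid].z_index, float(z_val))
        try:
            lm.solve(objective=None)
        except InfeasibleProblemError:
            continue
        vset = frozenset(lid for lid, z in zip(ids, assignment) if z)
        if count < best_count:
            best_count = count
            best = [vset]
        elif count == best_count:
            best.append(vset)
    return best
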