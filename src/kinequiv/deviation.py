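"""Deviation index and cross-model control-pattern comparison reports.

The flux-control summation theorem guarantees that a flux's control
coefficients over *all* enzymes of a system sum to one.  When a nested model
expansion adds reactions, summing only over the enzymes *shared* with the
smaller model leaves a gap: the deviation index

    DI(v) = | sum_{k in shared} C^v_k  -  1 |

equals exactly the total mean control held by the expansion-added enzymes
over flux v.  DI = 0 means the expansion is control-irrelevant for that flux;
large DI flags fluxes whose control conclusions depend on network size.
Reactions are classed by empirical DI percentile (low 0-25, mid 25-75,
high 75-100) for network-diagram colouring, ranked-controller tables mirror
the top-enzyme comparisons, and subsystem-wise absolute FCC deviations
localise where between-model control differences come from.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mca import KineticEnsemble
from .model_io import NestedMapping, StoichiometricModel

ENZYME_KINDS = ("enzymatic", "lumped")


def enzymatic_reaction_ids(model: StoichiometricModel) -> list[str]:
    """Reactions that count as enzymes (enzymatic and lumped kinds)."""
    return [r.id for r in model.reactions if r.kind in ENZYME_KINDS]


def shared_enzyme_set(
    mapping: NestedMapping, large_model: StoichiometricModel
) -> set[str]:
    """Large-model ids of enzymatic reactions shared with the small model."""
    kinds = {r.id: r.kind for r in large_model.reactions}
    return {
        lid
        for _, lid in mapping.shared_reactions
        if kinds.get(lid) in ENZYME_KINDS
    }


@dataclass
class DIReport:
    di: pd.Series  # per-flux deviation index (aggregated)
    shared_enzymes: list[str]
    aggregation: str  # population_mean_fcc | per_instance_mean
    per_instance: pd.DataFrame | None = None  # instances x fluxes
    percentile_class: pd.Series | None = None

    def to_json(self) -> str:
        payload = {
            "aggregation": self.aggregation,
            "shared_enzymes": self.shared_enzymes,
            "di": self.di.to_dict(),
        }
        if self.percentile_class is not None:
            payload["percentile_class"] = self.percentile_class.to_dict()
        return json.dumps(payload, indent=2)

    def to_tsv(self, path) -> None:
        df = self.di.rename("DI").to_frame()
        if self.percentile_class is not None:
            df["class"] = self.percentile_class
        df.to_csv(path, sep="\t", index_label="reaction")


def deviation_index(
    large_ensemble: KineticEnsemble,
    shared_enzymes: set[str] | list[str],
    aggregation: str = "population_mean_fcc",
    fluxes: list[str] | None = None,
) -> DIReport:
    """DI per flux over a shared enzyme set.

    ``population_mean_fcc`` (default): DI of the ensemble-mean FCC matrix.
    ``per_instance_mean``: mean of the per-instance DIs (the distribution is
    attached either way when instances are available).
    """
    shared = sorted(set(shared_enzymes))
    if not shared:
        raise ValueError("shared enzyme set is empty")
    if aggregation not in ("population_mean_fcc", "per_instance_mean"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    mean_fcc = large_ensemble.mean_fcc()
    missing = [e for e in shared if e not in mean_fcc.columns]
    if missing:
        raise ValueError(f"shared enzymes absent from FCC columns: {missing[:5]}")
    if fluxes is None:
        fluxes = list(mean_fcc.index)
    stack = large_ensemble.fcc_stack()  # (n, fluxes, enzymes)
    cols = [mean_fcc.columns.get_loc(e) for e in shared]
    rows = [mean_fcc.index.get_loc(f) for f in fluxes]
    per_inst = np.abs(stack[:, :, cols].sum(axis=2)[:, rows] - 1.0)
    per_instance = pd.DataFrame(per_inst, columns=fluxes)
    if aggregation == "population_mean_fcc":
        di = (mean_fcc.loc[fluxes, shared].sum(axis=1) - 1.0).abs()
    else:
        di = pd.Series(per_inst.mean(axis=0), index=fluxes)
    return DIReport(
        di=di.rename("DI"),
        shared_enzymes=shared,
        aggregation=aggregation,
        per_instance=per_instance,
    )


def percentile_classes(report: DIReport) -> DIReport:
    """Assign low/mid/high classes at the 25th and 75th DI percentiles.

    Ties take the lower class, so a degenerate all-equal distribution is
    entirely 'low'.
    """
    if len(report.di) < 4:
        raise ValueError("need at least 4 reactions for percentile classes")
    p25, p75 = np.percentile(report.di.to_numpy(), [25, 75])
    def classify(v: float) -> str:
        if v <= p25:
            return "low"
        if v <= p75:
            return "mid"
        return "high"
    report.percentile_class = report.di.map(classify).rename("class")
    return report


@dataclass
class RankingReport:
    target_flux: str
    table: pd.DataFrame  # enzyme, mean, q25, q75 (ranked by |mean| desc)
    top_k: int = 9

    @property
    def top(self) -> list[str]:
        return list(self.table["enzyme"].head(self.top_k))

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def rank_controllers(
    ensemble: KineticEnsemble, target_flux: str, top_k: int = 9
) -> RankingReport:
    """Enzymes ranked by absolute mean control over one flux, with quartiles."""
    mean_fcc = ensemble.mean_fcc()
    if target_flux not in mean_fcc.index:
        raise ValueError(f"target flux {target_flux!r} not in FCC rows")
    stack = ensemble.fcc_stack()
    row = mean_fcc.index.get_loc(target_flux)
    values = stack[:, row, :]  # instances x enzymes
    q25, q75 = np.percentile(values, [25, 75], axis=0)
    table = pd.DataFrame(
        {
            "enzyme": mean_fcc.columns,
            "mean": mean_fcc.loc[target_flux].to_numpy(),
            "q25": q25,
            "q75": q75,
        }
    )
    table["abs_mean"] = table["mean"].abs()
    table = (
        table.sort_values(["abs_mean", "enzyme"], ascending=[False, True])
        .drop(columns="abs_mean")
        .reset_index(drop=True)
    )
    return RankingReport(target_flux=target_flux, table=table, top_k=top_k)


def pairwise_top_controllers(
    ens_small: KineticEnsemble,
    ens_large: KineticEnsemble,
    mapping: NestedMapping,
    target_flux_small: str,
    top_k: int = 9,
) -> pd.DataFrame:
    """Side-by-side means/quartiles over the union of both models' top-k sets.

    ``target_flux_small`` names the flux in small-model ids; the mapping
    translates it (and the enzyme union) into the large model.
    """
    rxn_map = dict(mapping.shared_reactions)
    inv_map = {v: k for k, v in rxn_map.items()}
    target_large = rxn_map[target_flux_small]
    rank_s = rank_controllers(ens_small, target_flux_small, top_k)
    rank_l = rank_controllers(ens_large, target_large, top_k)
    union_small = [e for e in rank_s.top if e in rxn_map]
    union_small += [
        inv_map[e] for e in rank_l.top if e in inv_map and inv_map[e] not in union_small
    ]
    ts = rank_s.table.set_index("enzyme")
    tl = rank_l.table.set_index("enzyme")
    records = []
    for e in union_small:
        el = rxn_map[e]
        records.append(
            {
                "enzyme": e,
                "mean_small": ts.loc[e, "mean"],
                "q25_small": ts.loc[e, "q25"],
                "q75_small": ts.loc[e, "q75"],
                "mean_large": tl.loc[el, "mean"],
                "q25_large": tl.loc[el, "q25"],
                "q75_large": tl.loc[el, "q75"],
            }
        )
    return pd.DataFrame.from_records(records)


@dataclass
class SubsystemDeviationReport:
    deviations: pd.DataFrame  # reactions x subsystems
    reference_flux: pd.Series  # per reaction (small-model steady state)
    warnings: list[str] = field(default_factory=list)

    def to_tsv(self, path) -> None:
        out = self.deviations.copy()
        out.insert(0, "reference_flux", self.reference_flux)
        out.to_csv(path, sep="\t", index_label="reaction")


def subsystem_abs_deviation(
    ens_small: KineticEnsemble,
    ens_large: KineticEnsemble,
    mapping: NestedMapping,
    small_model: StoichiometricModel,
    reactions: list[str] | None = None,
    subsystems: list[str] | None = None,
) -> SubsystemDeviationReport:
    """Sum of |mean FCC| differences per (reaction, enzyme subsystem).

    Entry (i, j) aggregates, over the shared enzymes k belonging to subsystem
    j, the absolute difference between the two models' mean control of enzyme
    k over reaction i.  Reactions and enzymes are expressed in small-model
    ids; subsystem labels come from the small model.
    """
    rxn_map = dict(mapping.shared_reactions)
    mean_s = ens_small.mean_fcc()
    mean_l = ens_large.mean_fcc()
    shared_enz = [
        sid
        for sid in mean_s.columns
        if sid in rxn_map
        and rxn_map[sid] in mean_l.columns
        and small_model.reaction(sid).kind in ENZYME_KINDS
    ]
    subsys_of = {sid: small_model.reaction(sid).subsystem for sid in shared_enz}
    if subsystems is None:
        subsystems = sorted({s for s in subsys_of.values()})
    if reactions is None:
        reactions = [
            sid for sid in mean_s.index if sid in rxn_map and rxn_map[sid] in mean_l.index
        ]
    warnings = []
    data = np.zeros((len(reactions), len(subsystems)))
    for j, sub in enumerate(subsystems):
        enz = [e for e in shared_enz if subsys_of[e] == sub]
        if not enz:
            warnings.append(f"subsystem {sub!r} has no shared enzymes; entries are 0")
            continue
        enz_l = [rxn_map[e] for e in enz]
        for i, rid in enumerate(reactions):
            a = mean_s.loc[rid, enz].to_numpy()
            b = mean_l.loc[rxn_map[rid], enz_l].to_numpy()
            data[i, j] = np.abs(a - b).sum()
    dev = pd.DataFrame(data, index=reactions, columns=subsystems)
    ref_flux = pd.Series(
        {rid: float(ens_small.state.nf.get(rid, np.nan)) for rid in reactions},
        name="reference_flux",
    )
    return SubsystemDeviationReport(
        deviations=dev, reference_flux=ref_flux, warnings=warnings
    )


def export_graphml(
    report: DIReport, model: StoichiometricModel, path
) -> None:
    """Bipartite reaction/metabolite graph with DI values and classes attached."""
    import networkx as nx

    g = nx.Graph()
    for m in model.metabolites:
        g.add_node(f"met:{m.id}", kind="metabolite", label=m.id)
    for r in model.reactions:
        attrs = {"kind": "reaction", "label": r.id, "subsystem": r.subsystem}
        if r.id in report.di.index:
            attrs["di"] = float(report.di[r.id])
            if report.percentile_class is not None:
                attrs["di_class"] = str(report.percentile_class[r.id])
        g.add_node(f"rxn:{r.id}", **attrs)
        for m in r.stoichiometry:
            g.add_edge(f"rxn:{r.id}", f"met:{m}")
    nx.write_graphml(g, path)
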