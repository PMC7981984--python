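"""Stoichiometric models: containers, I/O, nesting and lumped-reaction comparison.

The central container is :class:`StoichiometricModel`, a plain in-memory
representation of a (reduced) metabolic network: metabolites, reactions with
exact rational stoichiometries, flux bounds, subsystem labels and optional
standard Gibbs energies.  Reduced models produced by systematic GEM reduction
come in *nested* families (each larger model contains the smaller one's
reactions plus expansion reactions); :func:`build_nested_mapping` validates and
materialises that relation, and :func:`compare_lumped_sets` reproduces the
Venn-style accounting of lumped biomass reactions across a family.

Supported formats:

* the package's TSV dialect, one row per (reaction, metabolite), which
  round-trips exactly (coefficients serialised as rational strings);
* SBML L3/FBC via cobrapy (stoichiometry, bounds, subsystems; Gibbs energies
  are supplied separately as they have no standard SBML encoding);
* a MAT-container reader for models deposited as MATLAB structs with fields
  ``rxns, mets, S, lb, ub`` (optionally ``subSystems``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    ModelValidationError,
    NestingError,
    ParseError,
    UnknownPresetError,
)

REACTION_KINDS = ("enzymatic", "transport", "lumped", "exchange", "biomass")
LUMP_PREFIX = "LMPD"
BASAL_TRANSPORT_PREFIX = "TransFlux"

TSV_COLUMNS = [
    "rxn_id",
    "metabolite_id",
    "coeff",
    "lb",
    "ub",
    "subsystem",
    "kind",
    "dG0",
    "dG0_err",
]


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    formula: str | None = None
    is_biomass_building_block: bool = False

    def __post_init__(self) -> None:
        if not self.compartment:
            raise ModelValidationError(f"metabolite {self.id!r}: empty compartment")


@dataclass
class Reaction:
    """A reaction with exact rational stoichiometry.

    ``stoichiometry`` maps metabolite id to a signed :class:`~fractions.Fraction`
    (negative = consumed).  ``kind`` follows the reduced-model conventions:
    lumped biomass-synthesis reactions carry the ``LMPD`` id prefix.
    """

    id: str
    stoichiometry: dict[str, Fraction]
    lower_bound: float = -1000.0
    upper_bound: float = 1000.0
    subsystem: str = ""
    kind: str = "enzymatic"
    delta_g0: float | None = None
    delta_g0_err: float | None = None
    constituent_reactions: tuple[str, ...] | None = None  # subnetwork of a lump

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )
        if not self.stoichiometry:
            raise ModelValidationError(f"reaction {self.id!r}: empty stoichiometry")
        if self.kind not in REACTION_KINDS:
            raise ModelValidationError(
                f"reaction {self.id!r}: unknown kind {self.kind!r}"
            )
        self.stoichiometry = {m: Fraction(c) for m, c in self.stoichiometry.items()}
        if self.id.startswith(LUMP_PREFIX):
            self.kind = "lumped"

    @property
    def is_lumped(self) -> bool:
        return self.kind == "lumped"

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    def net_stoichiometry_key(self) -> frozenset:
        """Canonical hashable form used for exact net-stoichiometry equality."""
        return frozenset((m, c) for m, c in self.stoichiometry.items() if c != 0)


@dataclass
class StoichiometricModel:
    name: str
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    _met_index: dict[str, int] = field(default_factory=dict, repr=False)
    _rxn_index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        self._rxn_index = {r.id: i for i, r in enumerate(self.reactions)}
        if len(self._met_index) != len(self.metabolites):
            raise ModelValidationError(f"model {self.name!r}: duplicate metabolite id")
        if len(self._rxn_index) != len(self.reactions):
            raise ModelValidationError(f"model {self.name!r}: duplicate reaction id")
        for r in self.reactions:
            for m in r.stoichiometry:
                if m not in self._met_index:
                    raise ParseError(
                        f"reaction {r.id!r} references undeclared metabolite {m!r}"
                    )

    # -- lookups -----------------------------------------------------------
    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def metabolite(self, mid: str) -> Metabolite:
        return self.metabolites[self._met_index[mid]]

    def reaction(self, rid: str) -> Reaction:
        return self.reactions[self._rxn_index[rid]]

    def has_reaction(self, rid: str) -> bool:
        return rid in self._rxn_index

    @property
    def lumped_reactions(self) -> list[Reaction]:
        return [r for r in self.reactions if r.is_lumped]

    def stoichiometric_matrix(self, exact: bool = False) -> np.ndarray:
        """S (metabolites x reactions); float by default, Fraction if exact."""
        dtype = object if exact else float
        S = np.zeros((len(self.metabolites), len(self.reactions)), dtype=dtype)
        if exact:
            S[:, :] = Fraction(0)
        for j, r in enumerate(self.reactions):
            for m, c in r.stoichiometry.items():
                S[self._met_index[m], j] = c if exact else float(c)
        return S

    @property
    def S(self) -> np.ndarray:
        return self.stoichiometric_matrix()

    def copy(self, name: str | None = None) -> "StoichiometricModel":
        return StoichiometricModel(
            name=name or self.name,
            metabolites=[replace(m) for m in self.metabolites],
            reactions=[
                replace(r, stoichiometry=dict(r.stoichiometry)) for r in self.reactions
            ],
        )

    def transported_metabolites(self) -> set[str]:
        """Metabolites touched by any transport or exchange reaction."""
        out: set[str] = set()
        for r in self.reactions:
            if r.kind in ("transport", "exchange"):
                out.update(r.stoichiometry)
        return out


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def _infer_kind(rid: str, stoich: dict[str, Fraction], kind: str | None) -> str:
    if rid.startswith(LUMP_PREFIX):
        return "lumped"
    if kind:
        return kind
    if len(stoich) == 1:
        return "exchange"
    return "enzymatic"


def load_model(path: str | Path, format: str | None = None) -> StoichiometricModel:
    """Load a model from TSV, SBML or a MAT container (format inferred from suffix)."""
    path = Path(path)
    if format is None:
        format = {".tsv": "tabular", ".xml": "sbml", ".sbml": "sbml", ".mat": "mat-container"}.get(
            path.suffix.lower()
        )
        if format is None:
            raise ParseError(f"cannot infer format of {path}")
    if format == "tabular":
        return _load_tsv(path)
    if format == "sbml":
        return _load_sbml(path)
    if format == "mat-container":
        return _load_mat(path)
    raise ParseError(f"unknown model format {format!r}")


def _load_tsv(path: Path) -> StoichiometricModel:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in TSV_COLUMNS[:5] if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    met_ids: dict[str, None] = {}
    rows_by_rxn: dict[str, list] = {}
    for _, row in df.iterrows():
        rows_by_rxn.setdefault(row["rxn_id"], []).append(row)
        met_ids.setdefault(row["metabolite_id"])
    metabolites = [
        Metabolite(id=mid, name=mid, compartment=_compartment_from_id(mid))
        for mid in met_ids
    ]
    reactions = []
    for rid, rows in rows_by_rxn.items():
        try:
            stoich = {r["metabolite_id"]: Fraction(r["coeff"]) for r in rows}
        except (ValueError, ZeroDivisionError) as exc:
            raise ParseError(f"{path}: reaction {rid!r}: bad coefficient ({exc})")
        first = rows[0]
        dg0 = first.get("dG0", "")
        dg0_err = first.get("dG0_err", "")
        reactions.append(
            Reaction(
                id=rid,
                stoichiometry=stoich,
                lower_bound=float(first["lb"]),
                upper_bound=float(first["ub"]),
                subsystem=first.get("subsystem", ""),
                kind=_infer_kind(rid, stoich, first.get("kind", "") or None),
                delta_g0=float(dg0) if dg0 != "" else None,
                delta_g0_err=float(dg0_err) if dg0_err != "" else None,
            )
        )
    return StoichiometricModel(name=path.stem, metabolites=metabolites, reactions=reactions)


def _compartment_from_id(mid: str) -> str:
    if "_" in mid and len(mid.rsplit("_", 1)[1]) == 1:
        return mid.rsplit("_", 1)[1]
    return "c"


def save_model(model: StoichiometricModel, path: str | Path) -> None:
    """Write the TSV dialect; exact round-trip of S, bounds and annotations."""
    records = []
    for r in model.reactions:
        for m, c in r.stoichiometry.items():
            records.append(
                {
                    "rxn_id": r.id,
                    "metabolite_id": m,
                    "coeff": str(c),
                    "lb": repr(r.lower_bound),
                    "ub": repr(r.upper_bound),
                    "subsystem": r.subsystem,
                    "kind": r.kind,
                    "dG0": "" if r.delta_g0 is None else repr(r.delta_g0),
                    "dG0_err": "" if r.delta_g0_err is None else repr(r.delta_g0_err),
                }
            )
    pd.DataFrame.from_records(records, columns=TSV_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


def _load_sbml(path: Path) -> StoichiometricModel:
    import cobra.io

    cm = cobra.io.read_sbml_model(str(path))
    metabolites = [
        Metabolite(
            id=m.id,
            name=m.name or m.id,
            compartment=m.compartment or "c",
            formula=m.formula or None,
        )
        for m in cm.metabolites
    ]
    reactions = []
    for r in cm.reactions:
        stoich = {m.id: Fraction(c).limit_denominator(10**6) for m, c in r.metabolites.items()}
        kind = None
        if r.boundary:
            kind = "exchange"
        elif len({m.compartment for m in r.metabolites}) > 1:
            kind = "transport"
        reactions.append(
            Reaction(
                id=r.id,
                stoichiometry=stoich,
                lower_bound=r.lower_bound,
                upper_bound=r.upper_bound,
                subsystem=getattr(r, "subsystem", "") or "",
                kind=_infer_kind(r.id, stoich, kind),
            )
        )
    return StoichiometricModel(
        name=cm.id or path.stem, metabolites=metabolites, reactions=reactions
    )


def save_sbml(model: StoichiometricModel, path: str | Path) -> None:
    import cobra
    import cobra.io

    cm = cobra.Model(model.name)
    mets = {
        m.id: cobra.Metabolite(
            m.id, name=m.name, compartment=m.compartment, formula=m.formula
        )
        for m in model.metabolites
    }
    cm.add_metabolites(list(mets.values()))
    rxns = []
    for r in model.reactions:
        cr = cobra.Reaction(r.id, lower_bound=r.lower_bound, upper_bound=r.upper_bound)
        cr.subsystem = r.subsystem
        rxns.append(cr)
    cm.add_reactions(rxns)
    for r in model.reactions:
        cm.reactions.get_by_id(r.id).add_metabolites(
            {mets[m]: float(c) for m, c in r.stoichiometry.items()}
        )
    cobra.io.write_sbml_model(cm, str(path))


def _mat_str(cell) -> str:
    a = np.atleast_1d(np.squeeze(np.asarray(cell)))
    if a.dtype.kind in "US":
        return str(a[()]) if a.shape == () else str(a[0])
    return str(cell)


def _load_mat(path: Path) -> StoichiometricModel:
    """Read a MATLAB-container model (COBRA/TFA style struct)."""
    from scipy.io import loadmat

    data = loadmat(str(path), squeeze_me=True, struct_as_record=False)
    structs = [v for k, v in data.items() if not k.startswith("__")]
    if not structs:
        raise ParseError(f"{path}: no MATLAB struct found")
    st = structs[0]
    try:
        rxns = [str(x) for x in np.atleast_1d(st.rxns)]
        mets = [str(x) for x in np.atleast_1d(st.mets)]
        S = np.asarray(
            st.S.todense() if hasattr(st.S, "todense") else st.S, dtype=float
        )
        lb = np.atleast_1d(np.asarray(st.lb, dtype=float))
        ub = np.atleast_1d(np.asarray(st.ub, dtype=float))
    except AttributeError as exc:
        raise ParseError(f"{path}: missing required field ({exc})")
    subsystems = [""] * len(rxns)
    if hasattr(st, "subSystems"):
        subsystems = [_mat_str(x) for x in np.atleast_1d(st.subSystems)]
    metabolites = [
        Metabolite(id=m, name=m, compartment=_compartment_from_id(m)) for m in mets
    ]
    reactions = []
    for j, rid in enumerate(rxns):
        stoich = {
            mets[i]: Fraction(S[i, j]).limit_denominator(10**6)
            for i in np.nonzero(S[:, j])[0]
        }
        if not stoich:
            continue  # blocked/empty column
        reactions.append(
            Reaction(
                id=rid,
                stoichiometry=stoich,
                lower_bound=float(lb[j]),
                upper_bound=float(ub[j]),
                subsystem=subsystems[j],
                kind=_infer_kind(rid, stoich, None),
            )
        )
    return StoichiometricModel(name=path.stem, metabolites=metabolites, reactions=reactions)


# ---------------------------------------------------------------------------
# Directionality presets
# ---------------------------------------------------------------------------

#: Preset name -> {reaction id: +1 (clamp to forward) | -1 (clamp to backward)}.
#: Signs follow the writing direction of the deposited reduced E. coli models:
#: acetate kinase / phosphotransacetylase toward acetate production, succinyl-CoA
#: synthetase toward succinate, FBA catabolic, Mg2+/Pi transport toward uptake,
#: polyphosphate kinases toward polymerisation.
DIRECTIONALITY_PRESETS: dict[str, dict[str, int]] = {
    "none": {},
    "ecoli_aerobic_glucose": {
        "FBA": +1,
        "ACKr": +1,
        "PTAr": +1,
        "SUCOAS": -1,
        "MG2tpp": +1,
        "PIt2rpp": +1,
        "PPK2r": +1,
        "PPKr": +1,
    },
}


def apply_directionality_preset(
    model: StoichiometricModel, preset: str
) -> tuple[StoichiometricModel, list[str]]:
    """Clamp listed reactions to one flux direction.

    Returns the modified model copy and a list of warning strings for preset
    reactions absent from the model (logged, not fatal).
    """
    if preset not in DIRECTIONALITY_PRESETS:
        raise UnknownPresetError(
            f"unknown preset {preset!r}; registered: "
            f"{sorted(DIRECTIONALITY_PRESETS)}"
        )
    out = model.copy()
    warnings: list[str] = []
    for rid, sign in DIRECTIONALITY_PRESETS[preset].items():
        if not out.has_reaction(rid):
            warnings.append(f"preset reaction {rid!r} absent from model {model.name!r}")
            continue
        r = out.reaction(rid)
        if sign > 0:
            r.lower_bound = max(r.lower_bound, 0.0)
        else:
            r.upper_bound = min(r.upper_bound, 0.0)
    return out, warnings


def add_basal_transporters(
    model: StoichiometricModel,
    excluded: set[str] | None = None,
    basal: float = 1e-6,
    upper: float = 1000.0,
) -> StoichiometricModel:
    """Append passive transporters for untransported intracellular metabolites.

    Each added reaction exports the metabolite with a small mandatory lower
    bound (basal diffusion through the membrane); metabolites in ``excluded``
    (highly polar or very large species) are skipped.
    """
    if basal <= 0:
        raise ValueError("basal flux must be positive")
    excluded = excluded or set()
    out = model.copy()
    transported = out.transported_metabolites()
    new = []
    for m in out.metabolites:
        if m.compartment != "c" or m.id in transported or m.id in excluded:
            continue
        new.append(
            Reaction(
                id=f"{BASAL_TRANSPORT_PREFIX}_{m.id}",
                stoichiometry={m.id: Fraction(-1)},
                lower_bound=basal,
                upper_bound=upper,
                kind="transport",
                subsystem="basal transport",
            )
        )
    if new:
        out = StoichiometricModel(
            name=out.name, metabolites=out.metabolites, reactions=out.reactions + new
        )
    return out


# ---------------------------------------------------------------------------
# Nested mapping
# ---------------------------------------------------------------------------


@dataclass
class NestedMapping:
    """Relation between a small model and a larger model that contains it."""

    small_name: str
    large_name: str
    shared_reactions: list[tuple[str, str]]
    added_reactions: list[str]
    shared_metabolites: list[tuple[str, str]]
    added_metabolites: list[str]
    stoichiometry_mismatches: list[str] = field(default_factory=list)

    @property
    def shared_reaction_ids_large(self) -> list[str]:
        return [b for _, b in self.shared_reactions]

    def to_json(self) -> str:
        return json.dumps(
            {
                "small": self.small_name,
                "large": self.large_name,
                "shared_reactions": self.shared_reactions,
                "added_reactions": self.added_reactions,
                "shared_metabolites": self.shared_metabolites,
                "added_metabolites": self.added_metabolites,
                "stoichiometry_mismatches": self.stoichiometry_mismatches,
            },
            indent=2,
        )


def build_nested_mapping(
    small: StoichiometricModel,
    large: StoichiometricModel,
    alias: dict[str, str] | None = None,
    metabolite_alias: dict[str, str] | None = None,
) -> NestedMapping:
    """Map every small-model reaction onto its large-model counterpart.

    Identity is exact id equality, optionally redirected through ``alias``
    tables.  A small-model reaction with no counterpart makes the pair
    non-nested and raises :class:`NestingError`; an id match whose
    stoichiometry differs is recorded as a mismatch.
    """
    alias = alias or {}
    met_alias = metabolite_alias or {}
    shared_rxns: list[tuple[str, str]] = []
    mismatches: list[str] = []
    for r in small.reactions:
        target = alias.get(r.id, r.id)
        if not large.has_reaction(target):
            raise NestingError(
                f"small-model reaction {r.id!r} has no counterpart in "
                f"{large.name!r}: models are not nested"
            )
        mapped = {met_alias.get(m, m): c for m, c in r.stoichiometry.items()}
        if mapped != large.reaction(target).stoichiometry:
            mismatches.append(r.id)
        shared_rxns.append((r.id, target))
    mapped_large = {b for _, b in shared_rxns}
    added_rxns = [rid for rid in large.reaction_ids if rid not in mapped_large]
    shared_mets = []
    for m in small.metabolites:
        target = met_alias.get(m.id, m.id)
        if target in large._met_index:
            shared_mets.append((m.id, target))
    mapped_mets = {b for _, b in shared_mets}
    added_mets = [mid for mid in large.metabolite_ids if mid not in mapped_mets]
    return NestedMapping(
        small_name=small.name,
        large_name=large.name,
        shared_reactions=shared_rxns,
        added_reactions=added_rxns,
        shared_metabolites=shared_mets,
        added_metabolites=added_mets,
        stoichiometry_mismatches=mismatches,
    )


# ---------------------------------------------------------------------------
# Lumped-reaction comparison
# ---------------------------------------------------------------------------


@dataclass
class LumpComparison:
    common_count: int
    unique_counts: dict[str, int]
    total_distinct: int
    equality_criterion: str
    constituent_union_counts: dict[str, int] | None = None
    constituent_common_count: int | None = None

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)


def compare_lumped_sets(
    models: list[StoichiometricModel],
    criterion: str = "net_stoichiometry",
    metabolite_alias: dict[str, str] | None = None,
) -> LumpComparison:
    """Venn-style counts of lumped reactions shared across a model family.

    ``net_stoichiometry``: two lumps are equal iff their signed coefficient
    maps are identical (exact rational comparison, after optional metabolite
    aliasing; no clearing of common factors).  ``subnetwork``: equality of the
    constituent-reaction sets, which also yields union/intersection counts of
    the constituent pools.
    """
    if criterion not in ("net_stoichiometry", "subnetwork"):
        raise ValueError(f"unknown criterion {criterion!r}")
    met_alias = metabolite_alias or {}
    keysets: dict[str, set] = {}
    for model in models:
        lumps = model.lumped_reactions
        if not lumps:
            raise ModelValidationError(f"model {model.name!r} has no lumped reactions")
        keys = set()
        for r in lumps:
            if criterion == "net_stoichiometry":
                keys.add(
                    frozenset(
                        (met_alias.get(m, m), c)
                        for m, c in r.stoichiometry.items()
                        if c != 0
                    )
                )
            else:
                if r.constituent_reactions is None:
                    raise ModelValidationError(
                        f"criterion 'subnetwork' requires constituent-reaction "
                        f"annotations; lump {r.id!r} of {model.name!r} has none"
                    )
                keys.add(frozenset(r.constituent_reactions))
        keysets[model.name] = keys
    all_keys = set().union(*keysets.values())
    common = set.intersection(*keysets.values())
    unique = {
        name: len(
            keys
            - set().union(*(k for n, k in keysets.items() if n != name))
        )
        if len(keysets) > 1
        else 0
        for name, keys in keysets.items()
    }
    comp = LumpComparison(
        common_count=len(common),
        unique_counts=unique,
        total_distinct=len(all_keys),
        equality_criterion=criterion,
    )
    if criterion == "subnetwork":
        pools = {name: set().union(*keys) if keys else set() for name, keys in keysets.items()}
        comp.constituent_union_counts = {n: len(p) for n, p in pools.items()}
        comp.constituent_common_count = len(set.intersection(*pools.values()))
    return comp


def count_lumped(model: StoichiometricModel) -> int:
    """Number of lumped reactions (LMPD-prefix convention plus explicit flags)."""
    return len(model.lumped_reactions)
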