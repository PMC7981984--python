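"""Kinetic parameterisations as sampled enzyme-saturation states.

Rather than sampling unknown rate constants directly, each enzyme-metabolite
binding interaction is characterised by a degree of saturation sigma in (0,1)
(the fractional occupancy of the binding site at the reference state), drawn
uniformly.  Together with the thermodynamic displacement Gamma of the
reference steady state, a saturation sample determines the full matrix of
scaled elasticities without ever fixing Km or kcat values:

    E_ij = eps_binding_ij - n_ij * Gamma_i / (1 - Gamma_i)

in the net-forward orientation of reaction i (n_ij < 0 for substrates).  The
binding term depends on the kinetic mechanism; the displacement term is
mechanism-independent and diverges as Gamma -> 1, which is why the TFA stage
keeps every active reaction away from equilibrium.

Binding terms by mechanism (substrate s, product p, coefficient n, Hill h):

==================  =====================  ====================
mechanism           substrate              product
==================  =====================  ====================
convenience         ``|n| (1 - sigma)``    ``-|n| sigma``
reversible_hill     ``h (1 - sigma)``      ``-h sigma``
mass_action         ``|n|``                ``0``
==================  =====================  ====================

Competitive inhibitors contribute ``-sigma``, activators ``+(1 - sigma)``.
Each choice reproduces the finite-difference elasticity of an explicit rate
law parameterised to the same (sigma, Gamma); the test suite checks this.

Nested-model equivalency is preserved by *stratified* sampling: saturations of
enzyme-metabolite pairs shared with the smaller model are copied bit-exactly
from its ensemble, and only expansion-specific pairs are redrawn (repeatedly,
until the resulting instance is locally stable or a retry budget is spent).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, NearEquilibriumError
from .model_io import NestedMapping, StoichiometricModel
from .sampling import SteadyState
from .thermo import DEFAULT_EXCLUDED_SPECIES

MECHANISMS = ("convenience", "reversible_hill", "mass_action")
SIGMA_EPS = 1e-6  # open-interval margin for sampled saturations
NEAR_EQUILIBRIUM_TOL = 1e-6  # minimum |1 - Gamma| for active reactions


@dataclass
class MechanismSpec:
    """Kinetic mechanism assignment for one reaction."""

    reaction_id: str
    mechanism: str = "convenience"
    hill_coefficients: dict[str, float] = field(default_factory=dict)
    modifiers: list[tuple[str, str]] = field(default_factory=list)  # (met, type)

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise ConfigurationError(
                f"unknown mechanism {self.mechanism!r} for {self.reaction_id!r}"
            )
        for m, h in self.hill_coefficients.items():
            if h < 1:
                raise ConfigurationError(
                    f"Hill coefficient for ({self.reaction_id}, {m}) must be >= 1"
                )
        for _, kind in self.modifiers:
            if kind not in ("inhibitor", "activator"):
                raise ConfigurationError(f"unknown modifier type {kind!r}")

    def saturation_pairs(self, reaction_stoich: dict) -> list[tuple[str, str]]:
        """Enzyme-metabolite pairs whose binding term needs a sampled sigma."""
        pairs = []
        if self.mechanism in ("convenience", "reversible_hill"):
            pairs = [
                (self.reaction_id, m)
                for m in reaction_stoich
                if m not in DEFAULT_EXCLUDED_SPECIES
            ]
        pairs += [(self.reaction_id, m) for m, _ in self.modifiers]
        return pairs


@dataclass
class SaturationSample:
    """One kinetic-parameter instance: sigma per (reaction, metabolite) pair."""

    sigma: dict[tuple[str, str], float]
    seed: int
    instance: int

    def __post_init__(self) -> None:
        for key, s in self.sigma.items():
            if not (0.0 < s < 1.0):
                raise ConfigurationError(f"sigma for {key} outside (0,1): {s}")


@dataclass
class ElasticityMatrix:
    """Scaled elasticities d ln v / d ln x (reactions x metabolites)."""

    E: np.ndarray
    reaction_ids: list[str]
    metabolite_ids: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.E, index=self.reaction_ids, columns=self.metabolite_ids)


def sigma_from_km(concentration: float, km: float) -> float:
    """Saturation implied by a literature Km at the reference concentration."""
    if concentration <= 0 or km <= 0:
        raise ValueError("concentration and Km must be positive")
    return concentration / (km + concentration)


def assign_mechanisms(
    model: StoichiometricModel,
    overrides: dict[str, MechanismSpec | str] | None = None,
) -> list[MechanismSpec]:
    """Default mechanism allocation: convenience kinetics for enzymatic and
    lumped reactions (unknown mechanisms), mass action for transport,
    diffusion and exchange steps; explicit overrides win."""
    overrides = overrides or {}
    for rid in overrides:
        if not model.has_reaction(rid):
            raise ConfigurationError(f"mechanism override for unknown reaction {rid!r}")
    specs = []
    for r in model.reactions:
        ov = overrides.get(r.id)
        if isinstance(ov, MechanismSpec):
            specs.append(ov)
            continue
        if isinstance(ov, str):
            specs.append(MechanismSpec(reaction_id=r.id, mechanism=ov))
            continue
        default = "mass_action" if r.kind in ("transport", "exchange") else "convenience"
        specs.append(MechanismSpec(reaction_id=r.id, mechanism=default))
    return specs


def load_mechanism_registry(path: str | Path) -> dict[str, MechanismSpec]:
    """Read a YAML mechanism registry: reaction id -> mechanism, hill, modifiers."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    out = {}
    for rid, entry in data.items():
        if isinstance(entry, str):
            out[rid] = MechanismSpec(reaction_id=rid, mechanism=entry)
        else:
            out[rid] = MechanismSpec(
                reaction_id=rid,
                mechanism=entry.get("mechanism", "convenience"),
                hill_coefficients=entry.get("hill", {}) or {},
                modifiers=[tuple(m) for m in entry.get("modifiers", [])],
            )
    return out


def _declared_pairs(
    specs: list[MechanismSpec], model: StoichiometricModel
) -> list[tuple[str, str]]:
    pairs: list[tuple[str, str]] = []
    for spec in specs:
        r = model.reaction(spec.reaction_id)
        pairs.extend(spec.saturation_pairs(r.stoichiometry))
    return pairs


def sample_saturations(
    specs: list[MechanismSpec],
    model: StoichiometricModel,
    n: int,
    seed: int,
    eps: float = SIGMA_EPS,
) -> list[SaturationSample]:
    """Draw ``n`` independent saturation samples, uniform on (eps, 1-eps)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    pairs = _declared_pairs(specs, model)
    rng = np.random.default_rng(seed)
    values = rng.uniform(eps, 1.0 - eps, size=(n, len(pairs)))
    return [
        SaturationSample(sigma=dict(zip(pairs, values[i])), seed=seed, instance=i)
        for i in range(n)
    ]


def elasticities_from_saturations(
    sample: SaturationSample,
    specs: list[MechanismSpec],
    state: SteadyState,
    model: StoichiometricModel,
    active_tol: float = 1e-9,
) -> ElasticityMatrix:
    """Convert a saturation sample plus the reference displacement into E.

    Reactions are oriented along their net flux (so Gamma < 1 in the oriented
    frame); the scaled elasticity is invariant to that orientation.  The
    displacement term is omitted for reactions without thermodynamic data and
    for inactive reactions (|NF| <= active_tol), whose rows carry binding
    terms only.  An active reaction at |1 - Gamma| < 1e-6 is rejected.
    """
    met_ids = model.metabolite_ids
    rxn_ids = model.reaction_ids
    met_pos = {m: i for i, m in enumerate(met_ids)}
    spec_by_rxn = {s.reaction_id: s for s in specs}
    E = np.zeros((len(rxn_ids), len(met_ids)))
    for i, rid in enumerate(rxn_ids):
        spec = spec_by_rxn.get(rid)
        if spec is None:
            raise ConfigurationError(f"no mechanism spec for reaction {rid!r}")
        r = model.reaction(rid)
        nf = float(state.nf.get(rid, 0.0))
        orient = -1.0 if nf < 0 else 1.0
        active = abs(nf) > active_tol
        gamma = None
        if rid in state.gamma.index:
            gamma = float(state.gamma[rid])
            if orient < 0:
                gamma = 1.0 / gamma
            if active and abs(1.0 - gamma) < NEAR_EQUILIBRIUM_TOL:
                raise NearEquilibriumError(
                    f"reaction {rid!r} is at thermodynamic equilibrium "
                    f"(Gamma = {gamma:.8f}); elasticities diverge"
                )
        for m, coeff in r.stoichiometry.items():
            if m in DEFAULT_EXCLUDED_SPECIES:
                continue
            n_or = orient * float(coeff)  # oriented coefficient
            is_substrate = n_or < 0
            sigma = sample.sigma.get((rid, m))
            if sigma is None and spec.mechanism != "mass_action":
                raise ConfigurationError(
                    f"saturation sample lacks sigma for pair ({rid!r}, {m!r})"
                )
            if spec.mechanism == "convenience":
                binding = (
                    abs(n_or) * (1.0 - sigma) if is_substrate else -abs(n_or) * sigma
                )
            elif spec.mechanism == "reversible_hill":
                h = spec.hill_coefficients.get(m, 1.0)
                binding = h * (1.0 - sigma) if is_substrate else -h * sigma
            else:  # mass_action
                binding = abs(n_or) if is_substrate else 0.0
            thermo = 0.0
            if gamma is not None and active:
                thermo = -n_or * gamma / (1.0 - gamma)
            E[i, met_pos[m]] = binding + thermo
        for m, kind in spec.modifiers:
            sigma = sample.sigma[(rid, m)]
            E[i, met_pos[m]] += -sigma if kind == "inhibitor" else (1.0 - sigma)
    return ElasticityMatrix(E=E, reaction_ids=rxn_ids, metabolite_ids=met_ids)


@dataclass
class StratifiedResult:
    """Outcome of stratified resampling into a larger model."""

    samples: list[SaturationSample]  # retained (stable) large-model instances
    retained_indices: list[int]  # source instance indices that survived
    n_input: int
    n_unstable: int

    @property
    def n_retained(self) -> int:
        return len(self.samples)

    @property
    def retained_fraction(self) -> float:
        return self.n_retained / self.n_input if self.n_input else float("nan")


def stratified_resample(
    small_ensemble: list[SaturationSample],
    mapping: NestedMapping,
    specs_large: list[MechanismSpec],
    large_model: StoichiometricModel,
    seed: int,
    stability_check: Callable[[SaturationSample], bool] | None = None,
    max_tries: int = 10,
    eps: float = SIGMA_EPS,
) -> StratifiedResult:
    """Carry saturation states into a larger nested model.

    For every small-model instance, the sigma values of shared
    enzyme-metabolite pairs are copied bit-exactly (reaction and metabolite
    ids translated through the mapping); expansion-specific pairs are redrawn
    uniformly until ``stability_check`` accepts the instance or ``max_tries``
    draws are exhausted, in which case the instance is dropped and counted as
    unstable in the larger model.
    """
    rxn_map = dict(mapping.shared_reactions)
    met_map = dict(mapping.shared_metabolites)
    all_pairs = _declared_pairs(specs_large, large_model)
    samples: list[SaturationSample] = []
    retained: list[int] = []
    n_unstable = 0
    for src_pos, src in enumerate(small_ensemble):
        # translate the source sigma keys into large-model ids
        translated = {}
        for (srid, smid), value in src.sigma.items():
            lrid = rxn_map.get(srid)
            lmid = met_map.get(smid, smid)
            if lrid is not None:
                translated[(lrid, lmid)] = value
        new_pairs = [p for p in all_pairs if p not in translated]
        rng = np.random.default_rng([seed, src.instance])
        accepted = None
        for _ in range(max(1, max_tries)):
            sigma = {p: translated[p] for p in all_pairs if p in translated}
            sigma.update(zip(new_pairs, rng.uniform(eps, 1.0 - eps, len(new_pairs))))
            candidate = SaturationSample(sigma=sigma, seed=seed, instance=src.instance)
            if stability_check is None or stability_check(candidate):
                accepted = candidate
                break
            if not new_pairs:
                break  # nothing to resample; instance is simply unstable here
        if accepted is None:
            n_unstable += 1
        else:
            samples.append(accepted)
            retained.append(src_pos)
    return StratifiedResult(
        samples=samples,
        retained_indices=retained,
        n_input=len(small_ensemble),
        n_unstable=n_unstable,
    )
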