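"""Saturation sampling, elasticity formulas and stratified resampling.

The elasticity oracle builds an explicit reversible rate law parameterised to
match a given (sigma, Gamma) pair — binding factors rho^n/(1+rho)^n with
rho = x/K chosen so the site occupancy at the reference equals sigma, times
the displacement factor (1 - Gamma(x)) — and differentiates it numerically.
Every analytic elasticity entry must agree with the central difference.
"""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from kinequiv.errors import ConfigurationError, NearEquilibriumError
from kinequiv.kinetics import (
    MechanismSpec,
    SaturationSample,
    assign_mechanisms,
    elasticities_from_saturations,
    sample_saturations,
    sigma_from_km,
    stratified_resample,
)
from kinequiv.model_io import build_nested_mapping
from kinequiv.sampling import SteadyState
from kinequiv.thermo import RT_DEFAULT

from conftest import make_model, rxn

RT = RT_DEFAULT


def one_reaction_state(stoich, gamma, nf=1.0, x_ref=None, rid="R1"):
    """Model + steady state for one reaction with prescribed displacement."""
    mets = sorted(stoich)
    model = make_model("t", [rxn(rid, stoich, dg0=0.0)], mets)
    x_ref = x_ref or {m: 1e-3 for m in mets}
    ln_x = pd.Series({m: math.log(x_ref[m]) for m in mets})
    # choose dG0 so that Gamma at the reference equals the requested value
    dg0 = RT * math.log(gamma) - RT * sum(
        float(c) * ln_x[m] for m, c in stoich.items()
    )
    model.reaction(rid).delta_g0 = dg0
    state = SteadyState(
        nf=pd.Series({rid: nf}),
        ln_x=ln_x,
        gamma=pd.Series({rid: gamma}),
        model_name="t",
    )
    return model, state


def oracle_elasticities(spec, reaction, state, sigma, h_delta=1e-5):
    """Central-difference elasticities of the explicit rate law."""
    stoich = {m: float(c) for m, c in reaction.stoichiometry.items()}
    participants = list(stoich) + [m for m, _ in spec.modifiers]
    x_ref = {m: math.exp(state.ln_x[m]) for m in participants}
    hills = {m: spec.hill_coefficients.get(m, 1.0) for m in stoich}

    def binding(m, x):
        n = abs(stoich[m])
        if spec.mechanism == "mass_action":
            return x ** n if stoich[m] < 0 else 1.0
        h = hills[m]
        s = sigma[(reaction.id, m)]
        rho_ref_h = s / (1.0 - s)  # rho^h at reference
        rho_h = rho_ref_h * (x / x_ref[m]) ** h
        if stoich[m] < 0:  # substrate: rho^(h n)/(1+rho^h)^n with n = |coeff|
            return rho_h ** n / (1.0 + rho_h) ** n if spec.mechanism == "convenience" \
                else rho_h / (1.0 + rho_h)
        return (1.0 + rho_h) ** -n if spec.mechanism == "convenience" \
            else 1.0 / (1.0 + rho_h)

    def modifier_factor(m, kind, x):
        s = sigma[(reaction.id, m)]
        rho = s / (1.0 - s) * (x / x_ref[m])
        return 1.0 / (1.0 + rho) if kind == "inhibitor" else rho / (1.0 + rho)

    def rate(x):
        dg = reaction.delta_g0 + RT * sum(
            stoich[m] * math.log(x[m]) for m in stoich
        )
        gamma = math.exp(dg / RT)
        v = 1.0 - gamma
        for m in stoich:
            v *= binding(m, x[m])
        for m, kind in spec.modifiers:
            v *= modifier_factor(m, kind, x[m])
        return v

    out = {}
    for m in participants:
        up, dn = dict(x_ref), dict(x_ref)
        up[m] = x_ref[m] * math.exp(h_delta)
        dn[m] = x_ref[m] * math.exp(-h_delta)
        out[m] = (math.log(abs(rate(up))) - math.log(abs(rate(dn)))) / (2 * h_delta)
    return out


@pytest.mark.parametrize(
    "gamma, coeff, sigma, expected",
    [
        (1e-12, -1, 1e-9, 1.0),  # irreversible limit at zero occupancy
        (0.5, -1, 0.4, 1.6),  # substrate: (1 - 0.4) + 0.5/0.5
        (0.5, +1, 0.3, -1.3),  # product: -0.3 - 0.5/0.5
    ],
)
def test_convenience_elasticity_worked_examples(gamma, coeff, sigma, expected):
    stoich = {"A": -1, "B": 1}
    met = "A" if coeff < 0 else "B"
    model, state = one_reaction_state(stoich, gamma)
    specs = [MechanismSpec(reaction_id="R1")]
    sample = SaturationSample(
        sigma={("R1", "A"): sigma if met == "A" else 0.5,
               ("R1", "B"): sigma if met == "B" else 0.5},
        seed=0,
        instance=0,
    )
    E = elasticities_from_saturations(sample, specs, state, model)
    val = E.to_frame().loc["R1", met]
    assert val == pytest.approx(expected, rel=1e-6)


@pytest.mark.parametrize(
    "mechanism, stoich, hill, modifiers",
    [
        ("convenience", {"A": -1, "B": 1}, {}, []),
        ("convenience", {"A": -1, "B": -2, "C": 1}, {}, []),
        ("mass_action", {"A": -1, "B": 1}, {}, []),
        ("reversible_hill", {"A": -1, "B": 1}, {"A": 2.0, "B": 2.0}, []),
        ("convenience", {"A": -1, "B": 1}, {}, [("I", "inhibitor"), ("M", "activator")]),
    ],
)
def test_elasticities_match_finite_difference_oracle(mechanism, stoich, hill, modifiers):
    mets = sorted(set(stoich) | {m for m, _ in modifiers})
    model = make_model("t", [rxn("R1", stoich, dg0=0.0)], mets)
    x_ref = {m: 1e-3 * (i + 1) for i, m in enumerate(mets)}
    ln_x = pd.Series({m: math.log(x_ref[m]) for m in mets})
    gamma = 0.3
    dg0 = RT * math.log(gamma) - RT * sum(float(c) * ln_x[m] for m, c in stoich.items())
    model.reaction("R1").delta_g0 = dg0
    state = SteadyState(
        nf=pd.Series({"R1": 1.0}), ln_x=ln_x, gamma=pd.Series({"R1": gamma})
    )
    spec = MechanismSpec(
        reaction_id="R1", mechanism=mechanism, hill_coefficients=hill,
        modifiers=modifiers,
    )
    pairs = spec.saturation_pairs(model.reaction("R1").stoichiometry)
    rng = np.random.default_rng(5)
    sample = SaturationSample(
        sigma={p: rng.uniform(0.2, 0.8) for p in pairs}, seed=5, instance=0
    )
    E = elasticities_from_saturations(sample, [spec], state, model)
    frame = E.to_frame()
    oracle = oracle_elasticities(spec, model.reaction("R1"), state, sample.sigma)
    for m, expected in oracle.items():
        assert frame.loc["R1", m] == pytest.approx(expected, rel=1e-6, abs=1e-8), m


def test_orientation_invariance_of_elasticities():
    """A reaction running backward gives the same scaled elasticities as the
    explicitly reversed reaction running forward."""
    stoich = {"A": -1, "B": 1}
    model_f, state_f = one_reaction_state(
        {"B": -1, "A": 1}, gamma=0.25, nf=1.0
    )  # reversed reaction, forward flux
    model_b, state_b = one_reaction_state(stoich, gamma=4.0, nf=-1.0)
    sigma = {("R1", "A"): 0.35, ("R1", "B"): 0.6}
    sample = SaturationSample(sigma=sigma, seed=0, instance=0)
    E_f = elasticities_from_saturations(
        sample, [MechanismSpec(reaction_id="R1")], state_f, model_f
    ).to_frame()
    E_b = elasticities_from_saturations(
        sample, [MechanismSpec(reaction_id="R1")], state_b, model_b
    ).to_frame()
    assert E_f.loc["R1", "A"] == pytest.approx(E_b.loc["R1", "A"], rel=1e-12)
    assert E_f.loc["R1", "B"] == pytest.approx(E_b.loc["R1", "B"], rel=1e-12)


def test_substrate_elasticity_diverges_towards_equilibrium():
    values = []
    for gamma in [0.5, 0.9, 0.99, 0.999]:
        model, state = one_reaction_state({"A": -1, "B": 1}, gamma)
        sample = SaturationSample(
            sigma={("R1", "A"): 0.5, ("R1", "B"): 0.5}, seed=0, instance=0
        )
        E = elasticities_from_saturations(
            sample, [MechanismSpec(reaction_id="R1")], state, model
        )
        values.append(E.to_frame().loc["R1", "A"])
    assert all(b > a for a, b in zip(values, values[1:]))


def test_near_equilibrium_is_rejected_by_name():
    model, state = one_reaction_state({"A": -1, "B": 1}, gamma=1.0 + 1e-9)
    sample = SaturationSample(
        sigma={("R1", "A"): 0.5, ("R1", "B"): 0.5}, seed=0, instance=0
    )
    with pytest.raises(NearEquilibriumError, match="R1"):
        elasticities_from_saturations(
            sample, [MechanismSpec(reaction_id="R1")], state, model
        )


def test_sparsity_pattern_matches_mechanisms(family):
    models, _, _ = family
    model = models[0]
    specs = assign_mechanisms(model)
    sample = sample_saturations(specs, model, n=1, seed=0)[0]
    nf = pd.Series({rid: 1.0 for rid in model.reaction_ids})
    gam = pd.Series({r.id: 0.5 for r in model.reactions if r.delta_g0 is not None})
    ln_x = pd.Series({m: math.log(1e-3) for m in model.metabolite_ids})
    state = SteadyState(nf=nf, ln_x=ln_x, gamma=gam)
    E = elasticities_from_saturations(sample, specs, state, model).to_frame()
    for r in model.reactions:
        participants = set(r.stoichiometry)
        for m in model.metabolite_ids:
            if m not in participants:
                assert E.loc[r.id, m] == 0.0


class TestAssignMechanisms:
    def test_defaults_by_kind(self, family):
        models, _, _ = family
        specs = {s.reaction_id: s for s in assign_mechanisms(models[0])}
        assert specs["R01"].mechanism == "convenience"
        assert specs["LMPD_bio"].mechanism == "convenience"
        assert specs["EX_upt"].mechanism == "mass_action"

    def test_override_wins(self, family):
        models, _, _ = family
        specs = {
            s.reaction_id: s
            for s in assign_mechanisms(
                models[0],
                {"R01": MechanismSpec(
                    reaction_id="R01", mechanism="reversible_hill",
                    hill_coefficients={"M01": 2.0},
                )},
            )
        }
        assert specs["R01"].mechanism == "reversible_hill"
        assert specs["R01"].hill_coefficients["M01"] == 2.0

    def test_unknown_reaction_override_rejected(self, family):
        models, _, _ = family
        with pytest.raises(ConfigurationError, match="GHOST"):
            assign_mechanisms(models[0], {"GHOST": "mass_action"})

    def test_hill_coefficient_below_one_rejected(self):
        with pytest.raises(ConfigurationError):
            MechanismSpec(reaction_id="R", hill_coefficients={"A": 0.5})


class TestSampleSaturations:
    def test_reproducible_and_in_open_interval(self, family):
        models, _, _ = family
        specs = assign_mechanisms(models[0])
        a = sample_saturations(specs, models[0], n=5, seed=11)
        b = sample_saturations(specs, models[0], n=5, seed=11)
        for sa, sb in zip(a, b):
            assert sa.sigma == sb.sigma
        for s in a:
            assert all(0.0 < v < 1.0 for v in s.sigma.values())

    def test_empirical_mean_is_one_half(self, family):
        models, _, _ = family
        specs = assign_mechanisms(models[0])
        samples = sample_saturations(specs, models[0], n=10000, seed=3)
        key = next(iter(samples[0].sigma))
        values = np.array([s.sigma[key] for s in samples])
        se = math.sqrt(1.0 / 12.0) / math.sqrt(len(values))
        assert abs(values.mean() - 0.5) < 3 * se


def test_sigma_from_km_matches_occupancy():
    assert sigma_from_km(1.0, 1.0) == 0.5
    assert sigma_from_km(3.0, 1.0) == 0.75


class TestStratifiedResample:
    def test_identity_mapping_copies_bit_exactly(self, family):
        models, _, _ = family
        model = models[0]
        specs = assign_mechanisms(model)
        source = sample_saturations(specs, model, n=10, seed=2)
        mapping = build_nested_mapping(model, model)
        result = stratified_resample(
            source, mapping, specs, model, seed=9, stability_check=None
        )
        assert result.n_retained == 10
        assert result.retained_fraction == 1.0
        for src, out in zip(source, result.samples):
            assert out.sigma == src.sigma

    def test_shared_pairs_equal_source_exactly(self, family):
        models, mappings, _ = family
        small, large, mapping = models[0], models[1], mappings[0]
        specs_s = assign_mechanisms(small)
        specs_l = assign_mechanisms(large)
        source = sample_saturations(specs_s, small, n=8, seed=4)
        result = stratified_resample(
            source, mapping, specs_l, large, seed=5, stability_check=None
        )
        rxn_map = dict(mapping.shared_reactions)
        for src, out in zip(source, result.samples):
            for (rid, mid), value in src.sigma.items():
                assert out.sigma[(rxn_map[rid], mid)] == value  # bit-exact

    def test_unstable_instances_are_counted_not_raised(self, family):
        models, mappings, _ = family
        specs_l = assign_mechanisms(models[1])
        source = sample_saturations(assign_mechanisms(models[0]), models[0], 6, seed=1)
        result = stratified_resample(
            source, mappings[0], specs_l, models[1], seed=2,
            stability_check=lambda s: False, max_tries=3,
        )
        assert result.n_retained == 0
        assert result.n_unstable == 6
        assert result.n_input == 6

    def test_deterministic_given_seed(self, family):
        models, mappings, _ = family
        specs_l = assign_mechanisms(models[1])
        source = sample_saturations(assign_mechanisms(models[0]), models[0], 4, seed=1)
        r1 = stratified_resample(source, mappings[0], specs_l, models[1], seed=7)
        r2 = stratified_resample(source, mappings[0], specs_l, models[1], seed=7)
        for a, b in zip(r1.samples, r2.samples):
            assert a.sigma == b.sigma
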