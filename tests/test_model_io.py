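"""Model containers, TSV/SBML/MAT I/O, nesting and lump comparison."""

from fractions import Fraction

import numpy as np
import pytest

from kinequiv.errors import (
    ModelValidationError,
    NestingError,
    ParseError,
    UnknownPresetError,
)
from kinequiv.model_io import (
    Metabolite,
    Reaction,
    StoichiometricModel,
    add_basal_transporters,
    apply_directionality_preset,
    build_nested_mapping,
    compare_lumped_sets,
    load_model,
    save_model,
)

from conftest import make_model, rxn


TOY_TSV = """rxn_id\tmetabolite_id\tcoeff\tlb\tub\tsubsystem\tkind\tdG0\tdG0_err
R1\tA\t-1\t-5\t5\tcore\tenzymatic\t-12.5\t1.0
R1\tB\t1\t-5\t5\tcore\tenzymatic\t-12.5\t1.0
R2\tB\t-1\t0\t8\tcore\tenzymatic\t\t
R2\tC\t1\t0\t8\tcore\tenzymatic\t\t
LMPD_x\tC\t-1\t0\t1\tbiomass\t\t\t
"""


def test_tsv_toy_loads_with_expected_matrix(tmp_path):
    path = tmp_path / "toy.tsv"
    path.write_text(TOY_TSV)
    model = load_model(path, format="tabular")
    assert model.S.shape == (3, 3)
    r1 = model.reaction("R1")
    assert (r1.lower_bound, r1.upper_bound) == (-5.0, 5.0)
    assert r1.delta_g0 == -12.5
    assert model.reaction("R2").delta_g0 is None
    # lumped reactions are recognised from the id prefix alone
    assert model.reaction("LMPD_x").kind == "lumped"


def test_tsv_round_trip_is_exact(family, tmp_path):
    models, _, _ = family
    original = models[1]
    path = tmp_path / "round.tsv"
    save_model(original, path)
    reloaded = load_model(path)
    assert reloaded.reaction_ids == original.reaction_ids
    assert set(reloaded.metabolite_ids) == set(original.metabolite_ids)
    rows = [reloaded.metabolite_ids.index(m) for m in original.metabolite_ids]
    assert np.array_equal(reloaded.S[rows], original.S)
    # a second cycle from the loaded model is bit-identical (fixed point)
    save_model(reloaded, tmp_path / "round2.tsv")
    again = load_model(tmp_path / "round2.tsv")
    assert again.metabolite_ids == reloaded.metabolite_ids
    assert np.array_equal(again.S, reloaded.S)
    for rid in original.reaction_ids:
        a, b = original.reaction(rid), reloaded.reaction(rid)
        assert a.stoichiometry == b.stoichiometry  # exact rational equality
        assert (a.lower_bound, a.upper_bound) == (b.lower_bound, b.upper_bound)
        assert a.kind == b.kind and a.subsystem == b.subsystem
        assert a.delta_g0 == b.delta_g0


def test_undeclared_metabolite_is_reported(tmp_path):
    bad = TOY_TSV + "R3\tGHOST\t-1\t0\t1\t\t\t\t\n"
    path = tmp_path / "bad.tsv"
    path.write_text(bad)
    # the TSV declares metabolites implicitly, so corrupt a model directly
    with pytest.raises(ParseError, match="R9"):
        make_model("m", [rxn("R9", {"missing": -1})], ["A"])
    load_model(path)  # GHOST becomes a declared metabolite in the dialect


def test_duplicate_reaction_id_rejected():
    with pytest.raises(ModelValidationError, match="duplicate"):
        make_model("m", [rxn("R1", {"A": -1}), rxn("R1", {"A": 1})], ["A"])


def test_bounds_must_be_ordered():
    with pytest.raises(ModelValidationError):
        rxn("R1", {"A": -1}, lb=2.0, ub=1.0)


def test_sbml_round_trip(family, tmp_path):
    from kinequiv.model_io import save_sbml

    models, _, _ = family
    original = models[0]
    path = tmp_path / "m.xml"
    save_sbml(original, path)
    reloaded = load_model(path, format="sbml")
    assert set(reloaded.reaction_ids) == set(original.reaction_ids)
    for rid in original.reaction_ids:
        a, b = original.reaction(rid), reloaded.reaction(rid)
        assert a.stoichiometry == b.stoichiometry
        assert a.lower_bound == pytest.approx(b.lower_bound)
    assert reloaded.reaction("LMPD_bio").kind == "lumped"


def test_mat_container_reader(tmp_path):
    from scipy.io import savemat

    S = np.array([[-1.0, 0.0], [1.0, -1.0]])
    savemat(
        tmp_path / "m.mat",
        {
            "model": {
                "rxns": np.array(["R1", "LMPD_y"], dtype=object),
                "mets": np.array(["a_c", "b_c"], dtype=object),
                "S": S,
                "lb": np.array([0.0, 0.0]),
                "ub": np.array([10.0, 5.0]),
            }
        },
    )
    model = load_model(tmp_path / "m.mat")
    assert np.array_equal(model.S, S)
    assert model.reaction("LMPD_y").kind == "lumped"
    assert model.metabolite("a_c").compartment == "c"


class TestDirectionalityPreset:
    def test_clamps_listed_reaction_forward(self):
        model = make_model("m", [rxn("ACKr", {"A": -1, "B": 1}, lb=-10, ub=10)], ["A", "B"])
        out, warnings = apply_directionality_preset(model, "ecoli_aerobic_glucose")
        clamped = out.reaction("ACKr")
        assert (clamped.lower_bound, clamped.upper_bound) == (0.0, 10.0)
        # original untouched
        assert model.reaction("ACKr").lower_bound == -10.0

    def test_empty_preset_is_identity(self):
        model = make_model("m", [rxn("R1", {"A": -1}, lb=-3, ub=3)], ["A"])
        out, warnings = apply_directionality_preset(model, "none")
        assert out.reaction("R1").lower_bound == -3.0
        assert warnings == []

    def test_missing_reaction_warns_not_fails(self):
        model = make_model("m", [rxn("R1", {"A": -1})], ["A"])
        out, warnings = apply_directionality_preset(model, "ecoli_aerobic_glucose")
        assert any("ACKr" in w for w in warnings)
        assert out.reaction("R1").lower_bound == model.reaction("R1").lower_bound

    def test_unknown_preset_lists_registered(self):
        model = make_model("m", [rxn("R1", {"A": -1})], ["A"])
        with pytest.raises(UnknownPresetError, match="ecoli_aerobic_glucose"):
            apply_directionality_preset(model, "nope")


class TestBasalTransporters:
    def _model(self):
        return make_model(
            "m",
            [
                rxn("R1", {"a_c": -1, "b_c": 1}),
                rxn("T_a", {"a_c": -1}, kind="transport"),
            ],
            ["a_c", "b_c", "big_c"],
        )

    def test_untransported_metabolite_gets_basal_export(self):
        out = add_basal_transporters(self._model(), excluded=set())
        added = out.reaction("TransFlux_b_c")
        assert added.lower_bound == 1e-6
        assert added.kind == "transport"

    def test_transported_metabolite_untouched(self):
        out = add_basal_transporters(self._model(), excluded=set())
        assert not out.has_reaction("TransFlux_a_c")

    def test_excluded_metabolite_skipped(self):
        out = add_basal_transporters(self._model(), excluded={"big_c"})
        assert not out.has_reaction("TransFlux_big_c")


class TestNestedMapping:
    def test_identical_models_map_identically(self, family):
        models, _, _ = family
        mapping = build_nested_mapping(models[0], models[0])
        assert mapping.added_reactions == []
        assert mapping.added_metabolites == []
        assert all(a == b for a, b in mapping.shared_reactions)

    def test_family_added_sets_match_generator(self, family):
        models, mappings, _ = family
        added = set(mappings[0].added_reactions)
        assert added == set(models[1].reaction_ids) - set(models[0].reaction_ids)
        assert added  # expansions are non-empty

    def test_restriction_recovers_small_matrix(self, family):
        models, mappings, _ = family
        small, large, mapping = models[0], models[1], mappings[0]
        cols = [large.reaction_ids.index(b) for _, b in mapping.shared_reactions]
        rows = [large.metabolite_ids.index(b) for _, b in mapping.shared_metabolites]
        assert np.array_equal(large.S[np.ix_(rows, cols)], small.S)

    def test_stoichiometry_mismatch_is_reported(self):
        small = make_model("s", [rxn("R1", {"A": -1, "B": 1})], ["A", "B"])
        large = make_model("l", [rxn("R1", {"A": -2, "B": 2})], ["A", "B"])
        mapping = build_nested_mapping(small, large)
        assert mapping.stoichiometry_mismatches == ["R1"]

    def test_missing_counterpart_raises_nesting_error(self):
        small = make_model("s", [rxn("R1", {"A": -1})], ["A"])
        large = make_model("l", [rxn("R2", {"A": -1})], ["A"])
        with pytest.raises(NestingError, match="not nested"):
            build_nested_mapping(small, large)


class TestLumpComparison:
    @staticmethod
    def _lump(rid, stoich, constituents=None):
        r = rxn(rid, stoich, lb=0, ub=1, kind="lumped")
        if constituents is not None:
            r.constituent_reactions = tuple(constituents)
        return r

    def test_two_model_overlap_counts(self):
        m1 = make_model(
            "m1",
            [self._lump("LMPD_a", {"A": -1}), self._lump("LMPD_b", {"B": -1})],
            ["A", "B", "C"],
        )
        m2 = make_model(
            "m2",
            [self._lump("LMPD_b2", {"B": -1}), self._lump("LMPD_c", {"C": -1})],
            ["A", "B", "C"],
        )
        comp = compare_lumped_sets([m1, m2])
        assert comp.common_count == 1
        assert comp.unique_counts == {"m1": 1, "m2": 1}
        assert comp.total_distinct == 3

    def test_self_comparison_all_common(self, family):
        models, _, _ = family
        comp = compare_lumped_sets([models[2], models[2]])
        assert comp.common_count == len(models[2].lumped_reactions)
        assert all(v == 0 for v in comp.unique_counts.values())

    def test_common_count_permutation_invariant(self, family):
        models, _, _ = family
        a = compare_lumped_sets(list(models))
        b = compare_lumped_sets(list(models[::-1]))
        assert a.common_count == b.common_count

    def test_scaled_stoichiometry_is_distinct(self):
        # 1 A -> 1 B and 2 A -> 2 B are different net reactions by design
        m1 = make_model("m1", [self._lump("LMPD_a", {"A": -1, "B": 1})], ["A", "B"])
        m2 = make_model("m2", [self._lump("LMPD_a", {"A": -2, "B": 2})], ["A", "B"])
        assert compare_lumped_sets([m1, m2]).common_count == 0

    def test_subnetwork_criterion_counts_constituents(self):
        m1 = make_model(
            "m1", [self._lump("LMPD_a", {"A": -1}, ["r1", "r2"])], ["A"]
        )
        m2 = make_model(
            "m2", [self._lump("LMPD_a", {"A": -1}, ["r2", "r3"])], ["A"]
        )
        comp = compare_lumped_sets([m1, m2], criterion="subnetwork")
        assert comp.common_count == 0  # different subnetworks
        assert comp.constituent_union_counts == {"m1": 2, "m2": 2}
        assert comp.constituent_common_count == 1  # r2 shared

    def test_subnetwork_without_annotations_rejected(self):
        m1 = make_model("m1", [self._lump("LMPD_a", {"A": -1})], ["A"])
        with pytest.raises(ModelValidationError, match="constituent"):
            compare_lumped_sets([m1, m1.copy("m2")], criterion="subnetwork")
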