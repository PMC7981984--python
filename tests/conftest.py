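"""Shared fixtures: synthetic nested families and small hand-built models."""

from fractions import Fraction

import pytest

from kinequiv.model_io import Metabolite, Reaction, StoichiometricModel
from kinequiv.pipeline import RunConfig, run_pipeline
from kinequiv.synthetic import ToyFamilySpec, generate_nested_toys

FAMILY_SEED = 0
PIPELINE_SEED = 1


def make_model(name, reactions, metabolite_ids):
    return StoichiometricModel(
        name=name,
        metabolites=[Metabolite(id=m) for m in metabolite_ids],
        reactions=reactions,
    )


def rxn(rid, stoich, lb=-10.0, ub=10.0, kind="enzymatic", dg0=None, subsystem=""):
    return Reaction(
        id=rid,
        stoichiometry={m: Fraction(c) for m, c in stoich.items()},
        lower_bound=lb,
        upper_bound=ub,
        kind=kind,
        delta_g0=dg0,
        subsystem=subsystem,
    )


@pytest.fixture(scope="session")
def family():
    """The standard 3-level synthetic family (models, mappings, physiology)."""
    return generate_nested_toys(ToyFamilySpec(seed=FAMILY_SEED))


@pytest.fixture(scope="session")
def pipeline_result():
    """Desk-scale end-to-end run: 3 levels, 200 kinetic instances at level 1."""
    config = RunConfig(
        synthetic={"seed": FAMILY_SEED},
        n_flux_samples=300,
        n_kinetic=200,
        seed=PIPELINE_SEED,
        warmup=300,
        thin=5,
        do_tva=True,
    )
    return run_pipeline(config)
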