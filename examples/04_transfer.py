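"""Carry a reference steady state from the small model into the next level.

The transfer MILP puts a +/-1% band around every shared intracellular flux
and minimises how many bands must be released; surviving bands are imposed
and the larger model's own representative state is sampled inside them.
"""

from kinequiv import (
    ThermoParams,
    ToyFamilySpec,
    build_tfa_problem,
    generate_nested_toys,
    sample_concentration_space,
    sample_flux_space,
    select_representative,
    transfer_steady_state,
)
from kinequiv.sampling import assemble_steady_state

models, mappings, physiology = generate_nested_toys(ToyFamilySpec(seed=0))
params = ThermoParams(min_net_flux=1e-4)

# reference state of the smallest model
p1 = build_tfa_problem(models[0], params, physiology)
p1.fix_directionality()
pool = sample_flux_space(p1, n=1000, seed=1)
_, row = select_representative(pool)
nf = row.copy()
nf.index = [s.removeprefix("NF_") for s in nf.index]
cpool = sample_concentration_space(p1, nf, n=1000, seed=2)
_, crow = select_representative(cpool)
reference = assemble_steady_state(p1, nf, crow)

p2 = build_tfa_problem(models[1], params, physiology)
state, flux_report, conc_report = transfer_steady_state(
    p2, mappings[0], reference, n=1000, seed=3, relaxation=0.01
)
print(
    f"flux phase: {flux_report.objective} band violation(s) "
    f"{flux_report.violated_ids}"
)
print(
    f"concentration phase: {conc_report.objective} band violation(s) "
    f"{conc_report.violated_ids}"
)
print("\nper-reaction deviation of the transferred fluxes from the reference:")
print(flux_report.table.round(5).to_string(index=False))
print(
    "\nNon-violated reactions stay within 1% of the reference, so the two "
    "levels describe the same operating state of the cell."
)
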