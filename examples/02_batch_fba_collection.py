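"""Comparative FBA of a model collection under a shared growth medium.

Three synthetic organisms with different uptake capacities are analysed
together: one batch solve per member, tabulated in collection order, then
column-normalized to percent of the best producer (the heat-map input).
"""

import fluxcompare as fc

members = [
    fc.fixtures.make_chain(k=3, uptake=u, model_id=name)
    for name, u in [("org_slow", 5.0), ("org_mid", 10.0), ("org_fast", 20.0)]
]
collection = fc.ModelCollection(name="demo", members=members)

# medium caps glucose influx at 8 for everyone, overriding native capacity
medium = fc.Medium(entries={"glc_e": 8.0})

table = fc.batch_fba(collection, "export", medium=medium)
print("maximal export flux under a glucose-8 medium:")
print(table.to_frame().to_string())
print()

unlimited = fc.batch_fba(collection, "export")
print("with unconstrained medium (native uptake bounds bind instead):")
print(unlimited.to_frame().to_string())
print()

percent = fc.relative_flux_matrix(unlimited)
print("as % of the best producer per objective:")
print(percent.to_string())
print()
print("Under the shared medium every organism is capped at 8 except the")
print("slow one, whose own 5-unit transporter is the tighter constraint.")
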