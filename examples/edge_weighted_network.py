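"""Edge-weighted contact energy network (EACEN) and its normalisation.

Every AACEN edge is re-weighted by the min–max normalised magnitude of
its contact energy: the weakest attractive contact gets exactly 0.0001,
the strongest exactly 1, everything else interpolates linearly in |e_ij|.
Strong contacts therefore act as short, preferred communication channels
in path-based metrics (path length = 1/weight).
"""

import io

from anca import assign_secondary_structure, build_eacen, metrics_report, \
    parse_structure
from anca.fixtures import make_peptide, make_toy_energy_table

model = parse_structure(io.StringIO(make_peptide("helix_peptide", 10)))
assign_secondary_structure(model)
table = make_toy_energy_table(7, negative_only=True)

net = build_eacen(model, table)
edges = sorted(net.edges, key=lambda e: e.weight)
print(f"{'edge':<14}{'e_ij':>10}{'weight':>12}")
for e in edges[:3] + edges[-3:]:
    print(f"{e.node_i}-{e.node_j:<8}{e.energy:>10.3f}{e.weight:>12.4f}")
print("...")
report = metrics_report(net)
print(report.network_row.to_string(index=False))
print()
print("The minimum-|e| edge carries weight 0.0001 and the maximum 1.0;")
print("L_net here averages 1/weight path lengths, so strongly coupled")
print("regions look compact while weak contacts stretch distances.")
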