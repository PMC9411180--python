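"""Detect Q-modules and S-modules on a GTOM-UPGMA dendrogram.

The pipeline converts a skull network into a generalized topological overlap
(GTOM) similarity matrix, clusters 1-GTOM with UPGMA, cuts the dendrogram at
the partition maximizing Newman-Girvan modularity Q (the Q-modules), and
tests every dendrogram cluster for significantly more internal than external
articulations (the S-modules, tiered at p < 0.001 / 0.01 / 0.05).
"""

from skullnet import SkullNetSpec, generate_skull_network, q_modules, s_modules
from skullnet.gtom import network_dendrogram

net, _, planted = generate_skull_network(
    SkullNetSpec(n_paired=10, n_midline=4, n_modules=3, seed=7)
)
dend = network_dendrogram(net, m=1)

qres = q_modules(net, dend)
n_modules = len(set(qres.partition.values()))
print(f"Q_max = {qres.q_value:.4f} at {n_modules} modules "
      f"(planted: {len(set(planted.values()))})")
for module_id in sorted(set(qres.partition.values())):
    members = sorted(v for v, m in qres.partition.items() if m == module_id)
    print(f"  module {module_id}: {', '.join(members)}")

significant = [s for s in s_modules(net, dend)
               if not s.degenerate and s.p_value < 0.05]
print(f"{len(significant)} S-modules at p < 0.05; strongest three:")
for s in sorted(significant, key=lambda s: s.p_value)[:3]:
    print(f"  p = {s.p_value:.2e} [{s.tier}]  {len(s.cluster)} bones")
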