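"""Network topology: do target genes sit in the interaction network's core?

Samples a 600-node interaction network in which 60 target proteins get 3x
the background expected degree and doubled odds of interacting with each
other, then profiles degree, coreness (k-core level) and target-neighbor
ratio, comparing targets against the rest of the network with KS tests.
"""

import tempfile
from pathlib import Path

from foxotarget import compare_groups, load_gene_list, read_edge_list
from foxotarget.simulate import gen_planted_hub_network

out = Path(tempfile.mkdtemp(prefix="foxotarget-"))
edges_path, targets_path, truth = gen_planted_hub_network(
    n_nodes=600,
    background_mean_degree=6.0,
    target_count=60,
    degree_multiplier=3.0,
    within_target_bias=2.0,
    seed=42,
    out_dir=out,
)

network = read_edge_list(edges_path)
targets = load_gene_list(targets_path, name="targets")
summaries = compare_groups(network, targets)

for s in summaries:
    print(
        f"{s.group:>8}: n={s.n:4d}  mean degree {s.mean_degree:6.2f}  "
        f"mean coreness {s.mean_coreness:5.2f}  mean ratio {s.mean_ratio:.3f}"
    )
print()
for feature, result in summaries[1].ks.items():
    print(f"KS targets vs rest, {feature:>8}: D={result.D:.3f}  p={result.p_value:.2E}")
print()
print("Targets show higher mean degree and coreness than the network at")
print("large, and the KS tests confirm the distributions differ — the")
print("planted hub structure is recovered from the edge list alone.")
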