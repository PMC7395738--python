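"""Drug-signature connectivity: finding a signature reverser.

The query is a disease signature (up/down gene sets). One drug in the
library pushes the same genes in the opposite directions (a candidate
therapeutic); another mimics the disease; decoys are random.
"""

from codegnet import DrugSignatureLibrary, connectivity_frame, rank_drugs

query_up = {f"U{i}" for i in range(10)}
query_down = {f"D{i}" for i in range(10)}
universe = query_up | query_down | {f"N{i}" for i in range(200)}

library = DrugSignatureLibrary(
    drugs={
        "reverser_rx": (frozenset(list(query_down)[:8]), frozenset(list(query_up)[:8])),
        "mimic_rx": (frozenset(list(query_up)[:8]), frozenset(list(query_down)[:8])),
        "decoy_rx": (frozenset({"N1", "N2", "N3"}), frozenset({"N4", "N5", "N6"})),
    },
    universe=universe,
)

reversers, mimics = rank_drugs(query_up, query_down, library)
print("reversal candidates (score ascending):")
print(connectivity_frame(reversers).to_string(index=False))
print()
best = reversers[0]
print(f"best reverser: {best.drug} (score {best.score:+.3f}, p {best.p_value:.2e})")
# Scores live in [-1, +1]: -1 would be an exact reversal of the query
# signature, +1 an exact mimic. The reverser's negative score comes from its
# up-set overlapping the query's down genes and vice versa; the p-value is a
# Bonferroni-adjusted hypergeometric test on the best quadrant overlap.
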