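"""Cluster genomes by shared ANF gene content (UPGMA over Jaccard).

Genomes with similar gene repertoires join at low heights; the printed
Newick tree is ultrametric (all leaves equidistant from the root), and the
leaf order is the row order for presence/absence heatmaps.
"""

from anfscreen import (
    build_matrix,
    default_catalog,
    distance_matrix,
    emulate_study_groups,
    leaf_order,
    newick_string,
    screen_collection,
    upgma,
)

catalog = default_catalog()
genomes, _ = emulate_study_groups(scale=3, seed=11)
hits = screen_collection(genomes, catalog)
matrix = build_matrix(hits, [g.genome_id for g in genomes])

dist = distance_matrix(matrix, metric="jaccard")
tree = upgma(dist, matrix.genome_ids)

print("UPGMA tree (branch lengths = half merge distance):")
print(newick_string(tree))
print("\nheatmap row order:", ", ".join(leaf_order(tree)))
# Genomes of the same taxon group share planted gene families, so they
# cluster together; the root height is half the largest average distance.
print(f"root height: {tree.root.height:.3f}")
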