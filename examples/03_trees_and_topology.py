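"""Morphological dendrogram, Newick round-trip and topological distances.

Builds the UPGMA (average linkage) tree from a morphological distance
matrix, serializes it to Newick, converts it to unit-branch-length
cophenetic ("topological") distances and collapses allele-level leaves of
a gene tree to sample level.
"""

import phylomorph as pm

fm, _gdm, species = pm.generate_congruent_dataset(4.0, 9, seed=5)
mdm = pm.morphological_distances(fm)
tree = pm.average_linkage_tree(mdm)
print("morphological UPGMA tree:")
print(pm.write_newick(tree))

topo = pm.topological_distances(tree)
print("\ntopological (edge-count) distances between the first 5 colonies:")
print(topo.to_dataframe().iloc[:5, :5])

gene_tree = pm.read_newick("(((A-1,A-2),B),(C,D));")
collapsed = pm.collapse_allele_distances(
    pm.topological_distances(gene_tree),
    {"A": ["A-1", "A-2"], "B": ["B"], "C": ["C"], "D": ["D"]})
print("\nallele-collapsed topological distances of ((A-1,A-2),B),(C,D):")
print(collapsed.to_dataframe())
print("\nA's entry to B averages the two allele-to-B edge counts (3 and 3);")
print("homozygotes count as two identical alleles, which leaves means unchanged.")
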