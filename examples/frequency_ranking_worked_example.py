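"""Aggregate two per-fold gene selections and rank by frequency.

Cross-validated selection produces a (possibly different) gene subset
per fold.  The frequency ranking scores each gene by how often it was
selected relative to the union size: genes picked in every fold are the
most stable biomarker candidates.
"""

from mgs import rank_by_frequency, top_eta, union_selections

fold1 = ["g1", "g3", "g4", "g5", "g6"]
fold2 = ["g1", "g2", "g4", "g6"]

counts = union_selections([fold1, fold2])
ranked = rank_by_frequency(counts)

print(f"union of {len(counts)} genes")
for gene, score in zip(ranked.genes, ranked.scores):
    print(f"  {gene}: selected {counts[gene]}x, relative frequency {score:.3f}")
print("top-3 panel:", top_eta(ranked, 3))

# Genes g1, g4, g6 were selected in both folds (relative frequency
# 2/6 = 0.333 each) and head the ranking; the single-fold genes follow
# at 1/6.  The top-eta panel is what a classifier would be trained on.
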