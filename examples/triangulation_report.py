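"""Triangulate CCA genes against validation sets and summarize a network.

Reproduces the reporting arithmetic of a pleiotropy study: Bonferroni
thresholds, Venn-region counts between the CCA gene list and external
evidence (gene-based test hits, TWAS hits, predicted drug targets), a
selection rule picking CCA genes backed by at least one validation set,
classification against known-disease-gene lists, and average degree of a
protein-protein interaction network.
"""

from pleiocca import (
    GeneSet,
    bonferroni_threshold,
    classify_genes,
    graph_summary,
    intersect_gene_sets,
    select_genes,
)
from pleiocca.report import format_threshold

print("Bonferroni thresholds (alpha = 0.01):")
print(f"  15302 gene tests  -> {format_threshold(bonferroni_threshold(0.01, 15302))}")
print(f"  440440 SNP tests  -> {format_threshold(bonferroni_threshold(0.01, 440440))}")

cca = GeneSet.from_iterable("CCA", ["FTO", "PAX8", "GATM", "GRIK1", "SLC5A1", "NPC1"])
vegas = GeneSet.from_iterable("VEGAS", ["FTO", "PAX8", "GATM", "ABCA1"])
twas = GeneSet.from_iterable("TWAS", ["GATM", "NPC1", "TP53"])
targets = GeneSet.from_iterable("TARGETS", ["SLC5A1", "EP300", "GRIK1"])

_, regions = intersect_gene_sets([cca, vegas, twas])
print("\nVenn regions (CCA / VEGAS / TWAS):")
for combo, count in sorted(regions.items()):
    print(f"  {' & '.join(combo)}: {count}")

validated = select_genes([cca, vegas, twas], "CCA & (VEGAS | TWAS)")
drugged = select_genes([cca, targets], "CCA & TARGETS")
print(f"\nCCA genes backed by VEGAS or TWAS: {sorted(validated.genes)}")
print(f"CCA genes that are drug targets:   {sorted(drugged.genes)}")

known_1 = GeneSet.from_iterable("T1", ["FTO", "PAX8"])
known_2 = GeneSet.from_iterable("T2", ["FTO", "GATM", "PAX8"])
table = classify_genes(validated, known_1, known_2)
print("\nclassification of validated genes (both / one / neither known list):")
for _, row in table.iterrows():
    print(f"  {row.GENE}: {row.STATUS}")

edges = [(f"P{i}", f"P{(i + 1) % 183}") for i in range(183)]
edges += [(f"P{i}", f"P{i + 50}") for i in range(19)]
gs = graph_summary(edges)
print(f"\nPPI network: {gs.n_nodes} nodes, {gs.n_edges} edges, "
      f"average degree {gs.mean_degree_display}")
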