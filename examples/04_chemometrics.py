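"""Correlation, PCA and clustering over the extract x activity matrix.

The packaged matrix (one row per extraction method, columns = totals and
five IC50s; partially synthetic, see rsmextract.datasets) is analysed
three ways: Pearson correlations with significance stars, PCA on the
correlation matrix (unit-free, eigenvalues sum to the 7 variables), and
Ward clustering on z-scores exported as Newick.
"""

from rsmextract import hca, pca, pearson_matrix
from rsmextract.datasets import load_activity_matrix

m = load_activity_matrix()
rho, pval, flags = pearson_matrix(m)
print("Pearson rho (TPC row):")
print(rho.loc["TPC"].round(3).to_string())
print("significance flags (TPC row):", flags.loc["TPC"].to_dict())

res = pca(m)
print("\neigenvalues:", [round(float(v), 2) for v in res.eigenvalues])
print("explained %:", [round(float(v), 1) for v in res.explained_percent])
print("PC1 loadings:")
print(res.loadings["PC1"].round(3).to_string())
print("totals load opposite the IC50s on PC1: high-phenolic extracts are the strong (low-IC50) ones")

tree = hca(m, linkage="ward")
print("\nWard dendrogram (Newick):", tree.to_newick())
print("3-cluster cut:", tree.cut(3))
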