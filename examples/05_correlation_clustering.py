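"""Trait correlations and Ward clustering of the 31 genotypes.

Genotype means are z-scored per trait, clustered on Euclidean distances, and
cut at two clusters; the cluster with higher grain yield should also lead on
water status, fertility and grain weight if the traits hang together.
"""

import linetester as lt

means = lt.load_fixture("table3_means")
mat = means.values_for("normal")

corr = lt.pearson_matrix(mat)
print("Correlation of grain yield (GYPP) with the other traits:")
for trait in mat.columns:
    if trait != "GYPP":
        print(f"  {trait:<8} r = {corr.r.loc['GYPP', trait]:+.2f} {corr.stars.loc['GYPP', trait]}")

z = lt.standardize(mat)
for method in ("ward", "average", "single"):
    ac = lt.agglomerative_coefficient(lt.hcluster(z, method))
    print(f"agglomerative coefficient ({method}): {ac:.3f}")

model = lt.hcluster(z, "ward")
k, votes = lt.select_k(z, range(2, 6))
print("optimal k by index vote:", k, votes)
summary = lt.cluster_summary(model.cut(k), mat)
print(summary[["RWC", "GYPP", "SpF", "GI"]].round(1))
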