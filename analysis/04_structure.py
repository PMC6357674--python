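"""Population structure: relationship-matrix PCA, PC-vs-geography
correlations, and a neighbor-joining tree from Euclidean distances.

Expected pattern: PC1 splits L1 from L2 with the hybrids in between;
within L1 (tauschii-only PCA) PC2 tracks the planted longitudinal cline;
the NJ tree shows three clades (L1, L2, wheat) with wheat inside/near L2.

Writes results/structure/{pca_scores.tsv, pca_variance.tsv, pc_geo.tsv,
tree.nwk}.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from lineage_scope import (
    GroupPartition,
    euclidean_distance,
    nj_tree,
    pc_geo_correlation,
    pca,
    read_passport,
    read_vcf,
    relationship_matrix,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    gm = read_vcf(RESULTS / "filtered.vcf")
    records = read_passport(RESULTS / "panel" / "passport.tsv")
    partition = GroupPartition.from_passport(records)
    out = RESULTS / "structure"
    out.mkdir(parents=True, exist_ok=True)
    present = set(gm.samples)

    res = pca(relationship_matrix(gm), n_components=3)
    scores = res.scores.reset_index().rename(columns={"index": "sample"})
    scores["group"] = [partition.group_of(s) for s in scores["sample"]]
    scores.to_csv(out / "pca_scores.tsv", sep="\t", index=False)
    print("PCA (whole panel): variance explained "
          + ", ".join(f"PC{i+1} {v:.1%}" for i, v in enumerate(res.variance_explained)))
    l1 = res.scores.loc[[s for s in partition.samples("L1") if s in present], "PC1"]
    l2 = res.scores.loc[[s for s in partition.samples("L2") if s in present], "PC1"]
    sep = l1.max() < l2.min() or l2.max() < l1.min()
    print(f"PC1 separates L1 from L2 with zero overlap: {sep}")

    # tauschii-only PCA for the intra-lineage clines
    taus = [s for s in gm.samples
            if partition.group_of(s) in ("L1", "L2")]
    res_t = pca(relationship_matrix(gm.subset_samples(taus)), n_components=3)
    geo = pc_geo_correlation(res_t, [r for r in records if r.id in set(taus)])
    geo.to_csv(out / "pc_geo.tsv", sep="\t", index=False)
    print("\nPC vs geography (tauschii only, pairwise-complete Pearson r):")
    print(geo.to_string(index=False, float_format=lambda x: f"{x:.3f}"))
    l1_ids = [s for s in partition.samples("L1") if s in set(taus)]
    lon = {r.id: r.longitude for r in records}
    r_l1 = np.corrcoef(res_t.scores.loc[l1_ids, "PC2"],
                       [lon[s] for s in l1_ids])[0, 1]
    print(f"within L1: r(PC2, longitude) = {r_l1:.3f} (planted east/west cline)")

    tree = nj_tree(euclidean_distance(gm))
    (out / "tree.nwk").write_text(tree.to_newick() + "\n")
    print(f"\nNJ tree: {len(tree.leaves)} leaves, "
          f"{tree.n_negative_clamped} negative branch(es) clamped -> results/structure/tree.nwk")


if __name__ == "__main__":
    main()
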