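"""Group-wise diversity: Nei gene diversity per group, pairwise Hudson
F_ST, and the joint L1/L2 minor-allele-frequency table.

Expected pattern: wheat has the lowest diversity (derived bottleneck),
F_ST(L1, wheat) > F_ST(L2, wheat) because the derived panel descends from
L2, and the L1-vs-L2 F_ST sits near the simulated divergence F = 0.5.

Writes results/diversity/{nei.tsv, fst.tsv, maf_joint.tsv}.
"""

from pathlib import Path

import pandas as pd

from lineage_scope import (
    GroupPartition,
    maf_spectrum,
    nei_diversity,
    pairwise_fst,
    read_passport,
    read_vcf,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    gm = read_vcf(RESULTS / "filtered.vcf")
    partition = GroupPartition.from_passport(read_passport(RESULTS / "panel" / "passport.tsv"))
    out = RESULTS / "diversity"
    out.mkdir(parents=True, exist_ok=True)
    present = set(gm.samples)

    rows = []
    subsets = {g: [s for s in partition.samples(g) if s in present]
               for g in partition.groups}
    subsets["tauschii_combined"] = subsets.get("L1", []) + subsets.get("L2", [])
    subsets["all"] = list(gm.samples)
    for name, ids in subsets.items():
        if not ids:
            continue
        rep = nei_diversity(gm, ids)
        rows.append({"group": name, "n_samples": len(ids),
                     "nei_index": rep.nei_index, "n_sites": rep.n_sites_used})
    nei = pd.DataFrame(rows)
    nei.to_csv(out / "nei.tsv", sep="\t", index=False)
    print("Nei gene diversity (expected heterozygosity):")
    print(nei.to_string(index=False, float_format=lambda x: f"{x:.4f}"))

    groups = [g for g in ("L1", "L2", "hybrid", "wheat") if len(subsets.get(g, [])) >= 2]
    fst = pairwise_fst(gm, partition, groups)
    fst.to_frame().to_csv(out / "fst.tsv", sep="\t", index=False)
    print("\npairwise Hudson F_ST (ratio of sums):")
    print(fst.to_frame().to_string(index=False, float_format=lambda x: f"{x:.4f}"))
    assert fst.get("L1", "wheat") > fst.get("L2", "wheat"), \
        "derived panel should be closer to L2"

    spectrum = maf_spectrum(gm, partition, ("L1", "L2"))
    spectrum.joint.to_csv(out / "maf_joint.tsv", sep="\t", index=False)
    print(f"\nsites segregating in L1 but invariant in L2: {spectrum.exclusive_counts['L1']}")
    print(f"sites segregating in L2 but invariant in L1: {spectrum.exclusive_counts['L2']}")


if __name__ == "__main__":
    main()
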