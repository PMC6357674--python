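"""Core-collection selection: greedy M-strategy cover of all observed
allele classes over the tauschii samples, then a phenotype-weighted,
quota-constrained reduction to a MiniCore-sized subset, with capture
metrics (percent segregating SNPs retained, Nei index).

Writes results/coreset/{core_full.tsv, minicore.tsv, capture.tsv}.
"""

from pathlib import Path

import pandas as pd

from lineage_scope import (
    GroupPartition,
    allele_classes,
    capture_metrics,
    greedy_m_selection,
    read_passport,
    read_phenotypes,
    read_vcf,
    reduce_core,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"
QUOTAS = {"L1": 8, "L2": 4}  # preserve the paper-style L1-heavy ratio at panel scale


def main() -> None:
    gm = read_vcf(RESULTS / "filtered.vcf")
    partition = GroupPartition.from_passport(read_passport(RESULTS / "panel" / "passport.tsv"))
    phenotypes = read_phenotypes(RESULTS / "panel" / "phenotypes.tsv")
    out = RESULTS / "coreset"
    out.mkdir(parents=True, exist_ok=True)

    # select over the wild (tauschii) samples only
    taus = [s for s in gm.samples if partition.group_of(s) in ("L1", "L2")]
    gmt = gm.subset_samples(taus)
    universe = allele_classes(gmt, phenotypes)
    core = greedy_m_selection(gmt, universe)
    pd.DataFrame({"rank": range(1, len(core.samples) + 1),
                  "sample": core.samples,
                  "new_classes": core.step_new_classes}).to_csv(
        out / "core_full.tsv", sep="\t", index=False)
    print(f"greedy M-strategy core: {len(core.samples)} of {len(taus)} samples "
          f"cover {100 * core.coverage_fraction:.1f}% of "
          f"{core.n_classes} allele/phenotype classes")

    mini = reduce_core(core, gmt, phenotypes, QUOTAS, partition, universe=universe)
    pd.DataFrame({"rank": range(1, len(mini.samples) + 1),
                  "sample": mini.samples,
                  "group": [partition.group_of(s) for s in mini.samples]}).to_csv(
        out / "minicore.tsv", sep="\t", index=False)

    rows = []
    for name, subset in (("full_core", core.samples), ("minicore", mini.samples)):
        m = capture_metrics(subset, gmt)
        rows.append({"set": name, "n_samples": len(subset), **m})
    capture = pd.DataFrame(rows)
    capture.to_csv(out / "capture.tsv", sep="\t", index=False)
    print(f"\nMiniCore ({QUOTAS['L1']} L1 + {QUOTAS['L2']} L2 = {len(mini.samples)} samples, "
          f"{len(taus) / len(mini.samples):.1f}-fold reduction):")
    print(capture.to_string(index=False, float_format=lambda x: f"{x:.3f}"))
    whole = capture_metrics(taus, gmt)
    print(f"\nwhole-collection Nei index {whole['nei_index']:.4f} vs "
          f"minicore {rows[1]['nei_index']:.4f}; "
          f"minicore retains {rows[1]['pct_segregating']:.1f}% of segregating SNPs")


if __name__ == "__main__":
    main()
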