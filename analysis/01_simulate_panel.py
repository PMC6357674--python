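"""Generate the study panel: two diverged inbred lineages, nine planted
inter-lineage hybrids (1 F1, 1 RIL, 7 hybrid-lineage), and a 20-line
derived low-diversity panel carrying planted L1 introgressions.

Writes results/panel/{panel.vcf, passport.tsv, phenotypes.tsv, truth_*.tsv}.
"""

from pathlib import Path

from lineage_scope import SimConfig, write_fixture

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 2019


def main() -> None:
    cfg = SimConfig(seed=SEED)
    out = RESULTS / "panel"
    paths = write_fixture(cfg, out, force=True)
    print(f"simulated panel with seed {SEED}:")
    print(f"  {cfg.n_l1} L1 + {cfg.n_l2} L2 + 9 hybrids + {cfg.n_wheat} wheat-like samples")
    print(f"  {cfg.n_sites} SNPs on {cfg.n_chromosomes} chromosomes, "
          f"lineage divergence F = {cfg.divergence_f}")
    print(f"  planted: {cfg.wheat_introgression_sites} multi-carrier L1 introgression sites, "
          f"{cfg.hybrid_private_fixed}+{cfg.hybrid_private_segregating} hybrid-group private sites")
    for p in paths:
        print(f"  wrote {p}")


if __name__ == "__main__":
    main()
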