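"""Synthetic two-lineage SNP panels with planted hybrids and introgressions.

The generator emulates the statistical structure of a filtered GBS panel
from a highly selfing species split into two diverged lineages (L1, L2):

* Ancestral allele frequencies per site are Uniform(0.1, 0.9); each lineage
  draws its own frequency from the Balding-Nichols distribution
  ``Beta(p(1-F)/F, (1-p)(1-F)/F)`` with ``F = divergence_f``, so pairwise
  F_ST between the lineages has known expectation F.
* Samples are inbred: one allele is drawn from the lineage frequency and
  duplicated (dosage 0 or 2); with probability ``residual_het`` the second
  allele is redrawn independently, leaving a trace of heterozygosity.
* Each lineage is split into two subpopulations by a second, weaker
  Balding-Nichols round; passport geography is correlated with the split
  (a longitudinal cline within L1, an altitudinal cline within L2).
* A derived low-diversity panel ("wheat") descends from a small bottleneck
  of L2 haplotypes, with a handful of L1-private alleles planted into >= 2
  carrier lines as ground-truth introgressions (plus optional single-carrier
  sites that a consensus rule must ignore).
* Planted inter-lineage hybrids: F1s (het wherever the two parents differ),
  recombinant-inbred mosaics (per-chromosome 2-state Markov chain over site
  order), and a "hybrid lineage" group sharing one mosaic prototype plus
  group-exclusive private alleles (some fixed, some segregating).
* Uniform missingness and a symmetric genotyping-error model are applied
  last, so the recorded truth stays clean.

Everything stochastic flows from one :func:`numpy.random.default_rng`
generator, so a seed fixes the panel bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .genotype_io import (
    MISSING,
    GenotypeMatrix,
    PhenotypeTable,
    SampleRecord,
    SnpSite,
    write_passport,
    write_phenotypes,
    write_vcf,
)

_BASES = np.array(list("ACGT"))


class ConfigurationError(ValueError):
    """Raised when a simulation config is internally infeasible."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic panel (defaults are the study conditions).

    The default panel is a desk-scale analogue of a wild-relative
    collection: 100 inbred accessions in two lineages diverged at F = 0.5,
    nine planted hybrids (1 F1, 1 RIL, 7 hybrid-lineage), and a 20-line
    derived panel descended from 4 L2 founders carrying 10 multi-carrier
    L1 introgression sites.
    """

    n_l1: int = 60
    n_l2: int = 40
    n_wheat: int = 20
    n_sites: int = 2000
    n_chromosomes: int = 7
    divergence_f: float = 0.5
    residual_het: float = 0.002
    missing_rate: float = 0.02
    error_rate: float = 0.001
    n_f1: int = 1
    n_ril: int = 1
    ril_breakpoints_per_chrom: float = 2.0
    hybrid_group_size: int = 7
    hybrid_breakpoints_per_chrom: float = 25.0
    hybrid_private_fixed: int = 20
    hybrid_private_segregating: int = 5
    wheat_founder_count: int = 4
    wheat_introgression_sites: int = 10
    wheat_introgression_carriers: int = 3
    wheat_single_carrier_sites: int = 2
    l1_substructure_f: float = 0.08
    l2_substructure_f: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_l1": self.n_l1, "n_l2": self.n_l2, "n_wheat": self.n_wheat,
            "n_sites": self.n_sites, "n_chromosomes": self.n_chromosomes,
            "n_f1": self.n_f1, "n_ril": self.n_ril,
            "hybrid_group_size": self.hybrid_group_size,
            "hybrid_private_fixed": self.hybrid_private_fixed,
            "hybrid_private_segregating": self.hybrid_private_segregating,
            "wheat_founder_count": self.wheat_founder_count,
            "wheat_introgression_sites": self.wheat_introgression_sites,
            "wheat_single_carrier_sites": self.wheat_single_carrier_sites,
        }
        for name, v in counts.items():
            if v < 0:
                raise ConfigurationError(f"{name} must be >= 0, got {v}")
        for name in ("residual_het", "missing_rate", "error_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name} must be in [0,1], got {v}")
        if not 0 < self.divergence_f < 1:
            raise ConfigurationError("divergence_f must be in (0,1)")
        for name in ("l1_substructure_f", "l2_substructure_f"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ConfigurationError(f"{name} must be in [0,1)")
        if self.n_l1 < 1 or self.n_l2 < 1:
            raise ConfigurationError("need at least one sample per lineage")
        if self.n_sites < 1 or self.n_chromosomes < 1:
            raise ConfigurationError("need n_sites >= 1 and n_chromosomes >= 1")
        if self.wheat_introgression_sites > 0:
            if self.wheat_introgression_carriers < 2:
                raise ConfigurationError("wheat_introgression_carriers must be >= 2")
            if self.wheat_introgression_carriers > self.n_wheat:
                raise ConfigurationError("more introgression carriers than wheat lines")
        if self.wheat_single_carrier_sites > 0 and self.n_wheat < 1:
            raise ConfigurationError("single-carrier sites require wheat lines")
        if self.n_wheat > 0 and not 1 <= self.wheat_founder_count <= self.n_l2:
            raise ConfigurationError("wheat_founder_count must be in [1, n_l2]")
        if self.hybrid_private_segregating > 0 and self.hybrid_group_size < 2:
            raise ConfigurationError(
                "segregating hybrid-group-private sites need group size >= 2"
            )

    @classmethod
    def from_file(cls, path: str | Path) -> "SimConfig":
        """Parse a plain-text ``key = value`` config file."""
        kwargs = {}
        types = {f.name: f.type for f in fields(cls)}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigurationError(f"bad config line: {line!r}")
            key, value = (x.strip() for x in line.split("=", 1))
            if key not in types:
                raise ConfigurationError(f"unknown config key: {key!r}")
            caster = float if types[key] == "float" else int
            kwargs[key] = caster(value)
        return cls(**kwargs)


@dataclass
class SimTruth:
    """Ground truth of a simulated panel, for parameter-recovery tests."""

    true_group: dict[str, str]
    subpop: dict[str, str]
    f1_parents: dict[str, tuple[str, str]]
    ril_parents: dict[str, tuple[str, str]]
    #: per RIL / hybrid-prototype sample: per-site ancestry, 0 = L1, 1 = L2
    ancestry: dict[str, np.ndarray]
    #: per mosaic sample: chromosome -> positions of the first site after each switch
    breakpoints: dict[str, dict[str, list[int]]]
    introgression_sites: list[str]
    introgression_carriers: dict[str, list[str]]
    single_carrier_sites: list[str]
    single_carrier_carriers: dict[str, list[str]]
    group_private_fixed_sites: list[str]
    group_private_segregating_sites: list[str]
    #: site id -> which allele ('ref'/'alt') is hybrid-group private
    group_private_allele: dict[str, str]
    #: genotype matrix before missingness/error injection
    clean_calls: np.ndarray


def _balding_nichols(rng: np.random.Generator, p: np.ndarray, f: float) -> np.ndarray:
    """Draw daughter frequencies around ``p`` at divergence ``f`` (0/1 stay fixed)."""
    if f <= 0:
        return p.copy()
    out = p.copy()
    inner = (p > 0) & (p < 1)
    scale = (1 - f) / f
    out[inner] = rng.beta(p[inner] * scale, (1 - p[inner]) * scale)
    return out


def _inbred_draw(
    rng: np.random.Generator, freqs: np.ndarray, n: int, residual_het: float
) -> tuple[np.ndarray, np.ndarray]:
    """(haplotypes bool (n, S), dosages int8 (n, S)) for n inbred samples."""
    s = freqs.shape[0]
    hap = rng.random((n, s)) < freqs
    dos = (2 * hap).astype(np.int8)
    if residual_het > 0:
        redraw = rng.random((n, s)) < residual_het
        second = rng.random((n, s)) < freqs
        dos = np.where(redraw, hap.astype(np.int8) + second.astype(np.int8), dos)
    return hap, dos.astype(np.int8)


def _mosaic(
    rng: np.random.Generator, chrom_slices: list[slice], rate: float, n_sites: int
) -> np.ndarray:
    """Per-site 2-state ancestry (0/1), Markov over site order within chromosomes."""
    anc = np.zeros(n_sites, dtype=np.int8)
    for sl in chrom_slices:
        length = sl.stop - sl.start
        state = int(rng.integers(2))
        if length > 1:
            t = min(rate / (length - 1), 1.0)
            switches = rng.random(length - 1) < t
            states = state ^ np.concatenate(([0], np.cumsum(switches) % 2)).astype(np.int8)
        else:
            states = np.array([state], dtype=np.int8)
        anc[sl] = states
    return anc


def simulate_panel(
    cfg: SimConfig,
) -> tuple[GenotypeMatrix, list[SampleRecord], PhenotypeTable, SimTruth]:
    """Simulate a full panel; see the module docstring for the model."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    s = cfg.n_sites

    # --- site layout ---------------------------------------------------
    base = s // cfg.n_chromosomes
    extra = s % cfg.n_chromosomes
    chrom_sizes = [base + (1 if i < extra else 0) for i in range(cfg.n_chromosomes)]
    chrom_names = [
        f"{i + 1}D" if cfg.n_chromosomes <= 9 else f"{i + 1:02d}D"
        for i in range(cfg.n_chromosomes)
    ]
    chrom_slices, start = [], 0
    for size in chrom_sizes:
        chrom_slices.append(slice(start, start + size))
        start += size
    sites: list[SnpSite] = []
    for name, sl in zip(chrom_names, chrom_slices):
        positions = np.cumsum(rng.integers(500, 5000, sl.stop - sl.start))
        for k, pos in enumerate(positions):
            ref, alt = _BASES[rng.choice(4, 2, replace=False)]
            sites.append(SnpSite(f"S{name}_{k:05d}", name, int(pos), ref, alt))

    # --- lineage allele frequencies ------------------------------------
    p_anc = rng.uniform(0.1, 0.9, s)
    p_l1 = _balding_nichols(rng, p_anc, cfg.divergence_f)
    p_l2 = _balding_nichols(rng, p_anc, cfg.divergence_f)
    p_l1_sub = [
        _balding_nichols(rng, p_l1, cfg.l1_substructure_f) for _ in range(2)
    ]
    p_l2_sub = [
        _balding_nichols(rng, p_l2, cfg.l2_substructure_f) for _ in range(2)
    ]

    # --- pure-lineage samples -------------------------------------------
    n_l1_west = cfg.n_l1 // 2
    n_l2_low = cfg.n_l2 // 2
    hap_l1w, dos_l1w = _inbred_draw(rng, p_l1_sub[0], n_l1_west, cfg.residual_het)
    hap_l1e, dos_l1e = _inbred_draw(rng, p_l1_sub[1], cfg.n_l1 - n_l1_west, cfg.residual_het)
    hap_l2l, dos_l2l = _inbred_draw(rng, p_l2_sub[0], n_l2_low, cfg.residual_het)
    hap_l2h, dos_l2h = _inbred_draw(rng, p_l2_sub[1], cfg.n_l2 - n_l2_low, cfg.residual_het)
    hap_l1 = np.vstack([hap_l1w, hap_l1e])
    dos_l1 = np.vstack([dos_l1w, dos_l1e])
    hap_l2 = np.vstack([hap_l2l, hap_l2h])
    dos_l2 = np.vstack([dos_l2l, dos_l2h])

    l1_ids = [f"L1-{i + 1:03d}" for i in range(cfg.n_l1)]
    l2_ids = [f"L2-{i + 1:03d}" for i in range(cfg.n_l2)]
    l1_subpop = ["L1_west"] * n_l1_west + ["L1_east"] * (cfg.n_l1 - n_l1_west)
    l2_subpop = ["L2_low"] * n_l2_low + ["L2_high"] * (cfg.n_l2 - n_l2_low)

    true_group: dict[str, str] = {}
    subpop: dict[str, str] = {}
    for sid, sub in zip(l1_ids, l1_subpop):
        true_group[sid], subpop[sid] = "L1", sub
    for sid, sub in zip(l2_ids, l2_subpop):
        true_group[sid], subpop[sid] = "L2", sub

    # --- hybrids ---------------------------------------------------------
    f1_ids = [f"F1-{i + 1:03d}" for i in range(cfg.n_f1)]
    ril_ids = [f"RIL-{i + 1:03d}" for i in range(cfg.n_ril)]
    hg_ids = [f"HG-{i + 1:03d}" for i in range(cfg.hybrid_group_size)]
    f1_parents: dict[str, tuple[str, str]] = {}
    ril_parents: dict[str, tuple[str, str]] = {}
    ancestry: dict[str, np.ndarray] = {}
    breakpoints: dict[str, dict[str, list[int]]] = {}

    def _record_breakpoints(anc: np.ndarray) -> dict[str, list[int]]:
        out: dict[str, list[int]] = {}
        for name, sl in zip(chrom_names, chrom_slices):
            seg = anc[sl]
            flips = np.flatnonzero(np.diff(seg)) + 1
            out[name] = [sites[sl.start + int(k)].position for k in flips]
        return out

    hybrid_rows: list[np.ndarray] = []
    for sid in f1_ids:
        i1 = int(rng.integers(cfg.n_l1))
        i2 = int(rng.integers(cfg.n_l2))
        f1_parents[sid] = (l1_ids[i1], l2_ids[i2])
        hybrid_rows.append((hap_l1[i1].astype(np.int8) + hap_l2[i2].astype(np.int8)))
        true_group[sid], subpop[sid] = "F1", "F1"
    for sid in ril_ids:
        i1 = int(rng.integers(cfg.n_l1))
        i2 = int(rng.integers(cfg.n_l2))
        ril_parents[sid] = (l1_ids[i1], l2_ids[i2])
        anc = _mosaic(rng, chrom_slices, cfg.ril_breakpoints_per_chrom, s)
        ancestry[sid] = anc
        breakpoints[sid] = _record_breakpoints(anc)
        hybrid_rows.append(
            (2 * np.where(anc == 0, hap_l1[i1], hap_l2[i2])).astype(np.int8)
        )
        true_group[sid], subpop[sid] = "RIL", "RIL"
    if cfg.hybrid_group_size > 0:
        # denser switching than a RIL: the hybrid lineage descends from
        # repeated intercrossing, so its private alleles interleave
        i1 = int(rng.integers(cfg.n_l1))
        i2 = int(rng.integers(cfg.n_l2))
        anc = _mosaic(rng, chrom_slices, cfg.hybrid_breakpoints_per_chrom, s)
        proto = (2 * np.where(anc == 0, hap_l1[i1], hap_l2[i2])).astype(np.int8)
        for sid in hg_ids:
            ril_parents[sid] = (l1_ids[i1], l2_ids[i2])
            ancestry[sid] = anc
            breakpoints[sid] = _record_breakpoints(anc)
            hybrid_rows.append(proto.copy())
            true_group[sid], subpop[sid] = "hybrid_lineage", "hybrid_lineage"

    # --- derived (wheat-like) panel --------------------------------------
    wheat_ids = [f"WH-{i + 1:03d}" for i in range(cfg.n_wheat)]
    if cfg.n_wheat > 0:
        founder_idx = rng.choice(cfg.n_l2, cfg.wheat_founder_count, replace=False)
        p_found = hap_l2[founder_idx].mean(axis=0)
        p_wheat = _balding_nichols(rng, p_found, cfg.divergence_f)
        _, dos_wheat = _inbred_draw(rng, p_wheat, cfg.n_wheat, cfg.residual_het)
    else:
        dos_wheat = np.zeros((0, s), dtype=np.int8)
    for sid in wheat_ids:
        true_group[sid], subpop[sid] = "wheat", "wheat"

    # --- assemble clean matrix -------------------------------------------
    sample_ids = l1_ids + l2_ids + f1_ids + ril_ids + hg_ids + wheat_ids
    blocks = [dos_l1, dos_l2]
    if hybrid_rows:
        blocks.append(np.vstack(hybrid_rows))
    blocks.append(dos_wheat)
    clean = np.vstack([b for b in blocks if b.shape[0] > 0]).astype(np.int8)
    idx_of = {sid: i for i, sid in enumerate(sample_ids)}
    l1_rows = np.array([idx_of[i] for i in l1_ids])
    l2_rows = np.array([idx_of[i] for i in l2_ids])
    hg_rows = np.array([idx_of[i] for i in hg_ids], dtype=np.intp)
    wheat_rows = np.array([idx_of[i] for i in wheat_ids], dtype=np.intp)

    # --- hybrid-group private alleles ------------------------------------
    gp_fixed_sites: list[str] = []
    gp_seg_sites: list[str] = []
    gp_allele: dict[str, str] = {}
    n_gp = cfg.hybrid_private_fixed + cfg.hybrid_private_segregating
    if n_gp > 0 and cfg.hybrid_group_size > 0:
        others = np.delete(np.arange(len(sample_ids)), hg_rows)
        background = clean[others]
        fixed0 = (background == 0).all(axis=0)
        fixed2 = (background == 2).all(axis=0)
        candidates = np.flatnonzero(fixed0 | fixed2)
        if len(candidates) < n_gp:
            raise ConfigurationError(
                f"only {len(candidates)} sites monomorphic outside the hybrid "
                f"group; {n_gp} group-private sites requested"
            )
        chosen = rng.choice(candidates, n_gp, replace=False)
        for k, j in enumerate(chosen):
            background_dosage = 0 if fixed0[j] else 2
            private_dosage = 2 - background_dosage
            gp_allele[sites[j].id] = "alt" if private_dosage == 2 else "ref"
            if k < cfg.hybrid_private_fixed:
                clean[hg_rows, j] = private_dosage
                gp_fixed_sites.append(sites[j].id)
            else:
                n_carry = int(rng.integers(1, cfg.hybrid_group_size))
                carriers = rng.choice(cfg.hybrid_group_size, n_carry, replace=False)
                clean[hg_rows, j] = background_dosage
                clean[hg_rows[carriers], j] = private_dosage
                gp_seg_sites.append(sites[j].id)

    # --- planted L1 introgressions in the derived panel -------------------
    intro_sites: list[str] = []
    intro_carriers: dict[str, list[str]] = {}
    single_sites: list[str] = []
    single_carriers: dict[str, list[str]] = {}
    n_intro = cfg.wheat_introgression_sites + cfg.wheat_single_carrier_sites
    if n_intro > 0:
        alt_l1 = clean[l1_rows]
        seg_l1 = (alt_l1 > 0).any(axis=0) & (alt_l1 < 2).any(axis=0)
        absent_l2 = (clean[l2_rows] == 0).all(axis=0)
        absent_wheat = (
            (clean[wheat_rows] == 0).all(axis=0)
            if cfg.n_wheat
            else np.ones(s, dtype=bool)
        )
        candidates = np.flatnonzero(seg_l1 & absent_l2 & absent_wheat)
        if len(candidates) < n_intro:
            raise ConfigurationError(
                f"only {len(candidates)} L1-private candidate sites; "
                f"{n_intro} introgression sites requested"
            )
        chosen = rng.choice(candidates, n_intro, replace=False)
        for k, j in enumerate(chosen):
            if k < cfg.wheat_introgression_sites:
                rows = rng.choice(
                    cfg.n_wheat, cfg.wheat_introgression_carriers, replace=False
                )
                clean[wheat_rows[rows], j] = 2
                intro_sites.append(sites[j].id)
                intro_carriers[sites[j].id] = sorted(wheat_ids[r] for r in rows)
            else:
                rows = rng.choice(cfg.n_wheat, 1, replace=False)
                clean[wheat_rows[rows], j] = 2
                single_sites.append(sites[j].id)
                single_carriers[sites[j].id] = sorted(wheat_ids[r] for r in rows)

    # --- noise: symmetric error, then missingness -------------------------
    calls = clean.copy()
    if cfg.error_rate > 0:
        flip = rng.random(calls.shape) < cfg.error_rate
        offset = rng.integers(1, 3, size=calls.shape).astype(np.int8)
        calls = np.where(flip, (calls + offset) % 3, calls).astype(np.int8)
    if cfg.missing_rate > 0:
        miss = rng.random(calls.shape) < cfg.missing_rate
        calls = np.where(miss, np.int8(MISSING), calls)

    gm = GenotypeMatrix(sample_ids, sites, calls)

    # --- passports ---------------------------------------------------------
    west_countries = ["Turkey", "Armenia", "Azerbaijan", "Georgia", "Syria"]
    east_countries = ["Afghanistan", "Tajikistan", "Turkmenistan", "Uzbekistan", "China"]
    records: list[SampleRecord] = []
    for sid in sample_ids:
        grp = true_group[sid]
        sub = subpop[sid]
        if grp == "L1":
            if sub == "L1_west":
                country = west_countries[int(rng.integers(len(west_countries)))]
                lon = float(rng.normal(44.0, 2.0))
            else:
                country = east_countries[int(rng.integers(len(east_countries)))]
                lon = float(rng.normal(68.0, 4.0))
            rec = SampleRecord(sid, "L1", country, lon,
                               float(rng.normal(38.0, 1.5)),
                               float(rng.normal(1300.0, 300.0)))
        elif grp == "L2":
            alt = (float(rng.uniform(0.0, 140.0)) if sub == "L2_low"
                   else float(rng.uniform(160.0, 1200.0)))
            rec = SampleRecord(sid, "L2", "Iran" if rng.random() < 0.6 else "Azerbaijan",
                               float(rng.normal(49.0, 1.5)),
                               float(rng.normal(37.5, 1.5)), alt)
        elif grp == "wheat":
            rec = SampleRecord(sid, "wheat", "United States")
        elif grp == "hybrid_lineage":
            rec = SampleRecord(sid, "hybrid", "Georgia",
                               float(rng.normal(44.8, 0.5)),
                               float(rng.normal(41.7, 0.5)),
                               float(rng.normal(600.0, 150.0)))
        else:  # F1 / RIL: provenance unknown
            rec = SampleRecord(sid, "hybrid", None)
        records.append(rec)

    # --- phenotypes ---------------------------------------------------------
    traits = ["leaf_rust", "stem_rust_ttksk", "hessian_fly"]
    res_prob = {
        "L1": [0.55, 0.35, 0.60],
        "L2": [0.25, 0.50, 0.30],
        "F1": [0.40, 0.40, 0.40],
        "RIL": [0.40, 0.40, 0.40],
        "hybrid_lineage": [0.40, 0.40, 0.40],
        "wheat": [0.10, 0.15, 0.10],
    }
    scores: dict[str, dict[str, str]] = {}
    for sid in sample_ids:
        probs = res_prob[true_group[sid]]
        entry = {}
        for trait, pr in zip(traits, probs):
            if rng.random() < 0.1:  # unscored
                continue
            entry[trait] = "R" if rng.random() < pr else "S"
        scores[sid] = entry
    phenotypes = PhenotypeTable(traits=traits, scores=scores)

    truth = SimTruth(
        true_group=true_group,
        subpop=subpop,
        f1_parents=f1_parents,
        ril_parents=ril_parents,
        ancestry=ancestry,
        breakpoints=breakpoints,
        introgression_sites=intro_sites,
        introgression_carriers=intro_carriers,
        single_carrier_sites=single_sites,
        single_carrier_carriers=single_carriers,
        group_private_fixed_sites=gp_fixed_sites,
        group_private_segregating_sites=gp_seg_sites,
        group_private_allele=gp_allele,
        clean_calls=clean,
    )
    return gm, records, phenotypes, truth


def write_fixture(cfg: SimConfig, out_dir: str | Path, force: bool = False) -> list[Path]:
    """Write panel.vcf, passport.tsv, phenotypes.tsv and truth tables to a directory."""
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not force:
        raise FileExistsError(f"{out_dir} is not empty (pass force=True to overwrite)")
    out_dir.mkdir(parents=True, exist_ok=True)
    gm, records, phenotypes, truth = simulate_panel(cfg)
    paths = {
        "vcf": out_dir / "panel.vcf",
        "passport": out_dir / "passport.tsv",
        "phenotypes": out_dir / "phenotypes.tsv",
        "truth_samples": out_dir / "truth_samples.tsv",
        "truth_sites": out_dir / "truth_sites.tsv",
    }
    write_vcf(gm, paths["vcf"])
    write_passport(records, paths["passport"])
    write_phenotypes(phenotypes, paths["phenotypes"])
    with open(paths["truth_samples"], "w") as fh:
        fh.write("id\ttrue_group\tsubpop\tparent_l1\tparent_l2\n")
        for sid in gm.samples:
            parents = truth.f1_parents.get(sid) or truth.ril_parents.get(sid) or ("", "")
            fh.write(
                f"{sid}\t{truth.true_group[sid]}\t{truth.subpop[sid]}"
                f"\t{parents[0]}\t{parents[1]}\n"
            )
    with open(paths["truth_sites"], "w") as fh:
        fh.write("site\trole\tcarriers\n")
        for site in truth.introgression_sites:
            fh.write(f"{site}\tintrogression\t{';'.join(truth.introgression_carriers[site])}\n")
        for site in truth.single_carrier_sites:
            fh.write(f"{site}\tsingle_carrier\t{';'.join(truth.single_carrier_carriers[site])}\n")
        for site in truth.group_private_fixed_sites:
            fh.write(f"{site}\thybrid_private_fixed\t\n")
        for site in truth.group_private_segregating_sites:
            fh.write(f"{site}\thybrid_private_segregating\t\n")
    return list(paths.values())
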