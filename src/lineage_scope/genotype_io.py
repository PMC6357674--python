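"""Genotype matrices, sample passports and phenotype tables.

The central container is :class:`GenotypeMatrix`: a samples x sites array of
alternate-allele dosages for diploid biallelic SNPs.  Calls are stored as
``int8`` with values 0 (hom ref), 1 (het), 2 (hom alt) and :data:`MISSING`
(-1) for no-calls.  The panel this models is a selfing species, so
heterozygosity is residual and phase is never tracked.

Supported exchange formats are VCF v4.2 (GT-only, read through cyvcf2) and
the tab-separated HapMap layout common in GBS pipelines, plus TSV passport
and phenotype tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for a missing genotype call.  Never a valid dosage.
MISSING: int = -1

_IUPAC_HET = {
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("CG"): "S",
    frozenset("AT"): "W",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
}


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


class ValidationError(ValueError):
    """Raised when parsed data violates a domain invariant."""


@dataclass(frozen=True)
class SnpSite:
    """A biallelic SNP site (1-based position, single-base alleles)."""

    id: str
    chromosome: str
    position: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValidationError(f"site {self.id}: position must be >= 1")
        if self.ref_allele == self.alt_allele:
            raise ValidationError(f"site {self.id}: ref and alt alleles are equal")


@dataclass(frozen=True)
class SampleRecord:
    """Passport entry for one accession; geographic fields may be missing (NaN)."""

    id: str
    group: str = "unknown"
    country: str | None = None
    longitude: float = float("nan")
    latitude: float = float("nan")
    altitude: float = float("nan")

    def __post_init__(self) -> None:
        if np.isfinite(self.latitude) and abs(self.latitude) > 90:
            raise ValidationError(f"sample {self.id}: |latitude| > 90")
        if np.isfinite(self.longitude) and abs(self.longitude) > 180:
            raise ValidationError(f"sample {self.id}: |longitude| > 180")


@dataclass
class PhenotypeTable:
    """Binary trait scores per sample: ``scores[sample][trait] -> 'R'|'S'`` (missing = absent)."""

    traits: list[str]
    scores: dict[str, dict[str, str]]

    def __post_init__(self) -> None:
        if len(set(self.traits)) != len(self.traits):
            raise ValidationError("duplicate trait names")

    def get(self, sample: str, trait: str) -> str | None:
        return self.scores.get(sample, {}).get(trait)


@dataclass
class GenotypeMatrix:
    """Samples x sites dosage matrix with site metadata.

    ``calls[i, j]`` is the alternate-allele dosage of sample ``i`` at site
    ``j`` (0/1/2) or :data:`MISSING`.  Sites are kept sorted by
    (chromosome, position, id); loaders enforce this.
    """

    samples: list[str]
    sites: list[SnpSite]
    calls: np.ndarray  # int8, shape (n_samples, n_sites)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.sites)):
            raise ValidationError(
                f"calls shape {self.calls.shape} != "
                f"({len(self.samples)}, {len(self.sites)})"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ValidationError("duplicate sample ids")
        ids = [s.id for s in self.sites]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate site ids")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValidationError("calls contain values outside {0,1,2,missing}")

    # -- basic accessors -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def site_ids(self) -> list[str]:
        return [s.id for s in self.sites]

    def sample_indices(self, ids: Iterable[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.asarray([lookup[i] for i in ids], dtype=np.intp)
        except KeyError as exc:  # pragma: no cover - defensive
            raise KeyError(f"unknown sample id {exc}") from None

    def site_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [s.id for s in self.sites],
                "chromosome": [s.chromosome for s in self.sites],
                "position": [s.position for s in self.sites],
                "ref": [s.ref_allele for s in self.sites],
                "alt": [s.alt_allele for s in self.sites],
            }
        )

    # -- subsetting ------------------------------------------------------

    def subset_samples(self, ids: Sequence[str]) -> "GenotypeMatrix":
        idx = self.sample_indices(ids)
        return GenotypeMatrix(list(ids), self.sites, self.calls[idx])

    def subset_sites(self, keep: np.ndarray) -> "GenotypeMatrix":
        """``keep``: boolean mask or integer index array over sites."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        sites = [self.sites[j] for j in keep]
        return GenotypeMatrix(list(self.samples), sites, self.calls[:, keep])

    def sorted_sites(self) -> "GenotypeMatrix":
        order = sorted(
            range(self.n_sites),
            key=lambda j: (
                self.sites[j].chromosome,
                self.sites[j].position,
                self.sites[j].id,
            ),
        )
        if order == list(range(self.n_sites)):
            return self
        return self.subset_sites(np.asarray(order, dtype=np.intp))

    # -- frequencies -----------------------------------------------------

    def alt_freq(self, sample_idx: np.ndarray | None = None) -> np.ndarray:
        """Alternate-allele frequency per site over non-missing calls (NaN if none)."""
        calls = self.calls if sample_idx is None else self.calls[sample_idx]
        obs = calls != MISSING
        n_alleles = 2 * obs.sum(axis=0)
        alt = np.where(obs, calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_alleles > 0, alt / n_alleles, np.nan)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.samples == other.samples
            and self.sites == other.sites
            and np.array_equal(self.calls, other.calls)
        )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Load biallelic SNP records from a VCF into a :class:`GenotypeMatrix`.

    Multiallelic and non-SNP records are skipped (count logged).  GT fields
    map to dosage: 0/0 -> 0, 0/1 or 1/0 -> 1, 1/1 -> 2, ./. -> missing.
    """
    import cyvcf2

    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    vcf = cyvcf2.VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    sites: list[SnpSite] = []
    rows: list[np.ndarray] = []
    skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            skipped += 1
            continue
        site_id = var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}"
        sites.append(SnpSite(site_id, var.CHROM, var.POS, var.REF, var.ALT[0]))
        # with gts012=True: 0=hom ref, 1=het, 2=hom alt, 3=unknown
        gt = np.asarray(var.gt_types, dtype=np.int8)
        gt[gt == 3] = MISSING
        rows.append(gt)
    vcf.close()
    if skipped:
        logger.info("read_vcf: skipped %d multiallelic/non-SNP records", skipped)
    if not sites:
        raise FormatError(f"{path}: no biallelic SNP records")
    calls = np.stack(rows, axis=1)
    return GenotypeMatrix(samples, sites, calls).sorted_sites()


_GT_CODE = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF v4.2 with a GT-only FORMAT column."""
    path = Path(path)
    chroms = list(dict.fromkeys(s.chromosome for s in gm.sites))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        for j, site in enumerate(gm.sites):
            gts = "\t".join(_GT_CODE[int(c)] for c in gm.calls[:, j])
            fh.write(
                f"{site.chromosome}\t{site.position}\t{site.id}\t"
                f"{site.ref_allele}\t{site.alt_allele}\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# HapMap
# ---------------------------------------------------------------------------

_HAPMAP_META = [
    "rs#", "alleles", "chrom", "pos", "strand", "assembly#",
    "center", "protLSID", "assayLSID", "panelLSID", "QCcode",
]


def read_hapmap(path: str | Path) -> GenotypeMatrix:
    """Read a HapMap-style TSV (11 metadata columns, then one column per sample).

    Genotypes may be single-letter IUPAC codes or two-letter pairs; ``N`` /
    ``NN`` is missing.  Alleles come from the ``alleles`` column ("A/G").
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[: len(_HAPMAP_META)]) != _HAPMAP_META:
        raise FormatError(f"{path}: not a HapMap header")
    samples = list(df.columns[len(_HAPMAP_META):])
    if not samples:
        raise FormatError(f"{path}: no sample columns")
    sites: list[SnpSite] = []
    rows: list[list[int]] = []
    for _, row in df.iterrows():
        alleles = str(row["alleles"]).split("/")
        if len(alleles) != 2 or any(len(a) != 1 for a in alleles):
            raise FormatError(f"{path}: bad alleles field {row['alleles']!r}")
        ref, alt = alleles
        het = _IUPAC_HET.get(frozenset((ref, alt)))
        site = SnpSite(str(row["rs#"]), str(row["chrom"]), int(row["pos"]), ref, alt)
        dosages = []
        for s in samples:
            code = str(row[s]).strip().upper()
            dosages.append(_hapmap_dosage(code, ref, alt, het, site.id))
        sites.append(site)
        rows.append(dosages)
    calls = np.asarray(rows, dtype=np.int8).T
    return GenotypeMatrix(samples, sites, calls).sorted_sites()


def _hapmap_dosage(code: str, ref: str, alt: str, het: str | None, site_id: str) -> int:
    if code in ("N", "NN", "", "NAN"):
        return MISSING
    if len(code) == 1:
        if code == ref:
            return 0
        if code == alt:
            return 2
        if het is not None and code == het:
            return 1
        raise FormatError(f"site {site_id}: unexpected genotype code {code!r}")
    if len(code) == 2:
        a, b = code[0], code[1]
        if {a, b} <= {ref, alt}:
            return int(a == alt) + int(b == alt)
        raise FormatError(f"site {site_id}: genotype {code!r} outside alleles {ref}/{alt}")
    raise FormatError(f"site {site_id}: malformed genotype code {code!r}")


def write_hapmap(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write the matrix as a HapMap-style TSV with two-letter genotype codes."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t".join(_HAPMAP_META + gm.samples) + "\n")
        for j, site in enumerate(gm.sites):
            codes = []
            for c in gm.calls[:, j]:
                c = int(c)
                if c == MISSING:
                    codes.append("NN")
                elif c == 0:
                    codes.append(site.ref_allele * 2)
                elif c == 2:
                    codes.append(site.alt_allele * 2)
                else:
                    codes.append(site.ref_allele + site.alt_allele)
            meta = [
                site.id, f"{site.ref_allele}/{site.alt_allele}", site.chromosome,
                str(site.position), "+", "NA", "NA", "NA", "NA", "NA", "NA",
            ]
            fh.write("\t".join(meta + codes) + "\n")


# ---------------------------------------------------------------------------
# Passport / phenotype tables
# ---------------------------------------------------------------------------

_PASSPORT_COLS = ["id", "group", "country", "longitude", "latitude", "altitude"]


def read_passport(path: str | Path) -> list[SampleRecord]:
    """Read a passport TSV (id, group, country, longitude, latitude, altitude)."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "group": str, "country": str})
    missing_cols = set(_PASSPORT_COLS) - set(df.columns)
    if missing_cols:
        raise FormatError(f"{path}: missing columns {sorted(missing_cols)}")
    if df["id"].duplicated().any():
        dups = df.loc[df["id"].duplicated(), "id"].tolist()
        raise ValidationError(f"duplicate sample ids in passport: {dups}")
    records = []
    for _, row in df.iterrows():
        records.append(
            SampleRecord(
                id=str(row["id"]),
                group=str(row["group"]) if pd.notna(row["group"]) else "unknown",
                country=str(row["country"]) if pd.notna(row["country"]) else None,
                longitude=float(row["longitude"]) if pd.notna(row["longitude"]) else float("nan"),
                latitude=float(row["latitude"]) if pd.notna(row["latitude"]) else float("nan"),
                altitude=float(row["altitude"]) if pd.notna(row["altitude"]) else float("nan"),
            )
        )
    return records


def write_passport(records: Sequence[SampleRecord], path: str | Path) -> None:
    def fmt(x: float) -> str:
        return "" if not np.isfinite(x) else f"{x:.6g}"

    with open(path, "w") as fh:
        fh.write("\t".join(_PASSPORT_COLS) + "\n")
        for r in records:
            fh.write(
                "\t".join(
                    [r.id, r.group, r.country or "",
                     fmt(r.longitude), fmt(r.latitude), fmt(r.altitude)]
                )
                + "\n"
            )


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    """Read a phenotype TSV: first column ``id``, then one column per trait (R/S/blank)."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.columns[0] != "id":
        raise FormatError(f"{path}: first column must be 'id'")
    traits = list(df.columns[1:])
    scores: dict[str, dict[str, str]] = {}
    for _, row in df.iterrows():
        entry = {}
        for t in traits:
            v = row[t]
            if pd.notna(v) and str(v).strip():
                entry[t] = str(v).strip()
        scores[str(row["id"])] = entry
    return PhenotypeTable(traits=traits, scores=scores)


def write_phenotypes(table: PhenotypeTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(["id"] + table.traits) + "\n")
        for sample in table.scores:
            row = [sample] + [table.scores[sample].get(t, "") for t in table.traits]
            fh.write("\t".join(row) + "\n")
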