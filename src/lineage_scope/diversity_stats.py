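"""Group-wise diversity and differentiation statistics.

Implements Nei's gene diversity (expected heterozygosity, h = 1 - sum f_a^2
per site, averaged over sites), pairwise Hudson F_ST with ratio-of-sums
averaging across sites, and per-group minor-allele-frequency spectra.

Hudson's estimator is used because it behaves well under unequal sample
sizes and its ratio-of-sums form has a clean interpretation under the
Balding-Nichols divergence model used by the bundled simulator.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, SampleRecord

logger = logging.getLogger(__name__)


@dataclass
class GroupPartition:
    """Assignment of sample ids to named groups (each id in exactly one group)."""

    mapping: dict[str, str]

    @classmethod
    def from_passport(cls, records: Sequence[SampleRecord]) -> "GroupPartition":
        return cls({r.id: r.group for r in records})

    @property
    def groups(self) -> list[str]:
        return sorted(set(self.mapping.values()))

    def samples(self, group: str) -> list[str]:
        if group not in set(self.mapping.values()):
            raise KeyError(f"unknown group {group!r}")
        return [s for s, g in self.mapping.items() if g == group]

    def group_of(self, sample: str) -> str:
        return self.mapping.get(sample, "unknown")

    def restrict(self, sample_ids: Iterable[str]) -> "GroupPartition":
        ids = set(sample_ids)
        return GroupPartition({s: g for s, g in self.mapping.items() if s in ids})


@dataclass
class DiversityReport:
    """Nei gene diversity for one sample subset."""

    nei_index: float
    n_sites_used: int
    per_site: np.ndarray  # NaN where the subset has no calls


@dataclass
class FstReport:
    """Pairwise Hudson F_ST between groups (ratio of sums over sites)."""

    values: dict[tuple[str, str], float]
    numerators: dict[tuple[str, str], float]
    denominators: dict[tuple[str, str], float]
    n_sites_used: dict[tuple[str, str], int]

    def get(self, a: str, b: str) -> float:
        if a == b:
            return 0.0
        key = (a, b) if (a, b) in self.values else (b, a)
        return self.values[key]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "group_a": a,
                "group_b": b,
                "fst": v,
                "n_sites": self.n_sites_used[(a, b)],
            }
            for (a, b), v in sorted(self.values.items())
        ]
        return pd.DataFrame(rows)


@dataclass
class MafSpectrum:
    """Per-group MAF vectors plus the joint per-site table."""

    per_group: dict[str, np.ndarray]
    joint: pd.DataFrame
    #: sites segregating in one group while fixed (MAF 0) in the other
    exclusive_counts: dict[str, int] = field(default_factory=dict)


def nei_diversity(
    gm: GenotypeMatrix,
    sample_ids: Sequence[str] | None = None,
    polymorphic_only: bool = False,
) -> DiversityReport:
    """Nei (1973) gene diversity averaged over sites for a sample subset.

    Per site ``h = 2 f (1 - f)`` with ``f`` the alternate-allele frequency
    within the subset (non-missing calls only).  Sites with no calls in the
    subset are skipped; monomorphic sites contribute h = 0 unless
    ``polymorphic_only`` is set.
    """
    if sample_ids is not None and len(sample_ids) == 0:
        raise ValueError("empty sample subset")
    idx = None if sample_ids is None else gm.sample_indices(sample_ids)
    f = gm.alt_freq(idx)
    h = 2.0 * f * (1.0 - f)
    used = np.isfinite(h)
    if polymorphic_only:
        used &= h > 0
    n_used = int(used.sum())
    if n_used == 0:
        raise ValueError("no usable sites in subset")
    return DiversityReport(
        nei_index=float(h[used].mean()), n_sites_used=n_used, per_site=h
    )


def _group_freq_counts(
    gm: GenotypeMatrix, sample_idx: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (alt frequency, allele-call count) for a sample subset."""
    calls = gm.calls[sample_idx]
    obs = calls != MISSING
    n = 2 * obs.sum(axis=0)
    alt = np.where(obs, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / np.maximum(n, 1), np.nan)
    return p, n


def hudson_fst_sums(
    p1: np.ndarray, n1: np.ndarray, p2: np.ndarray, n2: np.ndarray
) -> tuple[float, float, int]:
    """Hudson F_ST numerator/denominator sums over usable sites.

    Per site: num = (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1),
    den = p1(1-p2) + p2(1-p1); sites need n_i >= 2 alleles in both groups
    and den > 0.
    """
    ok = (n1 >= 2) & (n2 >= 2) & np.isfinite(p1) & np.isfinite(p2)
    p1, n1, p2, n2 = p1[ok], n1[ok], p2[ok], n2[ok]
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    use = den > 0
    return float(num[use].sum()), float(den[use].sum()), int(use.sum())


def pairwise_fst(
    gm: GenotypeMatrix,
    partition: GroupPartition,
    groups: Sequence[str] | None = None,
) -> FstReport:
    """Pairwise Hudson F_ST among groups, ratio-of-sums across sites.

    Values are reported unclamped; a negative estimate (possible under no
    differentiation) triggers a warning, not an error.
    """
    present = set(gm.samples)
    if groups is None:
        groups = [g for g in partition.groups if any(s in present for s in partition.samples(g))]
    cache: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for g in groups:
        ids = [s for s in partition.samples(g) if s in present]
        if len(ids) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 genotyped samples")
        cache[g] = _group_freq_counts(gm, gm.sample_indices(ids))
    values, nums, dens, nsites = {}, {}, {}, {}
    for a, b in combinations(groups, 2):
        p1, n1 = cache[a]
        p2, n2 = cache[b]
        num, den, n_used = hudson_fst_sums(p1, n1, p2, n2)
        if den == 0:
            raise ValueError(f"no usable sites for pair ({a}, {b})")
        fst = num / den
        if fst < 0:
            warnings.warn(f"negative F_ST estimate for ({a}, {b}): {fst:.4g}")
        values[(a, b)] = fst
        nums[(a, b)], dens[(a, b)], nsites[(a, b)] = num, den, n_used
    return FstReport(values, nums, dens, nsites)


def maf_spectrum(
    gm: GenotypeMatrix,
    partition: GroupPartition,
    groups: Sequence[str] = ("L1", "L2"),
) -> MafSpectrum:
    """Per-group minor-allele-frequency vectors and the joint per-site table."""
    present = set(gm.samples)
    per_group: dict[str, np.ndarray] = {}
    for g in groups:
        ids = [s for s in partition.samples(g) if s in present]
        if not ids:
            raise ValueError(f"group {g!r} has no genotyped samples")
        f = gm.alt_freq(gm.sample_indices(ids))
        per_group[g] = np.minimum(f, 1 - f)
    joint = pd.DataFrame({"site": gm.site_ids})
    for g in groups:
        joint[f"maf_{g}"] = per_group[g]
    exclusive: dict[str, int] = {}
    if len(groups) == 2:
        a, b = groups
        ma, mb = per_group[a], per_group[b]
        exclusive[a] = int(np.nansum((ma > 0) & (mb == 0)))
        exclusive[b] = int(np.nansum((mb > 0) & (ma == 0)))
    return MafSpectrum(per_group=per_group, joint=joint, exclusive_counts=exclusive)
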