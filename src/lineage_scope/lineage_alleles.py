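"""Lineage-private allele machinery: hybrids, painting, parentage, introgression.

A lineage-private allele is one segregating within one lineage (frequency
strictly between 0 and 1) while entirely absent (frequency exactly 0) from
the other.  Fixed inter-lineage differences are excluded — they separate
the lineages but say nothing about within-lineage ancestry.  Private
alleles are diagnostic of ancestry and drive four analyses:

* per-sample lineage contribution (share of private-allele copies from
  each lineage) and hybrid flagging;
* chromosome painting: the ordered sequence of private-allele lineages
  along each chromosome, whose switch count and "clarity" separate clean
  recombinant mosaics from diffuse admixture;
* parentage matching: percent identity at private sites between a hybrid
  and candidate parents from each lineage;
* the consensus introgression rule for a derived panel: a private site is
  assigned to the minor donor lineage only when at least ``min_carriers``
  independent derived lines carry its private allele.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diversity_stats import GroupPartition
from .genotype_io import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class PrivateAlleleTable:
    """Per-site record of which allele is private to which lineage.

    ``table`` columns: site (id), site_index, lineage, allele ('ref'/'alt'),
    freq (private-allele frequency within the donor lineage), calls_<lin>.
    """

    table: pd.DataFrame
    lineages: tuple[str, str]

    def __len__(self) -> int:
        return len(self.table)

    def counts(self) -> dict[str, int]:
        return self.table["lineage"].value_counts().to_dict()

    def private_dosage(self, gm: GenotypeMatrix, sample_rows: np.ndarray) -> np.ndarray:
        """Dosage of each private allele for the given sample rows.

        Shape (n_rows, n_entries); missing calls map to -1.
        """
        j = self.table["site_index"].to_numpy()
        calls = gm.calls[np.ix_(sample_rows, j)].astype(np.int16)
        is_alt = (self.table["allele"] == "alt").to_numpy()
        dos = np.where(is_alt, calls, 2 - calls)
        dos[calls == MISSING] = -1
        return dos


@dataclass
class PaintingTrack:
    """Ordered lineage labels at private-allele sites carried by one sample."""

    sample: str
    #: chromosome -> list of (position, lineage) events, position-sorted
    events: dict[str, list[tuple[int, str]]]
    switch_count: int
    informative: int
    clarity: float

    def to_bed(self) -> pd.DataFrame:
        """Runs of one lineage label as 0-based half-open BED intervals."""
        rows = []
        for chrom, evts in self.events.items():
            if not evts:
                continue
            start_pos, label = evts[0][0], evts[0][1]
            prev_pos = start_pos
            for pos, lab in evts[1:]:
                if lab != label:
                    rows.append((chrom, start_pos - 1, prev_pos, label))
                    start_pos, label = pos, lab
                prev_pos = pos
            rows.append((chrom, start_pos - 1, prev_pos, label))
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "lineage"])


def find_private_alleles(
    gm: GenotypeMatrix,
    partition: GroupPartition,
    lineages: tuple[str, str] = ("L1", "L2"),
    min_call_fraction: float = 0.5,
) -> PrivateAlleleTable:
    """Identify alleles segregating in one lineage and absent from the other.

    A site yields an allele private to lineage A iff the allele frequency
    is 0 in lineage B, strictly inside (0, 1) in lineage A, and both
    lineages have at least ``min_call_fraction`` non-missing calls there.
    Fixed differences (1 vs 0) are excluded.
    """
    lin_a, lin_b = lineages
    present = set(gm.samples)
    rows = {}
    for lin in lineages:
        ids = [s for s in partition.samples(lin) if s in present]
        if not ids:
            raise ValueError(f"lineage {lin!r} has no samples in the matrix")
        rows[lin] = gm.sample_indices(ids)
    freq, calls_frac, n_calls = {}, {}, {}
    for lin in lineages:
        calls = gm.calls[rows[lin]]
        obs = calls != MISSING
        n = obs.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq[lin] = np.where(n > 0, np.where(obs, calls, 0).sum(axis=0) / np.maximum(2 * n, 1), np.nan)
        calls_frac[lin] = n / len(rows[lin])
        n_calls[lin] = n
    callable_ = (calls_frac[lin_a] >= min_call_fraction) & (
        calls_frac[lin_b] >= min_call_fraction
    ) & (n_calls[lin_a] > 0) & (n_calls[lin_b] > 0)

    entries = []
    for donor, other in ((lin_a, lin_b), (lin_b, lin_a)):
        fd, fo = freq[donor], freq[other]
        # alt allele private to donor
        alt_mask = callable_ & (fo == 0) & (fd > 0) & (fd < 1)
        for j in np.flatnonzero(alt_mask):
            entries.append((gm.sites[j].id, j, donor, "alt", fd[j],
                            n_calls[lin_a][j], n_calls[lin_b][j]))
        # ref allele private to donor (alt fixed in the other lineage)
        ref_mask = callable_ & (fo == 1) & (fd > 0) & (fd < 1)
        for j in np.flatnonzero(ref_mask):
            entries.append((gm.sites[j].id, j, donor, "ref", 1 - fd[j],
                            n_calls[lin_a][j], n_calls[lin_b][j]))
    table = pd.DataFrame(
        entries,
        columns=["site", "site_index", "lineage", "allele", "freq",
                 f"calls_{lin_a}", f"calls_{lin_b}"],
    ).sort_values(["site_index", "lineage"], kind="stable").reset_index(drop=True)
    return PrivateAlleleTable(table=table, lineages=lineages)


def lineage_contribution(
    gm: GenotypeMatrix,
    pat: PrivateAlleleTable,
    samples: list[str] | None = None,
) -> pd.DataFrame:
    """Per-sample counts and percentages of private-allele copies per lineage.

    Copies are dosage-weighted (a het carries one copy, a hom two); the
    informative-site count is the number of private sites where the sample
    carries at least one copy.  Samples with zero informative sites get
    NaN percentages (warned).
    """
    if samples is None:
        samples = list(gm.samples)
    lin_a, lin_b = pat.lineages
    rows = gm.sample_indices(samples)
    dos = pat.private_dosage(gm, rows)  # (n_samples, n_entries), -1 missing
    carried = np.where(dos > 0, dos, 0)
    is_a = (pat.table["lineage"] == lin_a).to_numpy()
    count_a = carried[:, is_a].sum(axis=1)
    count_b = carried[:, ~is_a].sum(axis=1)
    informative = (carried > 0).sum(axis=1)
    total = count_a + count_b
    with np.errstate(invalid="ignore", divide="ignore"):
        pct_a = np.where(total > 0, count_a / np.maximum(total, 1), np.nan)
    if (total == 0).any():
        warnings.warn(
            f"{int((total == 0).sum())} sample(s) carry no private alleles"
        )
    return pd.DataFrame(
        {
            "sample": samples,
            f"count_{lin_a}": count_a,
            f"count_{lin_b}": count_b,
            f"pct_{lin_a}": pct_a,
            f"pct_{lin_b}": 1 - pct_a,
            "informative": informative,
        }
    )


def classify_hybrids(
    gm: GenotypeMatrix,
    pat: PrivateAlleleTable,
    partition: GroupPartition | None = None,
    minor_fraction_min: float = 0.10,
    min_informative: int = 100,
    samples: list[str] | None = None,
) -> pd.DataFrame:
    """Flag samples with substantial private-allele contribution from both lineages.

    A sample is flagged when its minor-lineage contribution is at least
    ``minor_fraction_min`` with at least ``min_informative`` informative
    sites.  The report is sorted by minor fraction, descending.
    """
    contrib = lineage_contribution(gm, pat, samples)
    lin_a, _ = pat.lineages
    minor = np.minimum(contrib[f"pct_{lin_a}"], 1 - contrib[f"pct_{lin_a}"])
    contrib = contrib.assign(minor_fraction=minor)
    if partition is not None:
        contrib["group"] = [partition.group_of(s) for s in contrib["sample"]]
    flagged = contrib[
        (contrib["minor_fraction"] >= minor_fraction_min)
        & (contrib["informative"] >= min_informative)
    ]
    return flagged.sort_values(
        "minor_fraction", ascending=False, kind="stable"
    ).reset_index(drop=True)


def paint_sample(gm: GenotypeMatrix, pat: PrivateAlleleTable, sample: str) -> PaintingTrack:
    """Chromosome painting of one sample by carried private alleles.

    Events are (position, donor lineage) at every private site where the
    sample carries the private allele; switches are adjacent unequal labels
    within a chromosome; clarity = 1 - switches / max(informative - 1, 1).
    """
    row = gm.sample_indices([sample])
    dos = pat.private_dosage(gm, row)[0]
    carried = dos > 0
    events: dict[str, list[tuple[int, str]]] = {}
    for k in np.flatnonzero(carried):
        j = int(pat.table["site_index"].iloc[k])
        site = gm.sites[j]
        events.setdefault(site.chromosome, []).append(
            (site.position, pat.table["lineage"].iloc[k])
        )
    switches = 0
    informative = int(carried.sum())
    for chrom in events:
        events[chrom].sort(key=lambda e: e[0])
        labels = [lab for _, lab in events[chrom]]
        switches += sum(a != b for a, b in zip(labels, labels[1:]))
    clarity = 1 - switches / max(informative - 1, 1)
    return PaintingTrack(
        sample=sample, events=events, switch_count=switches,
        informative=informative, clarity=clarity,
    )


def parentage_match(
    gm: GenotypeMatrix,
    pat: PrivateAlleleTable,
    sample: str,
    partition: GroupPartition,
    candidate_groups: tuple[str, ...] = ("L1", "L2"),
    exclude: set[str] | None = None,
    mode: str = "share",
) -> dict[str, pd.DataFrame]:
    """Rank candidate parents from each lineage by identity at private sites.

    Identity is the share of private-allele sites co-genotyped in query and
    candidate where the genotypes match.  ``mode='share'`` (default) counts
    a match when the two genotypes share at least one allele (only opposite
    homozygotes mismatch), which reduces to dosage equality on inbred data
    but scores an F1 correctly against its true parents;
    ``mode='exact'`` requires equal dosage.  Returns, per group, the full
    ranking (best first) with percent identities.
    """
    if mode not in ("share", "exact"):
        raise ValueError("mode must be 'share' or 'exact'")
    exclude = set(exclude or ())
    exclude.add(sample)
    present = set(gm.samples)
    q = pat.private_dosage(gm, gm.sample_indices([sample]))[0]
    out: dict[str, pd.DataFrame] = {}
    for group in candidate_groups:
        candidates = [
            s for s in partition.samples(group) if s in present and s not in exclude
        ]
        rows = []
        if candidates:
            c_dos = pat.private_dosage(gm, gm.sample_indices(candidates))
            for name, cd in zip(candidates, c_dos):
                both = (q >= 0) & (cd >= 0)
                n = int(both.sum())
                if n == 0:
                    warnings.warn(f"no co-genotyped private sites with {name}; skipped")
                    continue
                if mode == "share":
                    match = np.abs(q[both] - cd[both]) < 2
                else:
                    match = q[both] == cd[both]
                rows.append({"candidate": name, "identity_pct": 100 * match.mean(), "n_sites": n})
        ranking = pd.DataFrame(rows, columns=["candidate", "identity_pct", "n_sites"])
        if len(ranking):
            ranking = ranking.sort_values(
                ["identity_pct", "candidate"], ascending=[False, True], kind="stable"
            ).reset_index(drop=True)
        out[group] = ranking
    return out


def group_private_alleles(
    gm: GenotypeMatrix,
    partition: GroupPartition,
    target_group: str,
    background_groups: tuple[str, ...],
) -> tuple[pd.DataFrame, int, int]:
    """Alleles carried by the target group and absent from every background group.

    Returns (site table, n fixed in target, n segregating in target).
    Frequencies use non-missing calls; a qualifying allele has frequency 0
    in the pooled background and > 0 in the target.
    """
    target_ids = set(partition.samples(target_group))
    bg_ids: set[str] = set()
    for g in background_groups:
        bg_ids |= set(partition.samples(g))
    if target_ids & bg_ids:
        raise ValueError("target and background groups overlap")
    present = set(gm.samples)
    t_rows = gm.sample_indices([s for s in gm.samples if s in target_ids & present])
    b_rows = gm.sample_indices([s for s in gm.samples if s in bg_ids & present])
    if len(t_rows) == 0 or len(b_rows) == 0:
        raise ValueError("target or background has no genotyped samples")
    ft = gm.alt_freq(t_rows)
    fb = gm.alt_freq(b_rows)
    ok = np.isfinite(ft) & np.isfinite(fb)
    entries = []
    alt_private = ok & (fb == 0) & (ft > 0)
    for j in np.flatnonzero(alt_private):
        entries.append((gm.sites[j].id, int(j), "alt", ft[j], bool(ft[j] == 1)))
    ref_private = ok & (fb == 1) & (ft < 1)
    for j in np.flatnonzero(ref_private):
        entries.append((gm.sites[j].id, int(j), "ref", 1 - ft[j], bool(ft[j] == 0)))
    table = pd.DataFrame(
        entries, columns=["site", "site_index", "allele", "target_freq", "fixed"]
    ).sort_values("site_index", kind="stable").reset_index(drop=True)
    n_fixed = int(table["fixed"].sum())
    return table, n_fixed, len(table) - n_fixed


def consensus_introgression(
    gm: GenotypeMatrix,
    pat: PrivateAlleleTable,
    partition: GroupPartition,
    derived_group: str,
    min_carriers: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Consensus lineage assignment of private sites assayed in a derived panel.

    Per private site: assign the first lineage (the minor donor, e.g. L1)
    iff at least ``min_carriers`` derived samples carry its private allele;
    otherwise assign the second lineage iff at least one derived sample
    carries that lineage's private allele; otherwise the site is absent
    from the consensus.  Returns (calls table, per-chromosome/genome-wide
    summary of counts and percentages).
    """
    lin_a, lin_b = pat.lineages
    present = set(gm.samples)
    derived = [s for s in partition.samples(derived_group) if s in present]
    if not derived:
        raise ValueError(f"derived group {derived_group!r} has no genotyped samples")
    rows = gm.sample_indices(derived)
    dos = pat.private_dosage(gm, rows)
    carriers = (dos > 0).sum(axis=0)
    calls = []
    derived_arr = np.array(derived)
    for k in range(len(pat.table)):
        lineage = pat.table["lineage"].iloc[k]
        n_carry = int(carriers[k])
        assigned = None
        if lineage == lin_a and n_carry >= min_carriers:
            assigned = lin_a
        elif lineage == lin_b and n_carry >= 1:
            assigned = lin_b
        if assigned is None:
            continue
        j = int(pat.table["site_index"].iloc[k])
        carrier_ids = sorted(derived_arr[dos[:, k] > 0])
        calls.append(
            {
                "site": pat.table["site"].iloc[k],
                "chromosome": gm.sites[j].chromosome,
                "position": gm.sites[j].position,
                "lineage": assigned,
                "n_carriers": n_carry,
                "carriers": ";".join(carrier_ids),
            }
        )
    calls_df = pd.DataFrame(
        calls, columns=["site", "chromosome", "position", "lineage", "n_carriers", "carriers"]
    )
    rows_sum = []
    scopes = [("genome", calls_df)]
    scopes += [(c, g) for c, g in calls_df.groupby("chromosome")]
    for scope, sub in scopes:
        n_a = int((sub["lineage"] == lin_a).sum())
        n_b = int((sub["lineage"] == lin_b).sum())
        total = n_a + n_b
        rows_sum.append(
            {
                "scope": scope,
                f"n_{lin_a}": n_a,
                f"n_{lin_b}": n_b,
                f"pct_{lin_a}": 100 * n_a / total if total else np.nan,
                f"pct_{lin_b}": 100 * n_b / total if total else np.nan,
            }
        )
    return calls_df, pd.DataFrame(rows_sum)
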