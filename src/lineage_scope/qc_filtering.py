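"""Site and sample quality control for GBS SNP panels.

The filter cascade mirrors standard practice for inbred GBS panels:

1. site filters: MAF >= 0.01, missingness <= 20%, heterozygosity <= 5%
   (a selfing panel should carry almost no real heterozygotes);
2. an allelic-tag Fisher's exact test flagging sites whose het/missing
   pattern suggests collapsed paralogous tags rather than a single locus;
3. sample filters: missingness <= 80%, heterozygosity <= 5%;
4. removal of sites private to an outgroup (e.g. the derived wheat panel)
   before within-species analyses.

The Fisher table per site is ``[[n_het, n_hom_ref], [n_hom_alt,
n_missing]]``: if two paralogous tags were merged, samples carrying both
tags appear het and samples carrying neither appear missing, so an excess
of the het/missing diagonal (odds ratio > 1) with a small Bonferroni-
corrected p-value marks a non-allelic site.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .diversity_stats import GroupPartition
from .genotype_io import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


def site_stats(gm: GenotypeMatrix) -> pd.DataFrame:
    """Per-site MAF, missing fraction, het fraction, call count.

    MAF is allele-count based over non-missing calls (hets contribute one
    alternate allele); sites with zero calls get NaN statistics.
    """
    if gm.n_samples == 0 or gm.n_sites == 0:
        raise ValueError("empty genotype matrix")
    calls = gm.calls
    obs = calls != MISSING
    call_count = obs.sum(axis=0)
    alt = np.where(obs, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(call_count > 0, alt / np.maximum(2 * call_count, 1), np.nan)
        het = np.where(call_count > 0, (calls == 1).sum(axis=0) / np.maximum(call_count, 1), np.nan)
    return pd.DataFrame(
        {
            "site": gm.site_ids,
            "maf": np.minimum(f, 1 - f),
            "missing_fraction": 1 - call_count / gm.n_samples,
            "het_fraction": het,
            "call_count": call_count,
        }
    )


def sample_stats(gm: GenotypeMatrix) -> pd.DataFrame:
    """Per-sample missing and het fractions."""
    obs = gm.calls != MISSING
    n_obs = obs.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        het = np.where(n_obs > 0, (gm.calls == 1).sum(axis=1) / np.maximum(n_obs, 1), np.nan)
    return pd.DataFrame(
        {
            "sample": gm.samples,
            "missing_fraction": 1 - n_obs / gm.n_sites,
            "het_fraction": het,
        }
    )


def filter_sites(
    gm: GenotypeMatrix,
    maf_min: float = 0.01,
    missing_max: float = 0.20,
    het_max: float = 0.05,
) -> tuple[GenotypeMatrix, dict]:
    """Retain sites with MAF >= maf_min, missingness <= missing_max, het <= het_max.

    The removal log counts each criterion independently (a site can fail
    several) plus the total removed.
    """
    for name, v in (("maf_min", maf_min), ("missing_max", missing_max), ("het_max", het_max)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must be in [0,1]")
    stats = site_stats(gm)
    fail_maf = ~(stats["maf"] >= maf_min)  # NaN maf (no calls) fails
    fail_missing = stats["missing_fraction"] > missing_max
    fail_het = ~(stats["het_fraction"] <= het_max)
    keep = ~(fail_maf | fail_missing | fail_het)
    log = {
        "n_input": gm.n_sites,
        "removed_maf": int(fail_maf.sum()),
        "removed_missing": int(fail_missing.sum()),
        "removed_het": int(fail_het.sum()),
        "removed_total": int((~keep).sum()),
        "n_output": int(keep.sum()),
    }
    if log["n_output"] == 0:
        warnings.warn("site filter removed every site")
    return gm.subset_sites(keep.to_numpy()), log


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact p-value for the table [[a, b], [c, d]].

    Computed by direct summation of the hypergeometric pmf (log-space via
    ``gammaln``): outcomes at least as extreme are those with pmf <= the
    observed pmf, with a tiny relative tolerance so exact ties are kept.
    """
    r1, c1, n = a + b, a + c, a + b + c + d
    if n == 0:
        return 1.0
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    k = np.arange(lo, hi + 1)
    logpmf = (
        gammaln(r1 + 1) - gammaln(k + 1) - gammaln(r1 - k + 1)
        + gammaln(n - r1 + 1) - gammaln(c1 - k + 1) - gammaln(n - r1 - c1 + k + 1)
        - (gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1))
    )
    pmf = np.exp(logpmf)
    observed = pmf[a - lo]
    return float(min(pmf[pmf <= observed * (1 + 1e-9)].sum(), 1.0))


def allelic_tag_test(gm: GenotypeMatrix, alpha: float = 0.001) -> pd.DataFrame:
    """Flag sites whose het/missing association indicates merged paralogous tags.

    Per site the 2x2 table is [[n_het, n_hom_ref], [n_hom_alt, n_missing]];
    a site is flagged when the two-sided Fisher p-value is below the
    Bonferroni-corrected alpha (alpha / n_sites) AND the odds ratio
    ``(n_het * n_missing) / (n_hom_ref * n_hom_alt)`` exceeds 1 (excess of
    the joint het/missing diagonal).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0,1)")
    if gm.n_samples < 2:
        raise ValueError("need at least 2 samples")
    calls = gm.calls
    n_het = (calls == 1).sum(axis=0)
    n_ref = (calls == 0).sum(axis=0)
    n_alt = (calls == 2).sum(axis=0)
    n_mis = (calls == MISSING).sum(axis=0)
    pvals = np.array(
        [
            fisher_exact_two_sided(int(a), int(b), int(c), int(d))
            for a, b, c, d in zip(n_het, n_ref, n_alt, n_mis)
        ]
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        odds = np.where(
            n_ref * n_alt > 0,
            (n_het * n_mis) / np.maximum(n_ref * n_alt, 1),
            np.where(n_het * n_mis > 0, np.inf, np.nan),
        )
    threshold = alpha / gm.n_sites
    flagged = (pvals < threshold) & (odds > 1)
    return pd.DataFrame(
        {
            "site": gm.site_ids,
            "n_het": n_het,
            "n_hom_ref": n_ref,
            "n_hom_alt": n_alt,
            "n_missing": n_mis,
            "p_value": pvals,
            "odds_ratio": odds,
            "flagged": flagged,
        }
    )


def drop_flagged_sites(
    gm: GenotypeMatrix, tag_result: pd.DataFrame
) -> tuple[GenotypeMatrix, int]:
    """Remove sites flagged by :func:`allelic_tag_test`."""
    flagged = set(tag_result.loc[tag_result["flagged"], "site"])
    keep = np.array([s.id not in flagged for s in gm.sites])
    return gm.subset_sites(keep), len(flagged)


def filter_samples(
    gm: GenotypeMatrix, missing_max: float = 0.80, het_max: float = 0.05
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Remove samples exceeding either the missingness or the het threshold.

    Returns the reduced matrix and a log table of removed ids with reasons.
    """
    for name, v in (("missing_max", missing_max), ("het_max", het_max)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must be in [0,1]")
    stats = sample_stats(gm)
    fail_missing = stats["missing_fraction"] > missing_max
    fail_het = stats["het_fraction"] > het_max
    removed = stats[fail_missing | fail_het].copy()
    removed["reason"] = np.where(
        fail_missing[removed.index] & fail_het[removed.index],
        "missing+het",
        np.where(fail_missing[removed.index], "missing", "het"),
    )
    keep = [s for s in gm.samples if s not in set(removed["sample"])]
    if not keep:
        raise ValueError("sample filter removed every sample")
    return gm.subset_samples(keep), removed.reset_index(drop=True)


def drop_group_private_sites(
    gm: GenotypeMatrix, partition: GroupPartition, group: str
) -> tuple[GenotypeMatrix, int]:
    """Drop sites where an allele is carried only within ``group``.

    A site qualifies when all samples outside the group are fixed for one
    allele (hom, ignoring missing) and at least one group sample carries
    the other allele.  Sites with no outside calls are kept.
    """
    group_ids = set(partition.samples(group))  # raises KeyError if unknown
    in_group = np.array([s in group_ids for s in gm.samples])
    if not in_group.any():
        raise KeyError(f"group {group!r} has no samples in the matrix")
    inside = gm.calls[in_group]
    outside = gm.calls[~in_group]
    out_obs = outside != MISSING
    has_out = out_obs.any(axis=0)
    out_all_ref = ((outside == 0) | ~out_obs).all(axis=0) & has_out
    out_all_alt = ((outside == 2) | ~out_obs).all(axis=0) & has_out
    in_has_alt = (inside > 0).any(axis=0)
    in_has_ref = (inside == 1).any(axis=0) | (inside == 0).any(axis=0)
    private = (out_all_ref & in_has_alt) | (out_all_alt & in_has_ref)
    return gm.subset_sites(~private), int(private.sum())


@dataclass
class CascadeResult:
    """Output of the full QC cascade with per-stage dimension logging."""

    matrix: GenotypeMatrix
    site_log: dict
    n_tag_flagged: int
    removed_samples: pd.DataFrame
    n_group_private: int
    stages: list[tuple[str, int, int]]  # (stage, n_samples, n_sites) after stage


def run_cascade(
    gm: GenotypeMatrix,
    partition: GroupPartition | None = None,
    private_group: str | None = None,
    maf_min: float = 0.01,
    missing_max: float = 0.20,
    het_max: float = 0.05,
    sample_missing_max: float = 0.80,
    sample_het_max: float = 0.05,
    alpha: float = 0.001,
) -> CascadeResult:
    """Run the full QC cascade: sites -> tag test -> samples -> group-private."""
    stages = [("input", gm.n_samples, gm.n_sites)]
    gm1, site_log = filter_sites(gm, maf_min, missing_max, het_max)
    stages.append(("site_filter", gm1.n_samples, gm1.n_sites))
    tag = allelic_tag_test(gm1, alpha)
    gm2, n_flagged = drop_flagged_sites(gm1, tag)
    stages.append(("tag_test", gm2.n_samples, gm2.n_sites))
    gm3, removed = filter_samples(gm2, sample_missing_max, sample_het_max)
    stages.append(("sample_filter", gm3.n_samples, gm3.n_sites))
    n_private = 0
    if partition is not None and private_group is not None:
        gm4, n_private = drop_group_private_sites(gm3, partition, private_group)
    else:
        gm4 = gm3
    stages.append(("group_private", gm4.n_samples, gm4.n_sites))
    for stage, n_samp, n_site in stages:
        logger.info("cascade %-14s %5d samples x %6d sites", stage, n_samp, n_site)
    return CascadeResult(gm4, site_log, n_flagged, removed, n_private, stages)
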