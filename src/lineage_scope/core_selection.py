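"""Diversity-maximizing core-collection selection (greedy M strategy).

The M (maximization) strategy picks accessions so that every observed
allele class — each (site, allele) pair, optionally extended with
(trait, category) phenotype classes — is represented in as few accessions
as possible.  Here it is realized as greedy maximal-coverage set cover:
repeatedly add the sample covering the most still-uncovered classes, with
a lexicographic tie-break for determinism.  Greedy set cover carries the
classical (1 - 1/e) approximation guarantee for coverage at every prefix
size, which the test suite checks against exhaustive optima on small
panels.

A second, quota-constrained weighted pass (``reduce_core``) shrinks the
core to a target size while honoring per-group quotas and up-weighting
classes that represent resistant phenotypes — a formalization of
phenotype-guided manual curation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diversity_stats import GroupPartition, nei_diversity
from .genotype_io import MISSING, GenotypeMatrix, PhenotypeTable

logger = logging.getLogger(__name__)


@dataclass
class AlleleClassUniverse:
    """The coverable classes and which samples carry each.

    ``classes`` are (kind, name, value) tuples: ('allele', site_id,
    'ref'/'alt') or ('pheno', trait, category).  ``carriage`` is a boolean
    samples x classes matrix aligned with ``samples``.
    """

    classes: list[tuple[str, str, str]]
    samples: list[str]
    carriage: np.ndarray

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def resistant_mask(self) -> np.ndarray:
        """Classes that are resistant phenotype categories."""
        return np.array(
            [kind == "pheno" and value == "R" for kind, _, value in self.classes]
        )


@dataclass
class CoreSet:
    """Ordered selection with a per-step coverage trace."""

    samples: list[str]
    step_new_classes: list[int]
    coverage_fraction: float
    n_classes: int


def allele_classes(
    gm: GenotypeMatrix, phenotypes: PhenotypeTable | None = None
) -> AlleleClassUniverse:
    """Enumerate observed (site, allele) classes, plus phenotype categories."""
    if gm.n_samples == 0 or gm.n_sites == 0:
        raise ValueError("empty genotype matrix")
    calls = gm.calls
    has_ref = (calls == 0) | (calls == 1)
    has_alt = (calls == 2) | (calls == 1)
    classes: list[tuple[str, str, str]] = []
    cols: list[np.ndarray] = []
    for j, site in enumerate(gm.sites):
        if has_ref[:, j].any():
            classes.append(("allele", site.id, "ref"))
            cols.append(has_ref[:, j])
        if has_alt[:, j].any():
            classes.append(("allele", site.id, "alt"))
            cols.append(has_alt[:, j])
    if phenotypes is not None:
        observed: dict[tuple[str, str], np.ndarray] = {}
        for i, sample in enumerate(gm.samples):
            for trait, value in phenotypes.scores.get(sample, {}).items():
                observed.setdefault((trait, value), np.zeros(gm.n_samples, dtype=bool))[i] = True
        for (trait, value), mask in sorted(observed.items()):
            classes.append(("pheno", trait, value))
            cols.append(mask)
    carriage = np.stack(cols, axis=1) if cols else np.zeros((gm.n_samples, 0), dtype=bool)
    return AlleleClassUniverse(classes=classes, samples=list(gm.samples), carriage=carriage)


def greedy_m_selection(
    gm: GenotypeMatrix, universe: AlleleClassUniverse
) -> CoreSet:
    """Greedy maximal-coverage selection until all coverable classes are covered.

    Deterministic: ties on newly-covered count break by lexicographic
    sample id.
    """
    if universe.samples != gm.samples:
        raise ValueError("universe does not match the genotype matrix samples")
    carriage = universe.carriage
    n_classes = universe.n_classes
    order = np.argsort(np.array(universe.samples))  # lexicographic preference
    covered = np.zeros(n_classes, dtype=bool)
    available = np.ones(len(universe.samples), dtype=bool)
    selected: list[str] = []
    gains: list[int] = []
    while covered.sum() < n_classes:
        new_counts = (carriage & ~covered).sum(axis=1)
        new_counts[~available] = -1
        best_gain = new_counts.max()
        if best_gain <= 0:
            break  # remaining classes are uncoverable by unselected samples
        # lexicographically smallest id among maxima
        candidates = np.flatnonzero(new_counts == best_gain)
        best = min(candidates, key=lambda i: universe.samples[i])
        selected.append(universe.samples[best])
        gains.append(int(best_gain))
        covered |= carriage[best]
        available[best] = False
    return CoreSet(
        samples=selected,
        step_new_classes=gains,
        coverage_fraction=float(covered.sum()) / n_classes if n_classes else 1.0,
        n_classes=n_classes,
    )


def reduce_core(
    core: CoreSet,
    gm: GenotypeMatrix,
    phenotypes: PhenotypeTable | None,
    quotas: dict[str, int],
    partition: GroupPartition,
    target_size: int | None = None,
    universe: AlleleClassUniverse | None = None,
    w_pheno: float = 5.0,
) -> CoreSet:
    """Quota-constrained weighted greedy reduction of a core set.

    Scores a candidate by newly covered allele classes plus ``w_pheno``
    times newly covered resistant-trait classes; selection respects
    per-group quotas (group -> count) and stops at ``target_size``
    (default: sum of quotas).
    """
    if target_size is None:
        target_size = sum(quotas.values())
    if target_size != sum(quotas.values()):
        raise ValueError("target_size must equal the sum of quotas")
    if target_size > len(core.samples):
        raise ValueError("target_size exceeds the core size")
    for group, quota in quotas.items():
        avail = sum(1 for s in core.samples if partition.group_of(s) == group)
        if quota > avail:
            raise ValueError(
                f"quota {quota} for group {group!r} exceeds {avail} available core members"
            )
    if universe is None:
        universe = allele_classes(gm, phenotypes)
    sample_row = {s: i for i, s in enumerate(universe.samples)}
    weights = np.ones(universe.n_classes)
    weights[universe.resistant_mask()] = w_pheno
    is_pheno = np.array([kind == "pheno" for kind, _, _ in universe.classes])
    weights[is_pheno & ~universe.resistant_mask()] = 0.0  # susceptible classes neutral
    covered = np.zeros(universe.n_classes, dtype=bool)
    remaining = dict(quotas)
    pool = list(core.samples)
    selected: list[str] = []
    gains: list[int] = []
    while len(selected) < target_size:
        best_name, best_score, best_new = None, -1.0, 0
        for name in sorted(pool):
            group = partition.group_of(name)
            if remaining.get(group, 0) <= 0:
                continue
            new = universe.carriage[sample_row[name]] & ~covered
            score = float(weights[new].sum())
            if score > best_score:
                best_name, best_score, best_new = name, score, int(new.sum())
        if best_name is None:
            raise ValueError("quotas infeasible with the remaining pool")
        selected.append(best_name)
        gains.append(best_new)
        covered |= universe.carriage[sample_row[best_name]]
        remaining[partition.group_of(best_name)] -= 1
        pool.remove(best_name)
    return CoreSet(
        samples=selected,
        step_new_classes=gains,
        coverage_fraction=float(covered.sum()) / universe.n_classes
        if universe.n_classes
        else 1.0,
        n_classes=universe.n_classes,
    )


def coverage_of(universe: AlleleClassUniverse, samples: list[str]) -> int:
    """Number of classes covered by an arbitrary sample subset."""
    rows = [universe.samples.index(s) for s in samples]
    if not rows:
        return 0
    return int(universe.carriage[rows].any(axis=0).sum())


def capture_metrics(
    subset: list[str], gm: GenotypeMatrix
) -> dict[str, float]:
    """Diversity captured by a subset relative to the whole panel.

    ``pct_segregating``: 100 x (sites segregating within the subset) /
    (sites segregating in the full panel); a site segregates when both
    alleles are present among non-missing calls.  Also reports the Nei
    index of the subset.
    """
    if not subset:
        raise ValueError("empty subset")
    f_all = gm.alt_freq()
    f_sub = gm.alt_freq(gm.sample_indices(subset))
    seg_all = np.isfinite(f_all) & (f_all > 0) & (f_all < 1)
    seg_sub = np.isfinite(f_sub) & (f_sub > 0) & (f_sub < 1)
    n_all = int(seg_all.sum())
    nei = nei_diversity(gm, subset)
    return {
        "pct_segregating": 100.0 * seg_sub.sum() / n_all if n_all else float("nan"),
        "n_segregating_subset": int(seg_sub.sum()),
        "n_segregating_panel": n_all,
        "nei_index": nei.nei_index,
    }
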