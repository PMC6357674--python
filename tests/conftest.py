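"""Shared fixtures: simulated panels and small hand-built matrices."""

from __future__ import annotations

import numpy as np
import pytest

from lineage_scope import GenotypeMatrix, GroupPartition, SnpSite
from lineage_scope.synthetic_data import SimConfig, simulate_panel

DEFAULT_SEED = 2019


def make_matrix(rows, samples=None, chrom="1D", positions=None, n_chrom_split=None):
    """Build a GenotypeMatrix from a list of per-sample dosage rows.

    ``rows``: list of lists (use -1 for missing).  Sites land on one
    chromosome at increasing positions unless ``positions``/``chrom``
    (lists) are given.
    """
    calls = np.asarray(rows, dtype=np.int8)
    n_samples, n_sites = calls.shape
    if samples is None:
        samples = [f"S{i + 1:03d}" for i in range(n_samples)]
    if positions is None:
        positions = list(range(1, n_sites + 1))
    chroms = [chrom] * n_sites if isinstance(chrom, str) else chrom
    sites = [
        SnpSite(f"snp{j:04d}", chroms[j], positions[j], "A", "G")
        for j in range(n_sites)
    ]
    return GenotypeMatrix(list(samples), sites, calls)


def random_matrix(rng, n_samples, n_sites, missing_rate=0.1):
    calls = rng.integers(0, 3, size=(n_samples, n_sites)).astype(np.int8)
    miss = rng.random(calls.shape) < missing_rate
    calls[miss] = -1
    return make_matrix(calls)


@pytest.fixture(scope="session")
def default_panel():
    """The default simulated study panel (noise on), with its partition."""
    cfg = SimConfig(seed=DEFAULT_SEED)
    gm, records, phenotypes, truth = simulate_panel(cfg)
    partition = GroupPartition.from_passport(records)
    return {
        "cfg": cfg,
        "gm": gm,
        "records": records,
        "phenotypes": phenotypes,
        "truth": truth,
        "partition": partition,
    }


@pytest.fixture(scope="session")
def clean_panel():
    """Noise-free variant of the default panel (exact-recovery tests)."""
    cfg = SimConfig(seed=DEFAULT_SEED, error_rate=0.0, missing_rate=0.0, residual_het=0.0)
    gm, records, phenotypes, truth = simulate_panel(cfg)
    partition = GroupPartition.from_passport(records)
    return {
        "cfg": cfg,
        "gm": gm,
        "records": records,
        "phenotypes": phenotypes,
        "truth": truth,
        "partition": partition,
    }


@pytest.fixture(scope="session")
def hybrid_group_partition(clean_panel):
    """Partition that isolates the hybrid-lineage group from F1/RIL samples."""
    truth = clean_panel["truth"]
    part = clean_panel["partition"]
    gm = clean_panel["gm"]
    mapping = {}
    for s in gm.samples:
        if truth.true_group[s] == "hybrid_lineage":
            mapping[s] = "hybrid_lineage"
        else:
            mapping[s] = part.group_of(s)
    return GroupPartition(mapping)
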