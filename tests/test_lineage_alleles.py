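"""Private-allele discovery, contribution, painting, parentage, consensus."""

import numpy as np
import pytest

from lineage_scope import (
    GroupPartition,
    classify_hybrids,
    consensus_introgression,
    find_private_alleles,
    group_private_alleles,
    lineage_contribution,
    paint_sample,
    parentage_match,
)

from conftest import make_matrix, random_matrix


def brute_force_private(gm, groups, lineages=("L1", "L2"), min_call_fraction=0.5):
    """Independent per-site scan of both lineages' frequency conditions."""
    out = set()
    rows = {lin: [i for i, s in enumerate(gm.samples) if groups[s] == lin] for lin in lineages}
    for j in range(gm.n_sites):
        freqs, fracs = {}, {}
        for lin in lineages:
            col = [gm.calls[i, j] for i in rows[lin]]
            obs = [c for c in col if c >= 0]
            fracs[lin] = len(obs) / len(col)
            freqs[lin] = sum(obs) / (2 * len(obs)) if obs else None
        a, b = lineages
        if freqs[a] is None or freqs[b] is None:
            continue
        if fracs[a] < min_call_fraction or fracs[b] < min_call_fraction:
            continue
        for donor, other in ((a, b), (b, a)):
            fd, fo = freqs[donor], freqs[other]
            if fo == 0 and 0 < fd < 1:
                out.add((gm.sites[j].id, donor, "alt"))
            if fo == 1 and 0 < fd < 1:
                out.add((gm.sites[j].id, donor, "ref"))
    return out


class TestFindPrivateAlleles:
    def test_definition_example(self):
        gm = make_matrix([[0], [0], [2], [0], [0]])
        part = GroupPartition(
            {s: ("L1" if i < 3 else "L2") for i, s in enumerate(gm.samples)}
        )
        pat = find_private_alleles(gm, part)
        assert len(pat) == 1
        row = pat.table.iloc[0]
        assert (row.lineage, row.allele) == ("L1", "alt")
        assert row.freq == pytest.approx(1 / 3)

    def test_fixed_difference_excluded(self):
        gm = make_matrix([[2], [2], [0], [0]])
        part = GroupPartition(
            {s: ("L1" if i < 2 else "L2") for i, s in enumerate(gm.samples)}
        )
        assert len(find_private_alleles(gm, part)) == 0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(123)
        for _ in range(25):
            gm = random_matrix(rng, 24, 120)
            groups = {
                s: ("L1" if i < 10 else "L2" if i < 20 else "other")
                for i, s in enumerate(gm.samples)
            }
            pat = find_private_alleles(gm, GroupPartition(groups))
            ours = set(zip(pat.table.site, pat.table.lineage, pat.table.allele))
            assert ours == brute_force_private(gm, groups)

    def test_private_freq_zero_in_other_lineage(self, clean_panel):
        gm, part = clean_panel["gm"], clean_panel["partition"]
        pat = find_private_alleles(gm, part)
        l1_rows = gm.sample_indices(part.samples("L1"))
        l2_rows = gm.sample_indices(part.samples("L2"))
        dos_l1 = pat.private_dosage(gm, l1_rows)
        dos_l2 = pat.private_dosage(gm, l2_rows)
        is_l1 = (pat.table.lineage == "L1").to_numpy()
        assert (dos_l2[:, is_l1] <= 0).all()  # L1-private absent from L2
        assert (dos_l1[:, ~is_l1] <= 0).all()

    def test_missing_lineage_errors(self):
        gm = make_matrix([[0], [2]])
        with pytest.raises((ValueError, KeyError)):
            find_private_alleles(gm, GroupPartition({"S001": "L1", "S002": "L1"}))


class TestContribution:
    def test_pure_samples_are_pure(self, clean_panel):
        gm, part, truth = clean_panel["gm"], clean_panel["partition"], clean_panel["truth"]
        pat = find_private_alleles(gm, part)
        pure_l1 = part.samples("L1")[:5]
        contrib = lineage_contribution(gm, pat, pure_l1)
        assert (contrib["pct_L1"] == 1.0).all()
        assert (contrib["count_L2"] == 0).all()

    def test_percentages_sum_to_one(self, default_panel):
        gm, part = default_panel["gm"], default_panel["partition"]
        pat = find_private_alleles(gm, part)
        contrib = lineage_contribution(gm, pat)
        ok = contrib["informative"] > 0
        total = contrib.loc[ok, "pct_L1"] + contrib.loc[ok, "pct_L2"]
        assert np.allclose(total, 1.0)

    def test_f1_near_half(self, clean_panel):
        gm, part, truth = clean_panel["gm"], clean_panel["partition"], clean_panel["truth"]
        pat = find_private_alleles(gm, part)
        f1s = list(truth.f1_parents)
        contrib = lineage_contribution(gm, pat, f1s)
        assert ((contrib["pct_L1"] > 0.40) & (contrib["pct_L1"] < 0.60)).all()


class TestClassifyHybrids:
    def test_exactly_planted_hybrids_flagged(self, default_panel):
        gm, part, truth = (default_panel["gm"], default_panel["partition"],
                           default_panel["truth"])
        pat = find_private_alleles(gm, part)
        flagged = classify_hybrids(gm, pat, part)
        hybrids = {s for s, g in truth.true_group.items()
                   if g in ("F1", "RIL", "hybrid_lineage")}
        assert set(flagged["sample"]) == hybrids
        minors = flagged["minor_fraction"].to_numpy()
        assert (np.diff(minors) <= 1e-12).all()  # sorted descending

    def test_no_flags_on_error_free_pure_samples(self, clean_panel):
        gm, part = clean_panel["gm"], clean_panel["partition"]
        pat = find_private_alleles(gm, part)
        pure = part.samples("L1") + part.samples("L2")
        flagged = classify_hybrids(gm, pat, part, minor_fraction_min=1e-9,
                                   min_informative=1, samples=pure)
        assert len(flagged) == 0

    def test_extreme_threshold_keeps_only_balanced_samples(self, default_panel):
        # minor fraction is capped at 0.5, so a 0.5 threshold can only
        # retain perfectly balanced samples
        gm, part = default_panel["gm"], default_panel["partition"]
        pat = find_private_alleles(gm, part)
        flagged = classify_hybrids(gm, pat, part, minor_fraction_min=0.5)
        assert (flagged["minor_fraction"] == 0.5).all()
        assert set(flagged["group"]) <= {"hybrid"}


class TestPainting:
    def test_switch_count_and_clarity_definition(self):
        # hand-built: one chromosome, L1-private alt at 3 sites then L2-private
        # alt at 2 sites; the sample carries all five
        calls = [
            [2, 2, 2, 0, 0],  # L1 donor
            [0, 0, 0, 0, 0],  # L1
            [0, 0, 0, 2, 2],  # L2 donor
            [0, 0, 0, 0, 0],  # L2
            [2, 2, 2, 2, 2],  # query
        ]
        gm = make_matrix(calls, samples=["a", "b", "c", "d", "q"])
        part = GroupPartition({"a": "L1", "b": "L1", "c": "L2", "d": "L2", "q": "x"})
        pat = find_private_alleles(gm, part)
        track = paint_sample(gm, pat, "q")
        assert track.informative == 5
        assert track.switch_count == 1
        assert track.clarity == pytest.approx(0.75)
        bed = track.to_bed()
        assert bed.to_records(index=False).tolist() == [
            ("1D", 0, 3, "L1"), ("1D", 3, 5, "L2")
        ]

    def test_ril_painting_matches_truth_ancestry(self, clean_panel):
        gm, part, truth = clean_panel["gm"], clean_panel["partition"], clean_panel["truth"]
        pat = find_private_alleles(gm, part)
        ril = next(iter(truth.ril_parents))
        track = paint_sample(gm, pat, ril)
        anc = truth.ancestry[ril]
        pos_to_anc = {
            (s.chromosome, s.position): ("L1" if anc[j] == 0 else "L2")
            for j, s in enumerate(gm.sites)
        }
        for chrom, events in track.events.items():
            for pos, lineage in events:
                assert lineage == pos_to_anc[(chrom, pos)]
        true_bp = sum(len(v) for v in truth.breakpoints[ril].values())
        assert track.switch_count <= true_bp

    def test_hybrid_lineage_less_clear_than_ril(self, clean_panel):
        gm, part, truth = clean_panel["gm"], clean_panel["partition"], clean_panel["truth"]
        pat = find_private_alleles(gm, part)
        ril = next(s for s, g in truth.true_group.items() if g == "RIL")
        hyb = next(s for s, g in truth.true_group.items() if g == "hybrid_lineage")
        assert paint_sample(gm, pat, hyb).clarity < paint_sample(gm, pat, ril).clarity

    def test_relabeling_site_ids_keeps_switches(self, clean_panel):
        from lineage_scope.genotype_io import GenotypeMatrix, SnpSite

        gm, part, truth = clean_panel["gm"], clean_panel["partition"], clean_panel["truth"]
        ril = next(iter(truth.ril_parents))
        pat = find_private_alleles(gm, part)
        base = paint_sample(gm, pat, ril)
        renamed_sites = [
            SnpSite(f"renamed_{j}", s.chromosome, s.position, s.ref_allele, s.alt_allele)
            for j, s in enumerate(gm.sites)
        ]
        gm2 = GenotypeMatrix(list(gm.samples), renamed_sites, gm.calls.copy())
        pat2 = find_private_alleles(gm2, part)
        track2 = paint_sample(gm2, pat2, ril)
        assert track2.switch_count == base.switch_count
        assert track2.clarity == base.clarity


class TestParentage:
    def test_identical_candidate_scores_100(self):
        # query "q" is an exact copy of candidate "l1a"
        calls = [
            [2, 0, 0], [0, 2, 0],  # L1 (cols 0-1 L1-private alt)
            [0, 0, 2], [0, 0, 0],  # L2 (col 2 L2-private alt)
            [2, 0, 0],             # query, duplicates l1a
        ]
        gm = make_matrix(calls, samples=["l1a", "l1b", "l2a", "l2b", "q"])
        part = GroupPartition({"l1a": "L1", "l1b": "L1", "l2a": "L2",
                               "l2b": "L2", "q": "x"})
        pat = find_private_alleles(gm, part)
        pm = parentage_match(gm, pat, "q", part, candidate_groups=("L1",))
        best = pm["L1"].iloc[0]
        assert best.candidate == "l1a" and best.identity_pct == 100.0

    def test_true_parents_rank_first(self, clean_panel):
        gm, part, truth = clean_panel["gm"], clean_panel["partition"], clean_panel["truth"]
        pat = find_private_alleles(gm, part)
        hybrids = {s for s, g in truth.true_group.items()
                   if g in ("F1", "RIL", "hybrid_lineage")}
        for hybrid in sorted(hybrids)[:3]:
            parents = truth.f1_parents.get(hybrid) or truth.ril_parents.get(hybrid)
            pm = parentage_match(gm, pat, hybrid, part, exclude=hybrids)
            assert pm["L1"].iloc[0].candidate == parents[0]
            assert pm["L2"].iloc[0].candidate == parents[1]

    def test_removing_parents_lowers_identity(self, clean_panel):
        gm, part, truth = clean_panel["gm"], clean_panel["partition"], clean_panel["truth"]
        pat = find_private_alleles(gm, part)
        hybrids = {s for s, g in truth.true_group.items()
                   if g in ("F1", "RIL", "hybrid_lineage")}
        hybrid = next(iter(truth.f1_parents))
        parents = truth.f1_parents[hybrid]
        with_parents = parentage_match(gm, pat, hybrid, part, exclude=hybrids)
        without = parentage_match(gm, pat, hybrid, part,
                                  exclude=hybrids | set(parents))
        for group, parent in zip(("L1", "L2"), parents):
            assert (without[group].iloc[0].identity_pct
                    < with_parents[group].iloc[0].identity_pct)


class TestGroupPrivateAlleles:
    def test_exact_planted_counts(self, clean_panel, hybrid_group_partition):
        gm, truth = clean_panel["gm"], clean_panel["truth"]
        table, n_fixed, n_seg = group_private_alleles(
            gm, hybrid_group_partition, "hybrid_lineage", ("L1", "L2", "wheat")
        )
        assert n_fixed == len(truth.group_private_fixed_sites)
        assert n_seg == len(truth.group_private_segregating_sites)
        assert set(table.site) == set(
            truth.group_private_fixed_sites + truth.group_private_segregating_sites
        )

    def test_single_sample_target_freqs(self, clean_panel):
        gm, part = clean_panel["gm"], clean_panel["partition"]
        lone = part.samples("L1")[0]
        mapping = {s: ("me" if s == lone else "L1" if g == "L1" else g)
                   for s, g in part.mapping.items()}
        table, *_ = group_private_alleles(
            gm, GroupPartition(mapping), "me", ("L1", "L2")
        )
        assert set(table.target_freq) <= {0.5, 1.0}

    def test_lineage_subset_reports_only_true_singletons(self, clean_panel):
        # a subset of one lineage may legitimately own rare alleles absent
        # from the remaining members; every report must be such an allele
        gm, part = clean_panel["gm"], clean_panel["partition"]
        subset = part.samples("L1")[:8]
        mapping = dict(part.mapping)
        for s in subset:
            mapping[s] = "sub"
        table, *_ = group_private_alleles(gm, GroupPartition(mapping), "sub", ("L1",))
        rest = [s for s in part.samples("L1") if s not in subset]
        rest_rows = gm.sample_indices(rest)
        for _, row in table.iterrows():
            col = gm.calls[rest_rows, int(row.site_index)]
            obs = col[col >= 0]
            f_alt = obs.sum() / (2 * len(obs))
            assert (f_alt == 0) if row.allele == "alt" else (f_alt == 1)
        # such alleles are rare: far fewer than the subset's segregating sites
        sub_f = gm.alt_freq(gm.sample_indices(subset))
        n_seg_sub = int(((sub_f > 0) & (sub_f < 1)).sum())
        assert len(table) < 0.2 * n_seg_sub

    def test_overlap_errors(self, clean_panel):
        part = clean_panel["partition"]
        with pytest.raises(ValueError):
            group_private_alleles(clean_panel["gm"], part, "L1", ("L1", "L2"))


class TestConsensusIntrogression:
    def test_exact_on_clean_fixture(self, clean_panel):
        gm, part, truth = clean_panel["gm"], clean_panel["partition"], clean_panel["truth"]
        pat = find_private_alleles(gm, part)
        calls, summary = consensus_introgression(gm, pat, part, "wheat")
        called_l1 = set(calls.loc[calls.lineage == "L1", "site"])
        assert called_l1 == set(truth.introgression_sites)
        assert not called_l1 & set(truth.single_carrier_sites)
        for site in truth.introgression_sites:
            row = calls[calls.site == site].iloc[0]
            assert row.carriers.split(";") == truth.introgression_carriers[site]
        genome = summary[summary.scope == "genome"].iloc[0]
        assert genome.pct_L1 + genome.pct_L2 == pytest.approx(100.0)

    def test_threshold_monotonicity(self, default_panel):
        gm, part = default_panel["gm"], default_panel["partition"]
        pat = find_private_alleles(gm, part)
        loose, _ = consensus_introgression(gm, pat, part, "wheat", min_carriers=1)
        strict, _ = consensus_introgression(gm, pat, part, "wheat", min_carriers=2)
        assert set(strict.site) <= set(loose.site)

    def test_single_carrier_below_threshold(self):
        # 1 carrier of the L1-private allele among derived samples: no L1 call
        calls = [
            [2], [0],          # L1 (segregating -> alt is L1-private)
            [0], [0],          # L2
            [2], [0], [0],     # derived: one carrier
        ]
        gm = make_matrix(calls, samples=["l1a", "l1b", "l2a", "l2b", "w1", "w2", "w3"])
        part = GroupPartition({"l1a": "L1", "l1b": "L1", "l2a": "L2", "l2b": "L2",
                               "w1": "wheat", "w2": "wheat", "w3": "wheat"})
        pat = find_private_alleles(gm, part)
        out, _ = consensus_introgression(gm, pat, part, "wheat", min_carriers=2)
        assert len(out) == 0
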