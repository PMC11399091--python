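"""Stand-in decoy injection, merging, q re-estimation, and the final build."""

import numpy as np
import pandas as pd
import pytest

from quantcore.dataset_merge import (
    MergeEntry,
    combine_expression_profiles,
    filter_adjusted_fdr,
    inject_standin_decoys,
    merge_protein_lists,
    reestimate_qvalues,
)

from conftest import oracle_reestimate


class TestInjection:
    def test_all_zero_q_injects_nothing(self):
        lst = inject_standin_decoys([(f"p{i}", 0.0) for i in range(10)], "D")
        assert lst.decoys() == []

    def test_hand_rolled_cumulative_rounding(self):
        lst = inject_standin_decoys([("a", 0.0), ("b", 0.1), ("c", 0.2)], "D")
        decoys = lst.decoys()
        assert len(decoys) == 1
        assert decoys[0].q == 0.2
        # realized ratio 1/3 deviates from 0.2 by <= 0.5/3
        assert abs(1 / 3 - 0.2) <= 0.5 / 3

    def test_constant_q_steps_at_expected_ranks(self):
        lst = inject_standin_decoys([(f"p{i}", 0.02) for i in range(100)], "D")
        assert len(lst.decoys()) == 2  # d_25 = 1, d_75 = 2
        entries = lst.entries
        # decoys appear right after the 25th and 75th targets
        decoy_positions = [i for i, e in enumerate(entries) if e.is_standin_decoy]
        assert decoy_positions == [25, 76]

    def test_q_domain_enforced(self):
        with pytest.raises(ValueError, match="out of"):
            inject_standin_decoys([("a", 1.5)], "D")

    def test_duplicate_accessions_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            inject_standin_decoys([("a", 0.1), ("a", 0.2)], "D")

    def test_ratio_bound_holds_at_every_rank(self, rng):
        for _ in range(20):
            n = int(rng.integers(10, 2000))
            qs = np.sort(rng.random(n) * rng.choice([0.05, 0.5, 1.0]))
            lst = inject_standin_decoys(
                [(f"p{i}", float(q)) for i, q in enumerate(qs)], "D"
            )
            # cumulative decoys D_k right after each target's decoy block
            ranks: list[list] = []
            d = 0
            for e in lst.entries:
                if e.is_standin_decoy:
                    d += 1
                else:
                    ranks.append([len(ranks) + 1, e.q, 0])
                ranks[-1][2] = d
            for k, q, dk in ranks:
                assert abs(dk / k - q) <= 0.5 / k + 1e-12


class TestMerge:
    def test_lowest_q_kept_with_provenance(self):
        a = inject_standin_decoys([("P1", 0.05)], "A")
        b = inject_standin_decoys([("P1", 0.01)], "B")
        merged = merge_protein_lists([a, b])
        targets = [e for e in merged if not e.is_standin_decoy]
        assert targets == [MergeEntry("P1", 0.01, "B", False)]

    def test_single_list_passthrough(self):
        lst = inject_standin_decoys([("a", 0.3), ("b", 0.1)], "A")
        merged = merge_protein_lists([lst])
        assert sorted(e.accession for e in merged) == sorted(
            e.accession for e in lst.entries
        )

    def test_disjoint_union(self):
        a = inject_standin_decoys([(f"a{i}", 0.2) for i in range(3)], "A")
        b = inject_standin_decoys([(f"b{i}", 0.2) for i in range(4)], "B")
        merged = merge_protein_lists([a, b])
        targets = [e for e in merged if not e.is_standin_decoy]
        decoys = [e for e in merged if e.is_standin_decoy]
        assert len(targets) == 7
        assert len(decoys) == len(a.decoys()) + len(b.decoys())

    def test_sorted_targets_before_decoys_at_ties(self):
        lst = inject_standin_decoys([("a", 0.5), ("b", 0.5)], "A")
        merged = merge_protein_lists([lst])
        qs = [e.q for e in merged]
        assert qs == sorted(qs)
        tied = [e for e in merged if e.q == 0.5]
        flags = [e.is_standin_decoy for e in tied]
        assert flags == sorted(flags)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            merge_protein_lists([])


class TestReestimate:
    def test_hand_checked_counting(self):
        merged = [
            MergeEntry("t1", 0.0, "A"),
            MergeEntry("t2", 0.0, "A"),
            MergeEntry("d1", 0.01, "A", True),
            MergeEntry("t3", 0.01, "A"),
            MergeEntry("t4", 0.02, "A"),
            MergeEntry("d2", 0.02, "A", True),
        ]
        build = reestimate_qvalues(merged)
        assert [t.adjusted_q for t in build.targets] == pytest.approx(
            [0.0, 0.0, 1 / 3, 0.5]
        )

    def test_no_decoys_gives_zero(self):
        merged = [MergeEntry(f"t{i}", 0.1 * i, "A") for i in range(5)]
        build = reestimate_qvalues(merged)
        assert all(t.adjusted_q == 0.0 for t in build.targets)

    def test_all_decoys_rejected(self):
        with pytest.raises(ValueError, match="no target"):
            reestimate_qvalues([MergeEntry("d", 0.1, "A", True)])

    def test_matches_counting_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(2, 150))
            qs = rng.integers(0, 20, size=n) / 20.0
            dec = rng.random(n) < 0.3
            if dec.all():
                dec[0] = False
            merged = [
                MergeEntry(f"e{i}", float(q), "A", bool(d))
                for i, (q, d) in enumerate(zip(qs, dec))
            ]
            build = reestimate_qvalues(merged)
            got = [t.adjusted_q for t in build.targets]
            np.testing.assert_allclose(got, oracle_reestimate(list(zip(qs, dec))))

    def test_no_monotonize_returns_raw_ratios(self):
        merged = [
            MergeEntry("t1", 0.1, "A"),
            MergeEntry("d1", 0.1, "A", True),
            MergeEntry("t2", 0.5, "A"),
        ]
        raw = reestimate_qvalues(merged, monotonize=False)
        assert [t.adjusted_q for t in raw.targets] == [1.0, 0.5]

    def test_monotonicity_under_added_noise_dataset(self, rng):
        """Appending a dataset of pure high-q entries never lowers any
        existing target's adjusted q."""
        base_qs = np.sort(rng.random(200) * 0.05)
        base = inject_standin_decoys(
            [(f"p{i}", float(q)) for i, q in enumerate(base_qs)], "A"
        )
        noise = inject_standin_decoys(
            [(f"x{i}", float(0.5 + 0.5 * rng.random())) for i in range(300)], "B"
        )
        solo = {
            t.accession: t.adjusted_q
            for t in reestimate_qvalues(merge_protein_lists([base])).targets
        }
        both = {
            t.accession: t.adjusted_q
            for t in reestimate_qvalues(merge_protein_lists([base, noise])).targets
        }
        assert all(both[a] >= solo[a] - 1e-12 for a in solo)


class TestFilterAndProfiles:
    def test_strict_threshold_boundary(self):
        merged = [MergeEntry(f"t{i}", 0.0, "A") for i in range(3)]
        build = reestimate_qvalues(merged)
        build.targets = [
            t.__class__(t.accession, t.dataset, t.nominal_q, q)
            for t, q in zip(build.targets, (0.005, 0.0099, 0.01))
        ]
        retained, report = filter_adjusted_fdr(build, alpha=0.01)
        assert [t.adjusted_q for t in retained] == [0.005, 0.0099]
        assert report["n_retained"] == 2 and report["n_removed"] == 1

    def test_alpha_one_keeps_all_targets(self):
        merged = [
            MergeEntry("t1", 0.0, "A"),
            MergeEntry("t2", 0.5, "A"),
            MergeEntry("d", 0.5, "A", True),
        ]
        build = reestimate_qvalues(merged)
        retained, _ = filter_adjusted_fdr(build, alpha=1.0)
        assert len(retained) == 2
        # non-strict variant admits the boundary
        retained_le, _ = filter_adjusted_fdr(build, alpha=0.5, strict=False)
        assert len(retained_le) == 2

    def test_alpha_domain(self):
        build = reestimate_qvalues([MergeEntry("t", 0.0, "A")])
        with pytest.raises(ValueError):
            filter_adjusted_fdr(build, alpha=0.0)

    def test_expression_profiles_median_and_mad(self):
        build = reestimate_qvalues(
            [MergeEntry("P1", 0.0, "A"), MergeEntry("P2", 0.0, "A")]
        )
        retained, _ = filter_adjusted_fdr(build, alpha=0.5)
        quant = pd.DataFrame(
            {
                "accession": ["P1", "P1", "P2", "PX"],
                "dataset": ["A", "B", "A", "A"],
                "sample_class": ["tissue"] * 4,
                "ibaq": [100.0, 10000.0, 50.0, 1.0],
            }
        )
        profiles, skipped = combine_expression_profiles(retained, quant)
        assert skipped == 1  # PX is outside the build
        p1 = profiles[profiles["accession"] == "P1"].iloc[0]
        assert p1["median_log10_ibaq"] == pytest.approx(3.0)
        assert p1["n_datasets"] == 2
        p2 = profiles[profiles["accession"] == "P2"].iloc[0]
        assert p2["mad_log10_ibaq"] == 0.0  # single observation
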