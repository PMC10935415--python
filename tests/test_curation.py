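"""Activity merging, class assignment, redundancy pruning and splitting."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from zincscreen.curation import (
    DISCARD,
    ActivityRecord,
    CurationError,
    LigandEntry,
    assign_class,
    curate_records,
    maccs_similarity,
    merge_activity,
    prune_redundant,
    read_activity_csv,
    read_smiles_file,
    split_dataset,
)


def rec(ki, lid="L", sid="S"):
    return ActivityRecord(lid, sid, ki)


class TestMergeActivity:
    @pytest.mark.parametrize(
        "kis, expected",
        [
            ([1.0], 0.0),
            ([10.0, 50.0], (1.0 + np.log10(50.0)) / 2),  # spread 0.699 <= 1
            ([10.0, 10_000.0], DISCARD),  # spread 3 > 1
            ([100.0, 1000.0], 2.5),  # spread exactly 1: averaged
        ],
    )
    def test_merge_rule(self, kis, expected):
        result = merge_activity([rec(k, sid=f"S{i}") for i, k in enumerate(kis)])
        if expected == DISCARD:
            assert result == DISCARD
        else:
            assert result == pytest.approx(expected, abs=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.01, max_value=1e6), min_size=1, max_size=5))
    def test_permutation_invariance(self, kis):
        records = [rec(k, sid=f"S{i}") for i, k in enumerate(kis)]
        base = merge_activity(records)
        for perm in itertools.islice(itertools.permutations(records), 6):
            assert merge_activity(list(perm)) == base

    def test_nonpositive_ki_rejected(self):
        with pytest.raises(CurationError, match="L1"):
            ActivityRecord("L1", "S1", -5.0)
        with pytest.raises(CurationError):
            ActivityRecord("L1", "S1", 0.0)
        with pytest.raises(CurationError):
            merge_activity([])


class TestAssignClass:
    @pytest.mark.parametrize(
        "lg, expected",
        [(1.9, "high"), (2.0, "excluded"), (2.5, "excluded"), (3.0, "excluded"), (3.5, "low"), (-4.0, "high"), (7.0, "low")],
    )
    def test_strict_cuts(self, lg, expected):
        assert assign_class(lg) == expected

    def test_nonfinite_rejected(self):
        with pytest.raises(CurationError):
            assign_class(float("nan"))

    def test_merge_then_class_never_labels_boundary(self):
        # any merged lg(Ki) in [2, 3] must come out excluded
        for lg in np.linspace(1.5, 3.5, 21):
            cls = assign_class(float(lg))
            if 2.0 <= lg <= 3.0:
                assert cls == "excluded"
            else:
                assert cls in ("high", "low")


def entry(lid, smiles, lg, cls=None):
    return LigandEntry(lid, smiles, lg, cls or assign_class(lg))


class TestPruneRedundant:
    def test_identical_structures_keep_one(self):
        entries = [entry("A", "c1ccccc1CC(=O)NO", 0.0), entry("B", "c1ccccc1CC(=O)NO", 0.5)]
        kept, report = prune_redundant(entries)
        assert [e.ligand_id for e in kept] == ["A"]
        assert report["n_removed"] == 1

    def test_similarity_threshold_is_strict(self):
        # a pair exactly at the threshold is retained ("greater than" rule)
        a, b = "c1ccccc1CC(=O)NO", "Cc1ccccc1CC(=O)NO"
        sim = maccs_similarity(a, b)
        entries = [entry("A", a, 0.0), entry("B", b, 0.5)]
        kept_at, _ = prune_redundant(entries, threshold=sim)
        assert len(kept_at) == 2
        kept_below, _ = prune_redundant(entries, threshold=sim - 1e-9)
        assert len(kept_below) == 1

    def test_chain_pruning_leaves_no_conflicting_pair(self):
        # analog chain A~B~C: output audited exhaustively against the threshold
        entries = [
            entry("A", "c1ccccc1CC(=O)NO", 0.0),
            entry("B", "Cc1ccccc1CC(=O)NO", 0.3),
            entry("C", "CCc1ccccc1CC(=O)NO", 0.6),
            entry("D", "C1CCCCC1CCP(=O)(O)O", 1.0),
        ]
        kept, _ = prune_redundant(entries)
        for x, y in itertools.combinations(kept, 2):
            if x.activity_class == y.activity_class:
                assert maccs_similarity(x.structure, y.structure) <= 0.75

    def test_idempotent(self):
        entries = [
            entry("A", "c1ccccc1CC(=O)NO", 0.0),
            entry("B", "Cc1ccccc1CC(=O)NO", 0.3),
            entry("C", "c1ccsc1CCNC(N)=O", 4.0),
        ]
        kept, _ = prune_redundant(entries)
        again, report = prune_redundant(kept)
        assert [e.ligand_id for e in again] == [e.ligand_id for e in kept]
        assert report["n_removed"] == 0

    def test_cross_class_pairs_untouched_by_default(self):
        entries = [entry("A", "c1ccccc1CC(=O)NO", 0.0), entry("B", "c1ccccc1CC(=O)NO", 5.0)]
        kept, _ = prune_redundant(entries)
        assert len(kept) == 2  # same structure, different class
        kept_x, _ = prune_redundant(entries, within_class=False)
        assert len(kept_x) == 1

    def test_unparseable_structure_excluded_with_warning(self):
        entries = [entry("A", "not_a_smiles", 0.0), entry("B", "c1ccccc1CC(=O)NO", 0.5)]
        with pytest.warns(UserWarning, match="unparseable"):
            kept, report = prune_redundant(entries)
        assert [e.ligand_id for e in kept] == ["B"]
        assert report["unparseable_ids"] == ["A"]


class TestSplitDataset:
    @staticmethod
    def _entries(n_high, n_low):
        out = []
        for i in range(n_high):
            out.append(entry(f"H{i:03d}", "c1ccccc1CC(=O)NO", 0.0, "high"))
        for i in range(n_low):
            out.append(entry(f"L{i:03d}", "c1ccsc1CCNC(N)=O", 4.0, "low"))
        return out

    def test_modeling_external_counts_match_131_77_design(self):
        ds = split_dataset(self._entries(131, 77), modeling_fraction=165 / 208, seed=0)
        assert len(ds.subset("modeling")) == 165
        assert len(ds.subset("external_test")) == 43

    def test_inner_split_ratio(self):
        ds = split_dataset(self._entries(50, 50), modeling_fraction=1.0, seed=1)
        # modeling_fraction=1.0 is clipped to keep one external per class
        modeling = ds.subset("modeling")
        train, internal = ds.subset("train"), ds.subset("internal_test")
        assert len(train) + len(internal) == len(modeling)
        assert len(train) / len(modeling) == pytest.approx(0.7, abs=0.05)

    def test_seed_determinism(self):
        e = self._entries(30, 20)
        a = split_dataset(e, seed=42)
        b = split_dataset(e, seed=42)
        assert a.split_assignment == b.split_assignment
        assert a.inner_split == b.inner_split
        c = split_dataset(e, seed=43)
        assert a.split_assignment != c.split_assignment

    def test_cluster_based_inner_split(self, table200, ligand_set200):
        entries = [
            entry(l.ligand_id, l.smiles, l.lg_ki, l.true_class)
            for l in ligand_set200.ligands
        ]
        ds = split_dataset(entries, seed=0, features=table200)
        train, internal = ds.subset("train"), ds.subset("internal_test")
        ratio = len(train) / (len(train) + len(internal))
        assert 0.62 <= ratio <= 0.78
        # partitions are disjoint and exhaustive over the modeling set
        assert {e.ligand_id for e in train}.isdisjoint({e.ligand_id for e in internal})
        assert {e.ligand_id for e in train} | {e.ligand_id for e in internal} == {
            e.ligand_id for e in ds.subset("modeling")
        }

    def test_small_class_rejected(self):
        with pytest.raises(CurationError):
            split_dataset(self._entries(9, 1), seed=0)


class TestIO:
    def test_activity_and_smiles_round_trip(self, tmp_path):
        df = pd.DataFrame(
            {"ligand_id": ["L1", "L1"], "source_id": ["a", "b"], "ki_nM": [1.0, 2.0]}
        )
        df.to_csv(tmp_path / "act.csv", index=False)
        records = read_activity_csv(tmp_path / "act.csv")
        assert len(records) == 2 and records[0].ki_nM == 1.0
        (tmp_path / "ligs.smi").write_text("c1ccccc1\tL1\nCCO\tL2\n")
        structures = read_smiles_file(tmp_path / "ligs.smi")
        assert structures == {"L1": "c1ccccc1", "L2": "CCO"}

    def test_curate_records_merges_and_reports(self):
        records = [rec(10.0, "A", "s1"), rec(50.0, "A", "s2"), rec(1.0, "B", "s3"), rec(1e5, "B", "s4")]
        entries, report = curate_records(records, {"A": "CCO", "B": "CCC"})
        assert [e.ligand_id for e in entries] == ["A"]
        assert report["n_discarded_discordant"] == 1
        assert report["discarded_ids"] == ["B"]
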