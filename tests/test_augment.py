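"""SMILES enumeration, Topo-AL expansion, leakage hygiene, and the guard."""

import pytest

from classrt.augment import (
    AugmentConfig,
    enumerate_smiles,
    guarded_augment,
    topo_al_expand,
)
from classrt.chemio import DatasetTable, MoleculeRecord, canonicalize
from classrt.errors import ConfigurationError
from classrt.simfp import ecfp, tanimoto

IBUPROFEN = "CC(C)Cc1ccc(cc1)C(C)C(=O)O"


def table(smiles_rt, prefix="t"):
    return DatasetTable(
        [
            MoleculeRecord.from_smiles(f"{prefix}{i}", s, rt)
            for i, (s, rt) in enumerate(smiles_rt)
        ]
    )


class TestEnumerateSmiles:
    def test_k_zero_is_empty(self):
        assert enumerate_smiles("CCO", 0) == []

    def test_variants_roundtrip_and_are_distinct(self):
        parent = canonicalize(IBUPROFEN)
        variants = enumerate_smiles(IBUPROFEN, 5, seed=3)
        assert 0 < len(variants) <= 5
        assert len(set(variants)) == len(variants)
        for v in variants:
            assert v != parent
            assert canonicalize(v) == parent

    def test_single_atom_graph_falls_short(self):
        variants = enumerate_smiles("C", 5, seed=1)
        assert len(variants) < 5  # methane admits essentially one rendering

    def test_deterministic_given_seed(self):
        a = enumerate_smiles(IBUPROFEN, 5, seed=9)
        b = enumerate_smiles(IBUPROFEN, 5, seed=9)
        assert a == b


class TestTopoAL:
    def setup_method(self):
        # train: two benzoic acids; pool: a close analog (high sim), a distant
        # molecule (low sim), and a molecule that also sits in the test set.
        self.train = table([("OC(=O)c1ccccc1", 300.0), ("OC(=O)c1ccc(C)cc1", 350.0)])
        self.in_test = "OC(=O)c1ccc(Cl)cc1"
        self.pool = table(
            [
                ("OC(=O)c1ccc(CC)cc1", 360.0),  # analog
                ("NCCCCN", 100.0),  # distant
                (self.in_test, 340.0),  # leaks into test
            ],
            prefix="p",
        )
        self.test_like = table([(self.in_test, 340.0)], prefix="q")

    def _max_sim(self, smiles):
        f = ecfp(smiles)
        return max(tanimoto(f, ecfp(r.smiles_canonical)) for r in self.train.records)

    def test_similar_pool_record_included(self):
        assert self._max_sim("OC(=O)c1ccc(CC)cc1") >= 0.5
        out = topo_al_expand(self.train, self.pool, self.test_like, tau=0.5)
        assert canonicalize("OC(=O)c1ccc(CC)cc1") in out.canonical_set()

    def test_dissimilar_pool_record_excluded(self):
        assert self._max_sim("NCCCCN") < 0.5
        out = topo_al_expand(self.train, self.pool, self.test_like, tau=0.5)
        assert canonicalize("NCCCCN") not in out.canonical_set()

    def test_test_set_member_excluded_despite_high_similarity(self):
        assert self._max_sim(self.in_test) >= 0.5
        out = topo_al_expand(self.train, self.pool, self.test_like, tau=0.5)
        assert canonicalize(self.in_test) not in out.canonical_set()

    def test_recruits_keep_their_own_rt_and_tag(self):
        out = topo_al_expand(self.train, self.pool, self.test_like, tau=0.5)
        added = [r for r in out.records if out.provenance[r.id] == "topo_al_added"]
        assert added and all(r.rt == 360.0 for r in added)

    def test_unlabeled_pool_record_raises(self):
        pool = DatasetTable([MoleculeRecord.from_smiles("u0", "CCO")])
        with pytest.raises(ConfigurationError, match="rt"):
            topo_al_expand(self.train, pool, self.test_like, tau=0.5)

    def test_threshold_monotonicity(self):
        lo = topo_al_expand(self.train, self.pool, self.test_like, tau=0.2)
        hi = topo_al_expand(self.train, self.pool, self.test_like, tau=0.8)
        assert hi.canonical_set() <= lo.canonical_set()


class TestGuardedAugment:
    def _sets(self):
        train = table(
            [
                (IBUPROFEN, 500.0),
                ("OC(=O)c1ccccc1", 300.0),
                ("OC(=O)c1ccc(C)cc1", 350.0),
            ]
        )
        val = table([("OC(=O)c1ccc(F)cc1", 330.0)], prefix="v")
        test = table([("OC(=O)c1ccc(Cl)cc1", 340.0)], prefix="w")
        test_like = DatasetTable(
            list(val.records) + list(test.records),
            {r.id: "original" for r in list(val.records) + list(test.records)},
        )
        return train, val, test_like

    def test_guard_disabled_reaches_full_multiple(self):
        train, val, test_like = self._sets()
        cfg = AugmentConfig(k=5, guard_enabled=False, topo_enabled=False, seed=1)
        out = guarded_augment(train, val, None, test_like, cfg)
        n_orig = out.counts["n_original"]
        assert n_orig == 3
        # up to k variants per molecule; shortfall only from string collisions
        assert 0 < out.counts["n_se"] <= 5 * n_orig
        assert len(out.log) == 5

    def test_monotone_probe_never_stops_early(self):
        train, val, test_like = self._sets()
        maes = iter([10.0, 9.0, 8.0, 7.0, 6.0])
        cfg = AugmentConfig(k=5, guard_enabled=True, topo_enabled=False, seed=1)
        out = guarded_augment(train, val, None, test_like, cfg, lambda t, v: next(maes))
        assert len(out.log) == 5

    def test_rising_probe_stops_and_returns_best(self):
        train, val, test_like = self._sets()
        maes = iter([10.0, 9.0, 9.5])
        cfg = AugmentConfig(k=5, guard_enabled=True, topo_enabled=False,
                            guard_tolerance=0.01, seed=1)
        out = guarded_augment(train, val, None, test_like, cfg, lambda t, v: next(maes))
        assert [e["m"] for e in out.log] == [1, 2, 3]  # stopped after iteration 3
        # returned set is the iteration-2 (best) set: <= 2 variants/molecule
        per_parent = {}
        for r in out.table.records:
            if out.table.provenance[r.id] == "se_augmented":
                parent = r.id.split("#")[0]
                per_parent[parent] = per_parent.get(parent, 0) + 1
        assert per_parent and all(v <= 2 for v in per_parent.values())

    def test_counts_are_consistent_and_leak_free(self):
        train, val, test_like = self._sets()
        cfg = AugmentConfig(k=3, guard_enabled=False, topo_enabled=False, seed=2)
        out = guarded_augment(train, val, None, test_like, cfg)
        c = out.counts
        assert c["n_original"] + c["n_se"] + c["n_topo_al"] == len(out.table)
        assert not (out.table.canonical_set() & test_like.canonical_set())

    def test_enumerated_rows_share_parent_canonical_and_rt(self):
        train, val, test_like = self._sets()
        cfg = AugmentConfig(k=2, guard_enabled=False, topo_enabled=False, seed=4)
        out = guarded_augment(train, val, None, test_like, cfg)
        parents = {r.id: r for r in train.records}
        for r in out.table.records:
            if out.table.provenance[r.id] == "se_augmented":
                parent = parents[r.id.split("#")[0]]
                assert r.smiles_canonical == parent.smiles_canonical
                assert r.rt == parent.rt
                assert canonicalize(r.smiles_raw) == parent.smiles_canonical

    def test_determinism(self):
        train, val, test_like = self._sets()
        cfg = AugmentConfig(k=3, guard_enabled=False, topo_enabled=False, seed=8)
        a = guarded_augment(train, val, None, test_like, cfg)
        b = guarded_augment(train, val, None, test_like, cfg)
        assert [r.smiles_raw for r in a.table.records] == [
            r.smiles_raw for r in b.table.records
        ]
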