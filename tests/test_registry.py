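"""Registry semantics: dedup, persistent IDs, provenance, groups, replay."""

import random

import pytest

from lincskit.registry import (
    ProvenanceError, RegistryError, RegistryLedger, UnregisteredReference,
    data_level_role,
)


class TestRegisterReagent:
    def test_same_key_twice_returns_same_id(self, ledger):
        a = ledger.register_reagent("Small molecules", "INCHIKEY-A")
        b = ledger.register_reagent("Small molecules", "INCHIKEY-A")
        assert a == b
        assert len(ledger.entities) == 1

    def test_distinct_keys_get_consecutive_counters(self, ledger):
        a = ledger.register_reagent("Small molecules", "K1")
        b = ledger.register_reagent("Small molecules", "K2")
        assert (a, b) == ("LSM-000001", "LSM-000002")

    def test_random_register_calls_yield_set_cardinality(self, ledger):
        rng = random.Random(5)
        keys = [f"KEY-{rng.randint(1, 40)}" for _ in range(100)]
        for k in keys:
            ledger.register_reagent("Proteins", k)
        assert len(ledger.entities) == len(set(keys))

    def test_same_key_different_kind_is_distinct_entity(self, ledger):
        a = ledger.register_reagent("Proteins", "SHARED")
        b = ledger.register_reagent("Antibody reagents", "SHARED")
        assert a != b

    def test_empty_key_rejected(self, ledger):
        with pytest.raises(RegistryError):
            ledger.register_reagent("Small molecules", "  ")

    def test_unknown_kind_rejected(self, ledger):
        with pytest.raises(RegistryError):
            ledger.register_reagent("Plasmids", "K")


class TestMintId:
    def test_first_lsm_mint_is_zero_padded(self, ledger):
        assert ledger.mint_id("LSM") == "LSM-000001"

    def test_id_width_is_configurable(self):
        ledger = RegistryLedger(id_width=4)
        assert ledger.mint_id("LDS") == "LDS-0001"

    def test_unknown_kind_errors(self, ledger):
        with pytest.raises(RegistryError):
            ledger.mint_id("XXX")

    def test_no_reuse_after_tombstone(self, ledger):
        first = ledger.register_reagent("Small molecules", "K1")
        ledger.tombstone(first)
        second = ledger.register_reagent("Small molecules", "K2")
        assert second != first
        assert ledger.entities[first].withdrawn

    def test_thousand_mints_across_kinds_all_unique(self, ledger):
        rng = random.Random(1)
        kinds = ["LSM", "LDC", "LDG", "LDS", "LPR"]
        minted = [ledger.mint_id(rng.choice(kinds)) for _ in range(1000)]
        assert len(set(minted)) == 1000


class TestBatches:
    def test_two_centers_one_compound_two_batches(self, ledger):
        lincs_id = ledger.register_reagent("Small molecules", "K")
        ledger.record_batch("centerA", "b1", lincs_id, {"vendor": "X"})
        ledger.record_batch("centerB", "b1", lincs_id, {"vendor": "Y"})
        assert len(ledger.entities) == 1
        assert len(ledger.batches) == 2

    def test_identical_resubmission_is_idempotent(self, ledger):
        lincs_id = ledger.register_reagent("Small molecules", "K")
        ledger.record_batch("c", "b", lincs_id, {"lot": "1"})
        n_events = len(ledger.events)
        ledger.record_batch("c", "b", lincs_id, {"lot": "1"})
        assert len(ledger.batches) == 1
        assert len(ledger.events) == n_events

    def test_conflicting_resubmission_errors(self, ledger):
        lincs_id = ledger.register_reagent("Small molecules", "K")
        ledger.record_batch("c", "b", lincs_id, {"lot": "1"})
        with pytest.raises(RegistryError, match="different content"):
            ledger.record_batch("c", "b", lincs_id, {"lot": "2"})

    def test_batch_for_unknown_id_errors(self, ledger):
        with pytest.raises(UnregisteredReference):
            ledger.record_batch("c", "b", "LSM-000099")


class TestCellProvenance:
    @pytest.fixture()
    def cells(self, ledger):
        primary = ledger.register_reagent("Primary cells", "donor-1",
                                          {"Donor Age": 45, "Tissue": "skin"})
        ipsc = ledger.register_reagent("iPSCs", "ipsc-1",
                                       {"Reprogramming Method": "Sendai"})
        diff = ledger.register_reagent("Differentiated cells", "neuron-1",
                                       {"Terminal Cell Type": "neuron"})
        return primary, ipsc, diff

    def test_chain_of_three(self, ledger, cells):
        primary, ipsc, diff = cells
        ledger.link_cell_provenance(diff, ipsc)
        ledger.link_cell_provenance(ipsc, primary)
        assert ledger.parent_chain(diff) == [diff, ipsc, primary]

    def test_child_inherits_ancestor_metadata(self, ledger, cells):
        primary, ipsc, diff = cells
        ledger.link_cell_provenance(diff, ipsc)
        ledger.link_cell_provenance(ipsc, primary)
        resolved = ledger.resolve_inherited_metadata(diff)
        assert resolved["Donor Age"] == 45
        assert resolved["Terminal Cell Type"] == "neuron"
        # stored records untouched
        assert "Donor Age" not in ledger.entities[diff].metadata

    def test_inheritance_equals_fold_oracle(self, ledger, cells):
        primary, ipsc, diff = cells
        ledger.link_cell_provenance(diff, ipsc)
        ledger.link_cell_provenance(ipsc, primary)
        chain = ledger.parent_chain(diff)
        oracle = {}
        for lid in reversed(chain):
            oracle.update(ledger.entities[lid].metadata)
        assert ledger.resolve_inherited_metadata(diff) == oracle

    def test_nearest_ancestor_wins_on_conflict(self, ledger, cells):
        primary, ipsc, diff = cells
        ledger.entities[primary].metadata["Organism"] = "root"
        ledger.entities[ipsc].metadata["Organism"] = "middle"
        ledger.link_cell_provenance(diff, ipsc)
        ledger.link_cell_provenance(ipsc, primary)
        assert ledger.resolve_inherited_metadata(diff)["Organism"] == "middle"

    def test_parentless_cell_resolves_to_own_metadata(self, ledger, cells):
        primary, _, _ = cells
        assert ledger.resolve_inherited_metadata(primary) == \
            ledger.entities[primary].metadata

    def test_self_link_rejected(self, ledger, cells):
        primary, _, _ = cells
        with pytest.raises(ProvenanceError):
            ledger.link_cell_provenance(primary, primary)

    def test_cycle_rejected(self, ledger, cells):
        primary, ipsc, _ = cells
        ledger.link_cell_provenance(ipsc, primary)
        with pytest.raises(ProvenanceError, match="cycle"):
            ledger.link_cell_provenance(primary, ipsc)

    def test_non_cell_kind_rejected(self, ledger, cells):
        primary, _, _ = cells
        protein = ledger.register_reagent("Proteins", "P1")
        with pytest.raises(ProvenanceError, match="not a cell"):
            ledger.link_cell_provenance(protein, primary)


class TestDatasetGroups:
    def test_group_creation_mints_ldg(self, ledger):
        ldg = ledger.create_dataset_group("centerA", "L1000",
                                          "by release date")
        assert ldg == "LDG-000001"
        assert ledger.groups[ldg].partition_rule == "by release date"

    def test_fifty_groups_unique_increasing(self, ledger):
        ids = [ledger.create_dataset_group("c", "a") for _ in range(50)]
        assert len(set(ids)) == 50
        assert ids == sorted(ids)

    def test_levels_2_3_4_under_one_group(self, ledger):
        ldg = ledger.create_dataset_group("c", "L1000")
        lds = [ledger.add_dataset(ldg, level) for level in (2, 3, 4)]
        assert len(set(lds)) == 3
        assert len(ledger.groups[ldg].datasets) == 3

    def test_level_zero_rejected(self, ledger):
        ldg = ledger.create_dataset_group("c", "L1000")
        with pytest.raises(RegistryError):
            ledger.add_dataset(ldg, 0)

    def test_same_level_needs_distinct_flavors(self, ledger):
        ldg = ledger.create_dataset_group("c", "L1000")
        ledger.add_dataset(ldg, 4, flavor="landmark")
        ledger.add_dataset(ldg, 4, flavor="inferred")
        with pytest.raises(RegistryError, match="already has"):
            ledger.add_dataset(ldg, 4, flavor="landmark")

    def test_level_role_vocabulary(self):
        assert [data_level_role(i) for i in (1, 2, 3, 4, 5)] == \
            ["raw", "processed", "normalized", "signature", "signature"]


def populated_ledger():
    ledger = RegistryLedger()
    k1 = ledger.register_reagent("Small molecules", "KEY-A", {"m": 1})
    k2 = ledger.register_reagent("Primary cells", "donor", {"Donor Age": 30})
    k3 = ledger.register_reagent("iPSCs", "ipsc")
    ledger.link_cell_provenance(k3, k2)
    ledger.record_batch("centerA", "b1", k1, {"vendor": "X"})
    ldg = ledger.create_dataset_group("centerA", "L1000", "rule")
    lds = ledger.add_dataset(ldg, 3, None, {"f.tsv": "0" * 64},
                             {"Dataset Title": "t"})
    ledger.link_batch_to_dataset("centerA", "b1", lds)
    ledger.tombstone(k1)
    return ledger


class TestPersistence:
    def test_event_replay_reconstructs_identical_state(self):
        ledger = populated_ledger()
        clone = RegistryLedger.replay(ledger.events)
        assert clone.entities == ledger.entities
        assert clone.batches == ledger.batches
        assert clone.groups == ledger.groups
        assert clone.id_counters == ledger.id_counters

    def test_jsonl_round_trip_preserves_ids_and_counters(self, tmp_path):
        ledger = populated_ledger()
        path = tmp_path / "ledger.jsonl"
        ledger.to_jsonl(path)
        loaded = RegistryLedger.from_jsonl(path)
        assert loaded.id_counters == ledger.id_counters
        assert set(loaded.entities) == set(ledger.entities)
        assert loaded.entities == ledger.entities
        assert loaded.groups == ledger.groups

    def test_sqlite_round_trip_preserves_state(self, tmp_path):
        ledger = populated_ledger()
        path = tmp_path / "ledger.sqlite"
        ledger.to_sqlite(path)
        loaded = RegistryLedger.from_sqlite(path)
        assert loaded.entities == ledger.entities
        assert loaded.batches == ledger.batches
        assert loaded.id_counters == ledger.id_counters

    def test_integrity_scan_is_clean_after_mutations(self):
        assert populated_ledger().check_integrity() == []
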