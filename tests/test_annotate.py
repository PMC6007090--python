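"""Bioactivity curation, p-transform, aggregation, cross-references."""

import math
import random
from dataclasses import replace

import pytest
from hypothesis import given, settings, strategies as st

from lincskit.annotate import (
    ACCEPTED_ENDPOINTS, ActivityRecord, XrefResolver,
    aggregate_activities, filter_activities, map_target_symbol,
    normalize_endpoint, p_transform, p_transform_records, resolve_xrefs,
)
from lincskit.synth import generate_activity_table


def record(**overrides):
    base = dict(compound_key="CMPD-1", target_id="CHEMBL1",
                target_accession="P00001", endpoint="Ki", value=10.0,
                units="nM", confidence=5, assay_type="binding",
                is_concentration_response=True, relation="=")
    base.update(overrides)
    return ActivityRecord(**base)


class TestFilter:
    def test_confidence_below_five_rejected(self):
        retained, log = filter_activities([record(confidence=4)])
        assert retained == []
        assert log.reasons() == ["confidence"]

    def test_minimum_confidence_five_retained(self):
        retained, _ = filter_activities([record(confidence=5)])
        assert len(retained) == 1

    def test_assay_type_outside_binding_functional_rejected(self):
        retained, log = filter_activities([record(assay_type="ADMET")])
        assert retained == []
        assert log.reasons() == ["assay_type"]

    def test_unlisted_endpoint_rejected(self):
        retained, log = filter_activities([record(endpoint="Solubility")])
        assert retained == []
        assert log.reasons() == ["endpoint"]

    def test_non_concentration_response_rejected(self):
        retained, log = filter_activities(
            [record(is_concentration_response=False)])
        assert retained == []
        assert log.reasons() == ["concentration_response"]

    def test_censored_relation_excluded_by_default(self):
        retained, log = filter_activities([record(relation=">")])
        assert retained == []
        assert log.reasons() == ["censored_relation"]
        retained, _ = filter_activities([record(relation=">")],
                                        include_censored=True)
        assert len(retained) == 1

    def test_endpoint_matching_ignores_case_and_subscripts(self):
        for label in ("IC_50", "ic50", "IC 50", "KI", "k_d"):
            assert normalize_endpoint(label) in ACCEPTED_ENDPOINTS

    def test_first_failing_criterion_logged(self):
        _, log = filter_activities(
            [record(confidence=1, assay_type="ADMET")])
        assert log.reasons() == ["confidence"]

    def test_random_table_equals_predicate_oracle(self):
        rng = random.Random(13)
        endpoints = list(ACCEPTED_ENDPOINTS) + ["Solubility", "logP"]
        table = [record(
            confidence=rng.randint(0, 9),
            assay_type=rng.choice(["binding", "functional", "ADMET"]),
            endpoint=rng.choice(endpoints),
            is_concentration_response=rng.random() < 0.8,
        ) for _ in range(200)]
        retained, log = filter_activities(table)

        def oracle(r):
            return (r.confidence >= 5
                    and r.assay_type in ("binding", "functional")
                    and r.endpoint in ACCEPTED_ENDPOINTS
                    and r.is_concentration_response
                    and r.relation == "=")

        expected = [r for r in table if oracle(r)]
        assert [replace(r, endpoint=normalize_endpoint(r.endpoint))
                for r in expected] == retained
        assert len(log.entries) == len(table) - len(expected)


class TestPTransform:
    @pytest.mark.parametrize("value,units,expected", [
        (1, "uM", 6.0),
        (10, "nM", 8.0),
        (1, "nM", 9.0),
        (100, "pM", 10.0),
        (1, "M", 0.0),
    ])
    def test_exact_on_decade_grid(self, value, units, expected):
        assert p_transform(value, units) == pytest.approx(expected, abs=1e-12)

    def test_micro_sign_variants_accepted(self):
        assert p_transform(1, "µM") == p_transform(1, "uM")

    def test_unknown_units_rejected(self):
        with pytest.raises(ValueError, match="unknown concentration unit"):
            p_transform(1, "kg")

    def test_nonpositive_value_rejected(self):
        with pytest.raises(ValueError, match="nonpositive"):
            p_transform(0, "nM")

    def test_record_level_rejection_does_not_crash(self):
        out, log = p_transform_records([record(units="kg"), record()])
        assert len(out) == 1 and len(log.entries) == 1

    @settings(deadline=None, derandomize=True)
    @given(st.floats(min_value=1e-3, max_value=1e3),
           st.floats(min_value=1.01, max_value=100.0))
    def test_strictly_decreasing_in_concentration(self, value, factor):
        assert p_transform(value * factor, "nM") < p_transform(value, "nM")


class TestAggregate:
    def test_mean_of_two_p_values(self):
        records = [replace(record(), p_value=6.0),
                   replace(record(), p_value=7.0)]
        out, _ = aggregate_activities(records, {"CMPD-1": "LSM-000001"})
        assert len(out) == 1
        assert out[0].p_value_mean == pytest.approx(6.5)
        assert out[0].n_records == 2
        assert out[0].lsm_id == "LSM-000001"

    def test_single_record_mean_is_itself(self):
        out, _ = aggregate_activities([replace(record(), p_value=8.25)],
                                      {"CMPD-1": "LSM-000001"})
        assert out[0].p_value_mean == 8.25

    def test_unmapped_compound_logged_and_skipped(self):
        out, log = aggregate_activities([replace(record(), p_value=6.0)], {})
        assert out == []
        assert log.reasons() == ["unmapped_compound"]

    def test_mean_within_member_range(self):
        records, mapping, _ = generate_activity_table(8, 4, seed=3,
                                                      with_decoys=False)
        transformed, _ = p_transform_records(records)
        out, _ = aggregate_activities(transformed, mapping)
        for agg in out:
            members = [r.p_value for r in transformed
                       if (mapping[r.compound_key], r.target_id, r.endpoint)
                       == (agg.lsm_id, agg.target_id, agg.endpoint)]
            assert min(members) <= agg.p_value_mean <= max(members)

    def test_500_records_match_group_by_oracle_and_shuffle_invariant(self):
        rng = random.Random(21)
        records = []
        for _ in range(500):
            rec = record(
                compound_key=f"CMPD-{rng.randint(1, 12)}",
                target_id=f"CHEMBL{rng.randint(1, 6)}",
                endpoint=rng.choice(["Ki", "IC50"]),
            )
            records.append(replace(rec, p_value=rng.uniform(4, 10)))
        mapping = {f"CMPD-{i}": f"LSM-{i:06d}" for i in range(1, 13)}

        groups = {}
        for r in records:
            key = (mapping[r.compound_key], r.target_id, r.endpoint)
            groups.setdefault(key, []).append(r.p_value)
        oracle = {k: (sum(v) / len(v), len(v)) for k, v in groups.items()}

        out, _ = aggregate_activities(records, mapping)
        got = {(a.lsm_id, a.target_id, a.endpoint):
               (a.p_value_mean, a.n_records) for a in out}
        assert got.keys() == oracle.keys()
        for k in oracle:
            assert got[k][0] == pytest.approx(oracle[k][0], abs=1e-12)
            assert got[k][1] == oracle[k][1]

        shuffled = records[:]
        rng.shuffle(shuffled)
        out2, _ = aggregate_activities(shuffled, mapping)
        assert out == out2  # sorted output, order-invariant

    def test_duplicating_records_keeps_means_doubles_counts(self):
        records, mapping, _ = generate_activity_table(5, 3, seed=4,
                                                      with_decoys=False)
        transformed, _ = p_transform_records(records)
        base, _ = aggregate_activities(transformed, mapping)
        doubled, _ = aggregate_activities(transformed * 2, mapping)
        for a, b in zip(base, doubled):
            assert b.p_value_mean == pytest.approx(a.p_value_mean)
            assert b.n_records == 2 * a.n_records


class TestXrefs:
    def test_known_accession_maps_to_symbol(self):
        resolver = XrefResolver("UniProt", {"P00533": ("EGFR",)})
        assert map_target_symbol("P00533", resolver) == "EGFR"

    def test_unknown_accession_absent_and_logged(self):
        resolver = XrefResolver("UniProt", {})
        assert map_target_symbol("P99999", resolver) is None
        assert resolver.missing_log == ["P99999"]

    def test_batch_mapping_has_no_drops(self):
        resolver = XrefResolver("UniProt",
                                {f"P{i:05d}": (f"G{i}",) for i in range(5)})
        accessions = [f"P{i:05d}" for i in range(10)]
        outcomes = [map_target_symbol(a, resolver) for a in accessions]
        assert len(outcomes) == 10
        assert sum(o is not None for o in outcomes) == 5

    def test_per_source_entries_even_when_empty(self):
        resolvers = [
            XrefResolver("PubChem", {"KEY": ("CID123",)}),
            XrefResolver("ChEMBL", {"KEY": ("CHEMBL9",)}),
            XrefResolver("ChEBI", {"KEY": ("CHEBI:1",)}),
            XrefResolver("DrugCentral", {}),
            XrefResolver("PDB", {}),
            XrefResolver("BindingDB", {}),
        ]
        mapping, conflicts = resolve_xrefs("KEY", resolvers)
        assert len(mapping) == 6
        assert sum(bool(v) for v in mapping.values()) == 3
        assert conflicts == []

    def test_center_submitted_conflict_surfaced(self):
        resolvers = [XrefResolver("PubChem", {"KEY": ("CID111",)})]
        _, conflicts = resolve_xrefs("KEY", resolvers,
                                     submitted={"PubChem": "CID222"})
        assert len(conflicts) == 1
        assert conflicts[0].submitted == "CID222"
        assert conflicts[0].resolved == ("CID111",)

    def test_agreeing_submission_is_not_a_conflict(self):
        resolvers = [XrefResolver("PubChem", {"KEY": ("CID111",)})]
        _, conflicts = resolve_xrefs("KEY", resolvers,
                                     submitted={"PubChem": "CID111"})
        assert conflicts == []

    def test_no_resolvers_empty_mapping(self):
        mapping, conflicts = resolve_xrefs("KEY", [])
        assert mapping == {} and conflicts == []

    def test_tsv_round_trip(self, tmp_path):
        resolver = XrefResolver("ChEMBL", {"K1": ("A", "B"), "K2": ("C",)})
        path = tmp_path / "chembl.tsv"
        resolver.to_tsv(path)
        loaded = XrefResolver.from_tsv("ChEMBL", path)
        assert loaded.table == resolver.table


def test_pipeline_recovers_constructed_group_means():
    """filter -> p-transform -> aggregate recovers the planted means."""
    records, mapping, truth = generate_activity_table(6, 4, seed=8)
    retained, _ = filter_activities(records)
    transformed, _ = p_transform_records(retained)
    out, _ = aggregate_activities(transformed, mapping)
    got = {(a.lsm_id, a.target_id, a.endpoint):
           (a.p_value_mean, a.n_records) for a in out}
    assert got.keys() == truth.keys()
    for key, (mean, n) in truth.items():
        assert got[key][0] == pytest.approx(mean, abs=1e-9)
        assert got[key][1] == n
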