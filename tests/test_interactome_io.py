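"""Dialect readers, per-source filters, and the deduplicating merge."""

import numpy as np
import pytest

from mimicnet.interactome_io import (
    FilterPolicy,
    InteractionRecord,
    merge_records,
    normalize_accession,
    read_biogrid_table,
    read_mitab,
    read_string_table,
)
from mimicnet.synthetic_data import SyntheticSpec, generate_interactome


def mitab_row(
    id_a="P00001",
    id_b="P00002",
    tax_a="taxid:9606(human)",
    tax_b="taxid:9606(human)",
    itype='psi-mi:"MI:0407"(direct interaction)',
    conf="intact-miscore:0.70",
    pmid="pubmed:11111111",
):
    cols = [
        f"uniprotkb:{id_a}", f"uniprotkb:{id_b}", "-", "-", "-", "-",
        'psi-mi:"MI:0018"(two hybrid)', "-", pmid, tax_a, tax_b, itype,
        'psi-mi:"MI:0469"(IntAct)', "intact:EBI-1", conf,
    ]
    return "\t".join(cols)


class TestNormalizeAccession:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ("uniprotkb:P05067-2", "P05067"),
            ("p05067", "P05067"),
            ("P10636-8", "P10636"),
            ("intact:EBI-123", "EBI-123"),
        ],
    )
    def test_isoforms_prefixes_case(self, raw, expected):
        assert normalize_accession(raw) == expected


class TestReadMitab:
    def test_passing_row_kept(self):
        policy = FilterPolicy(min_mi_score=0.65)
        recs = read_mitab([mitab_row()], policy)
        assert len(recs) == 1
        assert recs[0].interaction_type == "direct interaction"
        assert recs[0].mi_score == pytest.approx(0.70)

    def test_score_below_cutoff_dropped(self):
        policy = FilterPolicy(min_mi_score=0.65)
        assert read_mitab([mitab_row(conf="intact-miscore:0.60")], policy) == []

    def test_twenty_row_fixture_counts(self):
        """3 non-human rows, 4 low-score rows, 2 colocalization rows out of
        20 leave 11 survivors."""
        rows = []
        for i in range(3):
            rows.append(mitab_row(id_a=f"P1{i:04d}", tax_b="taxid:10090(mouse)"))
        for i in range(4):
            rows.append(mitab_row(id_a=f"P2{i:04d}", conf="intact-miscore:0.30"))
        for i in range(2):
            rows.append(mitab_row(id_a=f"P3{i:04d}", itype='psi-mi:"MI:0403"(colocalization)'))
        for i in range(11):
            rows.append(mitab_row(id_a=f"P4{i:04d}"))
        assert len(rows) == 20
        recs = read_mitab(rows, FilterPolicy(min_mi_score=0.65))
        assert len(recs) == 11
        assert all(r.id_a.startswith("P4") for r in recs)

    def test_malformed_line_skipped_with_warning(self, caplog):
        bad = "only\tfour\tcolumns\there"
        recs = read_mitab([bad, mitab_row()], FilterPolicy())
        assert len(recs) == 1
        assert "expected 15 columns" in caplog.text

    def test_conflicting_taxids_dropped(self, caplog):
        row = mitab_row(tax_a="taxid:9606(human)|taxid:10090(mouse)")
        assert read_mitab([row], FilterPolicy()) == []
        assert "conflicting taxon" in caplog.text

    def test_missing_score_dropped_under_positive_threshold(self, caplog):
        row = mitab_row(conf="author-score:high")
        assert read_mitab([row], FilterPolicy(min_mi_score=0.5)) == []
        assert "no intact-miscore" in caplog.text

    def test_type_matched_by_mi_identifier(self):
        row = mitab_row(itype='psi-mi:"MI:0915"()')  # empty CV name, id only
        recs = read_mitab([row], FilterPolicy())
        assert len(recs) == 1

    def test_isoform_normalized_in_ids(self):
        recs = read_mitab([mitab_row(id_a="P05067-2")], FilterPolicy())
        assert recs[0].id_a == "P05067"


class TestReadStringTable:
    HEADER = "protein1 protein2 combined_score"

    def test_thousand_scale_autodetected(self):
        lines = [self.HEADER, "A B 950", "C D 850"]
        recs = read_string_table(lines, FilterPolicy())
        assert [(r.id_a, r.id_b) for r in recs] == [("A", "B")]
        assert recs[0].mi_score == pytest.approx(0.95)

    def test_unit_scale_cutoff(self):
        lines = [self.HEADER, "A B 0.85", "C D 0.95"]
        recs = read_string_table(lines, FilterPolicy())
        assert [(r.id_a, r.id_b) for r in recs] == [("C", "D")]

    def test_fixture_six_of_ten_pass(self):
        scores = [910, 920, 930, 940, 950, 901, 899, 500, 100, 700]
        lines = [self.HEADER] + [f"P{i:05d} Q{i:05d} {s}" for i, s in enumerate(scores)]
        assert len(read_string_table(lines, FilterPolicy())) == 6

    def test_non_numeric_score_skipped(self, caplog):
        lines = [self.HEADER, "A B high", "C D 950"]
        assert len(read_string_table(lines, FilterPolicy())) == 1
        assert "unparsable" in caplog.text


class TestReadBiogridTable:
    HEADER = "interactor_a\tinteractor_b\texperimental_system_type\tthroughput\tpmid"

    def test_two_distinct_pmids_kept(self):
        lines = [
            self.HEADER,
            "A\tB\tphysical\tLow Throughput\t1",
            "A\tB\tphysical\tLow Throughput\t2",
        ]
        recs = read_biogrid_table(lines, FilterPolicy(min_publications=2))
        assert len(recs) == 1 and recs[0].n_publications == 2

    def test_repeated_pmid_counts_once(self):
        lines = [self.HEADER] + ["A\tB\tphysical\tLow Throughput\t7"] * 3
        assert read_biogrid_table(lines, FilterPolicy(min_publications=2)) == []

    def test_high_throughput_rows_ignored(self):
        lines = [
            self.HEADER,
            "A\tB\tphysical\tHigh Throughput\t1",
            "A\tB\tphysical\tHigh Throughput\t2",
        ]
        assert read_biogrid_table(lines, FilterPolicy()) == []

    def test_missing_pmid_logged_not_counted(self, caplog):
        lines = [
            self.HEADER,
            "A\tB\tphysical\tLow Throughput\t",
            "A\tB\tphysical\tLow Throughput\t5",
        ]
        assert read_biogrid_table(lines, FilterPolicy(min_publications=2)) == []
        assert "missing publication id" in caplog.text

    def test_fixture_two_of_five_pairs_pass(self):
        lines = [self.HEADER]
        # pairs 1,2 pass; 3 has one pmid; 4 genetic; 5 high-throughput
        for pair, pmids in [("A1 B1", [1, 2]), ("A2 B2", [3, 4, 5])]:
            a, b = pair.split()
            for p in pmids:
                lines.append(f"{a}\t{b}\tphysical\tLow Throughput\t{p}")
        lines.append("A3\tB3\tphysical\tLow Throughput\t6")
        lines.append("A4\tB4\tgenetic\tLow Throughput\t7")
        lines.append("A5\tB5\tphysical\tHigh Throughput\t8")
        assert len(read_biogrid_table(lines, FilterPolicy(min_publications=2))) == 2


def rec(a, b, db="intact"):
    return InteractionRecord(id_a=a, id_b=b, taxid_a=9606, taxid_b=9606, source_db=db)


class TestMergeRecords:
    def test_same_pair_two_sources_one_edge_with_provenance(self):
        net = merge_records([[rec("A", "B", "intact")], [rec("B", "A", "biogrid")]])
        assert net.n_edges == 1
        assert net.edge_attrs("A", "B")["provenance"] == frozenset({"intact", "biogrid"})

    def test_disjoint_lists_sum(self):
        l1 = [rec(f"A{i}", f"B{i}") for i in range(3)]
        l2 = [rec(f"C{i}", f"D{i}", "string") for i in range(4)]
        assert merge_records([l1, l2]).n_edges == 7

    def test_merge_idempotent_and_order_independent(self, rng):
        lists = [
            [rec("A", "B"), rec("B", "C")],
            [rec("C", "B", "string"), rec("D", "E", "string")],
            [rec("A", "B", "biogrid")],
        ]
        ref = merge_records(lists)
        for perm in ([2, 1, 0], [1, 0, 2]):
            net = merge_records([lists[i] for i in perm])
            assert net.edges() == ref.edges()
            for u, v in net.edges():
                assert net.edge_attrs(u, v) == ref.edge_attrs(u, v)
        twice = merge_records(lists + lists)
        assert twice.edges() == ref.edges()


class TestPolicyProperties:
    def test_filtering_monotone_in_mi_score(self):
        """Raising the MI threshold never adds records (0.56 vs 0.65 style
        sensitivity grid on a synthetic interactome)."""
        lines, _ = generate_interactome(SyntheticSpec(rng_seed=11))
        previous = None
        for threshold in (0.2, 0.45, 0.56, 0.6, 0.65, 0.8, 0.95):
            kept = {
                r.pair for r in read_mitab(iter(lines), FilterPolicy(min_mi_score=threshold))
            }
            if previous is not None:
                assert kept <= previous
            previous = kept

    def test_every_kept_record_satisfies_policy(self):
        lines, _ = generate_interactome(SyntheticSpec(rng_seed=3))
        policy = FilterPolicy(min_mi_score=0.65)
        for r in read_mitab(iter(lines), policy):
            assert r.taxid_a == r.taxid_b == policy.taxid
            assert r.mi_score is not None and r.mi_score >= policy.min_mi_score
            assert r.interaction_type in policy.allowed_types
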