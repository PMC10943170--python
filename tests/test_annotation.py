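from __future__ import annotations

import itertools
import random

import networkx as nx
import pytest

from tcrgroups.annotate import (
    annotate_groups,
    build_group_network,
    hla_supertype_consistency,
    supertype_of,
    tabulate_antigen_sources,
    tetramer_consistency,
)
from tcrgroups.types import GroupScores, SpecificityGroup, TetramerRecord


def group_with(rec, gid, cdr3s, hla_enrichments=None):
    g = SpecificityGroup(
        group_id=gid,
        method="LOCAL",
        pattern=f"local {gid}",
        members=[rec(c, patient=f"P{i}") for i, c in enumerate(cdr3s)],
    )
    if hla_enrichments is not None:
        g.scores = GroupScores(hla_enrichments=hla_enrichments)
    return g


def tet(cdr3, epitope="GILGFVFTL", source="EBV", mhc="A*02"):
    return TetramerRecord(cdr3b_aa=cdr3, epitope=epitope, antigen_source=source, mhc_allele=mhc)


class TestAnnotateGroups:
    def test_exact_match_annotates_whole_group(self, rec):
        g = group_with(rec, "C1", ["CASSIRSSYEQYF", "CASSAAAAAAF"])
        (ann,) = annotate_groups([g], [tet("CASSIRSSYEQYF")])
        assert ann.annotated and ann.sources == {"EBV"}

    def test_no_match_leaves_unannotated(self, rec):
        g = group_with(rec, "C1", ["CASSAAAAAAF"])
        (ann,) = annotate_groups([g], [tet("CASSIRSSYEQYF")])
        assert not ann.annotated

    def test_multiple_sources_all_retained(self, rec):
        g = group_with(rec, "C1", ["CASSIRSSYEQYF"])
        db = [tet("CASSIRSSYEQYF", source="EBV"), tet("CASSIRSSYEQYF", epitope="NLVPMVATV", source="CMV")]
        (ann,) = annotate_groups([g], db)
        assert ann.sources == {"EBV", "CMV"}

    def test_idempotent_and_monotone_in_db(self, rec):
        g = group_with(rec, "C1", ["CASSIRSSYEQYF"])
        db = [tet("CASSIRSSYEQYF")]
        first = annotate_groups([g], db)
        again = annotate_groups([g], db)
        assert [a.epitopes for a in first] == [a.epitopes for a in again]
        bigger = annotate_groups([g], db + [tet("CASSZZZ")])
        assert bigger[0].annotated

    def test_empty_db_annotates_nothing(self, rec):
        g = group_with(rec, "C1", ["CASSAAAAAAF"])
        (ann,) = annotate_groups([g], [])
        assert not ann.annotated


class TestAntigenSourceTable:
    def test_split_proportions(self, rec):
        groups = [group_with(rec, f"C{i}", [f"CASSAA{chr(67+i)}AAF"]) for i in range(8)]
        db = [tet(f"CASSAA{chr(67+i)}AAF", source="EBV") for i in range(5)]
        annotations = annotate_groups(groups, db)
        ti_ids = {"C0", "C1", "C6"}  # C0, C1 annotated; C6 not
        table = tabulate_antigen_sources(annotations, ti_ids)
        row = table.set_index("antigen_source").loc["EBV"]
        assert row["n_ti_groups"] == 2 and row["prop_ti"] == pytest.approx(2 / 3)
        assert row["n_common_groups"] == 3 and row["prop_common"] == pytest.approx(3 / 5)

    def test_empty_annotations_give_empty_table(self):
        assert tabulate_antigen_sources([], set()).empty


class TestGroupNetwork:
    def test_shared_sequence_makes_edge(self, rec):
        a = group_with(rec, "A", ["CASSAAAAAAF", "CASSCCCCCCF"])
        b = group_with(rec, "B", ["CASSCCCCCCF", "CASSDDDDDDF"])
        c = group_with(rec, "C", ["CASSEEEEEEF"])
        net = build_group_network([a, b, c])
        assert set(net.edges) == {("A", "B")}
        comps = [sorted(x) for x in nx.connected_components(net)]
        assert sorted(comps) == [["A", "B"], ["C"]]

    def test_identical_groups_edge_but_no_self_loop(self, rec):
        a = group_with(rec, "A", ["CASSAAAAAAF"])
        b = group_with(rec, "B", ["CASSAAAAAAF"])
        net = build_group_network([a, b])
        assert set(net.edges) == {("A", "B")}
        assert not list(nx.selfloop_edges(net))

    def test_edges_match_brute_force_intersection_oracle(self, rec):
        rng = random.Random(5)
        cdr3_pool = [f"CASS{a}{b}DNEQF" for a in "ACDEFG" for b in "ACDEFG"]
        groups = [
            group_with(rec, f"G{i}", rng.sample(cdr3_pool, rng.randint(1, 5)))
            for i in range(12)
        ]
        net = build_group_network(groups)
        oracle = {
            tuple(sorted((a.group_id, b.group_id)))
            for a, b in itertools.combinations(groups, 2)
            if a.cdr3_set & b.cdr3_set
        }
        assert {tuple(sorted(e)) for e in net.edges} == oracle


class TestTetramerConsistency:
    def _pair(self, rec, i, source):
        shared = f"CASSP{chr(65 + i // 26)}{chr(65 + i % 26)}RDNEQF"
        a = group_with(rec, f"A{i}", [shared, f"CASSAA{chr(65 + i % 26)}{chr(65 + i // 26)}XAF"])
        b = group_with(rec, f"B{i}", [shared, f"CASSGG{chr(65 + i % 26)}{chr(65 + i // 26)}XGF"])
        db = [
            tet(a.members[1].cdr3b_aa, epitope=f"EPI{i}", source=source),
            tet(b.members[1].cdr3b_aa, epitope=f"EPI{i}", source=source),
        ]
        return [a, b], db

    def test_two_groups_same_tetramer_fully_consistent(self, rec):
        groups, db = self._pair(rec, 0, "EBV")
        annotations = annotate_groups(groups, db)
        report = tetramer_consistency(build_group_network(groups), annotations)
        assert (report.n_consistent, report.n_eligible, report.percent) == (2, 2, 100.0)

    def test_isolated_annotated_groups_not_applicable(self, rec):
        a = group_with(rec, "A", ["CASSAAAAAAF"])
        b = group_with(rec, "B", ["CASSCCCCCCF"])
        db = [tet("CASSAAAAAAF"), tet("CASSCCCCCCF", epitope="OTHER")]
        report = tetramer_consistency(build_group_network([a, b]), annotate_groups([a, b], db))
        assert report.n_eligible == 0 and report.percent is None

    def test_printed_percent_on_44_of_48_fixture(self, rec):
        groups, db = [], []
        for i in range(22):  # 22 consistent pairs = 44 consistent groups
            gs, entries = self._pair(rec, i, source="EBV" if i % 2 else "CMV")
            groups += gs
            db += entries
        for i in range(4):  # annotated groups whose only neighbor is unannotated
            shared = f"CASSQQ{chr(65 + i)}QRDNEQF"
            annotated = group_with(rec, f"X{i}", [shared, f"CASSWW{chr(65 + i)}WWAF"])
            naked = group_with(rec, f"Y{i}", [shared])
            groups += [annotated, naked]
            db.append(tet(annotated.members[1].cdr3b_aa, epitope=f"XEPI{i}", source="influenza"))
        annotations = annotate_groups(groups, db)
        report = tetramer_consistency(build_group_network(groups), annotations)
        assert (report.n_consistent, report.n_eligible) == (44, 48)
        assert report.percent == 91.7

    def test_percent_invariant_under_relabeling(self, rec):
        groups, db = self._pair(rec, 1, "CMV")
        for g, new in zip(groups, ("Z9", "Z1")):
            g.group_id = new
        annotations = annotate_groups(groups, db)
        report = tetramer_consistency(build_group_network(groups), annotations)
        assert report.percent == 100.0


class TestSupertypeConsistency:
    def test_concordant_and_discordant_groups(self, rec):
        concordant = group_with(
            rec, "C1", ["CASSAAAAAAF"], hla_enrichments=[("A*02", 3, 0.01)]
        )
        discordant = group_with(
            rec, "C2", ["CASSCCCCCCF"], hla_enrichments=[("DRB1*13", 2, 0.001)]
        )
        db = [tet("CASSAAAAAAF", mhc="HLA-A*02:01"), tet("CASSCCCCCCF", mhc="A*02")]
        annotations = annotate_groups([concordant, discordant], db)
        table = hla_supertype_consistency([concordant, discordant], annotations)
        row = table.set_index("supertype").loc["A*02"]
        assert row["n_annotated"] == 2 and row["n_concordant"] == 1
        assert row["percent"] == 50.0

    def test_planted_three_of_four_concordant(self, rec):
        groups, db = [], []
        for i in range(4):
            enr = [("A*11", 2, 0.01)] if i < 3 else [("B*44", 2, 0.01)]
            g = group_with(rec, f"C{i}", [f"CASSAA{chr(67 + i)}AAF"], hla_enrichments=enr)
            groups.append(g)
            db.append(tet(g.members[0].cdr3b_aa, mhc="A*11"))
        table = hla_supertype_consistency(groups, annotate_groups(groups, db))
        row = table.set_index("supertype").loc["A*11"]
        assert row["percent"] == 75.0

    def test_supertype_prefix_mapping(self):
        assert supertype_of("HLA-A*02:01") == "A*02"
        assert supertype_of("B*35:08") == "B*35"
        assert supertype_of("A*02:06", {"A*02": "A2-family"}) == "A2-family"
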