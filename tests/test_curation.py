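"""Replication filter, basetype/basegroup assembly, attribution."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from foramotu import curation
from foramotu.curation import (
    SequenceRecord,
    assemble_basegroups,
    attribute_partial,
    compute_diagnostic_sites,
    extract_basetypes,
    filter_replicated,
)


def rec(seq_id, individual, seq, quality="curated", **kw):
    return SequenceRecord(
        sequence_id=seq_id, individual_id=individual, station_id="S1",
        sequence=seq, quality=quality, **kw,
    )


class TestFilterReplicated:
    def test_all_identical_retained(self):
        records = [rec(f"s{i}", f"i{i}", "ACGT" * 5) for i in range(5)]
        curated, queue = filter_replicated(records, 3)
        assert len(curated) == 5 and not queue
        assert len({r.motif for r in curated}) == 1

    def test_threshold_boundary(self):
        records = [rec(f"a{i}", f"i{i}", "AAAA") for i in range(2)]
        records += [rec(f"b{i}", f"j{i}", "CCCC") for i in range(3)]
        curated, queue = filter_replicated(records, 3)
        assert {r.motif for r in curated} == {"CCCC"}
        assert {r.sequence_id for r in queue} == {"a0", "a1"}

    def test_partial_reads_never_define_basetypes(self):
        records = [rec(f"s{i}", f"i{i}", "GGGG", quality="partial")
                   for i in range(5)]
        curated, queue = filter_replicated(records, 3)
        assert not curated and len(queue) == 5

    def test_empty_input_warns(self, caplog):
        with caplog.at_level("WARNING"):
            curated, queue = filter_replicated([], 3)
        assert curated == [] and queue == []

    def test_study_dataset_retains_147(self, study_curation):
        assert len(study_curation["curated"]) == 147


class TestExtractBasetypes:
    def test_one_motif_one_basetype(self):
        records = [rec(f"s{i}", f"i{i}", "acg-t") for i in range(3)]
        bts = extract_basetypes(records)
        assert len(bts) == 1
        assert bts[0].motif == "ACGT"  # uppercased, gap-stripped
        assert bts[0].support == 3

    def test_study_dataset_17_basetypes(self, study_curation):
        assert len(study_curation["basetypes"]) == 17

    def test_synthetic_basetypes_match_planted_motifs(self, study_curation):
        planted = {
            r.motif for r in study_curation["curated"]
        }
        assert {bt.motif for bt in study_curation["basetypes"]} == planted


class TestAssembleBasegroups:
    def _records_for(self, assignments):
        """assignments: individual -> list of motifs carried."""
        out = []
        n = itertools.count()
        for ind, motifs in assignments.items():
            for m in motifs:
                out.append(rec(f"s{next(n)}", ind, m))
        return out

    def test_three_basetypes_two_individuals_one_basegroup(self):
        motifs = ["AAAA", "CCCC", "GGGG"]
        records = self._records_for(
            {"i1": motifs, "i2": motifs, "i3": ["AAAA"], "i4": ["CCCC"],
             "i5": ["GGGG"]}
        )
        bts = extract_basetypes(records)
        groups, rejected = assemble_basegroups(bts, records, 2)
        assert len(groups) == 1 and len(groups[0].basetypes) == 3
        assert not rejected

    def test_single_individual_cooccurrence_rejected(self):
        records = self._records_for(
            {"i1": ["AAAA", "CCCC"],
             "i2": ["AAAA"], "i3": ["AAAA"],
             "i4": ["CCCC"], "i5": ["CCCC"]}
        )
        bts = extract_basetypes(records)
        groups, rejected = assemble_basegroups(bts, records, 2)
        assert len(groups) == 2
        assert len(rejected) == 1
        assert rejected[0]["individuals"] == ["i1"]

    def test_study_dataset_15_basegroups_14_singletons(self, study_curation):
        groups = study_curation["basegroups"]
        assert len(groups) == 15
        sizes = sorted(len(g.basetypes) for g in groups)
        assert sizes == [1] * 14 + [3]
        assert len(study_curation["rejected"]) == 1

    @settings(max_examples=60, deadline=None)
    @given(st.lists(
        st.tuples(st.integers(0, 7), st.integers(0, 5)),
        min_size=1, max_size=30,
    ))
    def test_matches_bruteforce_components(self, pairs):
        """Connected components agree with a brute-force union-find on
        the accepted co-occurrence edges, and the merge identity
        basetypes - basegroups = sum(component size - 1) holds."""
        motifs = [f"{'ACGT'[b % 4]* 3}{b}" for b in range(8)]
        assignments = {}
        for bt, ind in pairs:
            assignments.setdefault(f"i{ind}", []).append(motifs[bt])
        # replicate every motif so the filter keeps them all
        for j, m in enumerate(set(itertools.chain(*assignments.values()))):
            assignments[f"fill{j}a"] = [m]
            assignments[f"fill{j}b"] = [m]
        records = self._records_for(assignments)
        bts = extract_basetypes(records)
        groups, _ = assemble_basegroups(bts, records, 2)

        # brute force: accepted edges then naive component closure
        witnesses = {}
        motif_to_bt = {bt.motif: bt.basetype_id for bt in bts}
        by_ind = {}
        for r in records:
            by_ind.setdefault(r.individual_id, set()).add(motif_to_bt[r.motif])
        for ind, s in by_ind.items():
            for a, b in itertools.combinations(sorted(s), 2):
                witnesses.setdefault((a, b), set()).add(ind)
        edges = [e for e, w in witnesses.items() if len(w) >= 2]
        comp = {bt.basetype_id: {bt.basetype_id} for bt in bts}
        changed = True
        while changed:
            changed = False
            for a, b in edges:
                union = comp[a] | comp[b]
                if union != comp[a] or union != comp[b]:
                    for t in union:
                        comp[t] = union
                    changed = True
        expected = {frozenset(c) for c in comp.values()}
        assert {frozenset(g.basetypes) for g in groups} == expected
        merged = sum(len(g.basetypes) - 1 for g in groups)
        assert len(bts) - len(groups) == merged


class TestDiagnosticSites:
    ALIGN = {"b1": "AACGT", "b2": "AGCGT", "b3": "AACGA"}

    def test_single_differing_column_is_diagnostic(self):
        table = compute_diagnostic_sites(
            {"b1": "AACGT", "b2": "AGCGT"},
            {"lvl1": {"b1": "X", "b2": "Y"}},
        )
        assert table.sites["lvl1"]["X"] == [(2, "A")]
        assert table.sites["lvl1"]["Y"] == [(2, "G")]

    def test_identical_motifs_yield_warning(self):
        table = compute_diagnostic_sites(
            {"b1": "AAAA", "b2": "AAAA"},
            {"lvl1": {"b1": "X", "b2": "Y"}},
        )
        assert table.sites["lvl1"]["X"] == []
        assert any("no diagnostic site" in w for w in table.warnings)

    def test_single_taxon_level_empty(self):
        table = compute_diagnostic_sites(
            {"b1": "AAAA"}, {"lvl1": {"b1": "X"}}
        )
        assert table.sites["lvl1"] == {}

    def test_planted_sites_subset_of_mutated_columns(self, study_curation,
                                                     study_hierarchy):
        """On the synthetic hierarchy every diagnostic site is a column
        where the planted mutation process actually substituted."""
        alignment = study_hierarchy["alignment"]
        hier = study_hierarchy["hierarchy"].assignments
        labels = {lvl: hier[lvl].to_dict() for lvl in ("lvl1", "lvl2", "lvl3")}
        table = compute_diagnostic_sites(alignment, labels)
        variable_cols = {
            c + 1 for c in range(len(next(iter(alignment.values()))))
            if len({s[c] for s in alignment.values()}) > 1
        }
        for level_sites in table.sites.values():
            for sites in level_sites.values():
                assert {c for c, _ in sites} <= variable_cols


class TestAttributePartial:
    def _setup(self):
        alignment = {
            "b1": "AAAAAAAACC",
            "b2": "AAAAAAAAGG",
            "b3": "TTTTAAAACC",
        }
        labels = {
            "lvl1": {"b1": "I", "b2": "I", "b3": "II"},
            "lvl2": {"b1": "Ia", "b2": "Ib", "b3": "IIa"},
        }
        table = compute_diagnostic_sites(alignment, labels)
        return alignment, labels, table

    def test_full_length_copy_gets_finest_label(self):
        alignment, labels, table = self._setup()
        r = rec("p1", "i1", "AAAAAAAACC", quality="partial")
        out = attribute_partial(r, table, alignment, labels)
        assert out["label"] == "Ia" and out["level"] == "lvl2"

    def test_fragment_covering_only_coarse_sites(self):
        alignment, labels, table = self._setup()
        # prefix covers the lvl1-diagnostic columns 1-4 but not 9-10
        r = rec("p2", "i1", "AAAAAA", quality="partial")
        out = attribute_partial(r, table, alignment, labels)
        assert out["level"] == "lvl1" and out["label"] == "I"

    def test_conflicting_states_unassigned(self):
        alignment, labels, table = self._setup()
        # lvl1 sites say II (TTTT) while suffix matches I's children -> the
        # first level already contradicts, nothing can be assigned cleanly
        r = rec("p3", "i1", "TTTTAAAAGG", quality="partial")
        out = attribute_partial(r, table, alignment, labels)
        assert out["conflicts"] or out["label"] != "Ia"

    def test_no_overlap_unassigned(self):
        alignment, labels, table = self._setup()
        r = rec("p4", "i1", "GGGGGGGGGG", quality="partial")
        out = attribute_partial(r, table, alignment, labels)
        assert out["label"] == "unassigned"

    def test_untruncated_curated_sequences_get_full_label(
        self, study_curation, study_hierarchy
    ):
        alignment = study_hierarchy["alignment"]
        hier = study_hierarchy["hierarchy"].assignments
        labels = {lvl: hier[lvl].to_dict() for lvl in ("lvl1", "lvl2", "lvl3")}
        table = compute_diagnostic_sites(alignment, labels)
        motif_to_bt = {m: bt for bt, m in alignment.items()}
        for r in study_curation["curated"][:20]:
            out = attribute_partial(r, table, alignment, labels)
            bt = motif_to_bt[r.motif]
            assert out["label"] == hier.loc[bt, "lvl3"]
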