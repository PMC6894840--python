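"""K80 distances, barcode-gap partitioning, PTP, hierarchy assembly."""

import math

import dendropy
import numpy as np
import pandas as pd
import pytest

from foramotu import delimitation as dl
from foramotu.curation import Basegroup
from foramotu.delimitation import (
    AbgdConfig,
    abgd_partition,
    build_hierarchy,
    import_partition,
    k80_distance,
    k80_pair,
    ptp_exhaustive,
    ptp_partition,
)


class TestK80:
    def test_identical_sequences_distance_zero(self):
        d, P, Q = k80_pair("ACGTACGT", "ACGTACGT")
        assert d == 0.0 and P == 0.0 and Q == 0.0

    def test_hand_evaluated_closed_form(self):
        # one transition and one transversion over five sites
        d, P, Q = k80_pair("AACGT", "AGCGA")
        assert P == pytest.approx(0.2) and Q == pytest.approx(0.2)
        expected = -0.5 * math.log(0.4) - 0.25 * math.log(0.6)
        assert d == pytest.approx(expected, abs=1e-9)
        assert d == pytest.approx(0.5858, abs=1e-4)

    def test_saturated_pair_flagged_infinite(self):
        # P + Q at the domain boundary: log argument <= 0
        d, _, _ = k80_pair("AAAA", "GGGG")
        assert math.isinf(d)
        dm = k80_distance({"a": "AAAA", "b": "GGGG"})
        assert ("a", "b") in dm.saturated

    def test_complete_deletion_of_gap_columns(self):
        d_full, *_ = k80_pair("ACGT", "ACGT")
        d_gap, *_ = k80_pair("AC-T", "ACGT")
        assert d_full == d_gap == 0.0
        with pytest.raises(ValueError, match="no comparable columns"):
            k80_pair("----", "ACGT")

    def test_matrix_symmetric_zero_diagonal(self):
        dm = k80_distance({"a": "ACGTAC", "b": "ACGTAA", "c": "ATGTAC"})
        assert np.allclose(dm.d, dm.d.T)
        assert np.allclose(np.diag(dm.d), 0.0)


def _planted_matrix(blocks, intra, inter, seed=0):
    """Distance matrix with within-block distances ~intra and
    between-block distances ~inter."""
    rng = np.random.default_rng(seed)
    taxa = [f"t{i:02d}" for i in range(sum(blocks))]
    labels = np.repeat(np.arange(len(blocks)), blocks)
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            base = intra if labels[i] == labels[j] else inter
            val = base * rng.uniform(0.8, 1.2)
            d[i, j] = d[j, i] = val
    return dl.DistanceMatrix(taxa=taxa, d=d, P=d * 0, Q=d * 0), labels


class TestAbgd:
    def test_all_distances_equal_single_group(self):
        n = 6
        d = np.full((n, n), 0.05)
        np.fill_diagonal(d, 0.0)
        dm = dl.DistanceMatrix(
            taxa=[f"t{i}" for i in range(n)], d=d, P=d * 0, Q=d * 0
        )
        ladder, initial, recursive = abgd_partition(dm)
        assert initial.n_groups == 1 and recursive.n_groups == 1

    def test_planted_two_cluster_gap(self):
        dm, labels = _planted_matrix([4, 4], intra=0.008, inter=0.12)
        _, initial, recursive = abgd_partition(
            dm, AbgdConfig(Pmin=0.001, Pmax=0.1)
        )
        assert initial.n_groups == 2
        assert recursive.n_groups == 2
        groups = pd.Series(initial.groups)
        for block in (0, 1):
            members = [t for t, l in zip(dm.taxa, labels) if l == block]
            assert groups[members].nunique() == 1

    def test_three_level_hierarchy_initial_top_recursive_finest(self):
        """Nested clusters: initial finds the dominant (top-level) gap,
        recursion descends to the finest planted clusters."""
        rng = np.random.default_rng(1)
        # 2 top-level clades x 2 subclades x 3 taxa
        taxa = [f"t{i:02d}" for i in range(12)]
        top = np.repeat([0, 1], 6)
        sub = np.repeat([0, 1, 2, 3], 3)
        n = 12
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                if sub[i] == sub[j]:
                    base = 0.004
                elif top[i] == top[j]:
                    base = 0.04
                else:
                    base = 0.25
                val = base * rng.uniform(0.9, 1.1)
                d[i, j] = d[j, i] = val
        dm = dl.DistanceMatrix(taxa=taxa, d=d, P=d * 0, Q=d * 0)
        _, initial, recursive = abgd_partition(dm)
        assert initial.n_groups == 2
        assert recursive.n_groups == 4
        rec_groups = pd.Series(recursive.groups)
        for s in range(4):
            members = [t for t, l in zip(taxa, sub) if l == s]
            assert rec_groups[members].nunique() == 1

    @pytest.mark.parametrize("seed", range(3))
    def test_group_count_monotone_in_prior(self, seed):
        dm, _ = _planted_matrix([3, 3, 3], intra=0.01, inter=0.15, seed=seed)
        ladder, *_ = abgd_partition(dm, AbgdConfig(n_steps=12))
        counts = [p.n_groups for _, p, _ in ladder]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_fewer_than_two_taxa_rejected(self):
        dm = dl.DistanceMatrix(taxa=["a"], d=np.zeros((1, 1)),
                               P=np.zeros((1, 1)), Q=np.zeros((1, 1)))
        with pytest.raises(ValueError):
            abgd_partition(dm)


def _tree(newick):
    return dendropy.Tree.get(data=newick, schema="newick")


def _group_sets(partition):
    groups = {}
    for t, g in partition.groups.items():
        groups.setdefault(g, set()).add(t)
    return {frozenset(g) for g in groups.values()}


class TestPtp:
    def test_star_tree_equal_branches_single_group(self):
        p = ptp_partition(_tree("(a:0.1,b:0.1,c:0.1,d:0.1):0.0;"))
        assert p.n_groups == 1

    def test_two_clades_with_long_stems(self):
        nwk = ("((a:0.01,b:0.012,c:0.011):0.3,"
               "(d:0.01,e:0.013,f:0.012):0.3):0.0;")
        p = ptp_partition(_tree(nwk))
        assert _group_sets(p) == {frozenset("abc"), frozenset("def")}

    def test_zero_length_tree_single_group(self):
        p = ptp_partition(_tree("(a:0.0,b:0.0):0.0;"))
        assert p.n_groups == 1

    @pytest.mark.parametrize("seed", range(10))
    def test_greedy_equals_exhaustive_on_small_trees(self, seed):
        """Random birth-death-like trees with two planted rate classes:
        the greedy search attains the exhaustive optimum (<=12 tips)."""
        import random

        rng = np.random.default_rng(seed)
        n_tips = int(rng.integers(4, 13))
        taxa = dendropy.TaxonNamespace([f"t{i}" for i in range(n_tips)])
        tree = dendropy.simulate.treesim.birth_death_tree(
            birth_rate=1.0, death_rate=0.0, taxon_namespace=taxa,
            num_extant_tips=n_tips, rng=random.Random(seed),
        )
        # rescale: internal edges long (speciation), pendant edges short
        for edge in tree.preorder_edge_iter():
            if edge.length is None:
                continue
            if edge.head_node.is_leaf():
                edge.length = float(rng.uniform(0.005, 0.02))
            else:
                edge.length = float(rng.uniform(0.2, 0.5))
        greedy = ptp_partition(tree)
        exact = ptp_exhaustive(tree)
        assert _group_sets(greedy) == _group_sets(exact)

    def test_import_path_pass_through(self):
        frame = pd.DataFrame(
            {"basetype_id": ["a", "b", "c"], "group": ["g1", "g1", "g2"]}
        )
        p = import_partition(frame)
        assert p.groups == {"a": "g1", "b": "g1", "c": "g2"}
        assert p.method == "imported"


def _partition(method, mapping):
    return dl.Partition(method=method, parameters={}, groups=mapping)


class TestBuildHierarchy:
    def test_single_basetype_trivial_hierarchy(self):
        bgs = [Basegroup(basegroup_id="BG1", basetypes=["b1"])]
        h = build_hierarchy(
            [_partition("abgd_initial", {"b1": "g1"})], bgs, {"b1": "sp1"}
        )
        row = h.assignments.loc["b1"]
        assert (row["lvl1"], row["lvl2"], row["lvl3"]) == ("I", "Ia", "Ia1")

    def test_oversplit_partition_rejected_naming_basegroup(self):
        bgs = [Basegroup(basegroup_id="BG1", basetypes=["b1", "b2"]),
               Basegroup(basegroup_id="BG2", basetypes=["b3"])]
        morpho = {"b1": "sp1", "b2": "sp1", "b3": "sp1"}
        good = _partition("abgd_initial", {"b1": "x", "b2": "x", "b3": "x"})
        bad = _partition("ptp", {"b1": "x", "b2": "y", "b3": "y"})
        h = build_hierarchy([good, bad], bgs, morpho)
        assert len(h.validation["discarded"]) == 1
        viol = h.validation["discarded"][0]["violations"][0]
        assert viol["type"] == "oversplit" and viol["basegroup"] == "BG1"

    def test_lumping_partition_rejected(self):
        bgs = [Basegroup(basegroup_id="BG1", basetypes=["b1"]),
               Basegroup(basegroup_id="BG2", basetypes=["b2"])]
        morpho = {"b1": "sp1", "b2": "sp2"}
        lumping = _partition("abgd_initial", {"b1": "x", "b2": "x"})
        fine = _partition("abgd_recursive", {"b1": "x", "b2": "y"})
        h = build_hierarchy([lumping, fine], bgs, morpho)
        assert h.validation["discarded"][0]["violations"][0]["type"] == "lumping"
        # the surviving partition serves as both coarsest and finest
        assert h.assignments["lvl1"].nunique() == 2

    def test_all_partitions_invalid_errors(self):
        bgs = [Basegroup(basegroup_id="BG1", basetypes=["b1", "b2"])]
        morpho = {"b1": "sp1", "b2": "sp1"}
        bad = _partition("ptp", {"b1": "x", "b2": "y"})
        with pytest.raises(ValueError, match="invalid"):
            build_hierarchy([bad], bgs, morpho)

    def test_nesting_invariant_on_study_hierarchy(self, study_hierarchy):
        """Every lvl-3 group maps into exactly one lvl-2 group, every
        lvl-2 into exactly one lvl-1."""
        a = study_hierarchy["hierarchy"].assignments
        assert (a.groupby("lvl3")["lvl2"].nunique() == 1).all()
        assert (a.groupby("lvl2")["lvl1"].nunique() == 1).all()

    def test_study_counts_match_survey(self, study_hierarchy):
        a = study_hierarchy["hierarchy"].assignments
        ingroup = a[a["morphospecies"] != "G_rubescens"]
        assert ingroup["lvl2"].nunique() == 8
        assert ingroup["morphospecies"].nunique() == 5
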