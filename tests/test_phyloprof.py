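"""Profiling tests: trimming, distances, NJ, rooting, Dollo, classification."""

from __future__ import annotations

import math

import dendropy
import numpy as np
import pytest

from orthoprof.alignment import MSA
from orthoprof.phyloprof import (
    GeneTree,
    bootstrap_support,
    build_presence_matrix,
    classify_paralogs,
    distance_matrix,
    distribution_label,
    dollo_ancestral,
    midpoint_root,
    nj_tree,
    trim_alignment,
)
from orthoprof.seqsim import SpeciesTree, simulate_species_tree

from .oracles import (
    all_rooted_shapes,
    all_unrooted_topologies,
    dollo_oracle,
    label_shape,
    shape_to_newick,
)


class TestTrim:
    def test_gap_free_unchanged(self):
        msa = MSA(["a", "b"], ["MKLV", "MRLV"])
        out = trim_alignment(msa, 0.5)
        assert out.rows == msa.rows

    def test_all_gap_column_removed_at_any_threshold(self):
        msa = MSA(["a", "b"], ["M-K", "M-R"])
        for thr in (0.0, 0.3, 0.7, 0.99):
            assert trim_alignment(msa, thr).n_cols == 2

    def test_half_gap_column_threshold_boundary(self):
        msa = MSA(["a", "b", "c", "d"], ["MK", "M-", "MK", "M-"])
        assert trim_alignment(msa, 0.4).n_cols == 1  # 50% gaps > 0.4 -> dropped
        assert trim_alignment(msa, 0.6).n_cols == 2  # 50% <= 0.6 -> kept

    def test_row_order_preserved(self):
        msa = MSA(["b", "a"], ["MK", "MR"])
        assert trim_alignment(msa, 0.5).names == ["b", "a"]


class TestDistances:
    def test_identical_rows_zero(self):
        names, d = distance_matrix(MSA(["a", "b"], ["MKLV", "MKLV"]))
        assert d[0, 1] == 0.0

    def test_hand_toy_poisson_correction(self):
        a = "AAAAAAAAAA"
        b = "CCAAAAAAAA"  # 2 mismatches over 10 shared columns
        names, d = distance_matrix(MSA(["a", "b"], [a, b]))
        assert d[0, 1] == pytest.approx(-math.log(0.8))

    def test_saturated_rows_capped(self):
        names, d = distance_matrix(MSA(["a", "b"], ["AAAA", "CCCC"]))
        assert d[0, 1] == pytest.approx(-math.log(1 - 0.95))

    def test_symmetric_zero_diagonal(self):
        msa = MSA(["a", "b", "c"], ["MKLV", "MRLV", "MKIV"])
        _, d = distance_matrix(msa)
        assert np.allclose(d, d.T) and np.allclose(np.diag(d), 0)


class TestNeighborJoining:
    def test_four_taxon_additive_unique_topology(self):
        # tree ((A:1,B:2):1,(C:3,D:4)) -> the only split is AB|CD
        names = ["A", "B", "C", "D"]
        d = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float
        )
        gt = nj_tree(names, d)
        assert gt.splits() == {frozenset({"C", "D"})}

    def test_three_taxa_closed_form_lengths(self):
        """The single unrooted 3-taxon topology reproduces the input distances
        exactly (limbs la=1, lb=2, lc=3 solve the three path equations)."""
        names = ["A", "B", "C"]
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        gt = nj_tree(names, d)
        pdm = gt.tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in gt.tree.taxon_namespace}
        for i, a in enumerate(names):
            for j, b in enumerate(names):
                if i < j:
                    assert pdm.distance(taxa[a], taxa[b]) == pytest.approx(d[i, j])

    def test_permutation_invariance(self, rng):
        topo = all_unrooted_topologies(["A", "B", "C", "D", "E"])[3]
        names, d = topo.additive_matrix(rng)
        base = nj_tree(names, d).splits()
        perm = rng.permutation(len(names))
        names_p = [names[i] for i in perm]
        d_p = d[np.ix_(perm, perm)]
        assert nj_tree(names_p, d_p).splits() == base

    @pytest.mark.parametrize("n_taxa", [4, 5, 6])
    def test_all_topologies_recovered_from_additive_matrices(self, n_taxa):
        """NJ recovers the generating topology for every unrooted shape."""
        taxa = [f"t{i}" for i in range(n_taxa)]
        rng = np.random.default_rng(1234 + n_taxa)
        topologies = all_unrooted_topologies(taxa)
        assert len(topologies) == {4: 3, 5: 15, 6: 105}[n_taxa]
        for topo in topologies:
            names, d = topo.additive_matrix(rng)
            gt = nj_tree(names, d)
            assert gt.splits() == topo.splits()

    def test_matches_skbio_on_random_additive_matrices(self, rng):
        """Cross-check against scikit-bio's independent NJ implementation."""
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        taxa = [f"t{i}" for i in range(6)]
        for topo in all_unrooted_topologies(taxa)[::20]:
            names, d = topo.additive_matrix(rng)
            ours = nj_tree(names, d).splits()
            sk_tree = skbio_nj(DistanceMatrix(d, names))
            all_leaves = set(names)
            ref = min(all_leaves)
            sk_splits = set()
            for node in sk_tree.traverse(include_self=False):
                if node.is_tip():
                    continue
                side = {t.name for t in node.tips()}
                if ref in side:
                    side = all_leaves - side
                if 1 < len(side) < len(all_leaves) - 1:
                    sk_splits.add(frozenset(side))
            assert ours == sk_splits

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(["A", "B"], np.zeros((2, 2)))


def _depths(tree):
    out = {}
    for lf in tree.leaf_node_iter():
        t, nd = 0.0, lf
        while nd.parent_node is not None:
            t += nd.edge.length or 0.0
            nd = nd.parent_node
        out[lf.taxon.label] = t
    return out


class TestMidpointRoot:
    def test_two_leaf_branch_split_evenly(self):
        t = dendropy.Tree.get(data="(A:1.0,B:3.0);", schema="newick",
                              preserve_underscores=True)
        gt = GeneTree(t, {"A": "A", "B": "B"}, {})
        rooted = midpoint_root(gt)
        depths = _depths(rooted.tree)
        assert depths["A"] == pytest.approx(2.0)
        assert depths["B"] == pytest.approx(2.0)

    def test_caterpillar_hand_computed(self):
        # diameter path A..D has length 1+1+1+4 = 7 -> midpoint 3.5 inside D's edge
        t = dendropy.Tree.get(
            data="(((A:1.0,B:1.0):1.0,C:1.0):1.0,D:4.0);", schema="newick",
            preserve_underscores=True,
        )
        gt = GeneTree(t, {x: x for x in "ABCD"}, {})
        rooted = midpoint_root(gt)
        depths = _depths(rooted.tree)
        assert depths["A"] == pytest.approx(3.5)
        assert depths["D"] == pytest.approx(3.5)

    def test_equidistance_on_random_trees(self, rng):
        for i in range(100):
            n = int(rng.integers(4, 10))
            taxa = [f"t{i}" for i in range(n)]
            topo_list = all_unrooted_topologies(taxa[:4])
            topo = topo_list[int(rng.integers(len(topo_list)))]
            for extra in taxa[4:]:
                edges = list(topo.edges())
                topo.insert_leaf(extra, edges[int(rng.integers(len(edges)))])
            names, d = topo.additive_matrix(rng)
            gt = nj_tree(names, d)
            rooted = midpoint_root(gt)
            depths = _depths(rooted.tree)
            diameter = max(
                d[i, j] for i in range(len(names)) for j in range(len(names))
            )
            assert max(depths.values()) == pytest.approx(diameter / 2, abs=1e-9)

    def test_deterministic_tie_break(self):
        t = dendropy.Tree.get(
            data="((A:2.0,B:2.0):1.0,(C:2.0,D:2.0):1.0);", schema="newick",
            preserve_underscores=True,
        )
        gt = GeneTree(t, {x: x for x in "ABCD"}, {})
        r1 = midpoint_root(gt).newick()
        r2 = midpoint_root(gt).newick()
        assert r1 == r2


class TestBootstrap:
    def _two_clan_msa(self):
        rows = {
            "a1": "AAAAAAAAAACCCCCCCCCC",
            "a2": "AAAAAAAAAACCCCCCCCCG",
            "a3": "AAAAAAAAAACCCCCCCCGG",
            "a4": "AAAAAAAAAACCCCCCCGGG",
            "b1": "WWWWWWWWWWPPPPPPPPPP",
            "b2": "WWWWWWWWWWPPPPPPPPPG",
            "b3": "WWWWWWWWWWPPPPPPPPGG",
            "b4": "WWWWWWWWWWPPPPPPPGGG",
        }
        return MSA(sorted(rows), [rows[k] for k in sorted(rows)])

    def test_saturated_signal_full_support(self):
        msa = self._two_clan_msa()
        gt = bootstrap_support(msa, n_reps=100, seed=3)
        clan_a = frozenset({"b1", "b2", "b3", "b4"})  # normalized away from 'a1'
        assert gt.supports[clan_a] == pytest.approx(100.0)

    def test_zero_reps_flagged_absent(self):
        gt = bootstrap_support(self._two_clan_msa(), n_reps=0, seed=3)
        assert gt.supports is None

    def test_same_seed_identical_supports(self):
        msa = self._two_clan_msa()
        g1 = bootstrap_support(msa, n_reps=50, seed=9)
        g2 = bootstrap_support(msa, n_reps=50, seed=9)
        assert g1.supports == g2.supports


class TestClassifyParalogs:
    def _gt(self, newick, species, supergroups, kingdoms=None):
        t = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
        return GeneTree(t, species, supergroups, kingdoms or {})

    def test_lineage_restricted_duplicate_called_in_paralog(self):
        """Pattern of a species-specific receptor duplicate: the two yeast
        copies sit together, their split is an in-paralog in that species."""
        gt = self._gt(
            "((R5_sc:1,R9_sc:1):1,(R5_hs:1,R5_at:1):1);",
            {"R5_sc": "sc", "R9_sc": "sc", "R5_hs": "hs", "R5_at": "at"},
            {"R5_sc": "Opisthokonta", "R9_sc": "Opisthokonta",
             "R5_hs": "Opisthokonta", "R5_at": "Archaeplastida"},
        )
        calls = classify_paralogs(gt)
        assert len(calls) == 1
        assert calls[0].classification == "in-paralog"
        assert calls[0].implicated_clade == "sc"

    def test_ancestral_split_called_deep(self):
        """Two subfamilies each spanning several supergroups: the basal split
        is an ancestral (deep) duplication."""
        sp = {f"{g}_{x}": x for g in ("A1", "A2") for x in ("hs", "sc", "tb")}
        sg = {}
        for k in sp:
            sg[k] = {"hs": "Opisthokonta", "sc": "Opisthokonta", "tb": "Excavata"}[sp[k]]
        gt = self._gt(
            "((A1_hs:1,(A1_sc:1,A1_tb:1):1):1,(A2_hs:1,(A2_sc:1,A2_tb:1):1):1);",
            sp, sg,
        )
        calls = classify_paralogs(gt)
        deep = [c for c in calls if c.classification == "deep"]
        assert len(deep) == 1
        assert deep[0].node_leaves == frozenset(sp)
        assert deep[0].implicated_clade == "Eukaryotes"

    def test_one_gene_per_species_no_calls(self):
        gt = self._gt(
            "((g1:1,g2:1):1,g3:1);",
            {"g1": "s1", "g2": "s2", "g3": "s3"},
            {"g1": "SAR", "g2": "SAR", "g3": "Excavata"},
        )
        assert classify_paralogs(gt) == []

    def test_unrooted_tree_rejected(self):
        t = dendropy.Tree.get(data="(A:1,B:1,C:1);", schema="newick",
                              preserve_underscores=True)
        gt = GeneTree(t, {x: x for x in "ABC"}, {x: "SAR" for x in "ABC"})
        with pytest.raises(ValueError, match="root"):
            classify_paralogs(gt)


class TestPresenceMatrix:
    @pytest.fixture(scope="class")
    def table(self):
        return simulate_species_tree(
            6,
            {"Opisthokonta:Metazoa": 1, "Opisthokonta:Fungi": 2, "Amoebozoa": 1,
             "SAR": 1, "Excavata": 1},
            seed=5,
        ).species_table()

    def test_everywhere_labels_eukaryotes(self, table):
        assert distribution_label(set(table.species), table) == "Eukaryotes"

    def test_fungi_only_labels_fungi(self, table):
        fungi = {i.species for i in table if i.kingdom == "Fungi"}
        assert distribution_label(fungi, table) == "Fungi"

    def test_multi_clade_sorted_list(self, table):
        amo = next(i.species for i in table if i.supergroup == "Amoebozoa")
        sar = next(i.species for i in table if i.supergroup == "SAR")
        assert distribution_label({amo, sar}, table) == "Amoebozoa/SAR"

    def test_empty_assignments_all_false(self, table):
        import pandas as pd

        empty = pd.DataFrame(columns=["family", "species", "gene", "status"])
        pm = build_presence_matrix(empty, table)
        assert pm.data.shape[0] == 0

    def test_matrix_from_assignments(self, table):
        import pandas as pd

        rows = [
            {"family": "f1", "species": sp, "gene": f"g_{sp}", "status": "kept"}
            for sp in table.species
        ] + [
            {"family": "f2", "species": table.species[0], "gene": "x", "status": "kept"},
            {"family": "f2", "species": table.species[1], "gene": "y", "status": "removed"},
        ]
        pm = build_presence_matrix(pd.DataFrame(rows), table)
        assert pm.labels["f1"] == "Eukaryotes"
        assert pm.data.loc["f2"].sum() == 1  # removed row does not count
        assert list(pm.data.columns) == table.species

    def test_tsv_column_order_matches_metadata(self, table, tmp_path):
        import pandas as pd

        rows = [{"family": "f1", "species": table.species[0], "gene": "g", "status": "kept"}]
        pm = build_presence_matrix(pd.DataFrame(rows), table)
        path = tmp_path / "pm.tsv"
        pm.to_tsv(path)
        header = path.read_text().splitlines()[0].split("\t")
        assert header == ["family"] + table.species + ["distribution"]


def _species_tree_from_shape(shape):
    newick = shape_to_newick(shape)
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    k = 0
    for node in tree.preorder_node_iter():
        if not node.is_leaf():
            node.label = f"N{k}"
            k += 1
    labels = {lf.taxon.label: "Opisthokonta" for lf in tree.leaf_node_iter()}
    return SpeciesTree(tree, labels)


class TestDollo:
    def test_all_present_gain_at_root_no_losses(self):
        st = _species_tree_from_shape(label_shape(all_rooted_shapes(5)[0]))
        rec = dollo_ancestral({s: True for s in st.species}, st)
        assert rec.gain_node == "N0" and rec.loss_branches == []

    def test_sister_loss_scenario(self):
        """Present in one leaf, absent in its sister: a single terminal loss
        below their common ancestor."""
        t = dendropy.Tree.get(
            data="((Dd:1.0,Eh:1.0)N1:1.0,Out:1.0)N0;", schema="newick",
            preserve_underscores=True,
        )
        t.seed_node.label = "N0"
        st = SpeciesTree(t, {"Dd": "Amoebozoa", "Eh": "Amoebozoa", "Out": "SAR"})
        rec = dollo_ancestral({"Dd": True, "Eh": False, "Out": True}, st)
        assert rec.loss_branches == ["Eh"]
        assert rec.gain_node == "N0"

    def test_empty_presence_rejected(self):
        st = _species_tree_from_shape(label_shape(all_rooted_shapes(4)[0]))
        with pytest.raises(ValueError):
            dollo_ancestral({s: False for s in st.species}, st)

    def test_all_shapes_all_rows_match_brute_force(self):
        """Every presence row on every 8-leaf rooted shape reproduces the
        enumerated minimal single-gain explanation."""
        shapes = all_rooted_shapes(8)
        assert len(shapes) == 23
        for shape in shapes:
            labeled = label_shape(shape)
            st = _species_tree_from_shape(labeled)
            leaves = st.species
            assert len(leaves) == 8
            for mask in range(1, 256):
                present = {s: bool(mask >> i & 1) for i, s in enumerate(leaves)}
                pres_set = {s for s, v in present.items() if v}
                rec = dollo_ancestral(present, st)
                min_losses, gain_sets = dollo_oracle(labeled, pres_set)
                assert len(rec.loss_branches) == min_losses, (labeled, pres_set)
                # gain node leaf set must be one of the optimal gains (the MRCA)
                gain_node = None
                for node in st.tree.preorder_node_iter():
                    label = node.taxon.label if node.is_leaf() else node.label
                    if label == rec.gain_node:
                        gain_node = node
                        break
                gain_leaves = frozenset(
                    lf.taxon.label for lf in gain_node.leaf_iter()
                )
                assert gain_leaves in gain_sets

    def test_pruning_present_leaf_increases_losses_by_at_most_one(self, rng):
        shapes = all_rooted_shapes(8)
        labeled = label_shape(shapes[7])
        st = _species_tree_from_shape(labeled)
        leaves = st.species
        for _ in range(50):
            mask = int(rng.integers(3, 256))
            present = {s: bool(mask >> i & 1) for i, s in enumerate(leaves)}
            pres = [s for s, v in present.items() if v]
            if len(pres) < 2:
                continue
            base = len(dollo_ancestral(present, st).loss_branches)
            drop = dict(present)
            drop[pres[0]] = False
            after = len(dollo_ancestral(drop, st).loss_branches)
            assert after <= base + 1
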