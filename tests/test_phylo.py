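import dendropy
import numpy as np
import pytest
from dendropy.calculate import treecompare

from tierminer import phylo
from tierminer.formats_io import parse_newick_string
from tierminer.homology import ReferenceEntry, align_global
from tierminer.tiering import MotifEvidence


def _ref(rid, label="CDDP", group="V", **kw):
    return ReferenceEntry(rid, "A" * 60, label, group, **kw)


def random_additive_tree(n_leaves, rng):
    """Random binary tree with positive branch lengths + its path-distance matrix."""
    taxa = [f"t{i}" for i in range(n_leaves)]
    ns = dendropy.TaxonNamespace(taxa)
    tree = dendropy.Tree(taxon_namespace=ns)
    nodes = [dendropy.Node(taxon=ns.get_taxon(t)) for t in taxa]
    active = list(nodes)
    while len(active) > 1:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        parent = dendropy.Node()
        for k in (i, j):
            parent.add_child(active[k])
            active[k].edge.length = float(rng.uniform(0.1, 1.0))
        active = [a for idx, a in enumerate(active) if idx not in (i, j)] + [parent]
    tree.seed_node = active[0]
    tree.is_rooted = False
    tree.update_bipartitions()

    # path distances computed by hand (independent of any library matrix code)
    depth: dict[dendropy.Node, float] = {tree.seed_node: 0.0}
    parent_of: dict[dendropy.Node, dendropy.Node] = {}
    for node in tree.preorder_node_iter():
        for ch in node.child_nodes():
            parent_of[ch] = node
            depth[ch] = depth[node] + ch.edge.length

    def ancestors(node):
        out = [node]
        while node in parent_of:
            node = parent_of[node]
            out.append(node)
        return out

    leaf_of = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}
    d = np.zeros((n_leaves, n_leaves))
    for i in range(n_leaves):
        for j in range(i + 1, n_leaves):
            a, b = leaf_of[taxa[i]], leaf_of[taxa[j]]
            anc_a = ancestors(a)
            anc_b = set(ancestors(b))
            lca = next(x for x in anc_a if x in anc_b)
            d[i, j] = d[j, i] = depth[a] + depth[b] - 2 * depth[lca]
    return tree, phylo.DistanceMatrix(taxa, d)


class TestPdistance:
    def test_identical_pair_zero(self):
        seqs = [("a", "MKLVAC" * 10), ("b", "MKLVAC" * 10), ("c", "WWWWWW" * 10)]
        dm = phylo.pdistance_matrix(seqs)
        assert dm.d[0, 1] == 0.0

    def test_one_in_ten_differs(self):
        a = "ACDEFGHIKL"
        b = "ACDEFGHIKM"  # one mismatch, no gaps
        dm = phylo.pdistance_matrix([("a", a * 3), ("b", (b * 3)), ("c", "W" * 30)])
        # 3 mismatches over 30 comparable columns
        assert dm.d[0, 1] == pytest.approx(0.1)

    def test_symmetry_and_zero_diagonal(self, rng):
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        seqs = [(f"s{i}", "".join(rng.choice(aa, size=40))) for i in range(4)]
        dm = phylo.pdistance_matrix(seqs)
        assert np.allclose(dm.d, dm.d.T)
        assert np.allclose(np.diag(dm.d), 0)

    def test_needs_three(self):
        with pytest.raises(ValueError):
            phylo.pdistance_matrix([("a", "MKLV"), ("b", "MKLV")])


class TestNjTree:
    def test_additive_four_taxon_topology(self):
        ids = ["A", "B", "C", "D"]
        d = np.array(
            [[0, 2, 4, 4], [2, 0, 4, 4], [4, 4, 0, 2], [4, 4, 2, 0]], dtype=float
        )
        tree = phylo.nj_tree(phylo.DistanceMatrix(ids, d))
        # four-point condition: AB|CD is the only valid split
        splits = set()
        for node in tree.preorder_node_iter():
            names = frozenset(lf.taxon.label for lf in node.leaf_iter())
            if 1 < len(names) < 4:
                splits.add(names)
        assert frozenset({"A", "B"}) in splits or frozenset({"C", "D"}) in splits

    def test_three_taxa_star(self):
        ids = ["A", "B", "C"]
        d = np.array([[0, 2, 3], [2, 0, 3], [3, 3, 0]], dtype=float)
        tree = phylo.nj_tree(phylo.DistanceMatrix(ids, d))
        assert {lf.taxon.label for lf in tree.leaf_node_iter()} == {"A", "B", "C"}

    def test_leaf_order_invariance(self, rng):
        _, dm = random_additive_tree(6, rng)
        t1 = phylo.nj_tree(dm)
        perm = list(rng.permutation(len(dm.ids)))
        dm2 = phylo.DistanceMatrix(
            [dm.ids[i] for i in perm], dm.d[np.ix_(perm, perm)]
        )
        t2 = phylo.nj_tree(dm2)
        ns = dendropy.TaxonNamespace(dm.ids)
        a = dendropy.Tree.get(data=t1.as_string(schema="newick"), schema="newick", taxon_namespace=ns)
        b = dendropy.Tree.get(data=t2.as_string(schema="newick"), schema="newick", taxon_namespace=ns)
        a.encode_bipartitions()
        b.encode_bipartitions()
        assert treecompare.symmetric_difference(a, b) == 0

    def test_non_symmetric_matrix_rejected(self):
        d = np.array([[0, 1, 2], [1.5, 0, 2], [2, 2, 0]], dtype=float)
        with pytest.raises(ValueError, match="symmetric"):
            phylo.DistanceMatrix(["a", "b", "c"], d)

    def test_recovers_random_additive_topologies(self):
        """100% recovery over >=50 random 5-8 leaf additive matrices."""
        rng = np.random.default_rng(123)
        for trial in range(50):
            n = int(rng.integers(5, 9))
            truth, dm = random_additive_tree(n, rng)
            est = phylo.nj_tree(dm)
            ns = truth.taxon_namespace
            est2 = dendropy.Tree.get(
                data=est.as_string(schema="newick"), schema="newick", taxon_namespace=ns
            )
            est2.is_rooted = False
            est2.encode_bipartitions()
            truth.encode_bipartitions()
            assert treecompare.symmetric_difference(truth, est2) == 0, f"trial {trial}"


class TestRootByOutgroup:
    def test_clean_split(self):
        tree = phylo.nj_tree(
            phylo.DistanceMatrix(
                ["A", "B", "C", "OUT"],
                np.array(
                    [[0, 1, 4, 6], [1, 0, 4, 6], [4, 4, 0, 6], [6, 6, 6, 0]], dtype=float
                ),
            )
        )
        rooted = phylo.root_by_outgroup(tree, {"OUT"})
        assert not rooted.outgroup_impure
        children = rooted.seed_node.child_nodes()
        sides = [phylo.leaf_names(c) for c in children]
        assert {"OUT"} in sides

    def test_all_leaves_outgroup_raises(self):
        tree = parse_newick_string("((A:1,B:1):1,C:1);")
        with pytest.raises(ValueError, match="every leaf"):
            phylo.root_by_outgroup(tree, {"A", "B", "C"})

    def test_unknown_id_raises(self):
        tree = parse_newick_string("((A:1,B:1):1,C:1);")
        with pytest.raises(ValueError, match="unknown"):
            phylo.root_by_outgroup(tree, {"Z"})


class TestCallClades:
    def test_two_query_split(self):
        tree = parse_newick_string("((Q1:1,RC:1):1,(RO:1,Q2:1):1);")
        tree.is_rooted = True
        panel = {"RC": _ref("RC", "CDDP"), "RO": _ref("RO", "OUT")}
        calls = {c.query_id: c for c in phylo.call_clades(tree, panel)}
        assert calls["Q1"].call == "CDDP-like"
        assert calls["Q2"].call == "outgroup-like"

    def test_mixed_clade_ambiguous(self):
        tree = parse_newick_string("((Q1:1,(RC:1,RO:1):1):1,RX:2);")
        tree.is_rooted = True
        panel = {"RC": _ref("RC", "CDDP"), "RO": _ref("RO", "OUT"), "RX": _ref("RX", "OUT")}
        calls = {c.query_id: c for c in phylo.call_clades(tree, panel)}
        assert calls["Q1"].call == "ambiguous"

    def test_group_majority_and_tie(self):
        tree = parse_newick_string("((Q1:1,(R1:1,(R2:1,R3:1):1):1):1,RX:2);")
        tree.is_rooted = True
        panel = {
            "R1": _ref("R1", "CDDP", "II"),
            "R2": _ref("R2", "CDDP", "V"),
            "R3": _ref("R3", "CDDP", "V"),
            "RX": _ref("RX", "OUT", "I"),
        }
        calls = {c.query_id: c for c in phylo.call_clades(tree, panel)}
        assert calls["Q1"].group == "V"

    def test_no_panel_leaves_raises(self):
        tree = parse_newick_string("((Q1:1,Q2:1):1,Q3:1);")
        with pytest.raises(ValueError, match="panel"):
            phylo.call_clades(tree, {})

    def test_invariant_to_insertion_order(self):
        # same topology written with rotated clause order
        panel = {"RC": _ref("RC", "CDDP"), "RO": _ref("RO", "OUT")}
        t1 = parse_newick_string("((Q1:1,RC:1):1,(RO:1,Q2:1):1);")
        t2 = parse_newick_string("((Q2:1,RO:1):1,(RC:1,Q1:1):1);")
        for t in (t1, t2):
            t.is_rooted = True
        c1 = sorted((c.query_id, c.call) for c in phylo.call_clades(t1, panel))
        c2 = sorted((c.query_id, c.call) for c in phylo.call_clades(t2, panel))
        assert c1 == c2


class TestConfirmGroup:
    def _setup(self, flank_flips=0):
        motif = "DEGRH"
        left = "AVLIM"  # hydrophobic flank
        right = "KNDES"  # non-hydrophobic flank
        ref_seq = "G" * 5 + left + motif + right + "G" * 5
        ref = ReferenceEntry("r", ref_seq, "CDDP", "V", motif1_anchor=10)
        q = list(ref_seq)
        flip_map = {"A": "K", "V": "N", "L": "D", "I": "E", "M": "S",
                    "K": "A", "N": "V", "D": "L", "E": "I", "S": "M"}
        flank_positions = list(range(5, 10)) + list(range(15, 20))
        for pos in flank_positions[:flank_flips]:
            q[pos] = flip_map[q[pos]]
        q = "".join(q)
        aln = align_global(q, ref_seq)
        return q, ref, aln

    def test_identical_flanks_score_1(self):
        q, ref, aln = self._setup(0)
        assert phylo.confirm_group(q, ref, aln) == 1.0

    def test_all_flipped_score_0(self):
        q, ref, aln = self._setup(10)
        assert phylo.confirm_group(q, ref, aln) == 0.0

    def test_single_flip_scores_09(self):
        q, ref, aln = self._setup(1)
        assert phylo.confirm_group(q, ref, aln) == pytest.approx(0.9)

    def test_no_anchor_undefined(self):
        ref = _ref("r")
        assert phylo.confirm_group("A" * 60, ref, align_global("A" * 60, ref.seq)) is None


class TestSelectRepresentative:
    def _ev(self, qid, state):
        ev = MotifEvidence(qid)
        ev.motif1 = state
        return ev

    def test_gap_member_skipped_for_motif_bearing(self):
        choice = phylo.select_representative(
            0,
            ["A", "B"],
            {"A": 5.0, "B": 3.0},
            {"A": self._ev("A", "gap"), "B": self._ev("B", "present")},
        )
        assert choice.representative_query_id == "B"
        assert choice.skipped_ids == [("A", "motif1 gap")]
        assert not choice.flagged

    def test_single_member(self):
        choice = phylo.select_representative(
            0, ["A"], {"A": 1.0}, {"A": self._ev("A", "present")}
        )
        assert choice.representative_query_id == "A"

    def test_all_gap_falls_back_flagged(self):
        choice = phylo.select_representative(
            0,
            ["A", "B"],
            {"A": 5.0, "B": 3.0},
            {"A": self._ev("A", "gap"), "B": self._ev("B", "gap")},
        )
        assert choice.representative_query_id == "A"
        assert choice.flagged

    def test_no_skipped_member_dominates(self):
        choice = phylo.select_representative(
            0,
            ["A", "B", "C"],
            {"A": 5.0, "B": 4.0, "C": 3.0},
            {
                "A": self._ev("A", "gap"),
                "B": self._ev("B", "present"),
                "C": self._ev("C", "present"),
            },
        )
        # no skipped member may combine higher abundance with motif1=present
        rep_ab = choice.abundance_rpkm
        for sid, why in choice.skipped_ids:
            assert "gap" in why or rep_ab >= 5.0

    def test_missing_abundance_raises(self):
        with pytest.raises(ValueError, match="abundance"):
            phylo.select_representative(0, ["A"], {}, {})
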