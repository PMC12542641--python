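"""Trees over query + panel proteins: neighbor joining, outgroup rooting,
monophyletic clade calls, group confirmation, representative selection.

NJ is the standard Saitou-Nei agglomeration with a pinned tie-break
(smallest index pair) so topologies are reproducible; negative branch
lengths are clamped to zero with the deficit moved to the sister branch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .homology import AlignmentResult, ReferenceEntry, align_global
from .tiering import MotifEvidence

HYDROPHOBIC = set("AVLIMFWYC")


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray  # symmetric, zero diagonal

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0):
            raise ValueError("distance matrix diagonal is not zero")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("distance matrix contains non-finite values")


def pdistance_matrix(seqs: list[tuple[str, str]]) -> DistanceMatrix:
    """p-distances from pairwise global alignments.

    d(i,j) = 1 - identical columns / comparable columns, where comparable
    columns are those with residues in both sequences (gap columns excluded
    from the denominator).
    """
    if len(seqs) < 3:
        raise ValueError("need at least 3 sequences")
    ids = [s[0] for s in seqs]
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            res: AlignmentResult = align_global(seqs[i][1], seqs[j][1])
            comparable = sum(
                1 for a, b in zip(res.query_aln, res.ref_aln) if a != "-" and b != "-"
            )
            if comparable == 0:
                raise ValueError(f"no comparable columns between {ids[i]} and {ids[j]}")
            ident = sum(
                1 for a, b in zip(res.query_aln, res.ref_aln) if a == b and a != "-"
            )
            d[i, j] = d[j, i] = 1.0 - ident / comparable
    return DistanceMatrix(ids, d)


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Neighbor-joining tree (unrooted, represented with a trifurcating seed)."""
    n = len(dm.ids)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    taxa = dendropy.TaxonNamespace(dm.ids)
    tree = dendropy.Tree(taxon_namespace=taxa)

    nodes: list[dendropy.Node] = []
    for name in dm.ids:
        node = dendropy.Node(taxon=taxa.get_taxon(name))
        nodes.append(node)
    d = dm.d.astype(float).copy()
    active = list(range(n))
    # distances indexed by position in `nodes`; grow matrix as nodes merge
    dist = {(i, j): d[i, j] for i in range(n) for j in range(n) if i < j}

    def get(i: int, j: int) -> float:
        return dist[(i, j)] if i < j else dist[(j, i)]

    while len(active) > 2:
        m = len(active)
        r = {i: sum(get(i, k) for k in active if k != i) for i in active}
        best = None
        best_q = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * get(i, j) - r[i] - r[j]
                if best_q is None or q < best_q - 1e-12:
                    best_q, best = q, (i, j)
        i, j = best
        dij = get(i, j)
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        # clamp negative lengths, moving the deficit to the sister branch
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = li
        parent.add_child(nodes[j])
        nodes[j].edge.length = lj
        u = len(nodes)
        nodes.append(parent)
        for k in active:
            if k in (i, j):
                continue
            dist[(min(k, u), max(k, u))] = 0.5 * (get(i, k) + get(j, k) - dij)
        active = [k for k in active if k not in (i, j)] + [u]

    i, j = active
    dij = get(i, j)
    # represent the final unrooted edge by hanging j off i's node
    root = nodes[i] if nodes[i].child_nodes() else nodes[j]
    other = nodes[j] if root is nodes[i] else nodes[i]
    root.add_child(other)
    other.edge.length = dij
    tree.seed_node = root
    tree.update_bipartitions(suppress_unifurcations=False)
    return tree


def leaf_names(node: dendropy.Node) -> set[str]:
    return {lf.taxon.label for lf in node.leaf_iter()}


def root_by_outgroup(tree: dendropy.Tree, outgroup_ids: set[str]) -> dendropy.Tree:
    """Root on the edge separating the outgroup from everything else.

    If no edge splits the outgroup cleanly, the edge maximizing outgroup
    purity is used and the tree is annotated with ``outgroup_impure=True``.
    """
    if not outgroup_ids:
        raise ValueError("outgroup_ids is empty")
    tree = tree.clone(depth=1)
    all_leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    unknown = set(outgroup_ids) - all_leaves
    if unknown:
        raise ValueError(f"unknown outgroup id(s): {sorted(unknown)}")
    if set(outgroup_ids) == all_leaves:
        raise ValueError("outgroup cannot contain every leaf")

    og = set(outgroup_ids)
    n = len(all_leaves)
    best_edge = None
    best_purity = -1.0
    exact = False
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        side = leaf_names(node)
        for candidate in (side, all_leaves - side):
            correct = len(og & candidate) + len((all_leaves - og) - candidate)
            purity = correct / n
            if purity > best_purity + 1e-12:
                best_purity = purity
                best_edge = node.edge
        if side == og or side == all_leaves - og:
            best_edge = node.edge
            best_purity = 1.0
            exact = True
            break
    tree.reroot_at_edge(best_edge, update_bipartitions=True, suppress_unifurcations=True)
    tree.outgroup_impure = not exact
    return tree


@dataclass
class CladeCall:
    query_id: str
    call: str  # CDDP-like | outgroup-like | ambiguous
    group: str  # I..VI or unknown
    supporting_reference_ids: list[str]
    clade_id: int


def call_clades(
    rooted_tree: dendropy.Tree,
    panel: dict[str, ReferenceEntry],
) -> list[CladeCall]:
    """Label each query leaf by the panel members of its minimal enclosing clade.

    The minimal rooted clade containing the query and >=1 panel leaf decides:
    CDDP-like when every panel leaf in it documents dioxane degradation,
    outgroup-like when none does, ambiguous when mixed. The group is the
    majority SDIMO group of those panel leaves (tie -> unknown). Queries
    sharing the same minimal panel set share a clade_id.
    """
    panel_ids = set(panel)
    leaves = [lf for lf in rooted_tree.leaf_node_iter()]
    if not any(lf.taxon.label in panel_ids for lf in leaves):
        raise ValueError("tree contains no panel leaves")

    calls: list[CladeCall] = []
    clade_key_to_id: dict[frozenset, int] = {}
    for lf in sorted(leaves, key=lambda x: x.taxon.label):
        qid = lf.taxon.label
        if qid in panel_ids:
            continue
        node = lf
        support: set[str] = set()
        while node is not None:
            support = leaf_names(node) & panel_ids
            if support:
                break
            node = node.parent_node
        if not support:
            support = panel_ids  # degenerate: whole tree
        key = frozenset(support)
        if key not in clade_key_to_id:
            clade_key_to_id[key] = len(clade_key_to_id)

        evid = {panel[r].has_dioxane_evidence for r in support}
        if evid == {True}:
            call = "CDDP-like"
        elif evid == {False}:
            call = "outgroup-like"
        else:
            call = "ambiguous"

        groups: dict[str, int] = {}
        for r in support:
            groups[panel[r].group] = groups.get(panel[r].group, 0) + 1
        top = max(groups.values())
        winners = sorted(g for g, k in groups.items() if k == top)
        group = winners[0] if len(winners) == 1 else "unknown"

        calls.append(
            CladeCall(
                query_id=qid,
                call=call,
                group=group,
                supporting_reference_ids=sorted(support),
                clade_id=clade_key_to_id[key],
            )
        )
    return calls


def confirm_group(
    query_seq: str,
    reference: ReferenceEntry,
    alignment: AlignmentResult,
    flank_width: int = 5,
) -> float | None:
    """Hydrophobicity-class agreement around the first di-iron motif.

    Returns the fraction of flank positions (+/-flank_width around the
    5-residue motif, motif excluded) where the query residue shares the
    reference residue's hydrophobicity class; None (flagged) when the motif
    region is unresolvable through the alignment.
    """
    if reference.motif1_anchor is None:
        return None
    anchor = reference.motif1_anchor
    flank_ref_positions = [anchor - k for k in range(1, flank_width + 1)] + [
        anchor + 4 + k for k in range(1, flank_width + 1)
    ]
    flank_ref_positions = [p for p in flank_ref_positions if 0 <= p < len(reference.seq)]
    if not flank_ref_positions:
        return None

    # column-walk: reference position -> aligned query residue (or None)
    q_at_ref: dict[int, str | None] = {}
    rpos = alignment.sstart - 1
    qpos = alignment.qstart - 1
    for qc, rc in zip(alignment.query_aln, alignment.ref_aln):
        if rc != "-":
            q_at_ref[rpos] = qc if qc != "-" else None
            rpos += 1
        if qc != "-":
            qpos += 1

    motif_cols = [q_at_ref.get(anchor + k) for k in range(5)]
    if all(c is None for c in motif_cols):
        return None  # motif region is a gap in the query

    n_match = 0
    for p in flank_ref_positions:
        qc = q_at_ref.get(p)
        rc = reference.seq[p]
        if qc is not None and (qc in HYDROPHOBIC) == (rc in HYDROPHOBIC):
            n_match += 1
    return n_match / len(flank_ref_positions)


@dataclass
class RepresentativeChoice:
    clade_id: int
    representative_query_id: str
    abundance_rpkm: float
    skipped_ids: list[tuple[str, str]] = field(default_factory=list)  # (id, reason)
    flagged: bool = False


def select_representative(
    clade_id: int,
    clade_members: list[str],
    abundances: dict[str, float],
    motif_evidence: dict[str, MotifEvidence],
) -> RepresentativeChoice:
    """Most abundant member whose first di-iron motif is present.

    Members are scanned in descending abundance (ties by id); members with a
    gapped/absent first motif are skipped with a reason. If no member
    qualifies, the overall most abundant is returned flagged.
    """
    if not clade_members:
        raise ValueError("clade is empty")
    missing = [m for m in clade_members if m not in abundances]
    if missing:
        raise ValueError(f"missing abundance for {missing}")
    ordered = sorted(clade_members, key=lambda m: (-abundances[m], m))
    skipped: list[tuple[str, str]] = []
    for m in ordered:
        ev = motif_evidence.get(m)
        if ev is not None and ev.motif1 == "present":
            return RepresentativeChoice(clade_id, m, abundances[m], skipped)
        state = ev.motif1 if ev is not None else "unknown"
        skipped.append((m, f"motif1 {state}"))
    return RepresentativeChoice(clade_id, ordered[0], abundances[ordered[0]], skipped[1:], flagged=True)
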