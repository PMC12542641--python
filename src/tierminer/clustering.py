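"""Greedy incremental identity clustering and dereplication.

Reimplements the published greedy-incremental scheme exactly (no k-mer
prefilter): sequences are scanned longest-first and each joins the first
existing cluster whose representative it matches at >=c identity (and >=aS
coverage when set), else founds a new cluster. Identity uses the
shorter-sequence denominator: identical columns / length of the shorter
sequence, from an exact global alignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .formats_io import SequenceRecord
from .homology import AlignmentResult, align_global, align_global_dna


@dataclass(frozen=True)
class ClusterParams:
    c: float = 0.999  # identity fraction over the shorter sequence
    aS: float | None = 0.999  # alignment coverage of the shorter sequence
    space: str = "protein"  # protein | nucleotide

    def __post_init__(self) -> None:
        if not (0 < self.c <= 1):
            raise ValueError("c must be in (0, 1]")
        if self.aS is not None and not (0 < self.aS <= 1):
            raise ValueError("aS must be in (0, 1]")
        if self.space not in ("protein", "nucleotide"):
            raise ValueError(f"unknown space {self.space!r}")


@dataclass
class Cluster:
    representative_id: str
    member_ids: list[str] = field(default_factory=list)
    member_identities: dict[str, float] = field(default_factory=dict)


def pair_identity(a: str, b: str, space: str = "protein") -> tuple[float, float]:
    """(identity, coverage) of a pair, both over the shorter sequence.

    identity = identical alignment columns / len(shorter);
    coverage = columns where both sequences have residues / len(shorter).
    """
    if a == b:
        return 1.0, 1.0
    res: AlignmentResult = align_global_dna(a, b) if space == "nucleotide" else align_global(a, b)
    shorter = min(len(a), len(b))
    n_id = res.n_identical
    n_both = sum(1 for x, y in zip(res.query_aln, res.ref_aln) if x != "-" and y != "-")
    return n_id / shorter, n_both / shorter


def _scan_order(seqs: list[SequenceRecord]) -> list[SequenceRecord]:
    return sorted(seqs, key=lambda r: (-len(r.seq), r.id))


_PRESCREEN_K = 16
_PRESCREEN_MIN_SHARE = 0.5


def _kmers(seq: str, k: int = _PRESCREEN_K) -> frozenset[str]:
    if len(seq) < k:
        return frozenset((seq,))
    return frozenset(seq[i : i + k] for i in range(len(seq) - k + 1))


def _prescreen_reject(a: frozenset, b: frozenset) -> bool:
    """True when shared k-mer content rules out near-identity.

    Only used at c >= 0.99: sequences >=99% identical under a score-optimal
    affine-gap alignment share the vast majority of their 16-mers, so a
    shared fraction below 0.5 (over the smaller set) cannot reach the
    threshold. Below c = 0.99 every pair is aligned exactly.
    """
    smaller = a if len(a) <= len(b) else b
    other = b if smaller is a else a
    return len(smaller & other) / len(smaller) < _PRESCREEN_MIN_SHARE


def greedy_cluster(seqs: list[SequenceRecord], params: ClusterParams) -> list[Cluster]:
    """Deterministic greedy clustering; clusters appear in founding order."""
    if not seqs:
        raise ValueError("no sequences to cluster")
    alphabet = "dna" if params.space == "nucleotide" else "protein"
    if any(s.alphabet != alphabet for s in seqs):
        raise ValueError(f"mixed alphabets: expected all {alphabet}")
    by_id = {s.id: s for s in seqs}
    if len(by_id) != len(seqs):
        raise ValueError("duplicate sequence ids")

    use_prescreen = params.c >= 0.99
    kmer_cache: dict[str, frozenset] = (
        {s.id: _kmers(s.seq) for s in seqs} if use_prescreen else {}
    )

    clusters: list[Cluster] = []
    for rec in _scan_order(seqs):
        placed = False
        for cl in clusters:
            rep = by_id[cl.representative_id]
            if use_prescreen and _prescreen_reject(kmer_cache[rec.id], kmer_cache[rep.id]):
                continue
            ident, cov = pair_identity(rec.seq, rep.seq, params.space)
            if ident >= params.c and (params.aS is None or cov >= params.aS):
                cl.member_ids.append(rec.id)
                cl.member_identities[rec.id] = ident
                placed = True
                break
        if not placed:
            clusters.append(
                Cluster(representative_id=rec.id, member_ids=[rec.id], member_identities={rec.id: 1.0})
            )
    return clusters


def dereplicate_contigs(
    contigs: list[SequenceRecord],
    params: ClusterParams = ClusterParams(c=0.999, aS=0.999, space="nucleotide"),
) -> tuple[list[SequenceRecord], dict[str, str]]:
    """Collapse identical/near-identical contigs to one representative each.

    Returns the nonredundant contig list (input order of representatives
    preserved) and the old-id -> representative-id mapping.
    """
    clusters = greedy_cluster(contigs, params)
    rep_of: dict[str, str] = {}
    for cl in clusters:
        for m in cl.member_ids:
            rep_of[m] = cl.representative_id
    reps = {cl.representative_id for cl in clusters}
    return [c for c in contigs if c.id in reps], rep_of


def identity_ladder(
    seqs: list[SequenceRecord],
    thresholds: tuple[float, ...] = (1.0, 0.99, 0.97, 0.95, 0.9),
    labels: dict[str, str] | None = None,
    label_of_interest: str | None = None,
    space: str = "protein",
) -> list[dict]:
    """Cluster the same sequences at a ladder of identity thresholds.

    Returns one row per threshold: c, n_clusters, n_clusters_with_label.
    ``labels`` maps sequence id -> clade label; a cluster counts as labeled
    when >=1 member carries ``label_of_interest`` (or any label when that is
    None). Label ids not in the sequence set are warned about and dropped.
    """
    labels = dict(labels or {})
    ids = {s.id for s in seqs}
    for lid in list(labels):
        if lid not in ids:
            warnings.warn(f"label for unknown sequence id {lid!r} dropped", stacklevel=2)
            del labels[lid]

    rows = []
    for c in thresholds:
        clusters = greedy_cluster(seqs, ClusterParams(c=c, aS=None, space=space))
        n_labeled = 0
        for cl in clusters:
            member_labels = {labels[m] for m in cl.member_ids if m in labels}
            if label_of_interest is None:
                if member_labels:
                    n_labeled += 1
            elif label_of_interest in member_labels:
                n_labeled += 1
        rows.append({"c": c, "n_clusters": len(clusters), "n_clusters_with_label": n_labeled})
    return rows


def write_clusters(clusters: list[Cluster], path) -> None:
    with open(path, "w") as fh:
        fh.write("representative_id\tmember_id\tidentity\n")
        for cl in clusters:
            for m in cl.member_ids:
                fh.write(f"{cl.representative_id}\t{m}\t{cl.member_identities[m]:.4f}\n")


def write_ladder(rows: list[dict], path) -> None:
    with open(path, "w") as fh:
        fh.write("c\tn_clusters\tn_clusters_with_label\n")
        for r in rows:
            fh.write(f"{r['c']}\t{r['n_clusters']}\t{r['n_clusters_with_label']}\n")
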