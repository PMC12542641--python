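"""Gene-neighborhood analysis on monooxygenase-bearing contigs.

Consensus annotation voting across heterogeneous annotators, operon-order
conformance, inverted-terminal-repeat detection, and fixed-length terminal
overlap (assembly-break) detection. External plasmid/virus/transposon/MITE
calls are pass-through flags, never computed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .formats_io import AnnotationVote, GeneFeature
from .synthetic_data import SUBUNIT_ORDER, revcomp

HOMOLOGY_ANNOTATOR = "blastp"
FALLBACK_EVALUE_MAX = 1e-5


@dataclass(frozen=True)
class ConsensusAnnotation:
    gene_id: str
    label: str
    status: str  # consensus | putative | hypothetical


def consensus_annotation(
    votes: list[AnnotationVote],
    gene_id: str = "",
    homology_annotator: str = HOMOLOGY_ANNOTATOR,
    fallback_evalue_max: float = FALLBACK_EVALUE_MAX,
) -> ConsensusAnnotation:
    """Three-branch rule on normalized labels.

    1. >=2 annotators agree on a non-sentinel label -> that label, consensus.
    2. else the homology source's lowest-e-value non-sentinel vote, provided
       its e-value is below the gate -> "putative <label>".
    3. else -> hypothetical.

    Order-invariant in the votes (ties in branch 1 broken by label count then
    alphabetically).
    """
    if not gene_id and votes:
        gene_id = votes[0].gene_id

    tally: dict[str, int] = {}
    for v in votes:
        if v.annotation:
            tally[v.annotation] = tally.get(v.annotation, 0) + 1
    if tally:
        best_n = max(tally.values())
        if best_n >= 2:
            label = sorted(l for l, n in tally.items() if n == best_n)[0]
            return ConsensusAnnotation(gene_id, label, "consensus")

    homology_votes = sorted(
        (v for v in votes if v.annotator == homology_annotator and v.annotation and v.evalue is not None),
        key=lambda v: (v.evalue, v.annotation),
    )
    if homology_votes and homology_votes[0].evalue < fallback_evalue_max:
        return ConsensusAnnotation(gene_id, f"putative {homology_votes[0].annotation}", "putative")

    return ConsensusAnnotation(gene_id, "hypothetical", "hypothetical")


@dataclass
class OperonCheck:
    contig_id: str
    found_order: list[str]
    conforms: bool | None  # None = not applicable (partial contig)
    missing: list[str] = field(default_factory=list)
    duplicated: list[str] = field(default_factory=list)


def check_operon_order(
    features: list[GeneFeature],
    subunit_labels: dict[str, str],
    expected: tuple[str, ...] = SUBUNIT_ORDER,
) -> OperonCheck:
    """Strand-aware conformance of the four-subunit gene order on one contig.

    Reverse-strand operons are read right-to-left (strand taken from the
    labeled subunit genes). Contigs missing subunits report them and return
    conforms=None; duplicated subunit labels force conforms=False.
    """
    if not features:
        raise ValueError("no features supplied")
    contig_id = features[0].contig_id
    ordered = sorted(features, key=lambda f: f.start)
    labeled = [(f, subunit_labels[f.gene_id]) for f in ordered if f.gene_id in subunit_labels]
    labeled = [(f, role) for f, role in labeled if role in expected]

    found = [role for _, role in labeled]
    dup = sorted({r for r in found if found.count(r) > 1})
    if dup:
        return OperonCheck(contig_id, found, False, duplicated=dup)

    minus = sum(1 for f, _ in labeled if f.strand == "-")
    if labeled and minus > len(labeled) / 2:
        found = list(reversed(found))

    missing = [r for r in expected if r not in found]
    if missing:
        return OperonCheck(contig_id, found, None, missing=missing)
    return OperonCheck(contig_id, found, found == list(expected))


@dataclass(frozen=True)
class ItrFinding:
    contig_id: str
    kind: str  # gene_pair | terminal_block
    first_id: str  # gene id or "5'"
    last_id: str  # gene id or "3'"
    length_bp: int


def _gene_dna(contig_seq: str, feature: GeneFeature) -> str:
    s, e = feature.span0
    dna = contig_seq[s:e]
    return revcomp(dna) if feature.strand == "-" else dna


def find_itr(
    contig_seq: str,
    features: list[GeneFeature],
    min_len: int = 100,
) -> list[ItrFinding]:
    """Exact inverted terminal repeats: the first/last gene pair in
    reverse-complement orientation, plus terminal k-mer blocks (>= min_len).
    """
    findings: list[ItrFinding] = []
    contig_id = features[0].contig_id if features else ""
    ordered = sorted(features, key=lambda f: f.start)
    if len(ordered) >= 2:
        first, last = ordered[0], ordered[-1]
        s1, e1 = first.span0
        s2, e2 = last.span0
        if e1 - s1 == e2 - s2 and contig_seq[s1:e1] == revcomp(contig_seq[s2:e2]):
            findings.append(
                ItrFinding(contig_id, "gene_pair", first.gene_id, last.gene_id, e1 - s1)
            )
    # longest terminal block: prefix == revcomp(suffix)
    best = 0
    for L in range(min_len, len(contig_seq) // 2 + 1):
        if contig_seq[:L] == revcomp(contig_seq[-L:]):
            best = L
    if best >= min_len:
        findings.append(ItrFinding(contig_id, "terminal_block", "5'", "3'", best))
    return findings


@dataclass(frozen=True)
class OverlapFinding:
    contig_a: str
    contig_b: str
    length_bp: int
    a_end: str  # "5'" | "3'"
    b_end: str
    identity: float = 1.0


def _longest_suffix_prefix(a: str, b: str, min_len: int) -> int:
    """Longest L >= min_len with a[-L:] == b[:L]; 0 when none."""
    for L in range(min(len(a), len(b)), min_len - 1, -1):
        if a[-L:] == b[:L]:
            return L
    return 0


def find_terminal_overlaps(
    contigs: list[tuple[str, str]],
    min_len: int = 100,
    max_mismatch: int = 0,
) -> list[OverlapFinding]:
    """Exact terminal overlaps between every contig pair.

    For each unordered pair, all four end combinations are checked (including
    reverse-complement joins); the longest exact match >= min_len per
    combination is reported. Only exact matching is implemented
    (max_mismatch=0); the parameter is a config hook.
    """
    if max_mismatch != 0:
        raise NotImplementedError("only exact overlap matching is supported")
    if len(contigs) < 2:
        raise ValueError("need at least 2 contigs")
    findings: list[OverlapFinding] = []
    for i in range(len(contigs)):
        for j in range(i + 1, len(contigs)):
            ida, sa = contigs[i]
            idb, sb = contigs[j]
            combos = [
                (sa, sb, "3'", "5'"),  # suffix(a) = prefix(b)
                (sb, sa, "5'", "3'"),  # prefix(a) = suffix(b)
                (sa, revcomp(sb), "3'", "3'"),  # suffix(a) = revcomp suffix(b)
                (revcomp(sb), sa, "5'", "5'"),  # prefix(a) = revcomp prefix(b)
            ]
            for x, y, a_end, b_end in combos:
                L = _longest_suffix_prefix(x, y, min_len)
                if L:
                    findings.append(OverlapFinding(ida, idb, L, a_end, b_end))
    return findings


def write_overlaps(findings: list[OverlapFinding], path) -> None:
    with open(path, "w") as fh:
        fh.write("contig_a\tcontig_b\ta_end\tb_end\tlength_bp\tidentity\n")
        for f in findings:
            fh.write(f"{f.contig_a}\t{f.contig_b}\t{f.a_end}\t{f.b_end}\t{f.length_bp}\t{f.identity:.3f}\n")


def write_neighborhood_report(
    annotations: list[ConsensusAnnotation],
    subunit_labels: dict[str, str],
    operon_checks: list[OperonCheck],
    itr_findings: list[ItrFinding],
    overlap_findings: list[OverlapFinding],
    path,
) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tlabel\tstatus\tsubunit_role\n")
        for a in annotations:
            fh.write(f"{a.gene_id}\t{a.label}\t{a.status}\t{subunit_labels.get(a.gene_id, '')}\n")
        fh.write("#operon\tcontig_id\tfound_order\tconforms\tmissing\n")
        for oc in operon_checks:
            conf = "NA" if oc.conforms is None else str(oc.conforms).lower()
            fh.write(
                f"#operon\t{oc.contig_id}\t{','.join(oc.found_order)}\t{conf}\t{','.join(oc.missing)}\n"
            )
        fh.write("#itr\tcontig_id\tkind\tfirst\tlast\tlength_bp\n")
        for it in itr_findings:
            fh.write(f"#itr\t{it.contig_id}\t{it.kind}\t{it.first_id}\t{it.last_id}\t{it.length_bp}\n")
        fh.write("#overlap\tcontig_a\tcontig_b\tends\tlength_bp\n")
        for ov in overlap_findings:
            fh.write(f"#overlap\t{ov.contig_a}\t{ov.contig_b}\t{ov.a_end}/{ov.b_end}\t{ov.length_bp}\n")
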