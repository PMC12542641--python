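"""Two-tier evidence gates and carboxylate di-iron center motif validation.

Tier 1: >=90% identity, >=125 aligned columns, >=60% query coverage, and at
least one intact di-iron center motif (contiguous D-E-x-R-H by default).
Tier 2: identity in [50, 90) with the same length/coverage gates and no
motif requirement. A contig carrying any Tier-1 candidate contributes no
Tier-2 candidates.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .formats_io import HomologyHit
from .homology import AlignmentResult, ReferenceEntry

DEFAULT_MOTIF_PATTERN = "DE.RH"


@dataclass(frozen=True)
class TierThresholds:
    tier1_min_pident: float = 90.0
    tier2_min_pident: float = 50.0
    min_alen: int = 125
    min_qcov: float = 60.0
    evalue_max: float = 1e-50

    def __post_init__(self) -> None:
        if not self.tier2_min_pident < self.tier1_min_pident:
            raise ValueError("tier windows must be disjoint")


@dataclass
class MotifEvidence:
    query_id: str
    motif1: str = "absent"  # present | absent | gap
    motif1_pos: int | None = None  # 0-based on the query
    motif2: str = "absent"
    motif2_pos: int | None = None
    pattern: str = DEFAULT_MOTIF_PATTERN

    @property
    def any_present(self) -> bool:
        return self.motif1 == "present" or self.motif2 == "present"


def _compile(pattern: str) -> re.Pattern:
    try:
        return re.compile(pattern)
    except re.error as exc:
        raise ValueError(f"malformed motif pattern {pattern!r}: {exc}") from exc


def _map_ref_pos_to_query(alignment: AlignmentResult, ref_pos0: int) -> tuple[str, int | None]:
    """Map a 0-based reference position through the alignment.

    Returns (state, query_pos0): state 'present' with the query position when
    the reference column aligns to a query residue, 'gap' when it aligns to a
    gap column, 'absent' when it falls outside the aligned region.
    """
    if alignment.is_empty:
        return "absent", None
    if not (alignment.sstart - 1 <= ref_pos0 < alignment.send):
        return "absent", None
    rpos = alignment.sstart - 1
    qpos = alignment.qstart - 1
    for qc, rc in zip(alignment.query_aln, alignment.ref_aln):
        if rc != "-" and rpos == ref_pos0:
            if qc == "-":
                return "gap", None
            return "present", qpos
        if rc != "-":
            rpos += 1
        if qc != "-":
            qpos += 1
    return "absent", None


def detect_motifs(
    query_seq: str,
    query_id: str = "",
    alignment: AlignmentResult | None = None,
    reference: ReferenceEntry | None = None,
    window: int = 10,
    pattern: str = DEFAULT_MOTIF_PATTERN,
) -> MotifEvidence:
    """Locate the first and second di-iron center motifs on a query protein.

    Anchored mode (default when the reference carries motif anchors) maps each
    reference anchor through the alignment: 'present' if the pattern matches
    within +/-window of the mapped position, 'gap' if the anchor lands in gap
    columns, 'absent' otherwise. Without anchors, the whole sequence is
    scanned and the first two pattern matches are recorded.
    """
    rx = _compile(pattern)
    if window < 0:
        raise ValueError("window must be >= 0")
    ev = MotifEvidence(query_id=query_id, pattern=pattern)

    anchors: list[int | None] = [None, None]
    if reference is not None:
        anchors = [reference.motif1_anchor, reference.motif2_anchor]

    if alignment is not None and reference is not None and any(a is not None for a in anchors):
        states: list[tuple[str, int | None]] = []
        for anchor in anchors:
            if anchor is None:
                states.append(("absent", None))
                continue
            state, qpos = _map_ref_pos_to_query(alignment, anchor)
            if state == "present":
                lo = max(0, qpos - window)
                hi = min(len(query_seq), qpos + window + 5)
                m = rx.search(query_seq[lo:hi])
                if m:
                    states.append(("present", lo + m.start()))
                else:
                    states.append(("absent", None))
            else:
                states.append((state, None))
        (ev.motif1, ev.motif1_pos), (ev.motif2, ev.motif2_pos) = states
    else:
        matches = list(rx.finditer(query_seq))[:2]
        if matches:
            ev.motif1, ev.motif1_pos = "present", matches[0].start()
        if len(matches) > 1:
            ev.motif2, ev.motif2_pos = "present", matches[1].start()
    return ev


def assign_tier(hit: HomologyHit, motifs: MotifEvidence, thresholds: TierThresholds = TierThresholds()) -> int | None:
    """Closed-form tier rule; returns 1, 2 or None."""
    if hit.qcov is None:
        raise ValueError("hit has no query coverage")
    t = thresholds
    if hit.alen < t.min_alen or hit.qcov < t.min_qcov:
        return None
    if hit.pident >= t.tier1_min_pident:
        return 1 if motifs.any_present else None
    if t.tier2_min_pident <= hit.pident < t.tier1_min_pident:
        return 2
    return None


@dataclass
class TierCandidate:
    query_id: str
    contig_id: str
    tier: int | None
    best_hit: HomologyHit
    motifs: MotifEvidence


@dataclass
class GateResult:
    tier1: list[TierCandidate] = field(default_factory=list)
    tier2: list[TierCandidate] = field(default_factory=list)
    tier1_fraction: dict[str, float] = field(default_factory=dict)  # per-sample, reported only


def gate(
    candidates: list[TierCandidate],
    thresholds: TierThresholds = TierThresholds(),
    proteins_per_sample: dict[str, int] | None = None,
    sample_of_contig: dict[str, str] | None = None,
) -> GateResult:
    """Split candidates into contig-exclusive tier lists.

    A contig that carries any Tier-1 candidate is removed from the Tier-2
    set. Optionally reports the per-sample Tier-1 fraction of predicted
    proteins (informational, never asserted).
    """
    res = GateResult()
    tier1_contigs: set[str] = set()
    for c in candidates:
        c.tier = assign_tier(c.best_hit, c.motifs, thresholds)
        if c.tier == 1:
            res.tier1.append(c)
            tier1_contigs.add(c.contig_id)
    for c in candidates:
        if c.tier == 2 and c.contig_id not in tier1_contigs:
            res.tier2.append(c)

    if proteins_per_sample and sample_of_contig:
        per_sample: dict[str, int] = {}
        for c in res.tier1:
            s = sample_of_contig.get(c.contig_id)
            if s is not None:
                per_sample[s] = per_sample.get(s, 0) + 1
        res.tier1_fraction = {
            s: 100.0 * per_sample.get(s, 0) / n for s, n in proteins_per_sample.items() if n
        }
    return res


def write_tiers(result: GateResult, path) -> None:
    with open(path, "w") as fh:
        fh.write("query_id\tcontig_id\ttier\treference_id\tpident\talen\tqcov\tmotif1\tmotif2\n")
        for c in result.tier1 + result.tier2:
            h = c.best_hit
            fh.write(
                f"{c.query_id}\t{c.contig_id}\t{c.tier}\t{h.reference_id}\t"
                f"{h.pident:.2f}\t{h.alen}\t{h.qcov:.2f}\t{c.motifs.motif1}\t{c.motifs.motif2}\n"
            )
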