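"""Contig RPKM per sample and clade-by-sample aggregation.

Only origin-sample abundance (the sample a contig was assembled from)
enters the clade matrix; cross-sample records are kept for reporting only.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class AbundanceRecord:
    sample_id: str
    contig_id: str
    rpkm: float
    origin_sample: bool


def rpkm(count: int, contig_len_bp: int, total_mapped: int) -> float:
    """reads / (kilobases of contig x millions of mapped reads)."""
    if contig_len_bp <= 0:
        raise ValueError("contig length must be positive")
    if total_mapped <= 0:
        raise ValueError("total mapped reads must be positive")
    if count < 0:
        raise ValueError("count must be non-negative")
    return count / ((contig_len_bp / 1000.0) * (total_mapped / 1e6))


def abundance_records(
    counts: dict[tuple[str, str], int],
    totals: dict[str, int],
    contig_lengths: dict[str, int],
    origin_of_contig: dict[str, str],
) -> list[AbundanceRecord]:
    """One record per (sample, contig) count, with origin attribution."""
    records = []
    for (sample, contig), n in sorted(counts.items()):
        if contig not in contig_lengths:
            raise ValueError(f"count references unknown contig {contig!r}")
        if sample not in totals:
            raise ValueError(f"no total_mapped for sample {sample!r}")
        records.append(
            AbundanceRecord(
                sample_id=sample,
                contig_id=contig,
                rpkm=rpkm(n, contig_lengths[contig], totals[sample]),
                origin_sample=origin_of_contig.get(contig) == sample,
            )
        )
    return records


@dataclass
class CladeAbundanceMatrix:
    cells: dict[tuple[int | str, str], float] = field(default_factory=dict)  # (clade, sample) -> rpkm
    group_totals: dict[str, float] = field(default_factory=dict)

    def total(self) -> float:
        return sum(self.cells.values())


def clade_matrix(
    member_clade: dict[str, int | str],
    member_group: dict[str, str],
    member_contig: dict[str, str],
    records: list[AbundanceRecord],
) -> CladeAbundanceMatrix:
    """Sum member origin-sample RPKMs per (clade, sample); roll up per group.

    ``member_*`` map query/member ids to their clade, SDIMO group and contig.
    Members without a clade are warned into an 'unassigned' row.
    """
    origin_rpkm: dict[str, tuple[str, float]] = {}
    for r in records:
        if r.origin_sample:
            origin_rpkm[r.contig_id] = (r.sample_id, r.rpkm)

    m = CladeAbundanceMatrix()
    for member, contig in member_contig.items():
        if contig not in origin_rpkm:
            raise ValueError(f"member {member!r}: no origin-sample abundance for contig {contig!r}")
        sample, val = origin_rpkm[contig]
        clade = member_clade.get(member, "unassigned")
        key = (clade, sample)
        m.cells[key] = m.cells.get(key, 0.0) + val
        group = member_group.get(member, "unknown")
        m.group_totals[group] = m.group_totals.get(group, 0.0) + val
    return m


def write_clade_matrix(m: CladeAbundanceMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("clade_id\tsample_id\trpkm\n")
        for (clade, sample), val in sorted(m.cells.items(), key=lambda kv: (str(kv[0][0]), kv[0][1])):
            fh.write(f"{clade}\t{sample}\t{val:.6f}\n")
        fh.write("#group_totals\n")
        for g, val in sorted(m.group_totals.items()):
            fh.write(f"#{g}\t{val:.6f}\n")


def write_abundance_records(records: list[AbundanceRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tcontig_id\trpkm\torigin_sample\n")
        for r in records:
            fh.write(f"{r.sample_id}\t{r.contig_id}\t{r.rpkm:.6f}\t{int(r.origin_sample)}\n")
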