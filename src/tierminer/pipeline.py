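"""End-to-end orchestration: screen -> tier -> dereplicate -> classify ->
abundance -> neighborhood, from one config, with machine-readable outputs.

Every stage writes its table into the run directory; the resolved config is
snapshotted alongside so parameter-sensitive gates are reproducible.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import abundance as ab
from . import clustering as cl
from . import formats_io as fio
from . import homology as hom
from . import neighborhood as nb
from . import phylo
from . import tiering

log = logging.getLogger("tierminer")


@dataclass
class PipelineConfig:
    contigs: str
    proteins: str
    features: str
    counts: str
    totals: str
    panel: str
    panel_labels: str
    hits: str | None = None  # precomputed 12-column tabular hits
    votes: str | None = None
    outdir: str = "run"
    seed: int = 0
    thresholds: tiering.TierThresholds = field(default_factory=tiering.TierThresholds)
    derep_c: float = 0.999
    derep_aS: float = 0.999
    ladder_thresholds: tuple[float, ...] = (1.0, 0.99, 0.97, 0.95, 0.9)
    flank_width: int = 5
    min_overlap_len: int = 100
    min_itr_len: int = 100

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "thresholds" in d and isinstance(d["thresholds"], dict):
            d["thresholds"] = tiering.TierThresholds(**d["thresholds"])
        if "ladder_thresholds" in d:
            d["ladder_thresholds"] = tuple(d["ladder_thresholds"])
        return cls(**d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["ladder_thresholds"] = list(self.ladder_thresholds)
        return d


@dataclass
class PipelineResult:
    outdir: Path
    hits: list[fio.HomologyHit]
    gate: tiering.GateResult
    clusters: list[cl.Cluster]
    clade_calls: list[phylo.CladeCall]
    representatives: list[phylo.RepresentativeChoice]
    matrix: ab.CladeAbundanceMatrix
    ladder: list[dict]
    overlaps: list[nb.OverlapFinding]
    itrs: list[nb.ItrFinding]
    operons: list[nb.OperonCheck]


def run_all(cfg: PipelineConfig) -> PipelineResult:
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    for name in ("contigs", "proteins", "features", "counts", "totals", "panel", "panel_labels"):
        p = getattr(cfg, name)
        if not Path(p).exists():
            raise FileNotFoundError(f"missing input {name}: {p}")

    fio.dump_config(cfg.to_dict(), outdir / "config.json")

    contigs = fio.read_fasta(cfg.contigs, "dna")
    proteins = fio.read_fasta(cfg.proteins, "protein")
    features = fio.read_features(cfg.features)
    counts = fio.read_counts(cfg.counts)
    totals = fio.read_totals(cfg.totals)
    panel = hom.build_panel(fio.read_fasta(cfg.panel, "protein"), hom.read_panel_labels(cfg.panel_labels))
    panel_by_id = {e.id: e for e in panel}
    contig_by_id = {c.id: c for c in contigs}
    protein_by_id = {p.id: p for p in proteins}
    contig_of_protein = {f.product_id: f.contig_id for f in features}
    log.info("inputs: %d contigs, %d proteins, %d panel entries", len(contigs), len(proteins), len(panel))

    # --- screen ------------------------------------------------------------
    precomputed = fio.read_tabular_hits(cfg.hits) if cfg.hits else None
    hits = hom.screen_panel(proteins, panel, evalue_max=cfg.thresholds.evalue_max, precomputed=precomputed)
    fio.write_tabular_hits(hits, outdir / "hits.tsv")
    log.info("screen: %d hits retained", len(hits))

    # --- tier --------------------------------------------------------------
    candidates: list[tiering.TierCandidate] = []
    alignments: dict[str, hom.AlignmentResult] = {}
    for qid, best in sorted(hom.best_hits(hits).items()):
        if qid not in protein_by_id:
            continue
        ref = panel_by_id[best.reference_id]
        aln = hom.align_local(protein_by_id[qid].seq, ref.seq)
        alignments[qid] = aln
        motifs = tiering.detect_motifs(protein_by_id[qid].seq, qid, alignment=aln, reference=ref)
        candidates.append(
            tiering.TierCandidate(
                query_id=qid,
                contig_id=contig_of_protein.get(qid, ""),
                tier=None,
                best_hit=best,
                motifs=motifs,
            )
        )
    gate_result = tiering.gate(candidates, cfg.thresholds)
    tiering.write_tiers(gate_result, outdir / "tiers.tsv")
    log.info("tier: %d tier-1, %d tier-2", len(gate_result.tier1), len(gate_result.tier2))

    # --- dereplicate tier-1 contigs ---------------------------------------
    tier1 = gate_result.tier1
    tier1_contig_ids = sorted({c.contig_id for c in tier1 if c.contig_id})
    clusters: list[cl.Cluster] = []
    rep_of: dict[str, str] = {}
    if tier1_contig_ids:
        tier1_contigs = [contig_by_id[c] for c in tier1_contig_ids if c in contig_by_id]
        _, rep_of = cl.dereplicate_contigs(
            tier1_contigs, cl.ClusterParams(c=cfg.derep_c, aS=cfg.derep_aS, space="nucleotide")
        )
        clusters = cl.greedy_cluster(
            tier1_contigs, cl.ClusterParams(c=cfg.derep_c, aS=cfg.derep_aS, space="nucleotide")
        )
    cl.write_clusters(clusters, outdir / "clusters.tsv")
    nonredundant = [c for c in tier1 if rep_of.get(c.contig_id, c.contig_id) == c.contig_id]
    log.info("dereplicate: %d nonredundant tier-1 contigs", len({c.contig_id for c in nonredundant}))

    # --- classify ----------------------------------------------------------
    calls: list[phylo.CladeCall] = []
    if nonredundant:
        leaves = [(c.query_id, protein_by_id[c.query_id].seq) for c in nonredundant]
        leaves += [(e.id, e.seq) for e in panel]
        dm = phylo.pdistance_matrix(leaves)
        tree = phylo.nj_tree(dm)
        outgroup = {e.id for e in panel if e.group == "V" and e.dioxane_label in ("OUT", "COMPOUT")}
        if not outgroup:
            outgroup = {e.id for e in panel if e.dioxane_label in ("OUT", "COMPOUT")}
        rooted = phylo.root_by_outgroup(tree, outgroup) if outgroup else tree
        fio.write_newick(rooted, outdir / "tree.nwk")
        calls = phylo.call_clades(rooted, panel_by_id)
    else:
        (outdir / "tree.nwk").write_text("")
    with open(outdir / "cladecalls.tsv", "w") as fh:
        fh.write("query_id\tcall\tgroup\tclade_id\tsupporting_references\n")
        for c in calls:
            fh.write(f"{c.query_id}\t{c.call}\t{c.group}\t{c.clade_id}\t{','.join(c.supporting_reference_ids)}\n")
    log.info("classify: %d clade calls", len(calls))

    # --- abundance ---------------------------------------------------------
    origin = {c.id: c.id.split("_")[0] for c in contigs}
    records = ab.abundance_records(counts, totals, {c.id: len(c.seq) for c in contigs}, origin)
    ab.write_abundance_records(records, outdir / "rpkm.tsv")
    call_by_query = {c.query_id: c for c in calls}
    members = [c for c in nonredundant if c.query_id in call_by_query]
    matrix = ab.clade_matrix(
        member_clade={c.query_id: call_by_query[c.query_id].clade_id for c in members},
        member_group={c.query_id: call_by_query[c.query_id].group for c in members},
        member_contig={c.query_id: c.contig_id for c in members},
        records=records,
    )
    ab.write_clade_matrix(matrix, outdir / "clade_matrix.tsv")

    # --- representatives ---------------------------------------------------
    origin_rpkm = {r.contig_id: r.rpkm for r in records if r.origin_sample}
    motif_by_query = {c.query_id: c.motifs for c in tier1}
    reps: list[phylo.RepresentativeChoice] = []
    by_clade: dict[int, list[str]] = {}
    for c in members:
        by_clade.setdefault(call_by_query[c.query_id].clade_id, []).append(c.query_id)
    contig_of = {c.query_id: c.contig_id for c in tier1}
    for clade_id in sorted(by_clade):
        mem = by_clade[clade_id]
        abund = {m: origin_rpkm.get(contig_of[m], 0.0) for m in mem}
        reps.append(phylo.select_representative(clade_id, mem, abund, motif_by_query))
    with open(outdir / "representatives.tsv", "w") as fh:
        fh.write("clade_id\trepresentative\trpkm\tflagged\tskipped\n")
        for r in reps:
            skipped = ";".join(f"{i}:{why}" for i, why in r.skipped_ids)
            fh.write(f"{r.clade_id}\t{r.representative_query_id}\t{r.abundance_rpkm:.6f}\t{int(r.flagged)}\t{skipped}\n")

    # --- identity ladder ---------------------------------------------------
    ladder_rows: list[dict] = []
    if nonredundant:
        seqs = [protein_by_id[c.query_id] for c in nonredundant]
        labels = {c.query_id: call_by_query[c.query_id].group for c in members}
        ladder_rows = cl.identity_ladder(seqs, cfg.ladder_thresholds, labels=labels, space="protein")
    cl.write_ladder(ladder_rows, outdir / "table1.tsv")

    # --- neighborhood ------------------------------------------------------
    votes = fio.read_votes(cfg.votes) if cfg.votes else []
    votes_by_gene: dict[str, list[fio.AnnotationVote]] = {}
    for v in votes:
        votes_by_gene.setdefault(v.gene_id, []).append(v)
    annotations = [
        nb.consensus_annotation(vs, gene_id=g) for g, vs in sorted(votes_by_gene.items())
    ]
    subunit_labels = {
        a.gene_id: a.label for a in annotations if a.label in nb.SUBUNIT_ORDER
    }
    tier1_contig_set = sorted({c.contig_id for c in nonredundant if c.contig_id})
    operons: list[nb.OperonCheck] = []
    itrs: list[nb.ItrFinding] = []
    for cid in tier1_contig_set:
        feats = [f for f in features if f.contig_id == cid]
        if not feats:
            continue
        if subunit_labels:
            operons.append(nb.check_operon_order(feats, subunit_labels))
        itrs.extend(nb.find_itr(contig_by_id[cid].seq, feats, min_len=cfg.min_itr_len))
    overlaps: list[nb.OverlapFinding] = []
    if tier1_contig_set and len(contigs) >= 2:
        # break detection needs the whole assembly: fragments of a tier-1
        # locus need not themselves carry the alpha gene
        pairs = [(c.id, c.seq) for c in contigs]
        all_overlaps = nb.find_terminal_overlaps(pairs, min_len=cfg.min_overlap_len)
        t1 = set(tier1_contig_set)
        overlaps = [o for o in all_overlaps if o.contig_a in t1 or o.contig_b in t1]
    nb.write_neighborhood_report(
        annotations, subunit_labels, operons, itrs, overlaps, outdir / "neighborhood.tsv"
    )

    log.info("done: outputs in %s", outdir)
    return PipelineResult(
        outdir=outdir,
        hits=hits,
        gate=gate_result,
        clusters=clusters,
        clade_calls=calls,
        representatives=reps,
        matrix=matrix,
        ladder=ladder_rows,
        overlaps=overlaps,
        itrs=itrs,
        operons=operons,
    )
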