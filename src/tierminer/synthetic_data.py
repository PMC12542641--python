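"""Multi-sample synthetic metagenomes with planted monooxygenase operons.

Everything is generated from one seeded :class:`numpy.random.Generator`, so a
fixed seed yields byte-identical output files. Divergence of planted alpha
subunits is positional substitution only (no indels), which makes the
realized identity and hence the expected tier derivable in closed form.
Background genes are composition-shuffled panel sequences — guaranteed no
retained panel homology while preserving residue composition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .formats_io import (
    GeneFeature,
    SequenceRecord,
    write_counts,
    write_fasta,
    write_features,
    write_totals,
)
from .homology import ReferenceEntry, write_panel_labels

AA20 = "ACDEFGHIKLMNPQRSTVWY"

# one deterministic codon per amino acid keeps nucleotide identity tied to
# protein identity for planted genes
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAT", "P": "CCG", "Q": "CAA", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
    "X": "NNN",
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

MOTIF1_POS = 100
MOTIF2_POS = 180
REF_LEN = 260

SUBUNIT_ORDER = ("alpha", "reductase", "beta", "coupling")
_SUBUNIT_LEN = {"reductase": 150, "beta": 120, "coupling": 90}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def reverse_translate(protein: str) -> str:
    return "".join(_CODON[a] for a in protein)


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA20), size=length))


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def _plant_motif(seq: list[str], pos: int, rng: np.random.Generator) -> None:
    wild = rng.choice(list(AA20))
    seq[pos : pos + 5] = ["D", "E", wild, "R", "H"]


# ---------------------------------------------------------------------------
# Reference panel
# ---------------------------------------------------------------------------

def make_reference_panel(
    rng: np.random.Generator,
    groups: tuple[str, ...] = ("I", "II", "III", "IV", "V", "VI"),
    include_motifless_comp: bool = True,
) -> list[ReferenceEntry]:
    """A labeled panel with one dioxane-evidence subfamily and one outgroup
    subfamily per SDIMO group.

    Subfamily members sit at ~95% identity to their subfamily ancestor; the
    two subfamilies of a group sit at ~70% identity to each other; groups are
    mutually unrelated random sequences. All entries share the same two
    di-iron motif anchor positions. Optionally one dioxane-positive COMP
    entry with both motifs ablated is appended (such references exist).
    """
    panel: list[ReferenceEntry] = []
    for group in groups:
        ancestor = list(_random_protein(rng, REF_LEN))
        _plant_motif(ancestor, MOTIF1_POS, rng)
        _plant_motif(ancestor, MOTIF2_POS, rng)
        ancestor = "".join(ancestor)
        out_ancestor, _ = mutate_to_identity(ancestor, 70.0, rng)

        for i, label in enumerate(("CDDP", "COMP")):
            seq, _ = mutate_to_identity(ancestor, 95.0, rng)
            panel.append(
                ReferenceEntry(
                    id=f"REF_{group}_{label}{i + 1}",
                    seq=seq,
                    dioxane_label=label,
                    group=group,
                    subtype=f"{group}-cddp-like",
                    motif1_anchor=MOTIF1_POS,
                    motif2_anchor=MOTIF2_POS,
                    dioxane_positive=True if label == "COMP" else None,
                )
            )
        for i, label in enumerate(("OUT", "COMPOUT")):
            seq, _ = mutate_to_identity(out_ancestor, 95.0, rng)
            panel.append(
                ReferenceEntry(
                    id=f"REF_{group}_{label}{i + 1}",
                    seq=seq,
                    dioxane_label=label,
                    group=group,
                    subtype=f"{group}-outgroup",
                    motif1_anchor=MOTIF1_POS,
                    motif2_anchor=MOTIF2_POS,
                    dioxane_positive=False if label == "COMPOUT" else None,
                )
            )
    if include_motifless_comp:
        base = panel[0].seq
        seq, _ = mutate_to_identity(base, 95.0, rng, ablate_first_motif=True, ablate_second_motif=True)
        panel.append(
            ReferenceEntry(
                id="REF_I_COMP_NOMOTIF",
                seq=seq,
                dioxane_label="COMP",
                group=panel[0].group,
                subtype="motifless-partial",
                motif1_anchor=None,
                motif2_anchor=None,
                dioxane_positive=True,
            )
        )
    return panel


# ---------------------------------------------------------------------------
# Controlled divergence
# ---------------------------------------------------------------------------

def mutate_to_identity(
    protein: str,
    target_identity: float,
    rng: np.random.Generator,
    ablate_first_motif: bool = False,
    ablate_second_motif: bool = False,
    motif_positions: tuple[int, int] = (MOTIF1_POS, MOTIF2_POS),
) -> tuple[str, float]:
    """Substitute positions to hit a target percent identity exactly.

    Substitutions avoid the two 5-residue motif windows unless ablation is
    requested, in which case the motif's E is forced to A (breaking the
    D-E-x-R-H pattern). Returns (mutated sequence, realized identity), the
    latter recomputed by direct positional comparison.
    """
    L = len(protein)
    if L < 50:
        raise ValueError("protein too short to mutate (need >= 50 residues)")
    if not (0 < target_identity <= 100):
        raise ValueError("target_identity must be in (0, 100]")

    motif_windows = set()
    for p in motif_positions:
        if 0 <= p and p + 5 <= L:
            motif_windows.update(range(p, p + 5))

    forced: list[int] = []
    if ablate_first_motif:
        forced.append(motif_positions[0] + 1)
    if ablate_second_motif:
        forced.append(motif_positions[1] + 1)

    n_sub = int(round(L * (1.0 - target_identity / 100.0)))
    n_sub = max(n_sub, len(forced))
    allowed = [i for i in range(L) if i not in motif_windows]
    if n_sub - len(forced) > len(allowed):
        raise ValueError(
            f"target identity {target_identity} unreachable: "
            f"{n_sub} substitutions needed, {len(allowed)} positions available"
        )

    positions = list(forced)
    if n_sub > len(forced):
        extra = rng.choice(len(allowed), size=n_sub - len(forced), replace=False)
        positions += [allowed[int(i)] for i in extra]

    seq = list(protein)
    for pos in positions:
        if pos in forced:
            seq[pos] = "A" if protein[pos] != "A" else "G"  # deterministic pattern break
            continue
        choices = [a for a in AA20 if a != protein[pos]]
        seq[pos] = choices[int(rng.integers(len(choices)))]
    mutated = "".join(seq)
    realized = 100.0 * sum(a == b for a, b in zip(protein, mutated)) / L
    return mutated, realized


# ---------------------------------------------------------------------------
# Simulation config and truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantSpec:
    reference_id: str
    target_identity: float
    ablate_first_motif: bool = False
    ablate_second_motif: bool = False
    include_full_operon: bool = True
    add_terminal_itr: bool = False
    paired_overlap_len: int | None = None
    sample_index: int | None = None  # round-robin when None

    def __post_init__(self) -> None:
        if not (0 < self.target_identity <= 100):
            raise ValueError("target_identity must be in (0, 100]")


@dataclass
class SimulationConfig:
    seed: int
    n_samples: int = 2
    n_contigs_per_sample: int = 5
    planted_operons: list[PlantSpec] = field(default_factory=list)
    background_gene_rate: float = 0.5  # genes per kb
    mean_depth: float = 50.0
    dispersion: float = 2.0
    background_contig_len: int = 3000

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_contigs_per_sample < 0:
            raise ValueError("sample/contig counts must be positive")
        if self.background_gene_rate <= 0 or self.mean_depth <= 0 or self.dispersion <= 0:
            raise ValueError("all rates must be positive")


@dataclass
class TruthRecord:
    gene_id: str
    contig_id: str
    sample_id: str
    role: str  # alpha | reductase | beta | coupling | transposase | decoy
    reference_id: str = ""
    realized_identity: float = 0.0
    group: str = ""
    dioxane_label: str = ""  # CDDP-like | outgroup-like | ""
    motif1_intact: bool = False
    motif2_intact: bool = False
    expected_tier: int | None = None


@dataclass
class SimulationResult:
    contigs: list[SequenceRecord]
    proteins: list[SequenceRecord]
    features: list[GeneFeature]
    counts: dict[tuple[str, str], int]
    totals: dict[str, int]
    truth: dict[str, TruthRecord]
    panel: list[ReferenceEntry]
    origin_of_contig: dict[str, str]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.contigs, outdir / "contigs.fna")
        write_fasta(self.proteins, outdir / "proteins.faa")
        write_features(self.features, outdir / "features.tsv")
        write_counts(self.counts, outdir / "counts.tsv")
        write_totals(self.totals, outdir / "totals.tsv")
        write_truth(self.truth, outdir / "truth.tsv")
        write_fasta(
            [SequenceRecord(e.id, e.seq, "protein") for e in self.panel],
            outdir / "panel.faa",
        )
        write_panel_labels(self.panel, outdir / "panel_labels.tsv")


def write_truth(truth: dict[str, TruthRecord], path: str | Path) -> None:
    cols = (
        "gene_id\tcontig_id\tsample_id\trole\treference_id\trealized_identity\t"
        "group\tdioxane_label\tmotif1_intact\tmotif2_intact\texpected_tier\n"
    )
    with open(path, "w") as fh:
        fh.write(cols)
        for t in sorted(truth.values(), key=lambda x: x.gene_id):
            fh.write(
                f"{t.gene_id}\t{t.contig_id}\t{t.sample_id}\t{t.role}\t{t.reference_id}\t"
                f"{t.realized_identity:.3f}\t{t.group}\t{t.dioxane_label}\t"
                f"{int(t.motif1_intact)}\t{int(t.motif2_intact)}\t"
                f"{'none' if t.expected_tier is None else t.expected_tier}\n"
            )


def read_truth(path: str | Path) -> dict[str, TruthRecord]:
    truth: dict[str, TruthRecord] = {}
    with open(path) as fh:
        header = fh.readline()
        assert header.startswith("gene_id\t")
        for line in fh:
            p = line.rstrip("\n").split("\t")
            truth[p[0]] = TruthRecord(
                gene_id=p[0], contig_id=p[1], sample_id=p[2], role=p[3],
                reference_id=p[4], realized_identity=float(p[5]), group=p[6],
                dioxane_label=p[7], motif1_intact=bool(int(p[8])),
                motif2_intact=bool(int(p[9])),
                expected_tier=None if p[10] == "none" else int(p[10]),
            )
    return truth


def expected_tier(realized_identity: float, motif1: bool, motif2: bool) -> int | None:
    if realized_identity >= 90.0:
        return 1 if (motif1 or motif2) else None
    if realized_identity >= 50.0:
        return 2
    return None


# ---------------------------------------------------------------------------
# Metagenome assembly
# ---------------------------------------------------------------------------

class _ContigBuilder:
    def __init__(self, contig_id: str, sample_id: str, rng: np.random.Generator):
        self.contig_id = contig_id
        self.sample_id = sample_id
        self.rng = rng
        self.parts: list[str] = [_random_dna(rng, int(rng.integers(60, 120)))]
        self.length = len(self.parts[0])
        self.features: list[GeneFeature] = []
        self.proteins: list[SequenceRecord] = []
        self._n = 0

    def add_gene(self, protein: str, strand: str = "+", dna: str | None = None) -> str:
        self._n += 1
        gene_id = f"{self.contig_id}_g{self._n}"
        dna = dna if dna is not None else reverse_translate(protein)
        if strand == "-":
            dna = revcomp(dna)
        start = self.length + 1  # 1-based inclusive
        self.parts.append(dna)
        self.length += len(dna)
        self.features.append(
            GeneFeature(self.contig_id, gene_id, start, self.length, strand, gene_id)
        )
        self.proteins.append(SequenceRecord(gene_id, protein, "protein"))
        spacer = _random_dna(self.rng, int(self.rng.integers(20, 60)))
        self.parts.append(spacer)
        self.length += len(spacer)
        return gene_id

    def finish(self) -> SequenceRecord:
        return SequenceRecord(self.contig_id, "".join(self.parts), "dna")


def simulate_metagenome(config: SimulationConfig, panel: list[ReferenceEntry] | None = None) -> SimulationResult:
    """Build contigs, proteins, features, counts and ground truth from a config."""
    rng = np.random.default_rng(config.seed)
    if panel is None:
        panel = make_reference_panel(rng)
    ref_by_id = {e.id: e for e in panel}

    contigs: list[SequenceRecord] = []
    proteins: list[SequenceRecord] = []
    features: list[GeneFeature] = []
    truth: dict[str, TruthRecord] = {}
    origin: dict[str, str] = {}

    samples = [f"S{i + 1}" for i in range(config.n_samples)]

    def register(builder: _ContigBuilder) -> None:
        rec = builder.finish()
        contigs.append(rec)
        proteins.extend(builder.proteins)
        features.extend(builder.features)
        origin[rec.id] = builder.sample_id

    # --- planted operon contigs -------------------------------------------
    for pi, spec in enumerate(config.planted_operons):
        ref = ref_by_id.get(spec.reference_id)
        if ref is None:
            raise ValueError(f"unknown panel reference {spec.reference_id!r}")
        sample = samples[(spec.sample_index if spec.sample_index is not None else pi) % config.n_samples]
        cid = f"{sample}_p{pi + 1}"
        builder = _ContigBuilder(cid, sample, rng)

        itr_protein = _random_protein(rng, 80) if spec.add_terminal_itr else None
        itr_dna = reverse_translate(itr_protein) if itr_protein else None
        if itr_protein:
            gid = builder.add_gene(itr_protein, "+", dna=itr_dna)
            truth[gid] = TruthRecord(gid, cid, sample, "transposase")

        alpha, realized = mutate_to_identity(
            ref.seq, spec.target_identity, rng,
            ablate_first_motif=spec.ablate_first_motif,
            ablate_second_motif=spec.ablate_second_motif,
        )
        gid = builder.add_gene(alpha)
        truth[gid] = TruthRecord(
            gid, cid, sample, "alpha",
            reference_id=ref.id,
            realized_identity=realized,
            group=ref.group,
            dioxane_label="CDDP-like" if ref.has_dioxane_evidence else "outgroup-like",
            motif1_intact=not spec.ablate_first_motif,
            motif2_intact=not spec.ablate_second_motif,
            expected_tier=expected_tier(
                realized, not spec.ablate_first_motif, not spec.ablate_second_motif
            ),
        )
        if spec.include_full_operon:
            for role in SUBUNIT_ORDER[1:]:
                sub = _random_protein(rng, _SUBUNIT_LEN[role])
                gid = builder.add_gene(sub)
                truth[gid] = TruthRecord(gid, cid, sample, role)

        if itr_protein:
            gid = builder.add_gene(itr_protein, "-", dna=itr_dna)
            truth[gid] = TruthRecord(gid, cid, sample, "transposase")

        register(builder)

        if spec.paired_overlap_len:
            L = spec.paired_overlap_len
            host = contigs[-1]
            if len(host.seq) < L:
                raise ValueError(f"contig {host.id} too short for {L}-bp overlap")
            mate_id = f"{sample}_p{pi + 1}m"
            mate_seq = host.seq[-L:] + _random_dna(rng, max(200, L))
            contigs.append(SequenceRecord(mate_id, mate_seq, "dna"))
            origin[mate_id] = sample

    # --- background contigs with shuffled-panel decoy genes ----------------
    for sample in samples:
        for j in range(config.n_contigs_per_sample):
            cid = f"{sample}_c{j + 1}"
            builder = _ContigBuilder(cid, sample, rng)
            n_genes = max(1, int(round(config.background_gene_rate * config.background_contig_len / 1000)))
            for _ in range(n_genes):
                src = panel[int(rng.integers(len(panel)))].seq
                decoy = "".join(rng.permutation(list(src)))
                gid = builder.add_gene(decoy)
                truth[gid] = TruthRecord(gid, cid, sample, "decoy")
            pad = config.background_contig_len - builder.length
            if pad > 0:
                builder.parts.append(_random_dna(rng, pad))
                builder.length += pad
            register(builder)

    # --- counts ------------------------------------------------------------
    counts: dict[tuple[str, str], int] = {}
    k = config.dispersion
    for contig in contigs:
        for sample in samples:
            mean = config.mean_depth if origin[contig.id] == sample else config.mean_depth / 5.0
            p = k / (k + mean)
            counts[(sample, contig.id)] = int(rng.negative_binomial(k, p))
    totals = {}
    for sample in samples:
        s = sum(n for (sm, _), n in counts.items() if sm == sample)
        totals[sample] = max(1_000_000, s * 10)

    return SimulationResult(
        contigs=contigs,
        proteins=proteins,
        features=features,
        counts=counts,
        totals=totals,
        truth=truth,
        panel=panel,
        origin_of_contig=origin,
    )
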