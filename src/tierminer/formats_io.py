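"""Readers and writers for every external representation the pipeline touches.

No science lives here. Coordinates are 1-based inclusive in files (GFF
convention) and 0-based half-open internally.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import dendropy
import yaml

PROTEIN_LETTERS = set("ACDEFGHIKLMNPQRSTVWYX")
DNA_LETTERS = set("ACGTN")


class FormatError(ValueError):
    """Raised on malformed input files."""


@dataclass(frozen=True)
class SequenceRecord:
    """One FASTA record; ``id`` is the header token before the first whitespace."""

    id: str
    seq: str
    alphabet: str = "protein"  # "protein" | "dna"
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise FormatError(f"invalid record id: {self.id!r}")
        if not self.seq:
            raise FormatError(f"empty sequence for record {self.id!r}")
        letters = PROTEIN_LETTERS if self.alphabet == "protein" else DNA_LETTERS
        bad = set(self.seq) - letters
        if bad:
            raise FormatError(
                f"illegal {self.alphabet} character(s) {sorted(bad)} in record {self.id!r}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class GeneFeature:
    """A gene on a contig. File coordinates are 1-based inclusive."""

    contig_id: str
    gene_id: str
    start: int  # 1-based inclusive
    end: int
    strand: str  # "+" | "-"
    product_id: str

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise FormatError(
                f"feature {self.gene_id}: invalid coordinates {self.start}..{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(f"feature {self.gene_id}: invalid strand {self.strand!r}")

    @property
    def span0(self) -> tuple[int, int]:
        """0-based half-open interval on the contig."""
        return self.start - 1, self.end


@dataclass
class HomologyHit:
    """One query-vs-reference alignment with its filter statistics."""

    query_id: str
    reference_id: str
    pident: float  # percent, 0-100
    alen: int  # aligned columns
    qcov: float | None = None  # percent of query covered, 0-100
    evalue: float | None = None
    score: float = 0.0
    qstart: int | None = None  # 1-based on query
    qend: int | None = None
    sstart: int | None = None
    send: int | None = None
    best: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.pident <= 100.0):
            raise FormatError(f"pident out of range: {self.pident}")
        if self.alen < 1:
            raise FormatError(f"alen must be >= 1, got {self.alen}")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, alphabet: str = "protein") -> list[SequenceRecord]:
    """Read a FASTA file into an order-preserving list of records.

    Duplicate ids and illegal characters raise :class:`FormatError`; an empty
    file warns and returns an empty list (absence is a legitimate outcome).
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    header: str | None = None
    chunks: list[str] = []
    header_line = 0

    def flush() -> None:
        if header is None:
            return
        rid = header.split()[0] if header.split() else ""
        if rid in seen:
            raise FormatError(f"duplicate id {rid!r} in {path}")
        seen.add(rid)
        seq = "".join(chunks).upper()
        try:
            records.append(SequenceRecord(rid, seq, alphabet, description=header))
        except FormatError as exc:
            raise FormatError(f"{path} near line {header_line}: {exc}") from exc

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise FormatError(f"{path} line {lineno}: sequence before header")
                letters = PROTEIN_LETTERS if alphabet == "protein" else DNA_LETTERS
                if set(line.upper()) - letters:
                    raise FormatError(
                        f"{path} line {lineno}: illegal {alphabet} character"
                    )
                chunks.append(line)
    flush()
    if not records:
        warnings.warn(f"empty FASTA: {path}", stacklevel=2)
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Tabular homology hits (12-column dialect)
# ---------------------------------------------------------------------------

_HIT_COLS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()


def read_tabular_hits(path: str | Path) -> list[HomologyHit]:
    """Parse 12-column tab-separated hits (qseqid..bitscore). qcov is left unset."""
    hits: list[HomologyHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise FormatError(
                    f"{path} line {lineno}: expected 12 columns, got {len(parts)}"
                )
            hits.append(
                HomologyHit(
                    query_id=parts[0],
                    reference_id=parts[1],
                    pident=float(parts[2]),
                    alen=int(parts[3]),
                    qstart=int(parts[6]),
                    qend=int(parts[7]),
                    sstart=int(parts[8]),
                    send=int(parts[9]),
                    evalue=float(parts[10]),
                    score=float(parts[11]),
                )
            )
    return hits


def write_tabular_hits(hits: Iterable[HomologyHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        h.query_id,
                        h.reference_id,
                        f"{h.pident:.3f}",
                        h.alen,
                        0,
                        0,
                        h.qstart or 0,
                        h.qend or 0,
                        h.sstart or 0,
                        h.send or 0,
                        "NA" if h.evalue is None else f"{h.evalue:.3g}",
                        f"{h.score:.1f}",
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Feature / counts / votes TSV
# ---------------------------------------------------------------------------

def read_features(path: str | Path) -> list[GeneFeature]:
    feats: list[GeneFeature] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("contig_id\t"):
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise FormatError(f"{path} line {lineno}: expected 6 columns")
            f = GeneFeature(parts[0], parts[1], int(parts[2]), int(parts[3]), parts[4], parts[5])
            if f.gene_id in seen:
                raise FormatError(f"{path} line {lineno}: duplicate gene_id {f.gene_id!r}")
            seen.add(f.gene_id)
            feats.append(f)
    return feats


def write_features(feats: Iterable[GeneFeature], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("contig_id\tgene_id\tstart\tend\tstrand\tproduct_id\n")
        for f in feats:
            fh.write(f"{f.contig_id}\t{f.gene_id}\t{f.start}\t{f.end}\t{f.strand}\t{f.product_id}\n")


def read_counts(path: str | Path) -> dict[tuple[str, str], int]:
    """Counts TSV (sample_id, contig_id, count) -> {(sample, contig): count}."""
    counts: dict[tuple[str, str], int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("sample_id\t"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise FormatError(f"{path} line {lineno}: expected 3 columns")
            n = int(parts[2])
            if n < 0:
                raise FormatError(f"{path} line {lineno}: negative count")
            counts[(parts[0], parts[1])] = n
    return counts


def write_counts(counts: dict[tuple[str, str], int], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tcontig_id\tcount\n")
        for (s, c), n in sorted(counts.items()):
            fh.write(f"{s}\t{c}\t{n}\n")


def read_totals(path: str | Path) -> dict[str, int]:
    """Totals TSV (sample_id, total_mapped) -> {sample: total}."""
    totals: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("sample_id\t"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path} line {lineno}: expected 2 columns")
            t = int(parts[1])
            if t <= 0:
                raise FormatError(f"{path} line {lineno}: total_mapped must be positive")
            totals[parts[0]] = t
    return totals


def write_totals(totals: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\ttotal_mapped\n")
        for s, t in sorted(totals.items()):
            fh.write(f"{s}\t{t}\n")


@dataclass(frozen=True)
class AnnotationVote:
    """One annotator's call for one gene; label is normalized at construction."""

    gene_id: str
    annotator: str
    annotation: str  # normalized; "" means the NONE sentinel
    evalue: float | None = None


_PUNCT_RE = re.compile(r"[^\w\s-]")
_NONE_LABELS = {"hypothetical", "unknown", "none", "na", "hypothetical protein", "unknown protein"}


def normalize_label(label: str) -> str:
    """Lowercase, strip punctuation, collapse whitespace; sentinel labels -> ''."""
    s = _PUNCT_RE.sub(" ", label.lower())
    s = " ".join(s.split())
    return "" if s in _NONE_LABELS else s


def read_votes(path: str | Path) -> list[AnnotationVote]:
    """Votes TSV (gene_id, annotator, annotation, evalue); evalue may be 'NA'."""
    votes: list[AnnotationVote] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("gene_id\t"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise FormatError(f"{path} line {lineno}: expected 4 columns")
            ev = None if parts[3] in ("", "NA", "na") else float(parts[3])
            votes.append(AnnotationVote(parts[0], parts[1], normalize_label(parts[2]), ev))
    return votes


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def read_newick(path: str | Path) -> dendropy.Tree:
    try:
        return dendropy.Tree.get(path=str(path), schema="newick", preserve_underscores=True)
    except Exception as exc:  # dendropy raises several parse error types
        raise FormatError(f"newick parse error in {path}: {exc}") from exc


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    """Write canonical newick: 6-decimal branch lengths, unquoted names."""
    s = tree.as_string(
        schema="newick",
        unquoted_underscores=True,
        suppress_rooting=True,
        real_value_format_specifier=".6f",
    )
    with open(path, "w") as fh:
        fh.write(s if s.endswith("\n") else s + "\n")


def parse_newick_string(text: str) -> dendropy.Tree:
    try:
        return dendropy.Tree.get(data=text, schema="newick", preserve_underscores=True)
    except Exception as exc:
        raise FormatError(f"newick parse error: {exc}") from exc


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> dict:
    path = Path(path)
    with open(path) as fh:
        if path.suffix in (".yaml", ".yml"):
            return yaml.safe_load(fh) or {}
        return json.load(fh)


def dump_config(cfg: dict, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if path.suffix in (".yaml", ".yml"):
            yaml.safe_dump(cfg, fh, sort_keys=True)
        else:
            json.dump(cfg, fh, indent=2, sort_keys=True)
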