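"""Mitogenome annotations: domain types, file I/O and circular coordinate math.

Coordinates are 1-based and inclusive on both ends, the convention used by
GenBank feature tables; a feature spanning the origin of the circular
chromosome is stored with ``end < start``.  Gene orientation follows the
crustacean-mitogenomics convention: ``J`` is the majority (deposited)
strand, ``N`` its reverse complement; the control region is stored
unoriented.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from . import vocab
from .vocab import CR, PCG, RRNA, TRNA, canonical_name, gene_class

J, N = "J", "N"

_COLUMNS = (
    "gene", "class", "orientation", "start", "end",
    "anticodon", "start_codon", "stop_codon",
)

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class AnnotationFormatError(ValueError):
    """Malformed annotation input (bad coordinates, unknown columns, ...)."""


@dataclass(frozen=True)
class GeneFeature:
    """One annotated gene or region on the circular mitochondrial chromosome."""

    name: str
    gene_class: str
    orientation: Optional[str]  # "J", "N", or None (control region)
    start: int                  # 1-based, inclusive
    end: int                    # 1-based, inclusive
    anticodon: Optional[str] = None
    start_codon: Optional[str] = None
    stop_codon: Optional[str] = None

    def __post_init__(self):
        expected = gene_class(self.name)
        if self.gene_class != expected:
            raise ValueError(
                f"{self.name}: class {self.gene_class!r} inconsistent with "
                f"vocabulary (expected {expected!r})"
            )
        if self.orientation not in (J, N, None):
            raise ValueError(f"{self.name}: orientation must be J, N or None")
        if self.start < 1 or self.end < 1:
            raise ValueError(f"{self.name}: coordinates must be >= 1")
        if self.anticodon is not None and self.gene_class != TRNA:
            raise ValueError(f"{self.name}: anticodon only valid for tRNAs")
        if (self.start_codon or self.stop_codon) and self.gene_class != PCG:
            raise ValueError(
                f"{self.name}: start/stop codons only valid for PCGs"
            )


@dataclass
class MitogenomeRecord:
    """A circular mitogenome: annotation (in file order) plus optional sequence."""

    accession: str
    genome_length: int
    features: list[GeneFeature] = field(default_factory=list)
    sequence: Optional[str] = None
    circular: bool = True

    def __post_init__(self):
        if self.genome_length < 1:
            raise ValueError("genome_length must be positive")
        if self.sequence is not None and len(self.sequence) != self.genome_length:
            raise ValueError(
                f"sequence length {len(self.sequence)} != genome_length "
                f"{self.genome_length}"
            )

    def feature(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def features_of_class(self, gene_class: str) -> list[GeneFeature]:
        return [f for f in self.features if f.gene_class == gene_class]

    def __eq__(self, other):
        if not isinstance(other, MitogenomeRecord):
            return NotImplemented
        return (
            self.accession == other.accession
            and self.genome_length == other.genome_length
            and self.circular == other.circular
            and self.features == other.features
            and self.sequence == other.sequence
        )


# ---------------------------------------------------------------------------
# coordinate arithmetic on the circle

def feature_length(feature: GeneFeature, genome_length: int) -> int:
    """Length in bp; a feature with ``end < start`` wraps the origin."""
    if feature.end >= feature.start:
        return feature.end - feature.start + 1
    return genome_length - feature.start + 1 + feature.end


def intergenic_spacer(prev: GeneFeature, nxt: GeneFeature,
                      genome_length: int) -> int:
    """Nucleotides between consecutive features; negative means overlap.

    ``start(next) - end(prev) - 1``, taken modulo the circle when the pair
    wraps the origin (detected as ``next`` starting before ``prev``).  The
    degenerate self-pair returns ``-length``.
    """
    raw = nxt.start - prev.end - 1
    if nxt.start < prev.start:  # annotation order wrapped past the origin
        raw += genome_length
    return raw


def strand_counts(record: MitogenomeRecord) -> tuple[int, int]:
    """(number of J-strand genes, number of N-strand genes); CR excluded."""
    j = sum(1 for f in record.features if f.orientation == J)
    n = sum(1 for f in record.features if f.orientation == N)
    return j, n


def feature_sequence(record: MitogenomeRecord, feature: GeneFeature,
                     oriented: bool = True) -> str:
    """Sequence of a feature, handling origin wrap.

    With ``oriented=True`` N-strand features are reverse-complemented to
    their mRNA sense; otherwise the J-strand slice is returned verbatim.
    """
    if record.sequence is None:
        raise ValueError("record carries no sequence")
    s = record.sequence
    if feature.end >= feature.start:
        sub = s[feature.start - 1:feature.end]
    else:
        sub = s[feature.start - 1:] + s[:feature.end]
    if oriented and feature.orientation == N:
        sub = reverse_complement(sub)
    return sub


# ---------------------------------------------------------------------------
# validation

@dataclass(frozen=True)
class Finding:
    level: str  # "error" | "warning"
    message: str


def validate_annotation(record: MitogenomeRecord,
                        spacer_warn_bp: int = 50) -> list[Finding]:
    """Structural checks; returns findings instead of raising.

    Errors: coordinates outside the genome, duplicate gene names.
    Warnings: missing members of the canonical 37-gene + CR complement, and
    intergenic spacers longer than ``spacer_warn_bp`` (default 50 bp) —
    large spacers in rearranged mitogenomes are often pseudogene remnants
    left behind by a tRNA translocation and are worth flagging.
    """
    findings: list[Finding] = []
    seen: set[str] = set()
    for f in record.features:
        if not (1 <= f.start <= record.genome_length
                and 1 <= f.end <= record.genome_length):
            findings.append(Finding(
                "error",
                f"{f.name}: coordinates {f.start}..{f.end} outside genome "
                f"of length {record.genome_length}",
            ))
        if f.name in seen:
            findings.append(Finding("error", f"duplicate gene name {f.name}"))
        seen.add(f.name)
    for name in vocab.ALL_NAMES:
        if name not in seen:
            findings.append(Finding("warning", f"missing gene {name}"))
    feats = record.features
    for prev, nxt in zip(feats, feats[1:] + feats[:1]):
        if prev is nxt:
            break
        gap = intergenic_spacer(prev, nxt, record.genome_length)
        if gap > spacer_warn_bp:
            findings.append(Finding(
                "warning",
                f"{gap} bp intergenic spacer between {prev.name} and "
                f"{nxt.name} (> {spacer_warn_bp} bp; possible pseudogene "
                f"remnant)",
            ))
    return findings


# ---------------------------------------------------------------------------
# feature-table (TSV) I/O

def _parse_int(text: str, row: int, column: str) -> int:
    try:
        return int(text.replace(",", ""))
    except ValueError:
        raise AnnotationFormatError(
            f"row {row}: cannot parse {column} value {text!r} as an integer"
        ) from None


_ORIENT_ALIASES = {
    "j": J, "f": J, "+": J, "forward": J,
    "n": N, "r": N, "-": N, "reverse": N,
}


def _parse_orientation(text: str, row: int) -> Optional[str]:
    t = text.strip()
    if t in ("", ".", "—", "--", "none"):
        return None
    try:
        return _ORIENT_ALIASES[t.lower()]
    except KeyError:
        raise AnnotationFormatError(
            f"row {row}: unknown orientation {text!r}"
        ) from None


def read_feature_table(path) -> MitogenomeRecord:
    """Read a tab-separated annotation table.

    Columns (header required): ``gene class orientation start end anticodon
    start_codon stop_codon``; ``#``-prefixed lines are comments; an optional
    ``#genome_length=N`` line fixes the genome length, which otherwise
    defaults to the maximum end coordinate.  Thousands separators in
    coordinates are tolerated.  Empty cells are written as ``.``.
    """
    path = Path(path)
    genome_length: Optional[int] = None
    header: Optional[list[str]] = None
    feats: list[GeneFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.lower().startswith("genome_length="):
                    genome_length = _parse_int(
                        body.split("=", 1)[1], lineno, "genome_length")
                continue
            cells = [c.strip() for c in line.split("\t")]
            if header is None:
                header = [c.lower() for c in cells]
                missing = [c for c in _COLUMNS if c not in header]
                if missing:
                    raise AnnotationFormatError(
                        f"header missing column(s): {', '.join(missing)}"
                    )
                continue
            row = dict(zip(header, cells))
            name = canonical_name(row["gene"])
            none = lambda v: None if v in ("", ".", "—") else v
            feats.append(GeneFeature(
                name=name,
                gene_class=gene_class(name),
                orientation=_parse_orientation(row["orientation"], lineno),
                start=_parse_int(row["start"], lineno, "start"),
                end=_parse_int(row["end"], lineno, "end"),
                anticodon=none(row["anticodon"]),
                start_codon=none(row["start_codon"]),
                stop_codon=none(row["stop_codon"]),
            ))
    if not feats:
        raise AnnotationFormatError(f"{path}: no features")
    if genome_length is None:
        genome_length = max(f.end for f in feats)
    return MitogenomeRecord(
        accession=path.stem, genome_length=genome_length, features=feats)


def write_feature_table(record: MitogenomeRecord, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#genome_length={record.genome_length}\n")
        fh.write("\t".join(_COLUMNS) + "\n")
        for f in record.features:
            cells = (
                f.name, f.gene_class, f.orientation or ".",
                str(f.start), str(f.end),
                f.anticodon or ".", f.start_codon or ".", f.stop_codon or ".",
            )
            fh.write("\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# GenBank / FASTA I/O (via Biopython)

_GB_KEY = {PCG: "CDS", TRNA: "tRNA", RRNA: "rRNA", CR: "misc_feature"}


def write_genbank(record: MitogenomeRecord, path) -> None:
    """Write the record as a GenBank flat file.

    Features are emitted as CDS/tRNA/rRNA/misc_feature with ``gene``,
    ``anticodon`` and start/stop-codon qualifiers; a record without a
    sequence is padded with ``N`` (the flat-file format requires one).
    """
    seq = record.sequence or "N" * record.genome_length
    sr = SeqRecord(Seq(seq), id=record.accession, name=record.accession[:16],
                   description="mitochondrion, complete genome")
    sr.annotations["molecule_type"] = "DNA"
    sr.annotations["topology"] = "circular" if record.circular else "linear"
    for f in record.features:
        strand = {J: +1, N: -1, None: None}[f.orientation]
        if f.end >= f.start:
            loc = SimpleLocation(f.start - 1, f.end, strand=strand)
        else:  # wrapped feature: join(start..L, 1..end)
            loc = SimpleLocation(f.start - 1, record.genome_length,
                                 strand=strand) + SimpleLocation(
                                     0, f.end, strand=strand)
        quals = {"gene": [f.name]}
        if f.anticodon:
            quals["anticodon"] = [f.anticodon]
        if f.start_codon:
            quals["start_codon"] = [f.start_codon]
        if f.stop_codon:
            quals["stop_codon"] = [f.stop_codon]
        if f.gene_class == CR:
            quals["note"] = ["control region"]
        sr.features.append(SeqFeature(loc, type=_GB_KEY[f.gene_class],
                                      qualifiers=quals))
    SeqIO.write([sr], str(path), "genbank")


def read_genbank(path) -> MitogenomeRecord:
    """Read a GenBank flat file; interprets CDS/tRNA/rRNA/misc_feature/D-loop."""
    try:
        sr = SeqIO.read(str(path), "genbank")
    except ValueError as exc:
        raise AnnotationFormatError(f"{path}: {exc}") from exc
    seq = str(sr.seq).upper()
    has_seq = bool(seq) and set(seq) <= set("ACGT")
    feats: list[GeneFeature] = []
    for ft in sr.features:
        if ft.type not in ("CDS", "tRNA", "rRNA", "misc_feature", "D-loop"):
            continue
        if ft.type == "D-loop":
            name = "CR"
        else:
            symbols = ft.qualifiers.get("gene") or ft.qualifiers.get("product")
            if not symbols:
                if ft.type == "misc_feature" and any(
                        "control region" in n.lower()
                        for n in ft.qualifiers.get("note", [])):
                    symbols = ["CR"]
                else:
                    continue
            name = canonical_name(symbols[0])
        cls = gene_class(name)
        parts = ft.location.parts
        start = int(parts[0].start) + 1
        end = int(parts[-1].end)
        strand = parts[0].strand
        orientation = None if cls == CR else (J if strand != -1 else N)
        one = lambda key: (ft.qualifiers.get(key) or [None])[0]
        feats.append(GeneFeature(
            name=name, gene_class=cls, orientation=orientation,
            start=start, end=end,
            anticodon=one("anticodon") if cls == TRNA else None,
            start_codon=one("start_codon") if cls == PCG else None,
            stop_codon=one("stop_codon") if cls == PCG else None,
        ))
    return MitogenomeRecord(
        accession=sr.id or Path(path).stem,
        genome_length=len(sr.seq),
        features=feats,
        sequence=seq if has_seq else None,
    )


def read_fasta(path) -> str:
    """Read the first sequence of a FASTA file as an upper-case string."""
    rec = next(SeqIO.parse(str(path), "fasta"), None)
    if rec is None:
        raise AnnotationFormatError(f"{path}: no FASTA record")
    return str(rec.seq).upper()


def write_fasta(sequence: str, path, label: str = "sequence",
                width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{label}\n")
        for i in range(0, len(sequence), width):
            fh.write(sequence[i:i + width] + "\n")
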