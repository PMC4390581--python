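"""Sequence and TSS-annotation input, and strand-aware promoter extraction.

All internal coordinates are 0-based half-open; 1-based conventions of the
supported annotation dialects (GFF3, BED, TSV) are converted at the I/O
boundary.  Promoter windows are reported in transcription orientation, so
"upstream" is always to the left of ``tss_offset`` regardless of strand.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

__all__ = [
    "GenomeSequence",
    "TssRecord",
    "PromoterWindow",
    "reverse_complement",
    "read_fasta",
    "read_tss_table",
    "extract_promoter",
    "write_promoters_fasta",
]

_ALLOWED = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeSequence:
    """One named contig with normalized residues (uppercase A/C/G/T/N)."""

    id: str
    residues: str

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class TssRecord:
    """One annotated transcription start site (1-based genomic coordinate)."""

    gene_id: str
    transcript_id: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(
                f"unknown strand {self.strand!r} for {self.gene_id} "
                "(expected '+' or '-')"
            )
        if self.tss < 1:
            raise ValueError(f"tss must be >= 1, got {self.tss} for {self.gene_id}")


@dataclass(frozen=True)
class PromoterWindow:
    """A promoter sequence window anchored at one TSS.

    ``sequence`` reads 5'->3' in the direction of transcription; for strand
    '-' it is the reverse complement of the genomic slice ``[start, end)``.
    ``tss_offset`` is the index within ``sequence`` of the TSS base.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    start: int
    end: int
    strand: str
    sequence: str
    tss_offset: int

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def header(self) -> str:
        return (
            f"{self.gene_id}|{self.transcript_id}|"
            f"{self.chrom}:{self.start}-{self.end}({self.strand})"
        )


def _normalize_residues(raw: str, record_id: str) -> str:
    seq = raw.upper().replace("U", "T")
    bad = next((i for i, b in enumerate(seq) if b not in _ALLOWED), None)
    if bad is not None:
        raise ValueError(
            f"non-IUPAC residue {seq[bad]!r} at position {bad} in record {record_id!r}"
        )
    return seq


def read_fasta(path: str | Path) -> dict[str, GenomeSequence]:
    """Load a multi-record FASTA into a mapping keyed by record id.

    Residues are uppercased, U is folded to T, and anything outside
    {A,C,G,T,N} is a hard error.  Duplicate ids and empty files are errors.
    """
    out: dict[str, GenomeSequence] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate FASTA record id {rec.id!r} in {path}")
        out[rec.id] = GenomeSequence(rec.id, _normalize_residues(str(rec.seq), rec.id))
    if not out:
        raise ValueError(f"no FASTA records found in {path}")
    return out


def _parse_gff3_attributes(field: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in field.strip().split(";"):
        part = part.strip()
        if part and "=" in part:
            key, value = part.split("=", 1)
            attrs[key.strip()] = value.strip()
    return attrs


def _read_gff3(path: Path, feature_type: str) -> list[TssRecord]:
    records = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"malformed GFF3 line in {path}: {line!r}")
            chrom, _, ftype, start, end, _, strand, _, attr_field = fields[:9]
            if ftype != feature_type:
                continue
            attrs = _parse_gff3_attributes(attr_field)
            transcript_id = attrs.get("ID", "")
            gene_id = attrs.get("Parent") or attrs.get("gene_id") or transcript_id
            if not gene_id:
                raise ValueError(f"GFF3 feature without ID/Parent in {path}: {line!r}")
            # GFF3 is 1-based inclusive: TSS is `start` on '+', `end` on '-'.
            tss = int(start) if strand == "+" else int(end)
            records.append(
                TssRecord(gene_id, transcript_id or gene_id, chrom, tss, strand)
            )
    return records


def _read_bed(path: Path) -> list[TssRecord]:
    records = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise ValueError(f"BED6 line with <6 fields in {path}: {line!r}")
            chrom, chrom_start, chrom_end, name, _, strand = fields[:6]
            # BED is 0-based half-open: TSS is chromStart+1 on '+', chromEnd on '-'.
            tss = int(chrom_start) + 1 if strand == "+" else int(chrom_end)
            records.append(TssRecord(name, name, chrom, tss, strand))
    return records


def _read_tsv(path: Path) -> list[TssRecord]:
    expected = ["gene_id", "transcript_id", "chrom", "tss", "strand"]
    records = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or [f.strip() for f in reader.fieldnames] != expected:
            raise ValueError(
                f"TSS TSV {path} must have header {expected}, got {reader.fieldnames}"
            )
        for row in reader:
            records.append(
                TssRecord(
                    row["gene_id"],
                    row["transcript_id"],
                    row["chrom"],
                    int(row["tss"]),
                    row["strand"],
                )
            )
    return records


def read_tss_table(
    path: str | Path,
    dialect: str = "tsv",
    feature_type: str = "mRNA",
) -> list[TssRecord]:
    """Read TSS annotations from a GFF3, BED6, or TSV file.

    Parameters
    ----------
    dialect : {"gff3", "bed", "tsv"}
    feature_type : GFF3 feature type whose start/end anchors the TSS
        (ignored for other dialects).
    """
    path = Path(path)
    if dialect == "gff3":
        return _read_gff3(path, feature_type)
    if dialect == "bed":
        return _read_bed(path)
    if dialect == "tsv":
        return _read_tsv(path)
    raise ValueError(f"unknown TSS dialect {dialect!r} (expected gff3, bed, or tsv)")


def extract_promoter(
    genome: Mapping[str, GenomeSequence],
    rec: TssRecord,
    upstream_bp: int = 2000,
    downstream_bp: int = 500,
) -> PromoterWindow:
    """Extract a strand-oriented promoter window around one TSS.

    The window spans ``upstream_bp`` bases before the TSS plus
    ``downstream_bp`` bases starting at the TSS (the TSS base counts as the
    first downstream base), clipped to the contig.  Truncation at contig
    edges shifts ``tss_offset``; the window is never padded.
    """
    if upstream_bp < 0 or downstream_bp < 1:
        raise ValueError("require upstream_bp >= 0 and downstream_bp >= 1")
    if rec.chrom not in genome:
        raise KeyError(f"chromosome {rec.chrom!r} not in the loaded sequence set")
    contig = genome[rec.chrom]
    tss0 = rec.tss - 1  # 0-based position of the TSS base
    if tss0 >= len(contig):
        raise ValueError(
            f"TSS {rec.tss} beyond contig {rec.chrom!r} of length {len(contig)}"
        )
    if rec.strand == "+":
        start, end = tss0 - upstream_bp, tss0 + downstream_bp
    else:
        start, end = tss0 - downstream_bp + 1, tss0 + upstream_bp + 1
    start_c, end_c = max(start, 0), min(end, len(contig))
    if start_c >= end_c:
        raise ValueError(
            f"promoter window for {rec.gene_id} lies entirely off contig {rec.chrom!r}"
        )
    seq = contig.residues[start_c:end_c]
    if rec.strand == "+":
        tss_offset = tss0 - start_c
    else:
        seq = reverse_complement(seq)
        tss_offset = end_c - 1 - tss0
    return PromoterWindow(
        gene_id=rec.gene_id,
        transcript_id=rec.transcript_id,
        chrom=rec.chrom,
        start=start_c,
        end=end_c,
        strand=rec.strand,
        sequence=seq,
        tss_offset=tss_offset,
    )


def write_promoters_fasta(windows: Iterable[PromoterWindow], path: str | Path) -> None:
    """Write promoter windows as FASTA, one record per window."""
    with open(path, "w") as fh:
        for win in windows:
            fh.write(f">{win.header}\n")
            for i in range(0, len(win.sequence), 70):
                fh.write(win.sequence[i : i + 70] + "\n")
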