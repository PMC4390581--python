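"""Degenerate consensus motif compilation, scanning, and in-silico editing.

Motifs are literal IUPAC consensus strings (no PWM scoring).  Scanning
enumerates every occurrence on one or both strands of a subject sequence;
overlapping matches are all reported.  An N in the subject matches nothing
except a motif-side N (conservative rule).
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .sequence_io import PromoterWindow, reverse_complement

__all__ = [
    "MotifDef",
    "MotifHit",
    "CompiledMotif",
    "CRE",
    "ATF4_MEF",
    "BUILTIN_MOTIFS",
    "compile_motif",
    "expansions",
    "scan_sequence",
    "scan_promoters",
    "Substitute",
    "Delete",
    "mutate_sequence",
    "hits_to_tsv",
    "hits_to_bed",
    "motif_map_text",
    "render_motif_map",
]

# IUPAC letter -> set of concrete bases it stands for.
IUPAC_CLASSES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

# Complement within the IUPAC alphabet (N maps to N).
IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


@dataclass(frozen=True)
class MotifDef:
    """A named degenerate consensus motif."""

    name: str
    consensus: str
    source: str = ""

    def __post_init__(self) -> None:
        if not self.consensus:
            raise ValueError("motif consensus must be non-empty")
        for i, letter in enumerate(self.consensus):
            if letter not in IUPAC_CLASSES:
                raise ValueError(
                    f"illegal consensus character {letter!r} at position {i} "
                    f"in motif {self.name!r}"
                )

    def __len__(self) -> int:
        return len(self.consensus)


CRE = MotifDef("CRE", "TGACGT", source="bZIP cyclic AMP response element core")
ATF4_MEF = MotifDef("ATF4_MEF", "TTKCATCAK", source="ChIP-derived Atf4 site, MEFs")
BUILTIN_MOTIFS: dict[str, MotifDef] = {m.name: m for m in (CRE, ATF4_MEF)}


def _letter_regex(letter: str) -> str:
    bases = IUPAC_CLASSES[letter]
    if letter == "N":
        bases += "N"  # motif N matches subject N; concrete letters never do
    return bases if len(bases) == 1 else f"[{bases}]"


class CompiledMotif:
    """A consensus compiled to regexes for overlapping both-strand search."""

    def __init__(self, motif: MotifDef):
        self.motif = motif
        fwd = "".join(_letter_regex(c) for c in motif.consensus)
        rc_consensus = motif.consensus.translate(IUPAC_COMPLEMENT)[::-1]
        rev = "".join(_letter_regex(c) for c in rc_consensus)
        # Lookahead captures make overlapping matches visible to finditer.
        self._fwd = re.compile(f"(?=({fwd}))")
        self._rev = re.compile(f"(?=({rev}))")

    def __len__(self) -> int:
        return len(self.motif)

    def matches(self, window: str) -> bool:
        """Does `window` (same length as the motif) satisfy the consensus?"""
        return len(window) == len(self.motif) and bool(self._fwd.match(window))

    def finditer(self, seq: str, strand: str) -> Iterable[tuple[int, str, str]]:
        pattern = self._fwd if strand == "+" else self._rev
        for m in pattern.finditer(seq):
            yield m.start(), strand, m.group(1)


def compile_motif(consensus: str | MotifDef, name: str | None = None) -> CompiledMotif:
    """Compile an IUPAC consensus (or MotifDef) into a reusable matcher."""
    if isinstance(consensus, MotifDef):
        motif = consensus
    else:
        motif = MotifDef(name or consensus, consensus)
    return CompiledMotif(motif)


def expansions(consensus: str) -> list[str]:
    """All concrete A/C/G/T sequences a degenerate consensus stands for."""
    pools = [IUPAC_CLASSES[c] for c in consensus]
    return ["".join(p) for p in itertools.product(*pools)]


def scan_sequence(
    seq: str,
    motif: MotifDef | CompiledMotif | str,
    strands: str = "both",
) -> list[tuple[int, str, str]]:
    """Enumerate motif occurrences in `seq`.

    Returns ``(offset, strand, matched)`` triples where `offset` is the
    5'-most base of the match in `seq` coordinates for either strand and
    `matched` is the subject window itself (for strand '-', its reverse
    complement satisfies the consensus).  Output is sorted by offset,
    forward strand first at ties.  A motif longer than `seq` yields [].
    """
    if strands not in {"forward", "reverse", "both"}:
        raise ValueError(f"strands must be forward/reverse/both, got {strands!r}")
    compiled = motif if isinstance(motif, CompiledMotif) else compile_motif(motif)
    hits: list[tuple[int, str, str]] = []
    if strands in {"forward", "both"}:
        hits.extend(compiled.finditer(seq, "+"))
    if strands in {"reverse", "both"}:
        hits.extend(compiled.finditer(seq, "-"))
    hits.sort(key=lambda h: (h[0], h[1]))
    return hits


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence in a promoter window, anchored to the TSS.

    ``pos_rel_tss`` locates the 5'-most base of the match in promoter
    orientation (negative = upstream, 0 = the TSS base); ``strand_rel`` is
    relative to promoter orientation.  Genomic fields carry the footprint on
    the forward genomic strand for BED output and deduplication.
    """

    gene_id: str
    transcript_id: str
    motif_name: str
    pos_rel_tss: int
    strand_rel: str
    matched: str
    chrom: str
    genomic_start: int
    genomic_strand: str

    @property
    def genomic_end(self) -> int:
        return self.genomic_start + len(self.matched)


def scan_promoters(
    windows: Sequence[PromoterWindow],
    motifs: Sequence[MotifDef],
    strands: str = "both",
) -> tuple[list[MotifHit], dict[str, bool]]:
    """Scan promoter windows for motifs; summarize site presence per gene.

    Hits shared by overlapping windows of the same gene (multiple TSSs) are
    deduplicated on their genomic footprint.  ``has_site[gene]`` is True iff
    any window of the gene carries at least one hit for at least one motif.
    """
    if not windows:
        raise ValueError("scan_promoters requires at least one promoter window")
    compiled = [compile_motif(m) for m in motifs]
    seen: set[tuple[str, str, str, int, str]] = set()
    hits: list[MotifHit] = []
    has_site: dict[str, bool] = {w.gene_id: False for w in windows}
    for win in windows:
        for cm in compiled:
            length = len(cm)
            for offset, strand_rel, matched in scan_sequence(win.sequence, cm, strands):
                if win.strand == "+":
                    g_start = win.start + offset
                    g_strand = strand_rel
                else:
                    g_start = win.end - offset - length
                    g_strand = "-" if strand_rel == "+" else "+"
                key = (win.gene_id, cm.motif.name, win.chrom, g_start, g_strand)
                if key in seen:
                    continue
                seen.add(key)
                hits.append(
                    MotifHit(
                        gene_id=win.gene_id,
                        transcript_id=win.transcript_id,
                        motif_name=cm.motif.name,
                        pos_rel_tss=offset - win.tss_offset,
                        strand_rel=strand_rel,
                        matched=matched,
                        chrom=win.chrom,
                        genomic_start=g_start,
                        genomic_strand=g_strand,
                    )
                )
                has_site[win.gene_id] = True
    hits.sort(key=lambda h: (h.gene_id, h.pos_rel_tss, h.strand_rel, h.motif_name))
    return hits, has_site


@dataclass(frozen=True)
class Substitute:
    """Replace the base at `position` (0-based) with `new_base`."""

    position: int
    new_base: str


@dataclass(frozen=True)
class Delete:
    """Remove the 0-based half-open interval [start, end)."""

    start: int
    end: int


def mutate_sequence(seq: str, edits: Sequence[Substitute | Delete]) -> str:
    """Apply point substitutions and deletions to a sequence (pure).

    Edit coordinates refer to the input sequence; edits are applied
    right-to-left so earlier coordinates stay valid.  Overlapping deletions
    and out-of-bounds edits are errors.
    """
    deletions = [e for e in edits if isinstance(e, Delete)]
    for e in edits:
        if isinstance(e, Substitute):
            if not (0 <= e.position < len(seq)):
                raise IndexError(f"substitution position {e.position} out of bounds")
            if e.new_base not in "ACGT":
                raise ValueError(f"substitution base must be A/C/G/T, got {e.new_base!r}")
        else:
            if not (0 <= e.start < e.end <= len(seq)):
                raise IndexError(f"deletion [{e.start}, {e.end}) out of bounds")
    deletions.sort(key=lambda d: d.start)
    for left, right in zip(deletions, deletions[1:]):
        if right.start < left.end:
            raise ValueError(
                f"overlapping deletions [{left.start},{left.end}) and "
                f"[{right.start},{right.end})"
            )
    out = seq
    def _key(e: Substitute | Delete) -> int:
        return e.position if isinstance(e, Substitute) else e.start
    for e in sorted(edits, key=_key, reverse=True):
        if isinstance(e, Substitute):
            out = out[: e.position] + e.new_base + out[e.position + 1 :]
        else:
            out = out[: e.start] + out[e.end :]
    return out


def hits_to_tsv(hits: Sequence[MotifHit]) -> str:
    """Render hits as a TSV with TSS-relative positions."""
    lines = [
        "gene_id\ttranscript_id\tmotif\tpos_rel_tss\tstrand_rel\tmatched"
        "\tchrom\tgenomic_start\tgenomic_end\tgenomic_strand"
    ]
    for h in hits:
        lines.append(
            f"{h.gene_id}\t{h.transcript_id}\t{h.motif_name}\t{h.pos_rel_tss}"
            f"\t{h.strand_rel}\t{h.matched}\t{h.chrom}\t{h.genomic_start}"
            f"\t{h.genomic_end}\t{h.genomic_strand}"
        )
    return "\n".join(lines) + "\n"


def hits_to_bed(hits: Sequence[MotifHit]) -> str:
    """Render hits as BED6 (genomic coordinates, forward-strand intervals)."""
    rows = sorted(hits, key=lambda h: (h.chrom, h.genomic_start, h.genomic_strand))
    lines = [
        f"{h.chrom}\t{h.genomic_start}\t{h.genomic_end}"
        f"\t{h.gene_id}|{h.motif_name}\t0\t{h.genomic_strand}"
        for h in rows
    ]
    return "\n".join(lines) + ("\n" if lines else "")


def motif_map_text(
    windows: Sequence[PromoterWindow],
    hits: Sequence[MotifHit],
    width: int = 80,
) -> str:
    """One text row per gene with arrowheads at hit positions.

    CRE-style hits render '>' / '<' by relative strand; other motifs render
    '^' / 'v'.  The TSS base is marked '|'.
    """
    by_gene: dict[str, list[MotifHit]] = {}
    for h in hits:
        by_gene.setdefault(h.gene_id, []).append(h)
    span_lo = min(-w.tss_offset for w in windows)
    span_hi = max(len(w) - w.tss_offset for w in windows)
    scale = (span_hi - span_lo) / max(width - 1, 1)
    lines = []
    name_w = max(len(w.gene_id) for w in windows)
    for win in sorted(windows, key=lambda w: w.gene_id):
        row = ["-"] * width
        row[min(int((0 - span_lo) / scale), width - 1)] = "|"
        for h in by_gene.get(win.gene_id, []):
            col = min(int((h.pos_rel_tss - span_lo) / scale), width - 1)
            if h.motif_name == "CRE":
                row[col] = ">" if h.strand_rel == "+" else "<"
            else:
                row[col] = "^" if h.strand_rel == "+" else "v"
        lines.append(f"{win.gene_id:<{name_w}} {''.join(row)}")
    lines.append(f"{'':<{name_w}} span {span_lo}..{span_hi} rel. TSS ('|')")
    return "\n".join(lines) + "\n"


def render_motif_map(
    windows: Sequence[PromoterWindow],
    hits: Sequence[MotifHit],
    path: str,
) -> None:
    """Plot a per-gene motif map (one row per gene, markers at hits)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    genes = sorted({w.gene_id for w in windows})
    y_of = {g: i for i, g in enumerate(genes)}
    fig, ax = plt.subplots(figsize=(8, 0.35 * len(genes) + 1.5))
    for win in windows:
        lo, hi = -win.tss_offset, len(win) - win.tss_offset
        ax.hlines(y_of[win.gene_id], lo, hi, color="0.8", lw=2)
    ax.axvline(0, color="k", lw=0.8)
    markers = {"+": ">", "-": "<"}
    for h in hits:
        color = "0.4" if h.motif_name == "CRE" else "k"
        ax.plot(
            h.pos_rel_tss,
            y_of[h.gene_id],
            marker=markers.get(h.strand_rel, "o"),
            color=color,
            linestyle="none",
            markersize=7,
        )
    ax.set_yticks(range(len(genes)))
    ax.set_yticklabels(genes)
    ax.set_xlabel("position relative to TSS (bp)")
    ax.invert_yaxis()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
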