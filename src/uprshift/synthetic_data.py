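"""Ground-truth fixture generation: planted motifs, fold changes, Ct tables.

Every generator is a pure function of its parameters and seed.  Promoter
backgrounds are rejection-sampled until free of the forbidden motifs on
both strands, so any site recovered downstream was planted on purpose.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .expression import ExpressionRecord, QpcrMeasurement
from .motif_scan import (
    BUILTIN_MOTIFS,
    MotifDef,
    compile_motif,
    expansions,
    scan_sequence,
)
from .sequence_io import (
    GenomeSequence,
    TssRecord,
    extract_promoter,
    reverse_complement,
)

__all__ = [
    "Placement",
    "GeneTruth",
    "SyntheticTruth",
    "PlantingError",
    "generate_background",
    "plant_motifs",
    "generate_cohort",
    "default_cohort_truth",
    "simulate_expression",
    "simulate_ct",
    "write_fixtures",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class Placement:
    """One planted motif occurrence, in promoter-relative coordinates."""

    motif_name: str
    pos_rel_tss: int
    strand: str


@dataclass(frozen=True)
class GeneTruth:
    gene_id: str
    placements: tuple[Placement, ...]
    true_label: str
    true_fold_change: float


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted design for a cohort: site placements plus regulation truth."""

    genes: tuple[GeneTruth, ...]
    upstream_bp: int = 2000
    downstream_bp: int = 500

    def __iter__(self):
        return iter(self.genes)

    def placements_by_gene(self) -> dict[str, tuple[Placement, ...]]:
        return {g.gene_id: g.placements for g in self.genes}

    def labels(self) -> dict[str, str]:
        return {g.gene_id: g.true_label for g in self.genes}


class PlantingError(RuntimeError):
    """Planting produced spurious junction hits or destroyed a planted one."""


def generate_background(
    n_genes: int,
    upstream_bp: int = 2000,
    downstream_bp: int = 500,
    gc_fraction: float = 0.5,
    forbidden: Sequence[MotifDef] = (BUILTIN_MOTIFS["CRE"], BUILTIN_MOTIFS["ATF4_MEF"]),
    seed: int = 0,
    pad: int = 25,
    max_attempts: int = 1000,
) -> tuple[dict[str, GenomeSequence], list[TssRecord]]:
    """Motif-free promoter backgrounds: one contig and one TSS per gene.

    Bases are i.i.d. with P(G) = P(C) = gc_fraction/2; any contig whose
    promoter window contains a forbidden motif on either strand is
    resampled.  Genes alternate between the two strands.
    """
    if not 0.0 < gc_fraction < 1.0:
        raise ValueError("gc_fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    probs = np.array(
        [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    )
    compiled = [compile_motif(m) for m in forbidden]
    contig_len = pad + upstream_bp + downstream_bp + pad
    genome: dict[str, GenomeSequence] = {}
    tss_records: list[TssRecord] = []
    for i in range(n_genes):
        gene_id = f"g{i + 1:03d}"
        chrom = f"contig_{gene_id}"
        strand = "+" if i % 2 == 0 else "-"
        tss0 = pad + upstream_bp if strand == "+" else pad + downstream_bp - 1
        rec = TssRecord(gene_id, gene_id, chrom, tss0 + 1, strand)
        for _ in range(max_attempts):
            seq = "".join(rng.choice(_BASES, size=contig_len, p=probs))
            contig = GenomeSequence(chrom, seq)
            window = extract_promoter({chrom: contig}, rec, upstream_bp, downstream_bp)
            if not any(scan_sequence(window.sequence, cm, "both") for cm in compiled):
                break
        else:
            raise RuntimeError(
                f"could not sample a motif-free background for {gene_id} in "
                f"{max_attempts} attempts; try shorter windows or fewer "
                "forbidden motifs"
            )
        genome[chrom] = contig
        tss_records.append(rec)
    return genome, tss_records


def _write_slice(residues: str, start: int, content: str) -> str:
    return residues[:start] + content + residues[start + len(content):]


def plant_motifs(
    genome: Mapping[str, GenomeSequence],
    tss_records: Sequence[TssRecord],
    placements: Mapping[str, Sequence[Placement]],
    seed: int = 0,
    motif_defs: Mapping[str, MotifDef] | None = None,
    upstream_bp: int = 2000,
    downstream_bp: int = 500,
) -> dict[str, GenomeSequence]:
    """Write motif instances into promoter windows at known positions.

    Degenerate letters are resolved uniformly at random (seeded); planting
    on promoter strand '-' writes the reverse complement onto the promoter
    orientation.  After planting, every window is rescanned and must yield
    exactly the planted (position, strand, motif) set — anything else
    raises :class:`PlantingError`.
    """
    motif_defs = dict(motif_defs or BUILTIN_MOTIFS)
    rng = np.random.default_rng(seed)
    by_gene = {rec.gene_id: rec for rec in tss_records}
    edited = dict(genome)
    for gene_id in sorted(placements):
        gene_placements = list(placements[gene_id])
        if not gene_placements:
            continue
        if gene_id not in by_gene:
            raise KeyError(f"gene {gene_id!r} has no TSS record")
        rec = by_gene[gene_id]
        window = extract_promoter(edited, rec, upstream_bp, downstream_bp)
        spans = []
        for p in gene_placements:
            motif = motif_defs[p.motif_name]
            offset = window.tss_offset + p.pos_rel_tss
            if offset < 0 or offset + len(motif) > len(window):
                raise ValueError(
                    f"placement {p} falls outside the promoter window of {gene_id}"
                )
            spans.append((offset, offset + len(motif), p, motif))
        spans.sort()
        for (s1, e1, *_), (s2, _, *_) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping placements in gene {gene_id}")
        contig = edited[rec.chrom]
        residues = contig.residues
        for offset, _, p, motif in spans:
            options = expansions(motif.consensus)
            concrete = options[int(rng.integers(len(options)))]
            oriented = concrete if p.strand == "+" else reverse_complement(concrete)
            if rec.strand == "+":
                g_start = window.start + offset
                forward = oriented
            else:
                g_start = window.end - offset - len(motif)
                forward = reverse_complement(oriented)
            residues = _write_slice(residues, g_start, forward)
        edited[rec.chrom] = GenomeSequence(rec.chrom, residues)
    _verify_planting(edited, tss_records, placements, motif_defs, upstream_bp, downstream_bp)
    return edited


def _verify_planting(
    genome: Mapping[str, GenomeSequence],
    tss_records: Sequence[TssRecord],
    placements: Mapping[str, Sequence[Placement]],
    motif_defs: Mapping[str, MotifDef],
    upstream_bp: int,
    downstream_bp: int,
) -> None:
    compiled = {name: compile_motif(m) for name, m in motif_defs.items()}
    for rec in tss_records:
        window = extract_promoter(genome, rec, upstream_bp, downstream_bp)
        found = {
            (name, offset - window.tss_offset, strand)
            for name, cm in compiled.items()
            for offset, strand, _ in scan_sequence(window.sequence, cm, "both")
        }
        expected = {
            (p.motif_name, p.pos_rel_tss, p.strand)
            for p in placements.get(rec.gene_id, ())
        }
        if found != expected:
            raise PlantingError(
                f"gene {rec.gene_id}: planted {sorted(expected)} but scan "
                f"recovered {sorted(found)}"
            )


def default_cohort_truth(
    upstream_bp: int = 2000, downstream_bp: int = 500
) -> SyntheticTruth:
    """The default 11-gene cohort: 7 up (6 with sites), 4 unchanged (1 with).

    Mirrors the 2x2 design (a,b,c,d) = (6,1,1,3) with sites spread across
    both motifs, both strands, and upstream/downstream positions.
    """
    up = 4.0
    genes = [
        GeneTruth("g001", (Placement("CRE", -1500, "+"),), "up", up),
        GeneTruth("g002", (Placement("CRE", -300, "-"),), "up", up),
        GeneTruth("g003", (Placement("ATF4_MEF", -800, "+"),), "up", up),
        GeneTruth("g004", (Placement("ATF4_MEF", -120, "-"),), "up", up),
        GeneTruth(
            "g005",
            (Placement("CRE", -1800, "+"), Placement("ATF4_MEF", 100, "+")),
            "up",
            up,
        ),
        GeneTruth("g006", (Placement("CRE", 250, "-"),), "up", up),
        GeneTruth("g007", (), "up", up),
        GeneTruth("g008", (Placement("CRE", -600, "+"),), "unchanged", 1.0),
        GeneTruth("g009", (), "unchanged", 1.0),
        GeneTruth("g010", (), "unchanged", 1.0),
        GeneTruth("g011", (), "unchanged", 1.0),
    ]
    return SyntheticTruth(tuple(genes), upstream_bp, downstream_bp)


def generate_cohort(
    truth: SyntheticTruth | None = None,
    gc_fraction: float = 0.45,
    seed: int = 0,
    max_retries: int = 20,
) -> tuple[dict[str, GenomeSequence], list[TssRecord], SyntheticTruth]:
    """Background + planting in one step, retrying on rare junction artifacts."""
    truth = truth or default_cohort_truth()
    placements = truth.placements_by_gene()
    for retry in range(max_retries):
        genome, tss_records = generate_background(
            n_genes=len(truth.genes),
            upstream_bp=truth.upstream_bp,
            downstream_bp=truth.downstream_bp,
            gc_fraction=gc_fraction,
            seed=seed + 7919 * retry,
        )
        try:
            planted = plant_motifs(
                genome,
                tss_records,
                placements,
                seed=seed + 7919 * retry,
                upstream_bp=truth.upstream_bp,
                downstream_bp=truth.downstream_bp,
            )
        except PlantingError:
            continue
        return planted, tss_records, truth
    raise RuntimeError(f"cohort generation failed after {max_retries} retries")


def simulate_expression(
    truth: SyntheticTruth,
    base_level: float = 100.0,
    noise_sd_log2: float = 0.0,
    seed: int = 0,
) -> list[ExpressionRecord]:
    """Expression table with planted fold changes and log2-normal noise.

    control = base * 2^e1, stress = base * fold_change * 2^e2 with
    independent e ~ Normal(0, noise_sd_log2).
    """
    if noise_sd_log2 < 0:
        raise ValueError("noise_sd_log2 must be >= 0")
    rng = np.random.default_rng(seed)
    n = len(truth.genes)
    eps = (
        rng.normal(0.0, noise_sd_log2, size=(n, 2))
        if noise_sd_log2 > 0
        else np.zeros((n, 2))
    )
    records = []
    for g, (e1, e2) in zip(truth.genes, eps):
        records.append(
            ExpressionRecord(
                g.gene_id,
                float(base_level * 2.0 ** e1),
                float(base_level * g.true_fold_change * 2.0 ** e2),
            )
        )
    return records


def simulate_ct(
    levels: Mapping[tuple[str, str], float],
    reference_gene: str = "RpL19",
    efficiency: float = 2.0,
    ct_ref_base: float = 18.0,
    n_replicates: int = 3,
    ct_noise_sd: float = 0.0,
    seed: int = 0,
) -> list[QpcrMeasurement]:
    """Ct table consistent with reference-gene normalization.

    ``levels`` maps (gene_id, condition) to the true relative level; each
    target replicate gets Ct = ct_ref_base - log_eff(level) + eta and the
    reference gene gets Ct = ct_ref_base + eta, eta ~ Normal(0, ct_noise_sd).
    """
    rng = np.random.default_rng(seed)
    log_eff = np.log(efficiency)

    def _noise() -> float:
        return float(rng.normal(0.0, ct_noise_sd)) if ct_noise_sd > 0 else 0.0

    out: list[QpcrMeasurement] = []
    conditions = sorted({cond for _, cond in levels})
    for cond in conditions:
        for rep in range(1, n_replicates + 1):
            out.append(
                QpcrMeasurement(reference_gene, cond, f"r{rep}", ct_ref_base + _noise())
            )
    for (gene, cond) in sorted(levels):
        level = levels[(gene, cond)]
        if level <= 0:
            raise ValueError(f"level must be > 0 for {(gene, cond)}")
        if efficiency == 2.0:
            ct_true = ct_ref_base - float(np.log2(level))
        else:
            ct_true = ct_ref_base - float(np.log(level) / log_eff)
        for rep in range(1, n_replicates + 1):
            out.append(QpcrMeasurement(gene, cond, f"r{rep}", ct_true + _noise()))
    return out


def write_fixtures(
    outdir: str | Path,
    seed: int = 0,
    truth: SyntheticTruth | None = None,
    noise_sd_log2: float = 0.0,
) -> dict[str, Path]:
    """Materialize a full fixture set (FASTA, TSS, expression, Ct, truth).

    Returns the mapping of fixture role to written path; the truth YAML
    records placements, labels, and the generating seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, tss_records, truth = generate_cohort(truth, seed=seed)
    paths = {
        "fasta": outdir / "promoters.fa",
        "tss": outdir / "tss.tsv",
        "expression": outdir / "expression.tsv",
        "qpcr": outdir / "qpcr.tsv",
        "truth": outdir / "truth.yaml",
    }
    with open(paths["fasta"], "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom].residues
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    with open(paths["tss"], "w") as fh:
        fh.write("gene_id\ttranscript_id\tchrom\ttss\tstrand\n")
        for rec in tss_records:
            fh.write(f"{rec.gene_id}\t{rec.transcript_id}\t{rec.chrom}\t{rec.tss}\t{rec.strand}\n")
    with open(paths["expression"], "w") as fh:
        fh.write("gene_id\tcontrol\tstress\n")
        for rec in simulate_expression(truth, noise_sd_log2=noise_sd_log2, seed=seed):
            fh.write(f"{rec.gene_id}\t{rec.control_level!r}\t{rec.stress_level!r}\n")
    levels = {
        (g.gene_id, "control"): 1.0 for g in truth.genes
    } | {
        (g.gene_id, "stress"): g.true_fold_change for g in truth.genes
    }
    with open(paths["qpcr"], "w") as fh:
        fh.write("gene_id\tcondition\treplicate\tct\n")
        for m in simulate_ct(levels, seed=seed):
            fh.write(f"{m.gene_id}\t{m.condition}\t{m.replicate_id}\t{m.ct!r}\n")
    truth_doc = {
        "seed": seed,
        "upstream_bp": truth.upstream_bp,
        "downstream_bp": truth.downstream_bp,
        "genes": [
            {
                "gene_id": g.gene_id,
                "true_label": g.true_label,
                "true_fold_change": g.true_fold_change,
                "placements": [
                    {
                        "motif_name": p.motif_name,
                        "pos_rel_tss": p.pos_rel_tss,
                        "strand": p.strand,
                    }
                    for p in g.placements
                ],
            }
            for g in truth.genes
        ],
    }
    with open(paths["truth"], "w") as fh:
        yaml.safe_dump(truth_doc, fh, sort_keys=False)
    return paths
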