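"""End-to-end orchestration: classify, scan, associate, report.

A run is a pure function of (inputs, config): every output file is written
deterministically (sorted rows, no timestamps) and a manifest records the
config, seed, library versions, and SHA-256 checksums of inputs and
outputs so a run can be reproduced and verified.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .association import analyze_association, contingency_report
from .expression import (
    classify_regulation,
    qpcr_relative,
    read_expression_table,
    read_qpcr_table,
)
from .motif_scan import (
    BUILTIN_MOTIFS,
    MotifDef,
    hits_to_bed,
    hits_to_tsv,
    motif_map_text,
    render_motif_map,
    scan_promoters,
)
from .sequence_io import extract_promoter, read_fasta, read_tss_table

logger = logging.getLogger("uprshift")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Run configuration; defaults match the published analysis parameters
    (-2000/+500 bp windows, 2-fold up / 1.5-fold down thresholds, CRE and
    ATF4_MEF motifs, both strands)."""

    fasta: str = ""
    tss: str = ""
    expression: str = ""
    qpcr: str | None = None
    tss_dialect: str = "tsv"
    feature_type: str = "mRNA"
    upstream_bp: int = 2000
    downstream_bp: int = 500
    motifs: list[dict[str, str]] = field(
        default_factory=lambda: [
            {"name": m.name, "consensus": m.consensus, "source": m.source}
            for m in BUILTIN_MOTIFS.values()
        ]
    )
    up_threshold: float = 2.0
    down_threshold: float = 1.5
    strands: str = "both"
    seed: int = 0
    outdir: str = "results"
    reference_gene: str = "RpL19"
    calibrate_to: str | None = "control"
    render_figure: bool = False

    def motif_defs(self) -> list[MotifDef]:
        return [
            MotifDef(m["name"], m["consensus"], m.get("source", "")) for m in self.motifs
        ]

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class PipelineResult:
    contingency: Any
    calls: list
    hits: list
    has_site: dict[str, bool]
    outputs: dict[str, Path]
    excluded_genes: list[str]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage and write the report bundle to ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    def _stage(name: str):
        logger.info("stage: %s", name)

    _stage("load inputs")
    genome = read_fasta(config.fasta)
    tss_records = read_tss_table(config.tss, config.tss_dialect, config.feature_type)
    expression = read_expression_table(config.expression)

    _stage("classify regulation")
    calls = [
        classify_regulation(rec, config.up_threshold, config.down_threshold)
        for rec in sorted(expression, key=lambda r: r.gene_id)
    ]
    annotated = {rec.gene_id for rec in tss_records}
    excluded = sorted({c.gene_id for c in calls} - annotated)
    if excluded:
        logger.warning(
            "genes with expression but no annotated TSS (excluded from the "
            "association table): %s",
            ", ".join(excluded),
        )
    calls_kept = [c for c in calls if c.gene_id in annotated]

    _stage("extract promoters and scan motifs")
    windows = [
        extract_promoter(genome, rec, config.upstream_bp, config.downstream_bp)
        for rec in sorted(tss_records, key=lambda r: (r.gene_id, r.transcript_id))
    ]
    hits, has_site = scan_promoters(windows, config.motif_defs(), config.strands)

    _stage("association")
    contingency = analyze_association(calls_kept, has_site)

    _stage("write outputs")
    outputs["regulation"] = outdir / "regulation_calls.tsv"
    with open(outputs["regulation"], "w") as fh:
        fh.write("gene_id\tfold_change\tlabel\tup_threshold\tdown_threshold\n")
        for c in calls:
            fh.write(
                f"{c.gene_id}\t{c.fold_change:.6g}\t{c.label}"
                f"\t{c.up_threshold}\t{c.down_threshold}\n"
            )
    outputs["hits_tsv"] = outdir / "motif_hits.tsv"
    outputs["hits_tsv"].write_text(hits_to_tsv(hits))
    outputs["hits_bed"] = outdir / "motif_hits.bed"
    outputs["hits_bed"].write_text(hits_to_bed(hits))
    outputs["motif_map"] = outdir / "motif_map.txt"
    outputs["motif_map"].write_text(motif_map_text(windows, hits))
    outputs["sites"] = outdir / "site_presence.tsv"
    with open(outputs["sites"], "w") as fh:
        fh.write("gene_id\thas_site\n")
        for gene in sorted(has_site):
            fh.write(f"{gene}\t{str(has_site[gene]).lower()}\n")
    outputs["contingency"] = outdir / "contingency.tsv"
    with open(outputs["contingency"], "w") as fh:
        fh.write("a\tb\tc\td\todds_ratio\tp_two_sided\tmethod\n")
        fh.write(
            f"{contingency.a}\t{contingency.b}\t{contingency.c}\t{contingency.d}"
            f"\t{contingency.odds_ratio:.6g}\t{contingency.p_two_sided:.10g}"
            f"\t{contingency.method}\n"
        )
    report = contingency_report(contingency)
    if excluded:
        report += "excluded (no TSS annotation): " + ", ".join(excluded) + "\n"
    outputs["report"] = outdir / "report.txt"
    outputs["report"].write_text(report)

    if config.qpcr:
        _stage("qPCR summary")
        measurements = read_qpcr_table(config.qpcr)
        reference = [m for m in measurements if m.gene_id == config.reference_gene]
        if not reference:
            raise ValueError(
                f"reference gene {config.reference_gene!r} absent from {config.qpcr}"
            )
        outputs["qpcr"] = outdir / "qpcr_summary.tsv"
        with open(outputs["qpcr"], "w") as fh:
            fh.write("gene_id\tcondition\tmean_level\tdispersion\tn_replicates\tflags\n")
            targets = sorted(
                {m.gene_id for m in measurements} - {config.reference_gene}
            )
            for gene in targets:
                rows = [m for m in measurements if m.gene_id == gene]
                rel = qpcr_relative(
                    rows, reference, calibrate_to=config.calibrate_to
                )
                for cond in sorted(rel):
                    r = rel[cond]
                    fh.write(
                        f"{r.gene_id}\t{r.condition}\t{r.mean_level:.10g}"
                        f"\t{r.dispersion:.10g}\t{r.n_replicates}"
                        f"\t{','.join(r.flags)}\n"
                    )

    if config.render_figure:
        outputs["figure"] = outdir / "motif_map.png"
        render_motif_map(windows, hits, str(outputs["figure"]))

    _stage("manifest")
    manifest = {
        "package": {"name": "uprshift", "version": __version__},
        "versions": _library_versions(),
        "config": config.to_dict(),
        "seed": config.seed,
        "inputs": {
            key: {"path": str(p), "sha256": _sha256(Path(p))}
            for key, p in (
                ("fasta", config.fasta),
                ("tss", config.tss),
                ("expression", config.expression),
                ("qpcr", config.qpcr),
            )
            if p
        },
        "outputs": {
            key: {"path": str(p), "sha256": _sha256(p)}
            for key, p in sorted(outputs.items())
            if p.suffix != ".png"
        },
        "excluded_genes": excluded,
    }
    outputs["manifest"] = outdir / "manifest.json"
    outputs["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    return PipelineResult(
        contingency=contingency,
        calls=calls,
        hits=hits,
        has_site=has_site,
        outputs=outputs,
        excluded_genes=excluded,
    )


def _library_versions() -> dict[str, str]:
    import numpy
    import pandas
    import scipy

    return {
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
    }
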