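# uprshift

Analysis pipeline for an ER-stress regulatory question: do promoters of
up-regulated metabolic genes carry Atf4-class binding motifs?  The package

- classifies genes as **up / down / unchanged** from control-vs-stress
  expression ratios (inclusive thresholds, defaults 2-fold up, 1.5-fold
  down),
- extracts strand-aware **promoter windows** (default 2 kb upstream + 0.5 kb
  downstream of each annotated TSS, the TSS base counting as the first
  downstream base) from FASTA + GFF3/BED6/TSV annotations,
- scans windows on **both strands** for degenerate IUPAC consensus motifs
  (built-ins: CRE `TGACGT` and ATF4_MEF `TTKCATCAK`), reporting every
  overlapping occurrence relative to the TSS,
- quantifies motif/up-regulation concordance as a 2×2 table with an exact
  two-sided Fisher test (probability-ordering rule, exact rational
  enumeration),
- supports **in-silico promoter mutagenesis** (point substitutions,
  deletions) with rescanning, mirroring reporter-construct experiments,
- computes **qPCR relative expression** (efficiency^(ΔCt), reference-gene
  normalized, geometric-mean summary with log-scale SE) and paired t-tests,
- ships a **synthetic-data generator**: motif-free rejection-sampled
  promoter backgrounds with motifs planted at known positions/strands,
  expression tables with planted fold-change classes and log2-normal noise,
  and Ct tables consistent with the qPCR model — so every stage is testable
  with known ground truth and no downloads.

## CLI

```sh
# generate a ground-truth fixture set (FASTA, TSS, expression, Ct, truth YAML)
uprshift make-fixtures --outdir fixtures --seed 11

# full pipeline from a YAML config
uprshift run --config config.yaml [--seed N] [--outdir DIR] [--figure]

# individual stages
uprshift scan --fasta F.fa --tss T.tsv --dialect tsv \
              --upstream 2000 --downstream 500 --strands both [--bed hits.bed]
uprshift classify --expression expr.tsv
uprshift qpcr --table ct.tsv --reference-gene RpL19 --calibrate-to control
uprshift associate --calls calls.tsv --sites sites.tsv
```

A minimal `config.yaml`:

```yaml
fasta: fixtures/promoters.fa
tss: fixtures/tss.tsv
expression: fixtures/expression.tsv
qpcr: fixtures/qpcr.tsv      # optional
outdir: results
seed: 11
```

`uprshift run` writes a deterministic report bundle: regulation-call TSV,
motif hits as TSV + BED6, a text motif map (PNG with `--figure`), the
contingency block, an optional qPCR summary, and a `manifest.json` with
config, seed, library versions, and SHA-256 checksums of all inputs and
outputs (re-running from the manifest reproduces the checksums).

## Layout

| module | contents |
|---|---|
| `uprshift.sequence_io` | FASTA / GFF3 / BED6 / TSV input, promoter extraction |
| `uprshift.motif_scan` | IUPAC motif compilation, both-strand scanning, mutagenesis |
| `uprshift.expression` | fold-change classification, qPCR ΔCt math, paired t-test |
| `uprshift.association` | 2×2 contingency + exact Fisher test |
| `uprshift.synthetic_data` | ground-truth generators and fixture writer |
| `uprshift.pipeline` / `uprshift.cli` | orchestration, manifest, CLI |
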