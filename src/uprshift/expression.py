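"""Fold-change classification and qPCR relative quantification.

Expression tables carry one control and one stress level per gene; genes
are labeled up / down / unchanged against inclusive fold-change thresholds.
qPCR Ct tables are reduced to reference-normalized relative levels
(efficiency^(Ct_ref - Ct_target)) summarized on the log scale, with a
paired t-test for condition contrasts.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ExpressionRecord",
    "RegulationCall",
    "QpcrMeasurement",
    "RelativeExpression",
    "read_expression_table",
    "read_qpcr_table",
    "classify_regulation",
    "qpcr_relative",
    "TTestResult",
    "paired_t_test",
    "benjamini_hochberg",
]


@dataclass(frozen=True)
class ExpressionRecord:
    """One gene's expression level under control and stress (same units)."""

    gene_id: str
    control_level: float
    stress_level: float

    def __post_init__(self) -> None:
        if self.control_level <= 0 or self.stress_level <= 0:
            raise ValueError(
                f"expression levels must be > 0 for {self.gene_id}: "
                f"control={self.control_level}, stress={self.stress_level}"
            )


@dataclass(frozen=True)
class RegulationCall:
    """A gene's fold change and its regulation label, with the thresholds used."""

    gene_id: str
    fold_change: float
    label: str
    up_threshold: float
    down_threshold: float


@dataclass(frozen=True)
class QpcrMeasurement:
    gene_id: str
    condition: str
    replicate_id: str
    ct: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.ct):
            raise ValueError(f"non-finite Ct for {self.gene_id}/{self.condition}")


@dataclass(frozen=True)
class RelativeExpression:
    """Reference-normalized expression level with replicate dispersion.

    ``mean_level`` is the geometric mean over replicates; ``dispersion`` is
    the SE of the log-levels propagated to the linear scale.
    """

    gene_id: str
    condition: str
    mean_level: float
    dispersion: float
    n_replicates: int
    flags: tuple[str, ...] = field(default=())


def read_expression_table(path: str | Path) -> list[ExpressionRecord]:
    """Read a TSV with header gene_id, control, stress."""
    expected = ["gene_id", "control", "stress"]
    records = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or [f.strip() for f in reader.fieldnames] != expected:
            raise ValueError(
                f"expression table {path} must have header {expected}, "
                f"got {reader.fieldnames}"
            )
        for row in reader:
            records.append(
                ExpressionRecord(
                    row["gene_id"], float(row["control"]), float(row["stress"])
                )
            )
    return records


def read_qpcr_table(path: str | Path) -> list[QpcrMeasurement]:
    """Read a TSV with header gene_id, condition, replicate, ct."""
    expected = ["gene_id", "condition", "replicate", "ct"]
    out = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or [f.strip() for f in reader.fieldnames] != expected:
            raise ValueError(
                f"qPCR table {path} must have header {expected}, got {reader.fieldnames}"
            )
        for row in reader:
            out.append(
                QpcrMeasurement(
                    row["gene_id"], row["condition"], row["replicate"], float(row["ct"])
                )
            )
    return out


def classify_regulation(
    record: ExpressionRecord,
    up_threshold: float = 2.0,
    down_threshold: float = 1.5,
) -> RegulationCall:
    """Label a gene up / down / unchanged from its stress/control ratio.

    Thresholds are inclusive: fold change >= up_threshold is "up", fold
    change <= 1/down_threshold is "down", anything between is "unchanged".
    """
    if up_threshold <= 1 or down_threshold <= 1:
        raise ValueError("thresholds must exceed 1")
    fc = record.stress_level / record.control_level
    if fc >= up_threshold:
        label = "up"
    elif fc <= 1.0 / down_threshold:
        label = "down"
    else:
        label = "unchanged"
    return RegulationCall(record.gene_id, fc, label, up_threshold, down_threshold)


def _delta_cts(
    target: Sequence[QpcrMeasurement],
    reference: Sequence[QpcrMeasurement],
    condition: str,
) -> np.ndarray:
    """Per-replicate (Ct_ref - Ct_target) for one condition.

    Replicates are paired by replicate_id when the id sets match; otherwise
    every target replicate is normalized by the reference mean Ct.
    """
    t = {m.replicate_id: m.ct for m in target if m.condition == condition}
    r = {m.replicate_id: m.ct for m in reference if m.condition == condition}
    if not t:
        raise ValueError(f"no target measurements for condition {condition!r}")
    if not r:
        raise ValueError(f"reference gene has no measurements for condition {condition!r}")
    if set(t) == set(r):
        return np.array([r[k] - t[k] for k in sorted(t)])
    ref_mean = float(np.mean(list(r.values())))
    return np.array([ref_mean - t[k] for k in sorted(t)])


def qpcr_relative(
    target: Sequence[QpcrMeasurement],
    reference: Sequence[QpcrMeasurement],
    efficiency: float = 2.0,
    calibrate_to: str | None = None,
) -> dict[str, RelativeExpression]:
    """Reference-normalized relative expression per condition.

    Per replicate pair, level = efficiency^(Ct_ref - Ct_target); replicate
    levels are summarized by their geometric mean, with dispersion the SE of
    the log-levels mapped back to the linear scale.  With ``calibrate_to``
    set, every condition is scaled so that condition's mean is 1.
    """
    if not 1.0 < efficiency <= 2.0:
        raise ValueError(f"efficiency must be in (1, 2], got {efficiency}")
    conditions = sorted({m.condition for m in target})
    if not conditions:
        raise ValueError("no target measurements supplied")
    gene_id = target[0].gene_id
    log_eff = math.log(efficiency)
    out: dict[str, RelativeExpression] = {}
    for cond in conditions:
        dcts = _delta_cts(target, reference, cond)
        log_levels = dcts * log_eff
        # efficiency**mean(dCt) rather than exp(mean(log)) keeps zero-noise
        # round trips through the Ct simulator bit-exact.
        mean_level = float(efficiency ** np.mean(dcts))
        flags: tuple[str, ...] = ()
        if len(dcts) == 1:
            se_log, flags = 0.0, ("single_replicate",)
        else:
            se_log = float(np.std(log_levels, ddof=1) / math.sqrt(len(dcts)))
        out[cond] = RelativeExpression(
            gene_id, cond, mean_level, mean_level * se_log, len(dcts), flags
        )
    if calibrate_to is not None:
        if calibrate_to not in out:
            raise ValueError(
                f"calibration condition {calibrate_to!r} absent from {conditions}"
            )
        scale = out[calibrate_to].mean_level
        out = {
            cond: RelativeExpression(
                r.gene_id,
                cond,
                r.mean_level / scale,
                r.dispersion / scale,
                r.n_replicates,
                r.flags,
            )
            for cond, r in out.items()
        }
    return out


class TTestResult(NamedTuple):
    t: float
    p: float
    df: int
    degenerate: bool = False


def paired_t_test(x: Sequence[float], y: Sequence[float]) -> TTestResult:
    """Two-sided paired t-test, t = mean(d) / (sd(d)/sqrt(n)) with d = x - y.

    Zero-variance differences are flagged degenerate: p = 1 when the mean
    difference is also zero, p = 0 (t = +/-inf) otherwise.
    """
    if len(x) != len(y):
        raise ValueError("paired samples must have equal length")
    n = len(x)
    if n < 2:
        raise ValueError("paired t-test requires at least 2 pairs")
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    df = n - 1
    if sd == 0.0:
        if mean == 0.0:
            return TTestResult(0.0, 1.0, df, degenerate=True)
        return TTestResult(math.copysign(math.inf, mean), 0.0, df, degenerate=True)
    t = mean / (sd / math.sqrt(n))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return TTestResult(t, p, df)


def benjamini_hochberg(pvalues: Sequence[float]) -> list[float]:
    """BH-adjusted p-values (optional; not applied by default)."""
    p = np.asarray(pvalues, dtype=float)
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj.tolist()
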