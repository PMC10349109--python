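"""Expression-evidence gating and small quantification formulas.

A candidate gene surviving the variant triage must also be credibly
expressed in the control tissue before it is pursued: a variant in a gene
the tissue barely transcribes is unlikely to drive the phenotype there.
Expression is measured in RPKM (reads per kilobase of transcript per
million mapped reads) and bucketed into credibility bins:

====================  =================
RPKM < 1              not credible
1 <= RPKM < 10        background level
10 <= RPKM < 100      middle level
RPKM >= 100           high level
====================  =================

The published bin edges leave RPKM exactly 1 and exactly 10 unassigned;
half-open intervals closed on the left are adopted here. The "high" bin
is added so the function is total on [0, inf).

Two small companion formulas are included because the surrounding study
design uses them: relative qPCR quantification by 2^-ddCt, and the
ellipsoid xenograft tumor-volume approximation 0.5 * L * S^2.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionBin",
    "ExpressionRecord",
    "GateResult",
    "compute_rpkm",
    "bin_rpkm",
    "percent_change",
    "ddct_relative_expression",
    "tumor_volume",
    "expression_gate",
]


class ExpressionBin(enum.IntEnum):
    """Credibility bins, ordered so comparisons mean 'at least as expressed'."""

    NOT_CREDIBLE = 0
    BACKGROUND = 1
    MIDDLE = 2
    HIGH = 3

    def __str__(self) -> str:
        return self.name.lower()


def compute_rpkm(read_count: int, gene_length_bp: int, total_mapped_reads: int) -> float:
    """RPKM = reads * 1e9 / (gene length in bp * library size)."""
    if gene_length_bp <= 0:
        raise ValueError(f"gene_length_bp must be positive, got {gene_length_bp}")
    if total_mapped_reads <= 0:
        raise ValueError(f"total_mapped_reads must be positive, got {total_mapped_reads}")
    if read_count < 0:
        raise ValueError(f"read_count must be non-negative, got {read_count}")
    return read_count * 1e9 / (gene_length_bp * total_mapped_reads)


@dataclass(frozen=True)
class ExpressionRecord:
    """Gene x sample expression measurement; RPKM derived from the counts."""

    gene: str
    sample_id: str
    read_count: int
    gene_length_bp: int
    total_mapped_reads: int

    @property
    def rpkm(self) -> float:
        return compute_rpkm(self.read_count, self.gene_length_bp, self.total_mapped_reads)

    @property
    def bin(self) -> ExpressionBin:
        return bin_rpkm(self.rpkm)


def bin_rpkm(rpkm: float) -> ExpressionBin:
    if rpkm < 0:
        raise ValueError(f"RPKM must be non-negative, got {rpkm}")
    if rpkm < 1:
        return ExpressionBin.NOT_CREDIBLE
    if rpkm < 10:
        return ExpressionBin.BACKGROUND
    if rpkm < 100:
        return ExpressionBin.MIDDLE
    return ExpressionBin.HIGH


def percent_change(case_value: float, control_value: float) -> float:
    """Signed percent change of case relative to control (-66 = 66% decrease)."""
    if control_value <= 0:
        raise ValueError(f"control_value must be positive, got {control_value}")
    return (case_value - control_value) / control_value * 100.0


def ddct_relative_expression(
    ct_target_case: float,
    ct_ref_case: float,
    ct_target_control: float,
    ct_ref_control: float,
) -> float:
    """Relative expression by the 2^-ddCt method.

    ddCt = (Ct_target - Ct_reference) in the case sample minus the same
    difference in the control sample; the returned fold change is 2**-ddCt.
    """
    for ct in (ct_target_case, ct_ref_case, ct_target_control, ct_ref_control):
        if not np.isfinite(ct):
            raise ValueError("Ct values must be finite")
    ddct = (ct_target_case - ct_ref_case) - (ct_target_control - ct_ref_control)
    return float(2.0 ** (-ddct))


def tumor_volume(long_diameter_mm: float, short_diameter_mm: float) -> float:
    """Xenograft tumor volume in mm^3: 0.5 * long * short^2."""
    if short_diameter_mm <= 0:
        raise ValueError("diameters must be positive")
    if short_diameter_mm > long_diameter_mm:
        raise ValueError(
            f"short diameter ({short_diameter_mm}) exceeds long diameter "
            f"({long_diameter_mm}); arguments are probably swapped"
        )
    return 0.5 * long_diameter_mm * short_diameter_mm * short_diameter_mm


@dataclass(frozen=True)
class GateResult:
    gene: str
    mean_case_rpkm: float
    mean_control_rpkm: float
    percent_change: float
    control_bin: ExpressionBin
    keep: bool


def _mean_rpkm(
    records: Sequence[ExpressionRecord], aggregate: str
) -> float:
    values = np.array([r.rpkm for r in records], dtype=float)
    if aggregate == "mean":
        return float(values.mean())
    if aggregate == "median":
        return float(np.median(values))
    raise ValueError(f"unknown aggregate {aggregate!r}; expected mean or median")


def expression_gate(
    candidate_genes: Sequence[str],
    expression_table: Sequence[ExpressionRecord],
    case_samples: Sequence[str],
    control_samples: Sequence[str],
    min_bin: ExpressionBin = ExpressionBin.MIDDLE,
    aggregate: str = "mean",
) -> list[GateResult]:
    """Keep candidate genes credibly expressed in the control samples.

    A gene is kept when the bin of its aggregated control RPKM is at least
    ``min_bin`` (default: middle, i.e. background-level expression is
    excluded). The percent change of the aggregated case RPKM relative to
    control is reported alongside, matching the study pattern of retaining
    a moderately expressed, down-regulated gene and discarding a candidate
    expressed below the credibility floor.

    ``aggregate`` selects mean (default) or median across samples; percent
    change is computed on the aggregated values.
    """
    by_gene: dict[str, dict[str, list[ExpressionRecord]]] = {}
    case_set, control_set = set(case_samples), set(control_samples)
    for rec in expression_table:
        slot = by_gene.setdefault(rec.gene, {"case": [], "control": []})
        if rec.sample_id in case_set:
            slot["case"].append(rec)
        elif rec.sample_id in control_set:
            slot["control"].append(rec)

    missing = [
        g
        for g in candidate_genes
        if g not in by_gene or not by_gene[g]["case"] or not by_gene[g]["control"]
    ]
    if missing:
        raise KeyError(
            "gene(s) missing from the expression table (need >=1 case and "
            f">=1 control sample each): {missing}"
        )

    results = []
    for gene in candidate_genes:
        case_rpkm = _mean_rpkm(by_gene[gene]["case"], aggregate)
        control_rpkm = _mean_rpkm(by_gene[gene]["control"], aggregate)
        control_bin = bin_rpkm(control_rpkm)
        results.append(
            GateResult(
                gene=gene,
                mean_case_rpkm=case_rpkm,
                mean_control_rpkm=control_rpkm,
                percent_change=percent_change(case_rpkm, control_rpkm),
                control_bin=control_bin,
                keep=control_bin >= min_bin,
            )
        )
    return results


# ---------------------------------------------------------------------------
# Expression table I/O
# ---------------------------------------------------------------------------

_EXPR_COLUMNS = ["gene", "sample_id", "read_count", "gene_length_bp", "total_mapped_reads"]


def read_expression_table(path) -> list[ExpressionRecord]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _EXPR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing expression columns {missing}")
    return [
        ExpressionRecord(
            gene=str(r.gene),
            sample_id=str(r.sample_id),
            read_count=int(r.read_count),
            gene_length_bp=int(r.gene_length_bp),
            total_mapped_reads=int(r.total_mapped_reads),
        )
        for r in df.itertuples(index=False)
    ]


def write_expression_table(records: Sequence[ExpressionRecord], path) -> None:
    lines = ["\t".join(_EXPR_COLUMNS)]
    for r in records:
        lines.append(
            "\t".join(
                [r.gene, r.sample_id, str(r.read_count), str(r.gene_length_bp), str(r.total_mapped_reads)]
            )
        )
    from pathlib import Path

    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")
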