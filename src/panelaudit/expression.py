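"""RNA-level expression calls for DNA variants.

A DNA variant counts as expressed when its alternate allele is seen in
the tumor RNA-seq reads covering the locus.  Loci with too little RNA
coverage (or no RNA count record at all) are not assessable and stay out
of every denominator; only assessable calls enter the not-expressed
fractions.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .cohort_io import ObservedVariant, RnaAlleleCount, VariantKey


@dataclass(frozen=True)
class ExpressionThresholds:
    """Pileup heuristics deciding expressed / not-expressed / not-assessable.

    min_assessable_depth: RNA reads required to judge the locus at all;
    min_alt_reads and min_alt_fraction: alt support required to call the
    variant expressed.
    """

    min_assessable_depth: int = 10
    min_alt_reads: int = 3
    min_alt_fraction: float = 0.05

    def __post_init__(self) -> None:
        if min(self.min_assessable_depth, self.min_alt_reads) < 0:
            raise ValueError("thresholds must be non-negative")
        if not 0.0 <= self.min_alt_fraction <= 1.0:
            raise ValueError("min_alt_fraction must be in [0,1]")


DEFAULT_EXPRESSION_THRESHOLDS = ExpressionThresholds()


@dataclass(frozen=True)
class ExpressionCall:
    patient_id: str
    key: VariantKey
    status: str  # expressed | not_expressed | not_assessable
    rna_depth: int
    rna_alt: int


def call_expression(count: RnaAlleleCount,
                    thresholds: ExpressionThresholds = DEFAULT_EXPRESSION_THRESHOLDS) -> ExpressionCall:
    """Pure status call from one RNA allele count."""
    if count.rna_depth < thresholds.min_assessable_depth:
        status = "not_assessable"
    elif (
        count.rna_alt >= thresholds.min_alt_reads
        and count.rna_alt / count.rna_depth >= thresholds.min_alt_fraction
    ):
        status = "expressed"
    else:
        status = "not_expressed"
    return ExpressionCall(count.patient_id, count.key, status, count.rna_depth, count.rna_alt)


def call_cohort_expression(
    counts: Iterable[RnaAlleleCount],
    thresholds: ExpressionThresholds = DEFAULT_EXPRESSION_THRESHOLDS,
) -> dict[tuple[str, VariantKey], ExpressionCall]:
    """Expression calls keyed by (patient, variant key)."""
    calls = {}
    for c in counts:
        k = (c.patient_id, c.key)
        if k in calls:
            raise ValueError(f"duplicate RNA count record for {c.patient_id} {c.key}")
        calls[k] = call_expression(c, thresholds)
    return calls


def _join(variants, calls, origin):
    for v in variants:
        if v.origin != origin:
            continue
        call = calls.get((v.patient_id, v.key))
        if call is None or call.status == "not_assessable":
            continue
        yield v, call


def expression_summary(
    variants: list[ObservedVariant],
    calls: dict[tuple[str, VariantKey], ExpressionCall],
    gene_order: list[str],
    origin: str = "somatic",
) -> pd.DataFrame:
    """Per-gene expression table for one origin, with a Total row.

    Columns: gene, n_assessed, n_not_expressed, pct_not_expressed (blank
    when no calls are assessable), n_patients_not_expressed (patients
    deduplicated per gene; the Total row deduplicates across genes).
    """
    per_gene = {g: {"n_assessed": 0, "n_not_expressed": 0, "patients": set()} for g in gene_order}
    all_patients: set[str] = set()
    for v, call in _join(variants, calls, origin):
        rec = per_gene.setdefault(
            v.gene, {"n_assessed": 0, "n_not_expressed": 0, "patients": set()}
        )
        rec["n_assessed"] += 1
        if call.status == "not_expressed":
            rec["n_not_expressed"] += 1
            rec["patients"].add(v.patient_id)
            all_patients.add(v.patient_id)
    rows = []
    for g in per_gene:
        rec = per_gene[g]
        rows.append(
            {
                "gene": g,
                "n_assessed": rec["n_assessed"],
                "n_not_expressed": rec["n_not_expressed"],
                "pct_not_expressed": _pct(rec["n_not_expressed"], rec["n_assessed"]),
                "n_patients_not_expressed": len(rec["patients"]),
            }
        )
    total_assessed = sum(r["n_assessed"] for r in rows)
    total_not = sum(r["n_not_expressed"] for r in rows)
    rows.append(
        {
            "gene": "Total",
            "n_assessed": total_assessed,
            "n_not_expressed": total_not,
            "pct_not_expressed": _pct(total_not, total_assessed),
            "n_patients_not_expressed": len(all_patients),
        }
    )
    return pd.DataFrame(rows)


def germline_expression_fraction(
    variants: list[ObservedVariant],
    calls: dict[tuple[str, VariantKey], ExpressionCall],
) -> tuple[int, int, float]:
    """(n_not_expressed, n_assessed, fraction) over germline variants."""
    n_assessed = n_not = 0
    for _, call in _join(variants, calls, "germline"):
        n_assessed += 1
        if call.status == "not_expressed":
            n_not += 1
    if n_assessed == 0:
        raise ZeroDivisionError("no assessable germline variants")
    return n_not, n_assessed, n_not / n_assessed


def _pct(num: int, den: int) -> str:
    if den == 0:
        return ""
    from .report import round_half_up_pct

    return str(round_half_up_pct(num, den))
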