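#!/usr/bin/env python
"""Assess RNA-level expression of the classified DNA variants.

Joins the RNA allele counts to the labeled variants, calls each locus
expressed / not expressed / not assessable, and summarizes not-expressed
fractions per gene and origin.  Writes expression_somatic.tsv and
expression_germline.tsv under results/.
"""
from pathlib import Path

from panelaudit.cohort_io import GenePanel, read_rna_table, read_variant_table
from panelaudit.expression import (
    call_cohort_expression,
    expression_summary,
    germline_expression_fraction,
)

BASE = Path(__file__).resolve().parents[1] / "results"
COHORT = BASE / "synthetic_cohort"


def main() -> None:
    panel = GenePanel.default()
    labeled = read_variant_table(COHORT / "labeled_variants.tsv", panel)
    calls = call_cohort_expression(read_rna_table(COHORT / "rna_counts.tsv"))

    somatic = expression_summary(labeled, calls, panel.gene_names, origin="somatic")
    germline = expression_summary(labeled, calls, panel.gene_names, origin="germline")
    somatic.to_csv(BASE / "expression_somatic.tsv", sep="\t", index=False)
    germline.to_csv(BASE / "expression_germline.tsv", sep="\t", index=False)

    total = somatic[somatic["gene"] == "Total"].iloc[0]
    g_not, g_assessed, g_frac = germline_expression_fraction(labeled, calls)
    print(
        f"somatic: {total['n_not_expressed']}/{total['n_assessed']} assessable SNVs "
        f"not expressed ({total['pct_not_expressed']}%), in "
        f"{total['n_patients_not_expressed']} unique patients"
    )
    print(f"germline: {g_not}/{g_assessed} not expressed ({100 * g_frac:.1f}%)")


if __name__ == "__main__":
    main()
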