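#!/usr/bin/env python
"""Replay the three tumor-only filter regimes and account FP/FN.

For each regime (dbSNP membership, AF >= 0.01, AF >= 0.001) the labeled
cohort is partitioned into retained/removed calls and the confusion
counts are tallied at cohort and gene scope.  Also reports the
per-patient burden and the druggable-gene impact under the AF >= 0.001
regime.  Writes filter_confusion.tsv and druggable_impact.tsv under
results/.
"""
from pathlib import Path

import pandas as pd

from panelaudit.cohort_io import DrugTargetMap, GenePanel, read_annotation_table, read_variant_table
from panelaudit.filters import (
    apply_filter,
    druggable_impact,
    false_positive_rate,
    per_patient_burden,
    standard_regimes,
    tally,
)
from panelaudit.origin import collapse_sites, common_germline_keys, informative

BASE = Path(__file__).resolve().parents[1] / "results"
COHORT = BASE / "synthetic_cohort"


def main() -> None:
    panel = GenePanel.default()
    labeled = read_variant_table(COHORT / "labeled_variants.tsv", panel)
    usable = informative(labeled)
    annotations = read_annotation_table(COHORT / "annotations.tsv")
    patients = sorted(pd.read_csv(COHORT / "truth.tsv", sep="\t")["patient_id"].unique())
    sites = collapse_sites(usable, cohort_size=len(patients))
    common = common_germline_keys(sites)

    rows = []
    retained_by_regime = {}
    for regime in standard_regimes():
        retained, removed = apply_filter(usable, annotations, regime, common)
        retained_by_regime[regime.name] = retained
        t = tally(retained, removed, "cohort")
        rows.append(
            {
                "regime": regime.name,
                "tp": t.true_positive,
                "fp": t.false_positive,
                "fn": t.false_negative,
                "germline_removed": t.germline_removed,
                "fp_rate_retained": round(false_positive_rate(t, "retained"), 4),
            }
        )
        print(
            f"{regime.name:>9}: retained {t.retained} calls, "
            f"FP {t.false_positive} ({100 * false_positive_rate(t, 'retained'):.0f}% of retained), "
            f"FN {t.false_negative} of {t.somatic_input} somatic"
        )
        for g in tally(retained, removed, "gene"):
            rows.append(
                {
                    "regime": regime.name, "scope_id": g.scope_id, "tp": g.true_positive,
                    "fp": g.false_positive, "fn": g.false_negative,
                    "germline_removed": g.germline_removed,
                }
            )
    pd.DataFrame(rows).to_csv(BASE / "filter_confusion.tsv", sep="\t", index=False)

    records, aggs = per_patient_burden(retained_by_regime["af_0.001"], patients)
    print(
        f"AF>=0.001 burden: {aggs['patients_with_any_fp']}/{aggs['n_patients']} patients "
        f"({100 * aggs['frac_with_any_fp']:.0f}%) with >=1 FP, "
        f"{aggs['patients_with_only_fp']} with only FPs; mean "
        f"{aggs['mean_retained_per_positive_patient']:.2f} retained calls per "
        "patient with >=1 call"
    )

    drug_map = DrugTargetMap.default()
    impact = druggable_impact(retained_by_regime, drug_map)
    impact_df = pd.DataFrame(
        [
            {"gene": g, **{rn: impact["per_gene"][rn].get(g, 0) for rn in retained_by_regime}}
            for g in drug_map.genes
        ]
    )
    impact_df.to_csv(BASE / "druggable_impact.tsv", sep="\t", index=False)
    uniq = impact["unique_patients"]
    print(
        "patients with >=1 FP in a drug-targetable gene: "
        + ", ".join(f"{rn}: {uniq[rn]}" for rn in uniq)
    )


if __name__ == "__main__":
    main()
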