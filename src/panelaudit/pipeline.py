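"""End-to-end orchestration: classify -> collapse -> filter -> express -> report.

`run_stages` operates on in-memory objects and returns the report
bundle; `run_all` wraps it with file/simulation input handling, writes
the bundle as byte-stable TSV/JSON files and emits a run manifest
(config snapshot, input digests, seed, timestamps) sufficient to
reproduce the run.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from collections import Counter
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from .cohort_io import (
    AnnotationLookup,
    DrugTargetMap,
    GenePanel,
    ObservedVariant,
    RnaAlleleCount,
    read_annotation_table,
    read_rna_table,
    read_variant_table,
    write_report_tables,
)
from .expression import (
    DEFAULT_EXPRESSION_THRESHOLDS,
    ExpressionThresholds,
    call_cohort_expression,
    expression_summary,
    germline_expression_fraction,
)
from .filters import (
    FilterRegime,
    apply_filter,
    druggable_impact,
    per_patient_burden,
    standard_regimes,
    tally,
)
from .origin import (
    DEFAULT_THRESHOLDS,
    ClassifierThresholds,
    classify_cohort,
    collapse_sites,
    common_germline_keys,
    informative,
    singleton_fraction,
)
from .report import burden_histogram, gene_origin_table, headline_summary, size_correlation
from .simulate import CohortConfig, generate_cohort

logger = logging.getLogger(__name__)

# Patient-level burden and the headline FP rates are reported for the
# least aggressive AF regime, the one a tumor-only workflow would
# plausibly deploy.
HEADLINE_REGIME = "af_0.001"


def _confusion_frame(tallies_by_regime: Mapping[str, dict]) -> pd.DataFrame:
    rows = []
    for regime_name, scoped in tallies_by_regime.items():
        for scope, ts in scoped.items():
            for t in [ts] if scope == "cohort" else ts:
                rows.append(
                    {
                        "regime": regime_name,
                        "scope": t.scope,
                        "scope_id": t.scope_id,
                        "tp": t.true_positive,
                        "fp": t.false_positive,
                        "fn": t.false_negative,
                        "germline_removed": t.germline_removed,
                    }
                )
    return pd.DataFrame(
        rows, columns=["regime", "scope", "scope_id", "tp", "fp", "fn", "germline_removed"]
    )


def run_stages(
    variants: list[ObservedVariant],
    annotations: AnnotationLookup | None,
    rna_counts: list[RnaAlleleCount],
    panel: GenePanel,
    patients: list[str] | None = None,
    *,
    thresholds: ClassifierThresholds = DEFAULT_THRESHOLDS,
    expression_thresholds: ExpressionThresholds = DEFAULT_EXPRESSION_THRESHOLDS,
    regimes: list[FilterRegime] | None = None,
    drug_map: DrugTargetMap | None = None,
    cohort_common_threshold: float = 0.02,
    fixture_mode: bool = False,
) -> dict:
    """Run every analysis stage and return the report bundle.

    The bundle maps table name -> DataFrame plus a ``summary`` JSON
    mapping; it is what :func:`panelaudit.cohort_io.write_report_tables`
    serializes.
    """
    if regimes is None:
        regimes = standard_regimes()
    if drug_map is None:
        drug_map = DrugTargetMap.default()
    if patients is None:
        patients = sorted({v.patient_id for v in variants})
    if any(r.kind == "af_threshold" or r.kind == "database_membership" for r in regimes):
        if annotations is None:
            raise ValueError(
                "filter stage: population annotation table required for "
                f"regimes {[r.name for r in regimes]}"
            )

    t0 = time.perf_counter()
    labeled, origin_counts = classify_cohort(variants, thresholds, trust_existing=fixture_mode)
    usable = informative(labeled)
    logger.info(
        "classify: %d variants -> %s (%.2fs)", len(variants), dict(origin_counts),
        time.perf_counter() - t0,
    )

    sites = collapse_sites(usable, cohort_size=len(patients))
    common_keys = common_germline_keys(sites, cohort_common_threshold)

    class_counts = {}
    gene_class = {g.gene: g.panel_class for g in panel.genes}
    for cls in ("tumor_driver", "inherited_risk"):
        class_counts[cls] = {
            "germline": sum(
                1 for v in usable if v.origin == "germline" and gene_class.get(v.gene) == cls
            ),
            "somatic": sum(
                1 for v in usable if v.origin == "somatic" and gene_class.get(v.gene) == cls
            ),
        }

    retained_by_regime: dict[str, list[ObservedVariant]] = {"no_filter": list(usable)}
    tallies_by_regime = {
        "no_filter": {
            "cohort": tally(usable, [], "cohort"),
            "gene": tally(usable, [], "gene"),
        }
    }
    cohort_tallies = {"no_filter": tallies_by_regime["no_filter"]["cohort"]}
    for regime in regimes:
        retained, removed = apply_filter(usable, annotations, regime, common_keys)
        retained_by_regime[regime.name] = retained
        tallies_by_regime[regime.name] = {
            "cohort": tally(retained, removed, "cohort"),
            "gene": tally(retained, removed, "gene"),
        }
        cohort_tallies[regime.name] = tallies_by_regime[regime.name]["cohort"]

    burden_regime = HEADLINE_REGIME if HEADLINE_REGIME in retained_by_regime else "no_filter"
    burden_records, burden_aggs = per_patient_burden(retained_by_regime[burden_regime], patients)
    bins, excluded = burden_histogram(burden_records)

    calls = call_cohort_expression(rna_counts, expression_thresholds)
    expr_somatic = expression_summary(labeled, calls, panel.gene_names, origin="somatic")
    expr_germline = expression_summary(labeled, calls, panel.gene_names, origin="germline")
    try:
        g_not, g_assessed, g_frac = germline_expression_fraction(labeled, calls)
    except ZeroDivisionError:
        g_not = g_assessed = 0
        g_frac = None
    som_total = expr_somatic[expr_somatic["gene"] == "Total"].iloc[0]
    expression_fractions = {
        "somatic_assessed": int(som_total["n_assessed"]),
        "somatic_not_expressed": int(som_total["n_not_expressed"]),
        "somatic_not_expressed_fraction": (
            int(som_total["n_not_expressed"]) / int(som_total["n_assessed"])
            if int(som_total["n_assessed"]) else None
        ),
        "germline_assessed": g_assessed,
        "germline_not_expressed": g_not,
        "germline_not_expressed_fraction": g_frac,
    }

    impact = druggable_impact(retained_by_regime, drug_map)
    impact_rows = []
    regime_names = list(retained_by_regime)
    for gene in drug_map.genes:
        impact_rows.append(
            {"gene": gene, **{rn: impact["per_gene"][rn].get(gene, 0) for rn in regime_names}}
        )
    impact_rows.append(
        {"gene": "unique_patients", **{rn: impact["unique_patients"][rn] for rn in regime_names}}
    )

    counts = [sum(1 for s in sites if s.gene == g) for g in panel.gene_names]
    lengths = [panel[g].cds_length for g in panel.gene_names]
    try:
        corr = size_correlation(counts, lengths)
        corr_dict = {"r": corr.r, "r_squared": corr.r_squared, "p_value": corr.p_value, "n": corr.n}
    except ValueError:
        corr_dict = None

    summary = headline_summary(
        origin_counts, class_counts, cohort_tallies, {burden_regime: burden_aggs},
        expression_fractions,
    )
    summary["n_unique_sites"] = len(sites)
    summary["n_dual_origin_sites"] = sum(1 for s in sites if s.dual_origin)
    summary["n_cohort_common_germline_sites"] = len(common_keys)
    summary["singleton_fraction"] = singleton_fraction(sites) if sites else None
    summary["size_correlation"] = corr_dict
    summary["classifier_thresholds"] = vars(thresholds).copy()
    summary["expression_thresholds"] = vars(expression_thresholds).copy()
    summary["burden_histogram_excluded"] = [
        {"patient_id": r.patient_id, "tp": r.n_true_positive, "fp": r.n_false_positive}
        for r in excluded
    ]

    burden_frame = pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "n_tp": r.n_true_positive,
                "n_fp": r.n_false_positive,
                "any_fp": int(r.any_false_positive),
                "only_fp": int(r.only_false_positive),
            }
            for r in burden_records
        ],
        columns=["patient_id", "n_tp", "n_fp", "any_fp", "only_fp"],
    )
    histogram_frame = pd.DataFrame(
        [{"n_tp": tp, "n_fp": fp, "n_patients": n} for (tp, fp), n in sorted(bins.items())],
        columns=["n_tp", "n_fp", "n_patients"],
    )

    return {
        "gene_origin_table": gene_origin_table(sites, usable, panel),
        "confusion": _confusion_frame(tallies_by_regime),
        "patient_burden": burden_frame,
        "burden_histogram": histogram_frame,
        "expression_somatic": expr_somatic,
        "expression_germline": expr_germline,
        "druggable_impact": pd.DataFrame(impact_rows, columns=["gene"] + regime_names),
        "summary": summary,
    }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(
    out_dir: str | Path,
    *,
    variant_table: str | Path | None = None,
    annotation_table: str | Path | None = None,
    rna_table: str | Path | None = None,
    panel_yaml: str | Path | None = None,
    simulate: bool = False,
    sim_config: CohortConfig | None = None,
    seed: int | None = None,
    fixture_mode: bool = False,
    thresholds: ClassifierThresholds = DEFAULT_THRESHOLDS,
    expression_thresholds: ExpressionThresholds = DEFAULT_EXPRESSION_THRESHOLDS,
) -> tuple[dict, dict]:
    """Run the full audit from files or from a simulated cohort.

    Returns (report bundle, manifest) and writes both under ``out_dir``.
    """
    out_dir = Path(out_dir)
    started = time.time()
    panel = GenePanel.from_yaml(panel_yaml) if panel_yaml else GenePanel.default()
    inputs: dict[str, str] = {}

    if simulate:
        config = sim_config or CohortConfig(seed=seed if seed is not None else 0)
        if seed is not None and (sim_config is None or sim_config.seed != seed):
            config.seed = seed
        cohort = generate_cohort(config)
        variants = cohort.variants_with_truth_origin() if fixture_mode else cohort.variants
        annotations = cohort.annotations
        rna_counts = cohort.rna_counts
        patients = cohort.patients
        config_snapshot = {
            k: v for k, v in vars(config).items() if k != "panel"
        }
    else:
        if variant_table is None:
            raise ValueError("classify stage: a variant table is required without --simulate")
        variants = read_variant_table(variant_table, panel)
        inputs[str(variant_table)] = _sha256(Path(variant_table))
        annotations = None
        if annotation_table is not None:
            annotations = read_annotation_table(annotation_table)
            inputs[str(annotation_table)] = _sha256(Path(annotation_table))
        rna_counts = []
        if rna_table is not None:
            rna_counts = read_rna_table(rna_table)
            inputs[str(rna_table)] = _sha256(Path(rna_table))
        patients = sorted({v.patient_id for v in variants})
        config_snapshot = {}

    bundle = run_stages(
        variants, annotations, rna_counts, panel, patients,
        thresholds=thresholds, expression_thresholds=expression_thresholds,
        fixture_mode=fixture_mode,
    )
    manifest = {
        "tool": "panelaudit",
        "version": __version__,
        "seed": seed if seed is not None else (sim_config.seed if sim_config else None),
        "simulated": simulate,
        "fixture_mode": fixture_mode,
        "config": config_snapshot,
        "classifier_thresholds": vars(thresholds).copy(),
        "expression_thresholds": vars(expression_thresholds).copy(),
        "inputs": inputs,
        "started_unix": started,
        "finished_unix": time.time(),
    }
    write_report_tables(bundle, out_dir)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return bundle, manifest
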