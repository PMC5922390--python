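"""Report tables, headline fractions and the gene-size correlation.

Every percentage in a table is re-derived from the integer counts of its
own row (rounded half-up, table style); full-precision fractions are
carried only in the JSON headline summary.

Also hosts loaders for the two packaged transcription fixtures: the
published per-gene variant-origin counts (lung and all-cancer cohorts)
and the published per-gene somatic-expression counts.
"""
from __future__ import annotations

import importlib.resources
from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd
from scipy import stats

from .cohort_io import GenePanel, ObservedVariant
from .filters import ConfusionTally, PatientBurden, false_positive_rate
from .origin import SiteSummary


def round_half_up_pct(num: float, den: float) -> int:
    """Integer percent with ties rounded up (table convention)."""
    if den == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    return int(Decimal(100 * num / den).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Packaged transcription fixtures
# ---------------------------------------------------------------------------

def load_variant_count_table() -> pd.DataFrame:
    """Published per-gene unique/germline/somatic counts for both cohorts."""
    ref = importlib.resources.files("panelaudit.data") / "variant_counts_by_gene.tsv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def load_expression_table() -> pd.DataFrame:
    """Published per-gene somatic expression assessment for both cohorts."""
    ref = importlib.resources.files("panelaudit.data") / "expression_by_gene.tsv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def variant_count_totals(df: pd.DataFrame, cohort: str) -> dict:
    """Cohort totals and panel-class subtotals from the per-gene count table.

    ``cohort`` is ``"lung"`` or ``"all"``; the returned dict carries raw
    sums plus the rounded germline/somatic percentages.
    """
    g, s, u = f"{cohort}_germline", f"{cohort}_somatic", f"{cohort}_unique"
    out = {
        "unique_sites": int(df[u].sum()),
        "germline": int(df[g].sum()),
        "somatic": int(df[s].sum()),
    }
    out["total"] = out["germline"] + out["somatic"]
    out["germline_pct"] = round_half_up_pct(out["germline"], out["total"])
    out["somatic_pct"] = round_half_up_pct(out["somatic"], out["total"])
    for cls in ("tumor_driver", "inherited_risk"):
        sub = df[df["panel_class"] == cls]
        germ, som = int(sub[g].sum()), int(sub[s].sum())
        out[cls] = {
            "unique_sites": int(sub[u].sum()),
            "germline": germ,
            "somatic": som,
            "somatic_pct": round_half_up_pct(som, germ + som) if germ + som else None,
        }
    return out


def expression_totals(df: pd.DataFrame, cohort: str) -> dict:
    a, n = f"{cohort}_assessed", f"{cohort}_not_expressed"
    assessed = int(df[a].sum())
    not_expr = int(df[n].sum())
    return {
        "assessed": assessed,
        "not_expressed": not_expr,
        "not_expressed_pct": round_half_up_pct(not_expr, assessed),
    }


# ---------------------------------------------------------------------------
# Computed tables
# ---------------------------------------------------------------------------

def gene_origin_table(
    sites: list[SiteSummary],
    variants: list[ObservedVariant],
    panel: GenePanel,
) -> pd.DataFrame:
    """Per-gene unique sites and germline/somatic counts with percentages.

    One row per panel gene plus a subtotal row per panel class; row
    percentages are germline/(germline+somatic) and its complement,
    blank for genes with no variants.
    """
    unique = Counter(s.gene for s in sites)
    germ = Counter(v.gene for v in variants if v.origin == "germline")
    som = Counter(v.gene for v in variants if v.origin == "somatic")

    def row(label, u, g, s, is_subtotal=False):
        total = g + s
        return {
            "gene": label,
            "unique_sites": u,
            "germline": g,
            "germline_pct": round_half_up_pct(g, total) if total else "",
            "somatic": s,
            "somatic_pct": round_half_up_pct(s, total) if total else "",
            "row_type": "subtotal" if is_subtotal else "gene",
        }

    rows = []
    for cls in ("tumor_driver", "inherited_risk"):
        members = panel.genes_in_class(cls)
        for pg in members:
            rows.append(row(pg.gene, unique[pg.gene], germ[pg.gene], som[pg.gene]))
        rows.append(
            row(
                f"{cls}_total",
                sum(unique[pg.gene] for pg in members),
                sum(germ[pg.gene] for pg in members),
                sum(som[pg.gene] for pg in members),
                is_subtotal=True,
            )
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    r_squared: float
    p_value: float
    n: int


def size_correlation(unique_site_counts: list[int], cds_lengths: list[int]) -> CorrelationResult:
    """Pearson correlation of per-gene unique-site counts vs CDS length.

    The p-value is the standard two-sided t test on r with n-2 degrees of
    freedom.
    """
    if len(unique_site_counts) != len(cds_lengths):
        raise ValueError("count and length vectors differ in length")
    n = len(unique_site_counts)
    if n < 3:
        raise ValueError("correlation needs at least 3 genes")
    if len(set(unique_site_counts)) == 1 or len(set(cds_lengths)) == 1:
        raise ValueError("zero variance: correlation undefined")
    res = stats.pearsonr(unique_site_counts, cds_lengths)
    return CorrelationResult(r=float(res.statistic), r_squared=float(res.statistic) ** 2,
                             p_value=float(res.pvalue), n=n)


def burden_histogram(
    records: list[PatientBurden], cap: int = 30
) -> tuple[dict[tuple[int, int], int], list[PatientBurden]]:
    """Histogram of (n_TP, n_FP) pairs over patients with >= 1 retained call.

    Patients whose retained-call count exceeds ``cap`` are listed as
    excluded outliers instead of binned (presentation convention).
    """
    bins: Counter = Counter()
    excluded = []
    for r in records:
        if r.n_retained == 0:
            continue
        if r.n_retained > cap:
            excluded.append(r)
        else:
            bins[(r.n_true_positive, r.n_false_positive)] += 1
    return dict(bins), excluded


def headline_summary(
    origin_counts: Counter,
    class_counts: dict[str, dict[str, int]],
    regime_tallies: dict[str, ConfusionTally],
    burden_aggregates: dict[str, dict],
    expression_fractions: dict[str, float | None],
) -> dict:
    """Assemble the cohort-level headline fractions into one JSON bundle.

    All inputs are required; a missing stage raises with its name.
    Rounding to integer percent happens only here, alongside the
    full-precision fractions.
    """
    for name, obj in (
        ("origin_classification", origin_counts),
        ("panel_class_counts", class_counts),
        ("filter_regimes", regime_tallies),
        ("patient_burden", burden_aggregates),
        ("expression_assessment", expression_fractions),
    ):
        if obj is None:
            raise ValueError(f"missing stage output: {name}")

    total = origin_counts["germline"] + origin_counts["somatic"]
    out: dict = {
        "cohort": {
            "n_variants_labeled": total,
            "n_germline": origin_counts["germline"],
            "n_somatic": origin_counts["somatic"],
            "n_ambiguous": origin_counts.get("ambiguous", 0),
            "n_unassigned": origin_counts.get("unassigned", 0),
            "germline_fraction": origin_counts["germline"] / total if total else None,
            "germline_pct": round_half_up_pct(origin_counts["germline"], total) if total else None,
        },
        "panel_class": {},
        "regimes": {},
        "burden": burden_aggregates,
        "expression": expression_fractions,
    }
    for cls, counts in class_counts.items():
        subtotal = counts["germline"] + counts["somatic"]
        out["panel_class"][cls] = {
            **counts,
            "somatic_pct": round_half_up_pct(counts["somatic"], subtotal) if subtotal else None,
        }
    for name, t in regime_tallies.items():
        entry = {
            "tp": t.true_positive,
            "fp": t.false_positive,
            "fn": t.false_negative,
            "germline_removed": t.germline_removed,
            "n_retained": t.retained,
        }
        entry["fp_rate_retained"] = (
            false_positive_rate(t, "retained") if t.retained else None
        )
        entry["fp_rate_total"] = (
            false_positive_rate(t, "total") if t.total_input else None
        )
        entry["fp_pct_retained"] = (
            round_half_up_pct(t.false_positive, t.retained) if t.retained else None
        )
        out["regimes"][name] = entry
    return out
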