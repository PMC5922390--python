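"""Tumor-only filter regimes and false-positive / false-negative accounting.

A tumor-only workflow cannot see the matched normal, so it removes
putative germline polymorphisms using population databases.  Three
regimes are modeled:

* ``database_membership`` — remove every variant present in the
  population database (dbSNP-style membership filter);
* ``af_threshold`` at cutoff 0.01 — remove variants with a reported
  population allele frequency >= 0.01;
* ``af_threshold`` at cutoff 0.001 — the same at >= 0.001.

AF regimes additionally apply a rescue rule (on by default): variants
with *no* reported frequency that are nonetheless database members AND
common germline variants within the cohort itself are removed too.

In this audit a false positive is a germline variant retained by the
filter (reported as somatic); a false negative is a true somatic variant
the filter removed.
"""
from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping

from .cohort_io import AnnotationLookup, DrugTargetMap, ObservedVariant, VariantKey


@dataclass(frozen=True)
class FilterRegime:
    kind: str  # database_membership | af_threshold
    af_cutoff: float | None = None
    rescue_rule_enabled: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("database_membership", "af_threshold"):
            raise ValueError(f"unknown filter kind {self.kind!r}")
        if self.kind == "af_threshold":
            if self.af_cutoff is None:
                raise ValueError("af_threshold regime requires af_cutoff")
            if not 0.0 < self.af_cutoff <= 1.0:
                raise ValueError(f"af_cutoff must be in (0,1], got {self.af_cutoff}")

    @property
    def name(self) -> str:
        if self.kind == "database_membership":
            return "dbsnp"
        return f"af_{self.af_cutoff:g}"


DBSNP_REGIME = FilterRegime("database_membership")
AF_001_REGIME = FilterRegime("af_threshold", af_cutoff=0.01)
AF_0001_REGIME = FilterRegime("af_threshold", af_cutoff=0.001)


def standard_regimes() -> list[FilterRegime]:
    """The three filter regimes audited: dbSNP membership, AF>=0.01, AF>=0.001."""
    return [DBSNP_REGIME, AF_001_REGIME, AF_0001_REGIME]


def _removed_by(variant: ObservedVariant, ann, regime: FilterRegime,
                cohort_common_keys: frozenset | set) -> bool:
    if regime.kind == "database_membership":
        return ann.in_database
    if ann.population_af is not None:
        return ann.population_af >= regime.af_cutoff
    # No reported frequency: retained unless rescued-out as a
    # database-known cohort-common germline site.
    return (
        regime.rescue_rule_enabled
        and ann.in_database
        and variant.key in cohort_common_keys
    )


def apply_filter(
    variants: list[ObservedVariant],
    annotations: AnnotationLookup,
    regime: FilterRegime,
    cohort_common_keys: Iterable[VariantKey] = (),
) -> tuple[list[ObservedVariant], list[ObservedVariant]]:
    """Partition labeled variants into (retained, removed) under a regime.

    ``cohort_common_keys`` is the set of cohort-common germline site keys
    feeding the rescue rule (see :func:`panelaudit.origin.common_germline_keys`).
    """
    common = frozenset(cohort_common_keys)
    retained, removed = [], []
    for v in variants:
        if _removed_by(v, annotations.get(v.key), regime, common):
            removed.append(v)
        else:
            retained.append(v)
    return retained, removed


@dataclass
class ConfusionTally:
    """TP/FP/FN accounting for one filter regime at one scope.

    true_positive: somatic retained; false_positive: germline retained;
    false_negative: somatic removed; germline_removed: germline correctly
    rejected.
    """

    scope: str  # cohort | gene | patient
    scope_id: str
    true_positive: int = 0
    false_positive: int = 0
    false_negative: int = 0
    germline_removed: int = 0

    @property
    def somatic_input(self) -> int:
        return self.true_positive + self.false_negative

    @property
    def germline_input(self) -> int:
        return self.false_positive + self.germline_removed

    @property
    def retained(self) -> int:
        return self.true_positive + self.false_positive

    @property
    def total_input(self) -> int:
        return self.somatic_input + self.germline_input


def _accumulate(tallies: dict, scope: str, scope_id: str, origin: str, retained: bool) -> None:
    t = tallies.get(scope_id)
    if t is None:
        t = tallies[scope_id] = ConfusionTally(scope=scope, scope_id=scope_id)
    if origin == "somatic":
        if retained:
            t.true_positive += 1
        else:
            t.false_negative += 1
    else:
        if retained:
            t.false_positive += 1
        else:
            t.germline_removed += 1


def tally(
    retained: list[ObservedVariant],
    removed: list[ObservedVariant],
    scope: str = "cohort",
) -> ConfusionTally | list[ConfusionTally]:
    """Confusion tally at cohort scope, or one tally per gene/patient.

    Every variant must already carry a germline or somatic label;
    ambiguous/unassigned variants must be excluded upstream.
    """
    if scope not in ("cohort", "gene", "patient"):
        raise ValueError(f"unknown scope {scope!r}")
    tallies: dict[str, ConfusionTally] = {}
    for is_retained, group in ((True, retained), (False, removed)):
        for v in group:
            if v.origin not in ("germline", "somatic"):
                raise ValueError(
                    f"variant {v.key} in {v.patient_id} has origin {v.origin!r}; "
                    "only germline/somatic variants may enter tallies"
                )
            if scope == "cohort":
                scope_id = "cohort"
            elif scope == "gene":
                scope_id = v.gene
            else:
                scope_id = v.patient_id
            _accumulate(tallies, scope, scope_id, v.origin, is_retained)
    if scope == "cohort":
        return tallies.get("cohort", ConfusionTally(scope="cohort", scope_id="cohort"))
    return [tallies[k] for k in sorted(tallies)]


def false_positive_rate(t: ConfusionTally, denominator: str = "retained") -> float:
    """FP rate as a fraction.

    ``retained``: FP / (FP + TP), the share of reported calls that are
    germline.  ``total``: FP / all germline+somatic input variants.
    """
    if denominator == "retained":
        denom = t.retained
    elif denominator == "total":
        denom = t.total_input
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if denom == 0:
        raise ZeroDivisionError(
            f"false positive rate undefined: zero {denominator} denominator"
        )
    return t.false_positive / denom


@dataclass
class PatientBurden:
    patient_id: str
    n_true_positive: int
    n_false_positive: int

    @property
    def n_retained(self) -> int:
        return self.n_true_positive + self.n_false_positive

    @property
    def any_false_positive(self) -> bool:
        return self.n_false_positive >= 1

    @property
    def only_false_positive(self) -> bool:
        return self.n_false_positive >= 1 and self.n_true_positive == 0


def per_patient_burden(
    retained: list[ObservedVariant],
    patients: Iterable[str],
) -> tuple[list[PatientBurden], dict]:
    """Per-patient retained-call burden plus cohort aggregates.

    The patient roster must include patients with zero retained calls:
    the any-FP / only-FP fractions are over all patients, while the mean
    retained count is over patients with at least one retained variant
    (zero-variant patients are excluded from that mean, as in burden
    histograms of reported calls).
    """
    roster = list(dict.fromkeys(patients))
    counts: dict[str, list[int]] = {p: [0, 0] for p in roster}
    for v in retained:
        if v.patient_id not in counts:
            raise ValueError(f"retained variant for {v.patient_id} not in the patient roster")
        counts[v.patient_id][0 if v.origin == "somatic" else 1] += 1
    records = [PatientBurden(p, tp, fp) for p, (tp, fp) in counts.items()]
    n_with_any = sum(1 for r in records if r.n_retained >= 1)
    aggregates = {
        "n_patients": len(records),
        "patients_with_any_variant": n_with_any,
        "patients_with_any_fp": sum(1 for r in records if r.any_false_positive),
        "patients_with_only_fp": sum(1 for r in records if r.only_false_positive),
        "frac_with_any_fp": (
            sum(1 for r in records if r.any_false_positive) / len(records) if records else 0.0
        ),
        "frac_with_only_fp": (
            sum(1 for r in records if r.only_false_positive) / len(records) if records else 0.0
        ),
        "mean_retained_per_positive_patient": (
            sum(r.n_retained for r in records) / n_with_any if n_with_any else 0.0
        ),
        "mean_fp_per_patient": (
            sum(r.n_false_positive for r in records) / len(records) if records else 0.0
        ),
    }
    return records, aggregates


def druggable_impact(
    retained_by_regime: Mapping[str, list[ObservedVariant]],
    drug_map: DrugTargetMap,
) -> dict:
    """Patients with >= 1 false-positive call in drug-targetable genes.

    For each regime, counts per druggable gene the patients with at least
    one retained germline variant in that gene (each patient counted once
    per gene regardless of multiplicity), plus the regime-level number of
    unique affected patients deduplicated across genes.
    """
    per_gene: dict[str, dict[str, int]] = {}
    unique_patients: dict[str, int] = {}
    for regime_name, retained in retained_by_regime.items():
        gene_patients: dict[str, set[str]] = defaultdict(set)
        all_patients: set[str] = set()
        for v in retained:
            if v.origin == "germline" and v.gene in drug_map:
                gene_patients[v.gene].add(v.patient_id)
                all_patients.add(v.patient_id)
        per_gene[regime_name] = {g: len(gene_patients[g]) for g in drug_map.genes}
        unique_patients[regime_name] = len(all_patients)
    return {"per_gene": per_gene, "unique_patients": unique_patients}
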