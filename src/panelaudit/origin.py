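"""Germline/somatic origin assignment from matched tumor/normal evidence.

The decision rule is a conventional paired-calling heuristic over read
counts at the stated ~30x normal / ~60x tumor depths:

* a variant with too little tumor support is ``unassigned``;
* strong normal support (alt reads and normal VAF both above the
  germline thresholds) marks it ``germline``;
* essentially absent normal support (alt reads at or below the somatic
  maximum, or normal VAF below the somatic VAF ceiling) marks it
  ``somatic``;
* normal evidence strictly between the two bands is ``ambiguous`` and is
  excluded from all downstream tallies, reported separately.

Site-level collapsing, cohort-common detection (carrier frequency above
a threshold) and the singleton fraction live here as well.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .cohort_io import ObservedVariant, VariantKey


@dataclass(frozen=True)
class ClassifierThresholds:
    """Evidence thresholds for the paired germline/somatic classifier."""

    min_tumor_alt: int = 4
    min_tumor_vaf: float = 0.05
    germline_min_normal_alt: int = 4
    germline_min_normal_vaf: float = 0.20
    somatic_max_normal_alt: int = 1
    somatic_max_normal_vaf: float = 0.02

    def __post_init__(self) -> None:
        for name in ("min_tumor_vaf", "germline_min_normal_vaf", "somatic_max_normal_vaf"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.somatic_max_normal_vaf >= self.germline_min_normal_vaf:
            raise ValueError(
                "somatic_max_normal_vaf must be below germline_min_normal_vaf "
                f"({self.somatic_max_normal_vaf} >= {self.germline_min_normal_vaf})"
            )


DEFAULT_THRESHOLDS = ClassifierThresholds()


def classify_origin(variant: ObservedVariant,
                    thresholds: ClassifierThresholds = DEFAULT_THRESHOLDS) -> str:
    """Return the origin label for one variant (pure function of evidence)."""
    if variant.tumor_alt < thresholds.min_tumor_alt or variant.tumor_vaf < thresholds.min_tumor_vaf:
        return "unassigned"
    n_alt, n_vaf = variant.normal_alt, variant.normal_vaf
    if n_alt >= thresholds.germline_min_normal_alt and n_vaf >= thresholds.germline_min_normal_vaf:
        return "germline"
    if n_alt <= thresholds.somatic_max_normal_alt or n_vaf < thresholds.somatic_max_normal_vaf:
        return "somatic"
    return "ambiguous"


def classify_cohort(
    variants: list[ObservedVariant],
    thresholds: ClassifierThresholds = DEFAULT_THRESHOLDS,
    trust_existing: bool = False,
) -> tuple[list[ObservedVariant], Counter]:
    """Label every variant and return (labeled list, counts by origin).

    ``trust_existing=True`` is fixture mode: variants that already carry a
    germline/somatic label (transcribed tables, synthetic truth) keep it
    and evidence thresholds are bypassed.
    """
    labeled = []
    counts: Counter = Counter()
    for v in variants:
        if trust_existing and v.origin in ("germline", "somatic"):
            lv = v
        else:
            lv = v.with_origin(classify_origin(v, thresholds))
        counts[lv.origin] += 1
        labeled.append(lv)
    for origin in ("germline", "somatic", "ambiguous", "unassigned"):
        counts.setdefault(origin, 0)
    return labeled, counts


def informative(variants: list[ObservedVariant]) -> list[ObservedVariant]:
    """Germline/somatic variants only: what downstream tallies consume."""
    return [v for v in variants if v.origin in ("germline", "somatic")]


@dataclass
class SiteSummary:
    """Per-unique-site counts across the cohort.

    ``dual_origin`` marks sites seen as germline in some patients and
    somatic in others; ``cohort_frequency`` is the carrier frequency
    (patients carrying the site / cohort size).
    """

    key: VariantKey
    gene: str
    n_germline: int = 0
    n_somatic: int = 0
    cohort_frequency: float = 0.0

    @property
    def dual_origin(self) -> bool:
        return self.n_germline >= 1 and self.n_somatic >= 1

    @property
    def n_total(self) -> int:
        return self.n_germline + self.n_somatic


def collapse_sites(variants: list[ObservedVariant], cohort_size: int) -> list[SiteSummary]:
    """Collapse labeled variants to one summary per unique SNV site.

    Only germline/somatic variants contribute.  A key mapped to two
    different genes indicates overlapping panel intervals and is an error.
    """
    if cohort_size < 1:
        raise ValueError("cohort_size must be >= 1")
    summaries: dict[VariantKey, SiteSummary] = {}
    for v in informative(variants):
        s = summaries.get(v.key)
        if s is None:
            s = summaries[v.key] = SiteSummary(key=v.key, gene=v.gene)
        elif s.gene != v.gene:
            raise ValueError(
                f"site {v.key} mapped to both {s.gene} and {v.gene}: "
                "panel intervals overlap"
            )
        if v.origin == "germline":
            s.n_germline += 1
        else:
            s.n_somatic += 1
    out = sorted(summaries.values(), key=lambda s: s.key)
    for s in out:
        s.cohort_frequency = s.n_total / cohort_size
    return out


def cohort_common_variants(sites: list[SiteSummary], threshold: float = 0.02) -> list[SiteSummary]:
    """Sites whose cohort carrier frequency strictly exceeds ``threshold``."""
    return [s for s in sites if s.cohort_frequency > threshold]


def common_germline_keys(sites: list[SiteSummary], threshold: float = 0.02) -> set[VariantKey]:
    """Keys of cohort-common sites with at least one germline observation.

    This is the membership set used by the AF-regime rescue rule:
    database-known variants without a reported population frequency are
    still removed when they are common germline variants within the
    cohort itself.
    """
    return {s.key for s in cohort_common_variants(sites, threshold) if s.n_germline >= 1}


def singleton_fraction(sites: list[SiteSummary]) -> float:
    """Fraction of unique sites observed in exactly one patient."""
    if not sites:
        raise ValueError("singleton_fraction undefined for an empty site list")
    return sum(1 for s in sites if s.n_total == 1) / len(sites)
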