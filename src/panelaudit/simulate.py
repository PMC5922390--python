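"""Synthetic paired tumor/normal cohorts with known ground truth.

The generator emulates the data structure of a matched tumor-normal
panel study so every pipeline stage is testable without any download:

* a germline SNP spectrum mixing cohort-common polymorphisms (carried
  with Hardy-Weinberg carrier probability 1-(1-AF)^2) and rare/private
  variants placed length-proportionally across the panel;
* somatic mutations drawn per patient, enriched in tumor-driver genes,
  with a fraction of events recurring at fixed hotspot sites;
* an incomplete population-annotation table: common sites are always
  database members, rare sites only sometimes, some database members
  lack a reported allele frequency, and somatic hotspots can be database
  members with no frequency — exercising every filter-rule branch;
* RNA allele counts with per-origin expression dropout.

Zygosity is collapsed to carrier/non-carrier: the audit never consumes
genotypes, and cohort-common detection uses carrier frequency.

Sequencing noise is off by default, making read evidence a deterministic
function of depth and allele fraction so classification tests are exact;
``sequencing_noise=True`` switches to binomial read sampling.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort_io import (
    AnnotationLookup,
    GenePanel,
    ObservedVariant,
    PopulationAnnotation,
    RnaAlleleCount,
    VariantKey,
    write_annotation_table,
    write_rna_table,
    write_variant_table,
)

_BASES = np.array(list("ACGT"))

# Recurrent somatic hotspots are concentrated in these driver genes when
# present in the panel (two sites each), mirroring common activating
# mutations in a cancer cohort.
_HOTSPOT_GENES = ["KRAS", "KRAS", "PIK3CA", "PIK3CA"]


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort.

    Defaults are chosen so that a ~600-patient cohort shows the regime a
    matched tumor-normal panel study of a cancer cohort exhibits: roughly
    95% of emitted variants germline, under one somatic event per patient
    concentrated in driver genes, a handful of cohort-common germline
    sites above the 0.02 carrier threshold, and expression dropout of
    0.18 (somatic) / 0.10 (germline).
    """

    n_patients: int = 600
    panel: GenePanel | None = None
    common_snp_count_per_gene: int = 1
    common_af_range: tuple[float, float] = (0.05, 0.40)
    rare_af_range: tuple[float, float] = (1e-5, 5e-4)
    rare_snp_rate_per_kb: float = 0.02
    somatic_rate_per_patient: float = 0.9
    driver_enrichment: float = 4.0
    hotspot_fraction: float = 0.25
    db_annotation_completeness: float = 0.6
    af_missing_given_in_db: float = 0.15
    somatic_in_db_rate: float = 0.5
    expression_dropout_somatic: float = 0.18
    expression_dropout_germline: float = 0.10
    tumor_depth_mean: int = 60
    normal_depth_mean: int = 30
    rna_depth_mean: int = 50
    germline_vaf: float = 0.5
    somatic_vaf: float = 0.4
    sequencing_noise: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.panel is None:
            self.panel = GenePanel.default()
        if len(self.panel) == 0:
            raise ValueError("empty panel")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for name in (
            "hotspot_fraction", "db_annotation_completeness", "af_missing_given_in_db",
            "somatic_in_db_rate", "expression_dropout_somatic", "expression_dropout_germline",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        for name, bounds in (("common_af_range", (0.0, 0.5)), ("rare_af_range", (0.0, 0.001))):
            lo, hi = getattr(self, name)
            if not (bounds[0] < lo <= hi <= bounds[1]):
                raise ValueError(f"{name} must be well-ordered within {bounds}, got ({lo}, {hi})")
        if min(self.rare_snp_rate_per_kb, self.somatic_rate_per_patient) < 0:
            raise ValueError("rates must be non-negative")


def default_study_config(seed: int = 0, **overrides) -> CohortConfig:
    """The packaged default study conditions (see :class:`CohortConfig`)."""
    return CohortConfig(seed=seed, **overrides)


@dataclass(frozen=True)
class TruthRecord:
    patient_id: str
    key: VariantKey
    gene: str
    true_origin: str  # germline | somatic
    true_expressed: bool
    population_af_true: float | None


@dataclass
class SyntheticCohort:
    """Generated inputs plus ground truth and the generating config."""

    config: CohortConfig
    patients: list[str]
    variants: list[ObservedVariant]  # origin left "unassigned": truth is separate
    annotations: AnnotationLookup
    rna_counts: list[RnaAlleleCount]
    truth: list[TruthRecord]
    expected_germline_fraction: float

    @property
    def truth_by_variant(self) -> dict[tuple[str, VariantKey], TruthRecord]:
        return {(t.patient_id, t.key): t for t in self.truth}

    def variants_with_truth_origin(self) -> list[ObservedVariant]:
        """Fixture-mode view: variants carrying their true origin label."""
        lookup = self.truth_by_variant
        return [v.with_origin(lookup[(v.patient_id, v.key)].true_origin) for v in self.variants]

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Emit the four flat files (variants, annotations, RNA, truth)."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "variants": out_dir / "variants.tsv",
            "annotations": out_dir / "annotations.tsv",
            "rna_counts": out_dir / "rna_counts.tsv",
            "truth": out_dir / "truth.tsv",
        }
        write_variant_table(self.variants, paths["variants"])
        write_annotation_table(self.annotations, paths["annotations"])
        write_rna_table(self.rna_counts, paths["rna_counts"])
        truth_rows = [
            {
                "patient_id": t.patient_id,
                "contig": t.key.contig,
                "pos": t.key.position,
                "ref": t.key.ref,
                "alt": t.key.alt,
                "gene": t.gene,
                "true_origin": t.true_origin,
                "true_expressed": int(t.true_expressed),
                "population_af_true": "" if t.population_af_true is None else f"{t.population_af_true:.6g}",
            }
            for t in self.truth
        ]
        pd.DataFrame(
            truth_rows,
            columns=["patient_id", "contig", "pos", "ref", "alt", "gene",
                     "true_origin", "true_expressed", "population_af_true"],
        ).to_csv(paths["truth"], sep="\t", index=False)
        return paths


class _SitePool:
    """Bookkeeping for distinct sites: keys, true AFs, annotations."""

    def __init__(self, rng: np.random.Generator) -> None:
        self.rng = rng
        self.used_positions: set[tuple[str, int]] = set()
        self.annotations: dict[VariantKey, PopulationAnnotation] = {}
        self.true_af: dict[VariantKey, float | None] = {}

    def new_key(self, panel_gene) -> VariantKey:
        contig, start, end = panel_gene.intervals[
            self.rng.integers(len(panel_gene.intervals))
        ]
        while True:
            pos = int(self.rng.integers(start, end + 1))
            if (contig, pos) not in self.used_positions:
                break
        self.used_positions.add((contig, pos))
        ref, alt = self.rng.choice(_BASES, size=2, replace=False)
        return VariantKey(contig, pos, str(ref), str(alt))


def _alt_reads(rng, depth: int, vaf: float, noise: bool) -> int:
    if noise:
        return int(rng.binomial(depth, vaf))
    return min(depth, round(depth * vaf))


def _depth(rng, mean: int, noise: bool) -> int:
    if noise:
        return max(1, int(rng.poisson(mean)))
    return mean


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate one cohort, fully reproducible from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    panel = config.panel
    pool = _SitePool(rng)
    genes = panel.genes
    cds_kb = np.array([g.cds_length for g in genes], dtype=float) / 1000.0
    total_kb = float(cds_kb.sum())

    # --- fixed site pools -------------------------------------------------
    common_sites: list[tuple[VariantKey, str, float]] = []  # (key, gene, af)
    for g in genes:
        for _ in range(config.common_snp_count_per_gene):
            key = pool.new_key(g)
            af = float(rng.uniform(*config.common_af_range))
            common_sites.append((key, g.gene, af))
            pool.true_af[key] = af
            # Cohort-common polymorphisms are always database members;
            # some lack a reported frequency (rescue-rule path).
            af_absent = rng.random() < config.af_missing_given_in_db
            pool.annotations[key] = PopulationAnnotation(
                key=key, in_database=True, population_af=None if af_absent else af
            )

    hotspot_genes = [g for g in _HOTSPOT_GENES if g in panel]
    if not hotspot_genes:  # fall back to the largest driver genes
        drivers = sorted(panel.genes_in_class("tumor_driver"),
                         key=lambda g: -g.cds_length)[:2] or genes[:2]
        hotspot_genes = [g.gene for g in drivers for _ in range(2)]
    hotspots: list[tuple[VariantKey, str]] = []
    for gene_name in hotspot_genes:
        key = pool.new_key(panel[gene_name])
        hotspots.append((key, gene_name))
        pool.true_af[key] = None
        in_db = rng.random() < config.somatic_in_db_rate
        pool.annotations[key] = PopulationAnnotation(key=key, in_database=in_db,
                                                     population_af=None)

    def register_rare_germline(key: VariantKey) -> None:
        if key in pool.true_af:
            return
        af = float(rng.uniform(*config.rare_af_range))
        pool.true_af[key] = af
        in_db = rng.random() < config.db_annotation_completeness
        af_absent = (not in_db) or rng.random() < config.af_missing_given_in_db
        pool.annotations[key] = PopulationAnnotation(
            key=key, in_database=in_db, population_af=None if af_absent else af
        )

    # Somatic gene weights: CDS-length proportional with driver enrichment.
    somatic_w = np.array(
        [
            g.cds_length * (config.driver_enrichment if g.panel_class == "tumor_driver" else 1.0)
            for g in genes
        ],
        dtype=float,
    )
    somatic_w /= somatic_w.sum()
    rare_w = cds_kb / total_kb

    # --- per-patient sampling --------------------------------------------
    width = max(3, len(str(config.n_patients)))
    patients = [f"P{i + 1:0{width}d}" for i in range(config.n_patients)]
    variants: list[ObservedVariant] = []
    truth: list[TruthRecord] = []
    rna_counts: list[RnaAlleleCount] = []
    noise = config.sequencing_noise

    for patient in patients:
        seen: set[VariantKey] = set()
        events: list[tuple[VariantKey, str, str]] = []  # (key, gene, origin)

        for key, gene, af in common_sites:
            carrier_p = 1.0 - (1.0 - af) ** 2
            if rng.random() < carrier_p:
                events.append((key, gene, "germline"))

        n_rare = rng.poisson(config.rare_snp_rate_per_kb * total_kb)
        for idx in rng.choice(len(genes), size=n_rare, p=rare_w):
            g = genes[int(idx)]
            key = pool.new_key(g)
            register_rare_germline(key)
            events.append((key, g.gene, "germline"))

        n_somatic = rng.poisson(config.somatic_rate_per_patient)
        for _ in range(n_somatic):
            if hotspots and rng.random() < config.hotspot_fraction:
                key, gene = hotspots[int(rng.integers(len(hotspots)))]
            else:
                g = genes[int(rng.choice(len(genes), p=somatic_w))]
                key = pool.new_key(g)
                gene = g.gene
                if key not in pool.true_af:
                    pool.true_af[key] = None
                    pool.annotations[key] = PopulationAnnotation(
                        key=key, in_database=False, population_af=None
                    )
            events.append((key, gene, "somatic"))

        for key, gene, origin in events:
            if key in seen:
                continue
            seen.add(key)
            t_depth = _depth(rng, config.tumor_depth_mean, noise)
            n_depth = _depth(rng, config.normal_depth_mean, noise)
            if origin == "germline":
                t_alt = _alt_reads(rng, t_depth, config.germline_vaf, noise)
                n_alt = _alt_reads(rng, n_depth, config.germline_vaf, noise)
            else:
                t_alt = _alt_reads(rng, t_depth, config.somatic_vaf, noise)
                # residual normal-tissue alt reads only under noise
                n_alt = int(rng.binomial(n_depth, 0.001)) if noise else 0
            consequence = "nonsense" if rng.random() < 0.1 else "missense"
            variants.append(
                ObservedVariant(
                    patient_id=patient, key=key, gene=gene, consequence=consequence,
                    tumor_depth=t_depth, tumor_alt=t_alt,
                    normal_depth=n_depth, normal_alt=n_alt,
                )
            )
            dropout_p = (
                config.expression_dropout_germline if origin == "germline"
                else config.expression_dropout_somatic
            )
            expressed = rng.random() >= dropout_p
            rna_depth = _depth(rng, config.rna_depth_mean, noise)
            vaf = config.germline_vaf if origin == "germline" else config.somatic_vaf
            rna_alt = _alt_reads(rng, rna_depth, vaf, noise) if expressed else 0
            rna_counts.append(RnaAlleleCount(patient, key, rna_depth, rna_alt))
            truth.append(
                TruthRecord(
                    patient_id=patient, key=key, gene=gene, true_origin=origin,
                    true_expressed=expressed, population_af_true=pool.true_af[key],
                )
            )

    # Expected germline share from the realized study conditions: common
    # carrier probabilities plus the rare rate, against the somatic rate.
    e_common = sum(1.0 - (1.0 - af) ** 2 for _, _, af in common_sites)
    e_germline = e_common + config.rare_snp_rate_per_kb * total_kb
    e_total = e_germline + config.somatic_rate_per_patient
    return SyntheticCohort(
        config=config,
        patients=patients,
        variants=variants,
        annotations=AnnotationLookup(pool.annotations.values()),
        rna_counts=rna_counts,
        truth=truth,
        expected_germline_fraction=e_germline / e_total,
    )
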