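"""Domain types and file IO for paired tumor/normal panel cohorts.

All coordinates are 1-based; panel intervals are closed on both ends
(VCF convention).  The analysis is restricted to single-nucleotide
variants: indels found in VCF input are dropped with a logged count.

External formats handled here:

* VCF v4.x (tumor and normal single-sample files) via :mod:`pysam`.
* Flat tab-separated tables for variants, population annotations, RNA
  allele counts and the gene→drug map, with fixed documented headers.
* YAML panel configuration (packaged default: the 35-gene panel split
  into 25 tumor-driver and 10 inherited-risk genes).
"""
from __future__ import annotations

import importlib.resources
import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import pysam
import yaml

logger = logging.getLogger(__name__)

_BASES = frozenset("ACGT")

VALID_ORIGINS = ("germline", "somatic", "unassigned", "ambiguous")
VALID_CONSEQUENCES = ("missense", "nonsense", "other")


@dataclass(frozen=True, order=True)
class VariantKey:
    """Genomic identity of an SNV: contig, 1-based position, ref and alt base.

    Two keys are equal iff all four fields are equal; unique-site
    collapsing across patients uses this identity.
    """

    contig: str
    position: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError(f"SNVs only: ref={self.ref!r} alt={self.alt!r}")
        if self.ref not in _BASES or self.alt not in _BASES:
            raise ValueError(f"ref/alt must be uppercase DNA bases, got {self.ref!r}>{self.alt!r}")
        if self.ref == self.alt:
            raise ValueError(f"alt must differ from ref at {self.contig}:{self.position}")
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.contig}:{self.position}{self.ref}>{self.alt}"


@dataclass
class ObservedVariant:
    """One patient's SNV with tumor/normal read evidence and assigned origin.

    ``origin`` stays ``"unassigned"`` until classification runs (or the
    input carries a trusted origin column in fixture mode).  Only
    missense/nonsense variants enter downstream tallies.
    """

    patient_id: str
    key: VariantKey
    gene: str
    consequence: str
    tumor_depth: int
    tumor_alt: int
    normal_depth: int
    normal_alt: int
    origin: str = "unassigned"

    def __post_init__(self) -> None:
        if not (0 <= self.tumor_alt <= self.tumor_depth):
            raise ValueError(
                f"tumor_alt must satisfy 0 <= {self.tumor_alt} <= {self.tumor_depth} "
                f"({self.patient_id} {self.key})"
            )
        if not (0 <= self.normal_alt <= self.normal_depth):
            raise ValueError(
                f"normal_alt must satisfy 0 <= {self.normal_alt} <= {self.normal_depth} "
                f"({self.patient_id} {self.key})"
            )
        if self.consequence not in VALID_CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")
        if self.origin not in VALID_ORIGINS:
            raise ValueError(f"unknown origin {self.origin!r}")

    @property
    def tumor_vaf(self) -> float:
        return self.tumor_alt / self.tumor_depth if self.tumor_depth else 0.0

    @property
    def normal_vaf(self) -> float:
        return self.normal_alt / self.normal_depth if self.normal_depth else 0.0

    def with_origin(self, origin: str) -> "ObservedVariant":
        return replace(self, origin=origin)


@dataclass(frozen=True)
class PopulationAnnotation:
    """Database membership plus optional population allele frequency.

    An absent AF (``None``) is distinct from AF = 0: the extra removal
    rule for cohort-common variants applies only to variants with *no
    reported* population allele frequency.
    """

    key: VariantKey
    in_database: bool
    population_af: float | None = None

    def __post_init__(self) -> None:
        if self.population_af is not None:
            if not self.in_database:
                raise ValueError(f"AF present implies a database record ({self.key})")
            if not 0.0 <= self.population_af <= 1.0:
                raise ValueError(f"population_af outside [0,1]: {self.population_af}")


class AnnotationLookup:
    """Total lookup from :class:`VariantKey` to :class:`PopulationAnnotation`.

    Misses return a "not in database, AF absent" annotation rather than
    raising, so filters can treat every variant uniformly.
    """

    def __init__(self, annotations: Iterable[PopulationAnnotation] = ()) -> None:
        self._table: dict[VariantKey, PopulationAnnotation] = {}
        for ann in annotations:
            if ann.key in self._table:
                raise ValueError(f"duplicate annotation for {ann.key}")
            self._table[ann.key] = ann

    def __len__(self) -> int:
        return len(self._table)

    def __contains__(self, key: VariantKey) -> bool:
        return key in self._table

    def __iter__(self):
        return iter(self._table.values())

    def get(self, key: VariantKey) -> PopulationAnnotation:
        ann = self._table.get(key)
        if ann is None:
            return PopulationAnnotation(key=key, in_database=False, population_af=None)
        return ann


@dataclass(frozen=True)
class PanelGene:
    gene: str
    panel_class: str
    cds_length: int
    intervals: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        if self.panel_class not in ("tumor_driver", "inherited_risk"):
            raise ValueError(f"unknown panel class {self.panel_class!r} for {self.gene}")
        if not self.intervals:
            raise ValueError(f"gene {self.gene} has no intervals")
        for contig, start, end in self.intervals:
            if start > end or start < 1:
                raise ValueError(f"bad interval {contig}:{start}-{end} for {self.gene}")
        if self.cds_length < 1:
            raise ValueError(f"cds_length must be positive for {self.gene}")


class GenePanel:
    """Gene panel: symbols, panel class, CDS length and genomic intervals."""

    def __init__(self, genes: Iterable[PanelGene]) -> None:
        self.genes: list[PanelGene] = list(genes)
        seen: set[str] = set()
        for g in self.genes:
            if g.gene in seen:
                raise ValueError(f"duplicate panel entry for {g.gene}")
            seen.add(g.gene)
        self._by_name = {g.gene: g for g in self.genes}

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self._by_name

    def __getitem__(self, gene: str) -> PanelGene:
        return self._by_name[gene]

    @property
    def gene_names(self) -> list[str]:
        return [g.gene for g in self.genes]

    def genes_in_class(self, panel_class: str) -> list[PanelGene]:
        return [g for g in self.genes if g.panel_class == panel_class]

    @property
    def contigs(self) -> set[str]:
        return {contig for g in self.genes for contig, _, _ in g.intervals}

    def gene_at(self, contig: str, position: int) -> str | None:
        """Return the panel gene covering ``contig:position``, or None.

        Panels are small (tens of genes, one or two intervals each), so a
        linear scan is fine and keeps interval semantics explicit.
        """
        for g in self.genes:
            for ctg, start, end in g.intervals:
                if ctg == contig and start <= position <= end:
                    return g.gene
        return None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GenePanel":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls._from_mapping(raw)

    @classmethod
    def _from_mapping(cls, raw: Mapping) -> "GenePanel":
        genes = []
        for entry in raw["genes"]:
            genes.append(
                PanelGene(
                    gene=entry["gene"],
                    panel_class=entry["class"],
                    cds_length=int(entry["cds_length"]),
                    intervals=tuple(
                        (str(c), int(s), int(e)) for c, s, e in entry["intervals"]
                    ),
                )
            )
        return cls(genes)

    @classmethod
    def default(cls) -> "GenePanel":
        """The packaged 35-gene panel (25 tumor-driver + 10 inherited-risk)."""
        ref = importlib.resources.files("panelaudit.data") / "panel_35gene.yaml"
        return cls._from_mapping(yaml.safe_load(ref.read_text()))


class DrugTargetMap:
    """Gene symbol → non-empty list of drugs directly targeting it."""

    def __init__(self, entries: Mapping[str, Iterable[str]]) -> None:
        self.entries: dict[str, list[str]] = {}
        for gene, drugs in entries.items():
            drugs = list(drugs)
            if not drugs:
                raise ValueError(f"gene {gene} has an empty drug list")
            self.entries[gene] = drugs

    def __contains__(self, gene: str) -> bool:
        return gene in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def genes(self) -> list[str]:
        return sorted(self.entries)

    @classmethod
    def from_tsv(cls, path) -> "DrugTargetMap":
        df = pd.read_csv(path, sep="\t", dtype=str)
        return cls({row.gene: row.drugs.split(";") for row in df.itertuples()})

    @classmethod
    def default(cls) -> "DrugTargetMap":
        """The packaged 12-gene druggable panel subset."""
        ref = importlib.resources.files("panelaudit.data") / "drug_targets.tsv"
        with importlib.resources.as_file(ref) as path:
            return cls.from_tsv(path)


@dataclass(frozen=True)
class RnaAlleleCount:
    """RNA-seq read support at one variant locus in one patient."""

    patient_id: str
    key: VariantKey
    rna_depth: int
    rna_alt: int

    def __post_init__(self) -> None:
        if not (0 <= self.rna_alt <= self.rna_depth):
            raise ValueError(
                f"rna_alt must satisfy 0 <= {self.rna_alt} <= {self.rna_depth}"
            )


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

VARIANT_TABLE_COLUMNS = [
    "patient_id", "contig", "pos", "ref", "alt", "gene", "consequence",
    "tumor_depth", "tumor_alt", "normal_depth", "normal_alt",
]

_COUNT_COLUMNS = ["tumor_depth", "tumor_alt", "normal_depth", "normal_alt"]


def _strip_chr(contig: str) -> str:
    return contig[3:] if contig.startswith("chr") else contig


def _check_contig_compatibility(tumor_contigs: set[str], normal_contigs: set[str]) -> None:
    """Raise on chr-prefix style mismatch between the two files."""
    if not tumor_contigs or not normal_contigs:
        return
    if tumor_contigs & normal_contigs:
        return
    if {_strip_chr(c) for c in tumor_contigs} & {_strip_chr(c) for c in normal_contigs}:
        raise ValueError(
            "contig naming mismatch between tumor and normal files "
            f"(e.g. {sorted(tumor_contigs)[0]!r} vs {sorted(normal_contigs)[0]!r}); "
            "enable chr-prefix normalization explicitly if intended"
        )


def _record_allele_depths(rec: pysam.VariantRecord) -> tuple[int, dict[str, int]]:
    """Return (total depth, alt base → supporting reads) for a VCF record.

    Uses sample AD when present, falling back to DP with zero alt support.
    """
    depth = 0
    alt_support: dict[str, int] = {}
    sample = rec.samples[0] if rec.samples else None
    ad = sample.get("AD") if sample is not None else None
    if ad is not None and ad[0] is not None:
        depth = int(sum(a for a in ad if a is not None))
        for alt, a in zip(rec.alts or (), ad[1:]):
            alt_support[alt] = int(a) if a is not None else 0
    else:
        dp = None
        if sample is not None:
            dp = sample.get("DP")
        if dp is None:
            dp = rec.info.get("DP")
        depth = int(dp) if dp is not None else 0
        for alt in rec.alts or ():
            alt_support[alt] = 0
    return depth, alt_support


def read_paired_vcf(
    tumor_path: str | Path,
    normal_path: str | Path,
    panel: GenePanel,
    consequence_tag: str = "CSQCLASS",
    normalize_chr_prefix: bool = False,
) -> list[ObservedVariant]:
    """Read matched tumor and normal single-sample VCFs into ObservedVariants.

    Only SNV records falling inside panel intervals are returned.
    Multi-allelic records are split into one variant per alt allele;
    indel alleles are dropped with a logged count.  A site absent from
    the normal file gets zero normal evidence.  Consequence is consumed
    from the INFO tag named by ``consequence_tag`` (default other).
    """

    def load(path):
        entries: dict[tuple[str, int, str, str], tuple[int, int]] = {}
        contigs: set[str] = set()
        dropped_indels = 0
        with pysam.VariantFile(str(path)) as vcf:
            patient = list(vcf.header.samples)[0] if list(vcf.header.samples) else Path(path).stem
            consequences: dict[tuple[str, int, str, str], str] = {}
            for rec in vcf:
                contig = rec.contig
                if normalize_chr_prefix:
                    contig = _strip_chr(contig)
                contigs.add(contig)
                depth, alt_support = _record_allele_depths(rec)
                csq = rec.info.get(consequence_tag)
                if isinstance(csq, tuple):
                    csq = csq[0]
                for alt in rec.alts or ():
                    if len(rec.ref) != 1 or len(alt) != 1 or alt == "*":
                        dropped_indels += 1
                        continue
                    k = (contig, rec.pos, rec.ref.upper(), alt.upper())
                    entries[k] = (depth, alt_support.get(alt, 0))
                    consequences[k] = str(csq) if csq is not None else "other"
        if dropped_indels:
            logger.info("dropped %d non-SNV alleles from %s", dropped_indels, path)
        return patient, entries, consequences, contigs

    patient_id, tumor, tumor_csq, tumor_contigs = load(tumor_path)
    _, normal, _, normal_contigs = load(normal_path)
    _check_contig_compatibility(tumor_contigs, normal_contigs)

    variants = []
    for (contig, pos, ref, alt), (t_depth, t_alt) in tumor.items():
        gene = panel.gene_at(contig, pos)
        if gene is None:
            continue
        n_depth, n_alt = normal.get((contig, pos, ref, alt), (0, 0))
        csq = tumor_csq[(contig, pos, ref, alt)]
        variants.append(
            ObservedVariant(
                patient_id=patient_id,
                key=VariantKey(contig, pos, ref, alt),
                gene=gene,
                consequence=csq if csq in VALID_CONSEQUENCES else "other",
                tumor_depth=t_depth,
                tumor_alt=min(t_alt, t_depth),
                normal_depth=n_depth,
                normal_alt=min(n_alt, n_depth),
            )
        )
    variants.sort(key=lambda v: (v.key, v.patient_id))
    return variants


def read_variant_table(path: str | Path, panel: GenePanel) -> list[ObservedVariant]:
    """Read the flat per-patient variant table (tab-separated, with header).

    Columns: patient_id, contig, pos, ref, alt, gene, consequence,
    tumor_depth, tumor_alt, normal_depth, normal_alt.  An optional
    ``origin`` column (fixture mode / synthetic truth) is consumed
    directly when present.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in VARIANT_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"variant table {path} missing columns: {missing}")

    for col in _COUNT_COLUMNS + ["pos"]:
        bad = df[~df[col].str.fullmatch(r"\d+")]
        if len(bad):
            raise ValueError(
                f"non-integer values in column {col!r} of {path} "
                f"(rows {bad.index.tolist()[:5]})"
            )
        df[col] = df[col].astype(int)

    unknown = df[~df["gene"].isin(panel.gene_names)]
    if len(unknown):
        offenders = unknown[["patient_id", "gene"]].drop_duplicates()
        raise ValueError(
            f"gene symbols not in the {len(panel)}-gene panel: "
            + ", ".join(f"{r.gene} ({r.patient_id})" for r in offenders.itertuples())
        )

    has_origin = "origin" in df.columns
    variants = []
    for row in df.itertuples():
        variants.append(
            ObservedVariant(
                patient_id=row.patient_id,
                key=VariantKey(row.contig, int(row.pos), row.ref, row.alt),
                gene=row.gene,
                consequence=row.consequence,
                tumor_depth=row.tumor_depth,
                tumor_alt=row.tumor_alt,
                normal_depth=row.normal_depth,
                normal_alt=row.normal_alt,
                origin=row.origin if has_origin else "unassigned",
            )
        )
    return variants


def read_annotation_table(path: str | Path) -> AnnotationLookup:
    """Read the population annotation table into a total lookup.

    Columns: contig, pos, ref, alt, in_database (0/1), population_af
    (empty field = no reported frequency).  Duplicate keys are rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["contig", "pos", "ref", "alt", "in_database", "population_af"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"annotation table {path} missing columns: {missing}")
    annotations = []
    for row in df.itertuples():
        af = None if pd.isna(row.population_af) or row.population_af == "" else float(row.population_af)
        annotations.append(
            PopulationAnnotation(
                key=VariantKey(row.contig, int(row.pos), row.ref, row.alt),
                in_database=row.in_database in ("1", "true", "True"),
                population_af=af,
            )
        )
    return AnnotationLookup(annotations)


def read_rna_table(path: str | Path) -> list[RnaAlleleCount]:
    """Read per-locus RNA allele counts (patient_id, contig, pos, ref, alt,
    rna_depth, rna_alt)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    counts = []
    for row in df.itertuples():
        counts.append(
            RnaAlleleCount(
                patient_id=row.patient_id,
                key=VariantKey(row.contig, int(row.pos), row.ref, row.alt),
                rna_depth=int(row.rna_depth),
                rna_alt=int(row.rna_alt),
            )
        )
    return counts


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def variants_to_frame(variants: Iterable[ObservedVariant], include_origin: bool = True) -> pd.DataFrame:
    rows = []
    for v in variants:
        row = {
            "patient_id": v.patient_id,
            "contig": v.key.contig,
            "pos": v.key.position,
            "ref": v.key.ref,
            "alt": v.key.alt,
            "gene": v.gene,
            "consequence": v.consequence,
            "tumor_depth": v.tumor_depth,
            "tumor_alt": v.tumor_alt,
            "normal_depth": v.normal_depth,
            "normal_alt": v.normal_alt,
        }
        if include_origin:
            row["origin"] = v.origin
        rows.append(row)
    cols = VARIANT_TABLE_COLUMNS + (["origin"] if include_origin else [])
    return pd.DataFrame(rows, columns=cols)


def write_variant_table(variants: Iterable[ObservedVariant], path: str | Path,
                        include_origin: bool = False) -> None:
    variants_to_frame(variants, include_origin=include_origin).to_csv(
        path, sep="\t", index=False
    )


def write_annotation_table(lookup: AnnotationLookup, path: str | Path) -> None:
    rows = [
        {
            "contig": a.key.contig,
            "pos": a.key.position,
            "ref": a.key.ref,
            "alt": a.key.alt,
            "in_database": int(a.in_database),
            "population_af": "" if a.population_af is None else f"{a.population_af:.6g}",
        }
        for a in sorted(lookup, key=lambda a: a.key)
    ]
    pd.DataFrame(rows, columns=["contig", "pos", "ref", "alt", "in_database", "population_af"]).to_csv(
        path, sep="\t", index=False
    )


def write_rna_table(counts: Iterable[RnaAlleleCount], path: str | Path) -> None:
    rows = [
        {
            "patient_id": c.patient_id,
            "contig": c.key.contig,
            "pos": c.key.position,
            "ref": c.key.ref,
            "alt": c.key.alt,
            "rna_depth": c.rna_depth,
            "rna_alt": c.rna_alt,
        }
        for c in counts
    ]
    pd.DataFrame(
        rows, columns=["patient_id", "contig", "pos", "ref", "alt", "rna_depth", "rna_alt"]
    ).to_csv(path, sep="\t", index=False)


def write_report_tables(results: Mapping[str, object], out_dir: str | Path) -> list[Path]:
    """Write a report bundle to ``out_dir`` as byte-stable TSV/JSON files.

    ``results`` maps table name → DataFrame, plus an optional ``summary``
    entry (a JSON-serializable mapping).  Returns the written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name in sorted(results):
        obj = results[name]
        if name == "summary":
            path = out_dir / "summary.json"
            path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
        else:
            path = out_dir / f"{name}.tsv"
            assert isinstance(obj, pd.DataFrame)
            obj.to_csv(path, sep="\t", index=False)
        written.append(path)
    return written
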