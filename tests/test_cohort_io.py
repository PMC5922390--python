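import pandas as pd
import pytest

from panelaudit.cohort_io import (
    AnnotationLookup,
    DrugTargetMap,
    GenePanel,
    PopulationAnnotation,
    VariantKey,
    read_annotation_table,
    read_paired_vcf,
    read_variant_table,
    write_report_tables,
    write_variant_table,
)

from conftest import make_variant

VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=chr7>
##contig=<ID=7>
##INFO=<ID=CSQCLASS,Number=1,Type=String,Description="Consequence class">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}
"""


def _vcf(tmp_path, name, sample, records):
    path = tmp_path / name
    path.write_text(VCF_HEADER.format(sample=sample) + "".join(r + "\n" for r in records))
    return path


@pytest.fixture
def vcf_pair(tmp_path):
    tumor = _vcf(
        tmp_path,
        "tumor.vcf",
        "TUMOR1",
        [
            # EGFR site present in both files
            "chr7\t55249071\t.\tC\tT\t.\t.\tCSQCLASS=missense\tGT:AD:DP\t0/1:36,24:60",
            # multi-allelic EGFR site absent from the normal
            "chr7\t55249100\t.\tC\tT,G\t.\t.\tCSQCLASS=nonsense\tGT:AD:DP\t0/1:30,20,10:60",
            # outside every panel interval
            "chr7\t1000000\t.\tA\tG\t.\t.\tCSQCLASS=missense\tGT:AD:DP\t0/1:30,30:60",
            # indel: parsed but dropped
            "chr7\t55249200\t.\tAG\tA\t.\t.\tCSQCLASS=other\tGT:AD:DP\t0/1:30,30:60",
        ],
    )
    normal = _vcf(
        tmp_path,
        "normal.vcf",
        "NORMAL1",
        ["chr7\t55249071\t.\tC\tT\t.\t.\t.\tGT:AD:DP\t0/1:15,15:30"],
    )
    return tumor, normal


class TestVariantKey:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(contig="chr1", position=5, ref="AG", alt="A"),  # indel
            dict(contig="chr1", position=5, ref="A", alt="A"),  # alt == ref
            dict(contig="chr1", position=0, ref="A", alt="G"),  # 1-based
            dict(contig="chr1", position=5, ref="N", alt="G"),  # not a base
        ],
    )
    def test_rejects_non_snv_identities(self, kwargs):
        with pytest.raises(ValueError):
            VariantKey(**kwargs)

    def test_equality_uses_all_four_fields(self):
        a = VariantKey("chr1", 5, "A", "G")
        assert a == VariantKey("chr1", 5, "A", "G")
        assert a != VariantKey("chr1", 5, "A", "T")
        assert a != VariantKey("chr2", 5, "A", "G")


class TestPairedVcf:
    def test_panel_restriction_split_and_normal_defaults(self, vcf_pair, panel):
        variants = read_paired_vcf(*vcf_pair, panel)
        # 1 shared SNV + 2 from the multi-allelic split; off-panel and
        # indel records never surface.
        assert len(variants) == 3
        by_key = {v.key: v for v in variants}
        shared = by_key[VariantKey("chr7", 55249071, "C", "T")]
        assert (shared.normal_depth, shared.normal_alt) == (30, 15)
        assert shared.consequence == "missense"
        assert shared.origin == "unassigned"
        split = [v for v in variants if v.key.position == 55249100]
        assert {v.key.alt for v in split} == {"T", "G"}
        assert [v.tumor_alt for v in sorted(split, key=lambda v: v.key.alt)] == [10, 20]
        for v in split:
            assert (v.normal_depth, v.normal_alt) == (0, 0)
            assert v.gene == "EGFR"

    def test_contig_naming_mismatch_is_an_error(self, tmp_path, panel):
        tumor = _vcf(
            tmp_path, "t.vcf", "T",
            ["chr7\t55249071\t.\tC\tT\t.\t.\t.\tGT:AD:DP\t0/1:36,24:60"],
        )
        normal = _vcf(
            tmp_path, "n.vcf", "N",
            ["7\t55249071\t.\tC\tT\t.\t.\t.\tGT:AD:DP\t0/1:15,15:30"],
        )
        with pytest.raises(ValueError, match="contig naming mismatch"):
            read_paired_vcf(tumor, normal, panel)

    def test_vcf_and_flat_table_agree_on_equivalent_content(self, vcf_pair, tmp_path, panel):
        from_vcf = read_paired_vcf(*vcf_pair, panel)
        table = tmp_path / "variants.tsv"
        write_variant_table(from_vcf, table)
        from_table = read_variant_table(table, panel)
        assert sorted(from_table, key=lambda v: v.key) == from_vcf


class TestVariantTable:
    def test_reads_valid_rows(self, tmp_path, panel):
        table = tmp_path / "v.tsv"
        write_variant_table([make_variant(patient=p) for p in ("P1", "P2", "P3")], table)
        assert len(read_variant_table(table, panel)) == 3

    def test_unknown_gene_is_an_error(self, tmp_path, panel):
        table = tmp_path / "v.tsv"
        v = make_variant()
        v.gene = "TP53"
        write_variant_table([v], table)
        with pytest.raises(ValueError, match="TP53"):
            read_variant_table(table, panel)

    def test_non_integer_counts_are_an_error(self, tmp_path, panel):
        table = tmp_path / "v.tsv"
        write_variant_table([make_variant()], table)
        df = pd.read_csv(table, sep="\t", dtype=str)
        df.loc[0, "tumor_alt"] = "many"
        df.to_csv(table, sep="\t", index=False)
        with pytest.raises(ValueError, match="tumor_alt"):
            read_variant_table(table, panel)

    def test_alt_exceeding_depth_violates_invariant(self, tmp_path, panel):
        table = tmp_path / "v.tsv"
        write_variant_table([make_variant()], table)
        df = pd.read_csv(table, sep="\t", dtype=str)
        df.loc[0, "tumor_alt"] = "100"
        df.to_csv(table, sep="\t", index=False)
        with pytest.raises(ValueError, match="tumor_alt"):
            read_variant_table(table, panel)


class TestAnnotationTable:
    HEADER = "contig\tpos\tref\talt\tin_database\tpopulation_af\n"

    def _read(self, tmp_path, rows):
        path = tmp_path / "ann.tsv"
        path.write_text(self.HEADER + "".join(r + "\n" for r in rows))
        return read_annotation_table(path)

    def test_af_and_membership_round_trip(self, tmp_path):
        lookup = self._read(tmp_path, ["chr1\t100\tA\tG\t1\t0.25", "chr1\t200\tC\tT\t1\t"])
        with_af = lookup.get(VariantKey("chr1", 100, "A", "G"))
        assert (with_af.in_database, with_af.population_af) == (True, 0.25)
        af_absent = lookup.get(VariantKey("chr1", 200, "C", "T"))
        assert af_absent.in_database and af_absent.population_af is None

    def test_lookup_miss_returns_not_in_database(self, tmp_path):
        lookup = self._read(tmp_path, [])
        miss = lookup.get(VariantKey("chr9", 5, "A", "T"))
        assert not miss.in_database and miss.population_af is None

    def test_duplicate_key_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="duplicate"):
            self._read(tmp_path, ["chr1\t100\tA\tG\t1\t0.25", "chr1\t100\tA\tG\t1\t0.30"])

    def test_af_without_database_membership_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="database record"):
            self._read(tmp_path, ["chr1\t100\tA\tG\t0\t0.25"])

    def test_af_outside_unit_interval_rejected(self, tmp_path):
        with pytest.raises(ValueError, match=r"\[0,1\]"):
            self._read(tmp_path, ["chr1\t100\tA\tG\t1\t1.5"])


class TestPackagedFixtures:
    def test_default_panel_composition(self, panel):
        assert len(panel) == 35
        assert len(panel.genes_in_class("tumor_driver")) == 25
        assert len(panel.genes_in_class("inherited_risk")) == 10
        assert panel.gene_at("chr7", 55249071) == "EGFR"
        assert panel.gene_at("chr7", 1) is None

    def test_default_drug_map_has_twelve_genes(self):
        drug_map = DrugTargetMap.default()
        assert drug_map.genes == [
            "ALK", "BRAF", "DNMT3A", "EGFR", "ERBB2", "JAK2",
            "KIT", "MET", "PDGFRA", "PDGFRB", "PIK3CA", "RET",
        ]
        assert all(drug_map.entries[g] for g in drug_map.genes)


class TestReportWriting:
    def test_byte_stable_and_empty_safe(self, tmp_path):
        bundle = {
            "per_gene": pd.DataFrame({"gene": ["EGFR"], "n": [3]}),
            "empty": pd.DataFrame(columns=["gene", "n"]),
            "summary": {"fraction": 0.5},
        }
        first = write_report_tables(bundle, tmp_path / "a")
        second = write_report_tables(bundle, tmp_path / "b")
        for p1, p2 in zip(first, second):
            assert p1.read_bytes() == p2.read_bytes()
        empty = (tmp_path / "a" / "empty.tsv").read_text()
        assert empty == "gene\tn\n"
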