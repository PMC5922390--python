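import random

import pytest

from panelaudit.cohort_io import (
    AnnotationLookup,
    DrugTargetMap,
    PopulationAnnotation,
    VariantKey,
)
from panelaudit.filters import (
    AF_0001_REGIME,
    AF_001_REGIME,
    DBSNP_REGIME,
    ConfusionTally,
    FilterRegime,
    apply_filter,
    druggable_impact,
    false_positive_rate,
    per_patient_burden,
    standard_regimes,
    tally,
)

from conftest import make_variant


def annotate(variant, in_database, population_af=None):
    return PopulationAnnotation(
        key=variant.key, in_database=in_database, population_af=population_af
    )


class TestFilterRegime:
    def test_af_regime_requires_cutoff(self):
        with pytest.raises(ValueError, match="af_cutoff"):
            FilterRegime("af_threshold")

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            FilterRegime("blacklist")

    def test_standard_regimes_cover_the_three_filters(self):
        assert [r.name for r in standard_regimes()] == ["dbsnp", "af_0.01", "af_0.001"]


class TestApplyFilter:
    def test_common_germline_snp_removed_by_af_regimes(self):
        v = make_variant(origin="germline")
        lookup = AnnotationLookup([annotate(v, True, 0.30)])
        for regime in (AF_001_REGIME, AF_0001_REGIME):
            retained, removed = apply_filter([v], lookup, regime)
            assert (retained, removed) == ([], [v])

    def test_somatic_hotspot_in_db_without_af_survives_af_regime(self):
        v = make_variant(origin="somatic")
        lookup = AnnotationLookup([annotate(v, True, None)])
        retained, removed = apply_filter([v], lookup, AF_0001_REGIME, cohort_common_keys=set())
        assert retained == [v] and removed == []

    def test_rescue_rule_removes_cohort_common_db_member_without_af(self):
        v = make_variant(origin="germline")
        lookup = AnnotationLookup([annotate(v, True, None)])
        retained, removed = apply_filter([v], lookup, AF_0001_REGIME, {v.key})
        assert retained == [] and removed == [v]
        # same variant survives when the rescue rule is disabled
        no_rescue = FilterRegime("af_threshold", af_cutoff=0.001, rescue_rule_enabled=False)
        retained, removed = apply_filter([v], lookup, no_rescue, {v.key})
        assert retained == [v]

    def test_af_absent_and_not_in_db_always_retained_by_af_regimes(self):
        v = make_variant(origin="germline")
        lookup = AnnotationLookup([])  # lookup miss: not in database
        retained, _ = apply_filter([v], lookup, AF_0001_REGIME, {v.key})
        assert retained == [v]

    def test_database_membership_removes_every_db_member(self):
        germ = make_variant(patient="P1", origin="germline")
        som = make_variant(patient="P2", origin="somatic")
        lookup = AnnotationLookup(
            [annotate(germ, True, 0.3)]  # somatic key identical -> also a member
        )
        retained, removed = apply_filter([germ, som], lookup, DBSNP_REGIME)
        assert retained == [] and set(v.patient_id for v in removed) == {"P1", "P2"}


class TestTally:
    def test_no_filter_baseline_matches_input_composition(self):
        variants = [make_variant(patient=f"P{i}", origin="germline") for i in range(7)] + [
            make_variant(patient=f"P{i + 7}", origin="somatic") for i in range(3)
        ]
        t = tally(variants, [], "cohort")
        assert (t.true_positive, t.false_positive, t.false_negative) == (3, 7, 0)
        assert t.germline_input == 7 and t.somatic_input == 3

    def test_unlabeled_variant_is_an_error(self):
        with pytest.raises(ValueError, match="origin"):
            tally([make_variant(origin="ambiguous")], [], "cohort")

    def test_gene_scope_tallies_sum_to_cohort(self, small_cohort):
        from panelaudit.origin import classify_cohort, collapse_sites, common_germline_keys, informative

        labeled, _ = classify_cohort(small_cohort.variants)
        usable = informative(labeled)
        sites = collapse_sites(usable, len(small_cohort.patients))
        common = common_germline_keys(sites)
        for regime in standard_regimes():
            retained, removed = apply_filter(usable, small_cohort.annotations, regime, common)
            cohort_t = tally(retained, removed, "cohort")
            gene_ts = tally(retained, removed, "gene")
            for field in ("true_positive", "false_positive", "false_negative", "germline_removed"):
                assert sum(getattr(t, field) for t in gene_ts) == getattr(cohort_t, field)


class TestFalsePositiveRate:
    def test_retained_denominator(self):
        t = ConfusionTally("cohort", "cohort", true_positive=45, false_positive=41)
        assert false_positive_rate(t, "retained") == pytest.approx(41 / 86)

    def test_total_denominator(self):
        t = ConfusionTally(
            "cohort", "cohort", true_positive=45, false_positive=701, false_negative=0
        )
        assert false_positive_rate(t, "total") == pytest.approx(701 / 746)

    def test_zero_false_positives_give_zero_rate(self):
        t = ConfusionTally("cohort", "cohort", true_positive=10)
        assert false_positive_rate(t, "retained") == 0.0
        assert false_positive_rate(t, "total") == 0.0

    def test_zero_denominator_is_an_error_not_zero(self):
        t = ConfusionTally("cohort", "cohort")
        with pytest.raises(ZeroDivisionError):
            false_positive_rate(t, "retained")


class TestPerPatientBurden:
    def test_flags_and_stated_denominators(self):
        retained = [
            make_variant(patient="P1", origin="germline"),
            make_variant(patient="P2", origin="germline"),
            make_variant(patient="P2", pos=55_249_100, origin="somatic"),
        ]
        records, aggs = per_patient_burden(retained, ["P1", "P2", "P3"])
        by_id = {r.patient_id: r for r in records}
        assert by_id["P1"].only_false_positive
        assert by_id["P2"].any_false_positive and not by_id["P2"].only_false_positive
        assert not by_id["P3"].any_false_positive
        # any-FP fraction over all patients, including the zero-variant one
        assert aggs["frac_with_any_fp"] == pytest.approx(2 / 3)

    def test_mean_excludes_zero_variant_patients(self):
        retained = [
            make_variant(patient="P1", origin="germline"),
            make_variant(patient="P1", pos=55_249_100, origin="germline"),
            make_variant(patient="P2", origin="somatic"),
            make_variant(patient="P2", pos=55_249_100, origin="somatic"),
        ]
        _, aggs = per_patient_burden(retained, ["P1", "P2", "P3"])
        assert aggs["mean_retained_per_positive_patient"] == pytest.approx(2.0)
        assert aggs["n_patients"] == 3

    def test_patient_outside_roster_is_an_error(self):
        with pytest.raises(ValueError, match="roster"):
            per_patient_burden([make_variant(patient="P9", origin="germline")], ["P1"])


class TestDruggableImpact:
    def _drug_map(self):
        return DrugTargetMap({"RET": ["cabozantinib"], "MET": ["crizotinib"]})

    def test_patient_counted_once_per_gene(self):
        retained = [
            make_variant(patient="P1", gene="RET", pos=43_600_000, contig="chr10", origin="germline"),
            make_variant(patient="P1", gene="RET", pos=43_600_100, contig="chr10", origin="germline"),
        ]
        impact = druggable_impact({"af_0.001": retained}, self._drug_map())
        assert impact["per_gene"]["af_0.001"]["RET"] == 1
        assert impact["unique_patients"]["af_0.001"] == 1

    def test_unique_total_deduplicates_across_genes(self):
        retained = [
            make_variant(patient="P1", gene="RET", pos=43_600_000, contig="chr10", origin="germline"),
            make_variant(patient="P1", gene="MET", origin="germline"),
        ]
        impact = druggable_impact({"af_0.001": retained}, self._drug_map())
        assert impact["per_gene"]["af_0.001"] == {"MET": 1, "RET": 1}
        assert impact["unique_patients"]["af_0.001"] == 1

    def test_true_positives_and_non_druggable_genes_ignored(self):
        retained = [
            make_variant(patient="P1", gene="RET", pos=43_600_000, contig="chr10", origin="somatic"),
            make_variant(patient="P2", gene="EGFR", origin="germline"),  # not in this map
        ]
        impact = druggable_impact({"dbsnp": retained}, self._drug_map())
        assert impact["unique_patients"]["dbsnp"] == 0


def brute_force_confusion(variants, lookup, regime, common_keys):
    """Independent per-variant re-evaluation of the published filter rules."""
    tp = fp = fn = gr = 0
    for v in variants:
        ann = lookup.get(v.key)
        if regime.kind == "database_membership":
            removed = ann.in_database
        else:
            if ann.population_af is not None:
                removed = ann.population_af >= regime.af_cutoff
            else:
                removed = bool(
                    regime.rescue_rule_enabled and ann.in_database and v.key in common_keys
                )
        if v.origin == "somatic":
            fn += removed
            tp += not removed
        else:
            gr += removed
            fp += not removed
    return tp, fp, fn, gr


def random_small_cohort(rng: random.Random):
    """Up to 50 labeled variants with randomized annotation states."""
    variants, annotations, common = [], [], set()
    n = rng.randint(1, 50)
    for i in range(n):
        v = make_variant(
            patient=f"P{rng.randint(1, 8)}",
            pos=55_200_000 + i,
            origin=rng.choice(["germline", "somatic"]),
        )
        variants.append(v)
        in_db = rng.random() < 0.7
        af = None
        if in_db and rng.random() < 0.7:
            af = rng.choice([0.0, 0.00005, 0.0005, 0.001, 0.005, 0.01, 0.02, 0.3])
        if rng.random() < 0.5:
            annotations.append(PopulationAnnotation(v.key, in_db, af))
        if rng.random() < 0.3:
            common.add(v.key)
    return variants, AnnotationLookup(annotations), common


class TestOracleEquivalence:
    def test_tally_matches_brute_force_on_randomized_cohorts(self):
        rng = random.Random(20240917)
        for _ in range(60):
            variants, lookup, common = random_small_cohort(rng)
            for regime in standard_regimes():
                retained, removed = apply_filter(variants, lookup, regime, common)
                assert set(id(v) for v in retained) | set(id(v) for v in removed) == set(
                    id(v) for v in variants
                )
                t = tally(retained, removed, "cohort")
                assert (
                    t.true_positive, t.false_positive, t.false_negative, t.germline_removed
                ) == brute_force_confusion(variants, lookup, regime, common)
                n_som = sum(1 for v in variants if v.origin == "somatic")
                assert t.true_positive + t.false_negative == n_som
                assert t.false_positive + t.germline_removed == len(variants) - n_som


class TestMonotonicity:
    def test_lower_cutoff_never_retains_more(self):
        rng = random.Random(5)
        for _ in range(20):
            variants, lookup, common = random_small_cohort(rng)
            r_strict, _ = apply_filter(variants, lookup, AF_0001_REGIME, common)
            r_loose, _ = apply_filter(variants, lookup, AF_001_REGIME, common)
            assert {id(v) for v in r_strict} <= {id(v) for v in r_loose}
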