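import pytest

from panelaudit.cohort_io import GenePanel, ObservedVariant, VariantKey
from panelaudit.simulate import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def panel():
    return GenePanel.default()


@pytest.fixture(scope="session")
def small_cohort():
    """A 40-patient noise-free synthetic cohort shared across tests."""
    return generate_cohort(CohortConfig(seed=7, n_patients=40))


def make_variant(
    patient="P1",
    contig="chr7",
    pos=55_249_071,
    ref="C",
    alt="T",
    gene="EGFR",
    consequence="missense",
    tumor_depth=60,
    tumor_alt=24,
    normal_depth=30,
    normal_alt=0,
    origin="unassigned",
):
    """An EGFR-locus SNV with overridable evidence, for targeted cases."""
    return ObservedVariant(
        patient_id=patient,
        key=VariantKey(contig, pos, ref, alt),
        gene=gene,
        consequence=consequence,
        tumor_depth=tumor_depth,
        tumor_alt=tumor_alt,
        normal_depth=normal_depth,
        normal_alt=normal_alt,
        origin=origin,
    )
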