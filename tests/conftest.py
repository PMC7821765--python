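import pytest

from cardiovar.model import Cohort, PatientRecord, PredictorPanel, Variant
from cardiovar.sim import SimConfig, simulate_cohort, simulate_variant_pool


def make_variant(vid="v1", **kw):
    base = dict(
        variant_id=vid,
        chrom="chr1",
        pos=100,
        ref="A",
        alt="G",
        gene="TTN",
        effect="nonsynonymous_snv",
    )
    base.update(kw)
    return Variant(**base)


@pytest.fixture
def make_var():
    return make_variant


@pytest.fixture(scope="session")
def small_config():
    # scaled-down pool, full-size arms: fast but structurally complete
    return SimConfig(seed=11, n_raw_variants=600)


@pytest.fixture(scope="session")
def small_sim(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def default_sim():
    return simulate_cohort(SimConfig(seed=5))


@pytest.fixture
def tiny_cohort():
    """5 patients, 10 variants, hand-built carriage."""
    variants = [
        make_variant(f"v{i}", predictor_calls=PredictorPanel.from_damaging(i))
        for i in range(10)
    ]
    patients = [
        PatientRecord("p0", "CHD_VT", lvef=40.0, carried={"v9": "het", "v0": "het"}),
        PatientRecord("p1", "CHD_VT", lvef=35.0, carried={"v5": "het"}),
        PatientRecord("p2", "DCM_VT", lvef=25.0, carried={"v2": "het", "v3": "hom"}),
        PatientRecord("p3", "iVT", lvef=60.0, carried={}),
        PatientRecord("p4", "CONTROL", carried={"v1": "het"}),
    ]
    return Cohort(variants=variants, patients=patients)
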