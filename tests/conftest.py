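import hypothesis
import pytest

from pathscreen import (
    ConstructRecord,
    LibraryManifest,
    SampleRow,
    SampleSheet,
    ScreenScenario,
    assign_barcodes,
    default_manifest,
)
from pathscreen.screen_sim import make_index_set

hypothesis.settings.register_profile(
    "suite", derandomize=True, max_examples=30, deadline=None
)
hypothesis.settings.load_profile("suite")


@pytest.fixture(scope="session")
def manifest():
    """The packaged default library (36 activators, 17 pathways, 3 controls)."""
    return default_manifest()


@pytest.fixture
def mini_manifest():
    """A 6-record toy library: 2 pathways, 2 negative controls, 1 positive."""
    records = [
        ConstructRecord("ACT_A1", "PathA", "ProtA1", role="pathway_activator"),
        ConstructRecord("ACT_A2", "PathA", "ProtA2", role="pathway_activator"),
        ConstructRecord("ACT_B1", "PathB", "ProtB1", role="pathway_activator"),
        ConstructRecord("NEG_1", "", "HcRed", role="negative_control"),
        ConstructRecord("NEG_2", "", "luciferase", role="negative_control"),
        ConstructRecord("POS_1", "", "MEK1", role="positive_control"),
    ]
    return assign_barcodes(LibraryManifest(records), min_hamming=2, seed=11)


@pytest.fixture
def mini_samplesheet():
    """Four samples: drug/vehicle at two doses, one tech rep each."""
    idx = make_index_set(4, seed=5)
    rows = [
        SampleRow("drug_lo_t1", idx[0], "drug", "lo"),
        SampleRow("veh_lo_t1", idx[1], "vehicle", "lo"),
        SampleRow("drug_hi_t1", idx[2], "drug", "hi"),
        SampleRow("veh_hi_t1", idx[3], "vehicle", "hi"),
    ]
    return SampleSheet(rows).validate()


@pytest.fixture
def tiny_scenario():
    """A fast, small screen used where absolute scale does not matter."""
    return ScreenScenario(
        n_cells=30_000,
        capacity=150_000,
        days=5,
        read_depth=3_000,
        tech_reps=2,
        seed=7,
    ).validate()
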