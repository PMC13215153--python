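import logging

import pytest
from hypothesis import HealthCheck, settings

from rarecure import fixtures as fx
from rarecure.trial_match import OntologyHierarchy, SnapshotRegistry

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

logging.getLogger("rarecure").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def snapshot_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("snapshots")
    fx.make_snapshots(out)
    return out


@pytest.fixture(scope="session")
def hierarchy(snapshot_dir) -> OntologyHierarchy:
    return OntologyHierarchy.from_tsv(snapshot_dir / "ontology.tsv")


@pytest.fixture(scope="session")
def registry(snapshot_dir) -> SnapshotRegistry:
    return SnapshotRegistry.from_jsonl(snapshot_dir / "trials.jsonl")


@pytest.fixture(scope="session")
def cohort_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("cohort")
    fx.make_cohort(fx.CohortSpec(n_patients=20, seed=7, zero_variant_fraction=0.1), out)
    return out
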