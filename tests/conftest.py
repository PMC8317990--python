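import numpy as np
import pytest

from listrct import ParticipantRecord, TrialDataset, SimulationConfig, generate_trial


def make_record(pid, arm="do_nothing", list_group="control", responses=None,
                counts=None, completed=True, **demo):
    demo.setdefault("age_band", "25-34")
    demo.setdefault("gender", "female")
    demo.setdefault("country", "UK")
    demo.setdefault("education", "bachelor_some_college")
    demo.setdefault("first_language", "English")
    if responses is None:
        responses = (1,) * 18
    if counts is None:
        counts = (2, 2, 2, 2, 2)
    return ParticipantRecord(participant_id=pid, arm=arm, list_group=list_group,
                             knowledge_responses=responses, list_counts=counts,
                             completed=completed, **demo)


def minimal_dataset(**kwargs):
    """One record per arm × list cell — the smallest analysable design."""
    records = []
    i = 0
    for arm in ("do_nothing", "apc", "covideo"):
        for lg in ("control", "treatment"):
            records.append(make_record(f"P{i:03d}", arm=arm, list_group=lg, **kwargs))
            i += 1
    return TrialDataset.from_records(records, provenance="fixture")


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture
def six_cell_dataset():
    return minimal_dataset()


@pytest.fixture(scope="session")
def small_trial():
    """A modest synthetic trial shared by read-only analysis tests."""
    return generate_trial(SimulationConfig(n_per_cell=400, seed=20260920))


def cell_dataset(cell_counts, experiment_index=1):
    """Build a dataset with specified list counts per arm × list cell.

    ``cell_counts``: {(arm, list_group): sequence of counts} for the given
    experiment; other experiments get zeros.
    """
    records = []
    i = 0
    for (arm, lg), values in cell_counts.items():
        for v in values:
            counts = [0] * 5
            counts[experiment_index - 1] = int(v)
            records.append(make_record(f"C{i:05d}", arm=arm, list_group=lg,
                                       counts=tuple(counts)))
            i += 1
    return TrialDataset.from_records(records, provenance="cell-fixture")
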