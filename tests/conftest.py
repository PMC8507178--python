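from __future__ import annotations

from datetime import datetime, timedelta, timezone

import pytest

from chemcollab import canonicalize, fixture_log
from chemcollab.event_log import DesignEvent, ExperimentLog
from chemcollab.synthetic import fixture_expectations

BASE_TIME = datetime(2021, 3, 1, 10, 0, 0, tzinfo=timezone.utc)


def make_log(rows, mode="collective", target_smiles=None, experiment_id="test"):
    """Build a log from (event_id, participant, seconds, parent, smiles, score)
    tuples — the compact notation used throughout the tests."""
    events = [
        DesignEvent(
            event_id=eid,
            timestamp=BASE_TIME + timedelta(seconds=sec),
            participant_id=who,
            smiles=smi,
            parent_event_id=parent,
            score=score,
        )
        for eid, who, sec, parent, smi, score in rows
    ]
    return ExperimentLog(
        experiment_id=experiment_id,
        mode=mode,
        target=canonicalize(target_smiles) if target_smiles else None,
        events=events,
    )


@pytest.fixture(scope="session")
def fixture_experiment():
    return fixture_log()


@pytest.fixture(scope="session")
def fixture_expected():
    return fixture_expectations()


@pytest.fixture(scope="session")
def albuterol():
    return canonicalize("CC(C)(C)NCC(O)c1ccc(O)c(CO)c1")
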