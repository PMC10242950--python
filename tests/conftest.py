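import pytest

from beastlab.core_model import CohortDataset, ParticipantRecord, TrialRound
from beastlab.scoring import filter_participants, score_cohort
from beastlab.synthetic_cohort import SimulationConfig, simulate_cohort


def make_round(i, e1, x, e2, true_count=43):
    return TrialRound(round_index=i, true_count=true_count, e1=e1, x=x, e2=e2)


def make_participant(pid, round_triples, group="TD"):
    """round_triples: list of (e1, x, e2) for rounds 1..5."""
    rounds = tuple(make_round(i + 1, *t) for i, t in enumerate(round_triples))
    return ParticipantRecord(participant_id=pid, group=group, rounds=rounds)


@pytest.fixture(scope="session")
def default_cohort():
    """One cohort at the default study conditions (45/31/32 participants)."""
    return simulate_cohort(SimulationConfig(rng_seed=7))


@pytest.fixture(scope="session")
def scored_cohort(default_cohort):
    retained, _ = filter_participants(score_cohort(default_cohort))
    return retained
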