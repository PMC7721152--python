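import numpy as np
import pytest

from ecwm.designs import GroupObservation, QuestionDesign, StudyDataset

P1, P2 = 0.158, 0.842


@pytest.fixture
def ecwm_pair() -> StudyDataset:
    """Reconstructed ECWM counts of the published two-arm survey."""
    return StudyDataset(
        [
            GroupObservation("ecwm_p1", QuestionDesign.crosswise(P1), 455, 140),
            GroupObservation("ecwm_p2", QuestionDesign.crosswise(P2), 456, 320),
        ]
    )


@pytest.fixture
def dq_group() -> StudyDataset:
    """Direct-questioning control arm (49 'agree' of 450)."""
    return StudyDataset(
        [GroupObservation("dq", QuestionDesign.direct(), 450, 49)]
    )


@pytest.fixture
def full_study(ecwm_pair, dq_group) -> StudyDataset:
    return StudyDataset(list(ecwm_pair) + list(dq_group))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20201207)
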