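"""Shared fixtures: synthetic trials are generated once per session."""

import numpy as np
import pytest

import splitbelt as sb


@pytest.fixture(scope="session")
def noiseless_trial() -> sb.SyntheticTrial:
    """Compact-protocol trial with zero stride-to-stride noise."""
    cfg = sb.SyntheticConfig.compact(seed=1, noise_sd=0.0)
    return sb.generate_trial(cfg, sb.ProtocolSchedule.compact())


@pytest.fixture(scope="session")
def noiseless_result(noiseless_trial) -> sb.SubjectResult:
    data = sb.SubjectData.from_trial(noiseless_trial)
    return sb.run_subject(data, sb.AnalysisConfig(), "S01")


@pytest.fixture(scope="session")
def smooth_delta() -> np.ndarray:
    """A structured, non-collinear 360-component on(+) delta."""
    cfg = sb.SyntheticConfig(seed=7, noise_sd=0.0)
    sim = sb.simulate_stride_vectors(cfg, sb.ProtocolSchedule.compact())
    return sim["transition_deltas"]["on(+)"]
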