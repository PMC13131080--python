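import pytest

from ergopart import AnalysisPolicies, ProtocolSpec, SyntheticConfig, analyze_session
from ergopart.synth import generate_session


@pytest.fixture(scope="session")
def noiseless_cs():
    return generate_session(SyntheticConfig(noise_sd_l_s=0.0), ProtocolSpec.cs())


@pytest.fixture(scope="session")
def noiseless_ts():
    return generate_session(SyntheticConfig(noise_sd_l_s=0.0), ProtocolSpec.ts())


def _analyze(session):
    return analyze_session(
        session.breath,
        session.reps,
        session.lactate,
        session.marks,
        session.timeline,
        session.participant,
        policies=AnalysisPolicies(),
    )


@pytest.fixture(scope="session")
def analyzed_cs(noiseless_cs):
    return _analyze(noiseless_cs)


@pytest.fixture(scope="session")
def analyzed_ts(noiseless_ts):
    return _analyze(noiseless_ts)
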