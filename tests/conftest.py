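import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_sim():
    """One small clean synthetic run shared by read-only tests."""
    from chuvee.simulate import SimConfig, simulate
    config = SimConfig(seed=11, counts={
        "ANAKIN_COMPLETE": 1, "ANAKIN_DEFECTIVE_2LTR": 1, "ANAKIN_DEFECTIVE": 1,
        "PAO_COMPLETE": 1, "PAO_DEFECTIVE": 1, "SOLO_LTR": 2, "SOLO_GLY": 1,
        "RDRP_EVE": 1, "NP_EVE": 1,
    }, n_contigs=3, contig_length=150_000)
    return simulate(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_dna(rng, n, p_gc=0.5):
    bases = np.array(list("ACGT"))
    p = np.array([(1 - p_gc) / 2, p_gc / 2, p_gc / 2, (1 - p_gc) / 2])
    return "".join(bases[rng.choice(4, size=n, p=p)])
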