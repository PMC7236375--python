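import numpy as np
import pytest

from structvar import reactivity as rx
from structvar import synthetic_data as sd


@pytest.fixture(scope="session")
def small_truth():
    """A small planted transcriptome shared by read-only tests."""
    cfg = sd.SimConfig(
        n_transcripts=25, n_switch_sites=10, n_bound_sites=8, n_unbound_sites=8, seed=11
    )
    return sd.make_transcriptome(cfg, np.random.default_rng(11))


@pytest.fixture(scope="session")
def small_stage_pair(small_truth):
    """Noisy reactivity profiles for the two stages of the small transcriptome."""
    rng = np.random.default_rng(12)
    ra = rx.stage_reactivities(
        sd.flatten_pairs(sd.simulate_rtstops(small_truth, "4hpf", rng)), stage="4hpf"
    )
    rb = rx.stage_reactivities(
        sd.flatten_pairs(sd.simulate_rtstops(small_truth, "6hpf", rng)), stage="6hpf"
    )
    return ra, rb


@pytest.fixture(scope="session")
def noiseless_stage_pair(small_truth):
    rng = np.random.default_rng(0)
    na = rx.stage_reactivities(
        sd.flatten_pairs(sd.simulate_rtstops(small_truth, "4hpf", rng, replicates=1, noiseless=True)),
        stage="4hpf",
    )
    nb = rx.stage_reactivities(
        sd.flatten_pairs(sd.simulate_rtstops(small_truth, "6hpf", rng, replicates=1, noiseless=True)),
        stage="6hpf",
    )
    return na, nb
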