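import numpy as np
import pytest

from wavepipe import synthetic as syn


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_session():
    """Compact six-class population shared by io/laminar/qc tests."""
    cfg = syn.default_config(
        units_per_class=10, train_duration_s=60.0, trials_per_condition=2
    )
    return syn.build_population(cfg, seed=11)


@pytest.fixture(scope="session")
def shape_families():
    """Three well-separated waveform families for clustering tests."""
    specs = [
        syn.GeneratorClassSpec(name="narrow", trough_to_peak_ms=0.2),
        syn.GeneratorClassSpec(name="broad", trough_to_peak_ms=0.7),
        syn.GeneratorClassSpec(name="tri", trough_to_peak_ms=0.35, phases="triphasic"),
    ]
    W, labels, _ = syn.waveform_bank(
        n_per_class=30, noise_frac=0.05, seed=5, classes=specs
    )
    return W, labels
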