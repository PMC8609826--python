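import numpy as np
import pytest

from rumizyme import simulate

#: published inactivation rate constants (min^-1) per temperature (degC)
PRINTED_K = {25.0: 0.0017, 40.0: 0.0180, 50.0: 0.2400, 60.0: 0.92}
ASSAY_TIMES = [0.0, 10.0, 20.0, 30.0, 40.0, 50.0, 60.0, 70.0]
SUBSTRATE_GRID = [0.0, 0.88, 1.75, 3.5, 7.0, 15.0, 30.0]
DSF_GRID = np.arange(25.0, 95.0 + 1e-9, 0.5)


@pytest.fixture
def noiseless_cfg():
    return simulate.SimulationConfig(seed=0, noise_sd=0.0)


@pytest.fixture
def printed_courses(noiseless_cfg):
    """Noiseless decay courses generated at the four published k values."""
    return [
        simulate.simulate_decay_course(k, ASSAY_TIMES, noiseless_cfg, temperature_c=t)
        for t, k in PRINTED_K.items()
    ]


@pytest.fixture
def toy_family(noiseless_cfg):
    spec = simulate.FamilySimSpec(
        family_count=3, seqs_per_family=4, seq_length=80, within_family_divergence=0.04
    )
    cfg = simulate.SimulationConfig(seed=11)
    return simulate.simulate_family_db(spec, cfg)
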