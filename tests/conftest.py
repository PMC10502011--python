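import numpy as np
import pytest

from tedyn.config import PipelineConfig
from tedyn.simulate import BurstSpec, SimConfig, TEFamilySpec, simulate_te_history


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def ltr_only_config():
    """One Copia family, two bursts (young and old), no conversion."""
    return SimConfig(
        seed=7,
        te_families=[TEFamilySpec("copia1", "Copia", 4900, 300)],
        burst_spec=[BurstSpec("copia1", 0.2, 250), BurstSpec("copia1", 2.0, 250)],
        conversion_rate=0.0,
    )


@pytest.fixture(scope="session")
def ltr_history(ltr_only_config):
    return simulate_te_history(ltr_only_config)


@pytest.fixture(scope="session")
def small_genome():
    """A compact a1/a2 genome pair with all feature classes planted."""
    from tedyn.simulate import assemble_genomes

    cfg = SimConfig(seed=3)
    return cfg, assemble_genomes(cfg)


@pytest.fixture()
def pipeline_config():
    cfg = PipelineConfig()
    # the simulator draws hit e-values from [1e-120, 1e-40]; a fixed secondary
    # threshold keeps every planted hit and rejects only the decoys
    cfg.filter.evalue_threshold = 1e-30
    return cfg
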