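import numpy as np
import pytest

from paleodup.simulate import SimConfig, WgdEvent, simulate_genome


@pytest.fixture(scope="session")
def small_bundle():
    """Compact genome: one WGD at Ks 1.0, moderate tandem activity."""
    cfg = SimConfig(
        n_chromosomes=3,
        n_ancestral_genes=300,
        wgd_events=(WgdEvent(1.0, 0.3, 0.3, "GO:0003700"),),
        tandem_rate=0.15,
        seed=7,
    )
    bundle, truth = simulate_genome(cfg)
    return cfg, bundle, truth


@pytest.fixture(scope="session")
def small_bundle_dir(small_bundle, tmp_path_factory):
    _, bundle, _ = small_bundle
    outdir = tmp_path_factory.mktemp("bundle")
    paths = bundle.write(outdir)
    return paths


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
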