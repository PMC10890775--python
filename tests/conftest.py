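import numpy as np
import pytest

from isoqtl.simulate import SimConfig, simulate_study


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def tiny_study():
    """3 genes x 20 SNPs x 40 samples: enough to exercise every code path."""
    cfg = SimConfig(n=40, genes=3, snps=20, sigma_g2=0.3, seed=11)
    expr, geno, truths = simulate_study(cfg)
    return cfg, expr, geno, truths


@pytest.fixture(scope="session")
def null_study():
    """All-null study used for calibration checks (iid expression)."""
    cfg = SimConfig(n=60, genes=200, snps=30, null_fraction=1.0, seed=5)
    expr, geno, truths = simulate_study(cfg)
    return cfg, expr, geno, truths
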