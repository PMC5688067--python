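import numpy as np
import pytest

from nudixmap.epistasis import KnockdownPanel
from nudixmap.simulate import GeneratorConfig, gen_knockdown_panel


@pytest.fixture(scope="session")
def null_panel_clean():
    """Zero-noise panel with no planted interactions: the exact null."""
    cfg = GeneratorConfig(n_genes=8, noise_sd=0.0, seed=101)
    panel, truth = gen_knockdown_panel(cfg)
    return panel, truth


@pytest.fixture(scope="session")
def planted_panel():
    """Noisy panel with planted aggravating and alleviating pairs."""
    cfg = GeneratorConfig(
        n_genes=24,
        noise_sd=0.05,
        n_replicates=3,
        n_planted_aggravating=10,
        n_planted_alleviating=10,
        effect_size=0.3,
        seed=7,
    )
    panel, truth = gen_knockdown_panel(cfg)
    return panel, truth


@pytest.fixture()
def tiny_panel():
    """Hand-built panel with known arithmetic."""
    return KnockdownPanel(
        genes=["a", "b", "c"],
        single_viability={"a": np.array([0.8, 0.8]), "b": np.array([0.5, 0.5]), "c": np.array([1.0, 1.0])},
        double_viability={
            ("a", "b"): np.array([0.4, 0.4]),
            ("a", "c"): np.array([0.7, 0.7]),
            ("b", "c"): np.array([0.65, 0.65]),
        },
    )
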