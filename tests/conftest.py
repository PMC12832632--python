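import numpy as np
import pandas as pd
import pytest

from regenhubnet.synthdata import SynthConfig, generate_sections


@pytest.fixture(scope="session")
def single_section():
    """One post-injury section with 4 planted modules, used as a bank of
    metacell-equivalents for network tests."""
    cfg = SynthConfig(
        timepoint_labels=("2dpi",),
        marker_fraction_course=(0.3,),
        n_celltypes=1,
        cells_per_type=200,
        n_genes=330,
        n_modules_shared=2,
        n_modules_regen_only=2,
        module_size=30,
        within_module_rho=0.7,
        seed=0,
    )
    sections, truth = generate_sections(cfg)
    return sections[0], truth


@pytest.fixture(scope="session")
def small_series():
    """A short four-timepoint series (one control) at reduced size."""
    cfg = SynthConfig(
        timepoint_labels=("juvenile", "2dpi", "5dpi", "60dpi"),
        marker_fraction_course=(0.06, 0.37, 0.33, 0.06),
        n_celltypes=2,
        cells_per_type=120,
        n_genes=200,
        n_modules_shared=1,
        n_modules_regen_only=1,
        module_size=24,
        seed=3,
    )
    sections, truth = generate_sections(cfg)
    return cfg, sections, truth


def expression_frame(section):
    frame = pd.DataFrame(section.values, columns=list(section.genes))
    return frame.loc[:, frame.std(axis=0) > 0]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
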