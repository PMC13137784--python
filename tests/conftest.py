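import numpy as np
import pytest

import stingsig as ss


@pytest.fixture(scope="session")
def small_config() -> ss.SimConfig:
    """A compact but fully structured study: 2 modules of 60 genes."""
    return ss.SimConfig(n_genes=400, n_modules=2, module_size=60, seed=11)


@pytest.fixture(scope="session")
def small_timecourse(small_config):
    return ss.simulate_timecourse(small_config)


@pytest.fixture(scope="session")
def small_annotations(small_config, small_timecourse):
    _, truth = small_timecourse
    return ss.simulate_annotations(small_config, truth)


@pytest.fixture(scope="session")
def default_discovery():
    """Full-size discovery run shared by the slower end-to-end tests."""
    cfg = ss.SimConfig(seed=1)
    cm, truth = ss.simulate_timecourse(cfg)
    annot, tfbs, ppi = ss.simulate_annotations(cfg, truth)
    disc = ss.discover_modules(cm, ppi)
    return cfg, cm, truth, annot, tfbs, ppi, disc


def treated_and_times(cm):
    treated = [s for s in cm.samples if cm.metadata.loc[s, "condition"] == "treated"]
    return treated, cm.metadata.loc[treated, "time_h"].to_numpy(dtype=float)
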