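import numpy as np
import pytest

import racescreen as rs


@pytest.fixture(scope="session")
def cfg_t7():
    return rs.default_config("T7")


@pytest.fixture(scope="session")
def t7_model():
    return rs.build_activity_model("t7_like", fold_range=5.0, seed=7)


@pytest.fixture(scope="session")
def small_screen(cfg_t7, t7_model):
    """A 3×10^4-read T7-like screen shared by cheap tests."""
    reads, truth, library = rs.simulate_screen(
        cfg_t7, t7_model, depth=30_000, seed=3
    )
    return reads, truth, library


@pytest.fixture(scope="session")
def small_processed(cfg_t7, small_screen):
    reads, _, _ = small_screen
    filtered, stats = rs.process_run(reads, None, cfg_t7)
    return filtered, stats
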