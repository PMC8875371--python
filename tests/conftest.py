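"""Shared fixtures: expensive forward runs are session-scoped."""

from __future__ import annotations

import pytest

from cardioem.config import load_config
from cardioem.engine import run, summarize
from cardioem.synthetic import make_strain_fixture


@pytest.fixture(scope="session")
def baseline_result():
    """Shipped baseline configuration, 15 cycles at dt = 0.5 ms."""
    return run(load_config(None))


@pytest.fixture(scope="session")
def baseline_summary(baseline_result):
    return summarize(baseline_result)


@pytest.fixture(scope="session")
def lbbb_result():
    """Default model with the left bundle branch disabled."""
    return run(load_config({"conduction": {"lbbb": True}}), n_cycles=8, dt=1.0)


@pytest.fixture(scope="session")
def model_fixtures():
    """The three LBBB synthetic patients (model mode), plus healthy."""
    return {name: make_strain_fixture(name, mode="model")
            for name in ("healthy", "lbbb_nonischemic", "lbbb_lateral_scar",
                         "lbbb_anteroseptal_scar")}
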