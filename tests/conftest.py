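"""Shared fixtures: the calibrated defaults and cached scenario runs.

Full tissue runs (460 min warm-up + recording at dt = 0.01 min) cost a few
seconds each, so each scenario is integrated once per session and shared.
"""

from __future__ import annotations

import pytest

from somitesim.params import apply_perturbation, default_parameters
from somitesim.simulator import run


@pytest.fixture(scope="session")
def defaults():
    return default_parameters()


@pytest.fixture(scope="session")
def wt_run(defaults):
    """Wild type over five-plus segmentation cycles."""
    return run(defaults, "wild_type", t_end=160.0, record_every=1.0)


@pytest.fixture(scope="session")
def ripply_ko_run(defaults):
    return run(defaults, "ripply_ko", t_end=100.0, record_every=1.0)


@pytest.fixture(scope="session")
def her_ko_run(defaults):
    return run(defaults, "her_ko", t_end=60.0, record_every=1.0)


@pytest.fixture(scope="session")
def her_ko_mek_run(defaults):
    """her KO plus ten-fold dpErk reduction (MEK inhibition)."""
    p = apply_perturbation(defaults, "her_ko")
    return run(p, "mek_inhibition", t_end=60.0, record_every=1.0)


@pytest.fixture(scope="session")
def no_pfl_run(defaults):
    return run(defaults, "no_pfl", t_end=100.0, record_every=1.0)


@pytest.fixture(scope="session")
def stepwise_run(defaults):
    return run(defaults, "erk_stepwise", t_end=130.0, record_every=1.0)
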