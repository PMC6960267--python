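"""Shared fixtures.

The recovery-study fixtures are the expensive part of the suite: each runs a
reduced replication study (shorter chains, fewer replications than a full
simulation study) at a fixed design cell and is shared session-wide by every
test that scores it.
"""

import numpy as np
import pytest

from sathm import MCMCConfig, SimDesign, run_recovery

# Reduced protocol used throughout: 6000 iterations / 2000 burn-in, 2 chains,
# thinning 2 (the full protocol is 30000/10000).
REDUCED = dict(n_iter=6000, burn_in=2000, n_chains=2, thin=2)


@pytest.fixture(scope="session")
def study_500_30():
    """5-replication SATHM recovery study at N=500 persons, m=30 items."""
    design = SimDesign(n_persons=500, n_items=30, seed=0)
    cfg = MCMCConfig(seed=0, **REDUCED)
    return run_recovery(design, cfg, n_replications=5)


@pytest.fixture(scope="session")
def study_500_60():
    """3-replication SATHM recovery study at N=500 persons, m=60 items."""
    design = SimDesign(n_persons=500, n_items=60, seed=0)
    cfg = MCMCConfig(seed=0, **REDUCED)
    return run_recovery(design, cfg, n_replications=3)
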