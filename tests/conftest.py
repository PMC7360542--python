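import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from polykasp.pipeline import profile_probe
from polykasp.simulate import SimConfig, simulate_polyploid_locus, simulate_probe_context


def make_context(left: str, pair: str, right: str) -> str:
    """Pad flanks symmetrically to >= 50 with a neutral composition."""
    padL = ("ACGT" * 20)[: max(0, 50 - len(left))]
    padR = ("ACGT" * 20)[: max(0, 50 - len(right))]
    left, right = padL + left, right + padR
    # keep flanks equal length
    if len(left) > len(right):
        right = right + "ACGT" * 20
        right = right[: len(left)]
    elif len(right) > len(left):
        left = ("ACGT" * 20 + left)[-len(right) :]
    return f"{left}[{pair[0]}/{pair[1]}]{right}"


@pytest.fixture(scope="session")
def hexaploid():
    """A 3-copy locus with a guaranteed discriminating column at +35."""
    cfg = SimConfig(seed=7, offtarget_states=("T", "G"))
    assemblies, truth = simulate_polyploid_locus(cfg)
    record = simulate_probe_context(truth, rng=cfg.rng())
    return cfg, assemblies, truth, record


@pytest.fixture(scope="session")
def hexaploid_profile(hexaploid):
    cfg, assemblies, truth, record = hexaploid
    decoded, profile = profile_probe(record, assemblies)
    assert profile is not None
    return decoded, profile, truth, assemblies


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
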