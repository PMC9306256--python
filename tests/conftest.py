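import numpy as np
import pandas as pd
import pytest

from mousemeth import Manifest, SimConfig, simulate_manifest, simulate_study


@pytest.fixture(scope="session")
def mini_config():
    return SimConfig(seed=7, strains=("129S1", "AJ", "BALBc", "C57BL6"))


@pytest.fixture(scope="session")
def mini_study(mini_config):
    """One simulated study shared across read-only tests."""
    manifest, annot, true_betas, signals, truth = simulate_study(mini_config)
    return {
        "manifest": manifest,
        "annot": annot,
        "true_betas": true_betas,
        "signals": signals,
        "truth": truth,
        "config": mini_config,
    }


@pytest.fixture(scope="session")
def mini_manifest(mini_study):
    return mini_study["manifest"]


@pytest.fixture()
def tiny_manifest():
    """Hand-built manifest small enough to reason about by eye."""
    rows = []
    for i in range(5):
        rows.append(dict(probe_id=f"cg0000000{i}_TC11", chemistry="Infinium-I",
                         channel="Red", target="CG", chrom="chr1", pos=1000 + i,
                         strand="+", categories="", mask_default=False))
    for i in range(3):
        rows.append(dict(probe_id=f"cg0000001{i}_BC11", chemistry="Infinium-I",
                         channel="Green", target="CG", chrom="chr1", pos=2000 + i,
                         strand="+", categories="", mask_default=False))
    rows.append(dict(probe_id="cg00000099_TC21", chemistry="Infinium-II",
                     channel="Both", target="CG", chrom="chr2", pos=500,
                     strand="-", categories="", mask_default=False))
    rows.append(dict(probe_id="uk00000001_TC21", chemistry="Infinium-II",
                     channel="Both", target="CG", chrom="chr2", pos=600,
                     strand="+", categories="", mask_default=True))
    return Manifest(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260926)
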