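import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import medipchip as mc

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cfg():
    return mc.SimConfig(n_promoters=50, seed=11)


@pytest.fixture(scope="session")
def small_design(small_cfg):
    return mc.generate_design(small_cfg)


@pytest.fixture(scope="session")
def small_experiment(small_cfg, small_design):
    arrays, manifest = mc.generate_medip_experiment(small_design, small_cfg)
    return arrays, manifest


def toy_signal(m_values, spacing=100, promoter="P0", chrom="chr1",
               n_support=None, analysis_id="toy"):
    """Build a SmoothedSignal with probes `spacing` bp apart on one promoter."""
    n = len(m_values)
    mids = 1000 + spacing * np.arange(n)
    df = pd.DataFrame({
        "chrom": chrom,
        "promoter_id": promoter,
        "gene_symbol": f"Gene_{promoter}",
        "win_start": mids - 300,
        "win_end": mids + 300,
        "m_smoothed": np.asarray(m_values, dtype=float),
        "n_support": n_support if n_support is not None else np.full(n, 6),
    }, index=pd.Index([f"{promoter}_{i:03d}" for i in range(n)], name="probe_id"))
    return mc.SmoothedSignal(analysis_id, df)
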