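import numpy as np
import pandas as pd
import pytest

from metabodiverge import MetabolomePanel, SynthConfig, generate_panel


@pytest.fixture(scope="session")
def small_panel() -> MetabolomePanel:
    """A compact 48-sample panel with a planted 35% affected fraction."""
    config = SynthConfig(
        n_per_line=24,
        n_metabolites_per_block=(12, 10, 14, 8),
        frac_affected=0.35,
        seed=20230831,
    )
    return generate_panel(config)


@pytest.fixture(scope="session")
def signal_panel() -> MetabolomePanel:
    """A 200-metabolite panel sized like a reduced study, strong signal."""
    config = SynthConfig(
        n_per_line=24,
        n_metabolites_per_block=(52, 36, 87, 25),
        frac_affected=0.35,
        seed=7,
    )
    return generate_panel(config)


def make_manual_panel(abundance: np.ndarray, line, met_ids=None, block="polar"):
    """Build a MetabolomePanel from a raw matrix for constructed examples."""
    n, p = abundance.shape
    line = np.asarray(line)
    met_ids = met_ids or [f"M{j:03d}" for j in range(p)]
    sample_ids = [f"{ln}{i:02d}" for i, ln in enumerate(line)]
    samples = pd.DataFrame(
        {
            "line": line,
            "sex": np.tile(["M", "F"], n)[:n],
            "imf": 1.0 + 0.45 * (line == "H"),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return MetabolomePanel(
        abundance=pd.DataFrame(abundance, index=samples.index, columns=met_ids),
        samples=samples,
        blocks=pd.Series(block, index=pd.Index(met_ids, name="metabolite_id")),
    )
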