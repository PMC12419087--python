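import numpy as np
import pytest

from trcaf import ScrnaSimConfig, simulate_scrna
from trcaf.scrna import normalize, qc_filter


def small_scrna_cfg(seed=0, **overrides):
    """Compact mixed-population simulation used across unit tests."""
    base = dict(
        n_genes=300,
        n_cells=1200,
        marker_modules={
            "A": [f"A{i:02d}" for i in range(1, 7)],
            "B": ["PRRX1"] + [f"B{i:02d}" for i in range(2, 7)],
            "C": [f"C{i:02d}" for i in range(1, 7)],
            "D": [f"D{i:02d}" for i in range(1, 9)],
        },
        marker_log_fc=float(np.log(4)),
        seed=seed,
    )
    base.update(overrides)
    return ScrnaSimConfig(**base)


@pytest.fixture(scope="session")
def norm_adata():
    adata = simulate_scrna(small_scrna_cfg(seed=11))
    return normalize(qc_filter(adata))


@pytest.fixture(scope="session")
def fibro_adata(norm_adata):
    return norm_adata[
        (norm_adata.obs["cell_type"] == "fibroblast").to_numpy()
    ].copy()
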