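import numpy as np
import pandas as pd
import pytest

from structbias import BIAS_COLUMNS, design_grid


@pytest.fixture
def rng():
    return np.random.default_rng(20150708)


@pytest.fixture
def toy_sample_k2():
    """Fixed 10-row, two-predictor data matrix (outcome last)."""
    return np.array(
        [
            [1.2, 0.7, 2.1],
            [-0.3, 1.5, 0.9],
            [0.8, -0.2, 1.4],
            [2.1, 1.1, 3.0],
            [-1.4, -0.9, -2.2],
            [0.5, 0.3, 0.2],
            [1.9, 2.2, 2.8],
            [-0.7, 0.1, -1.0],
            [0.0, -1.3, -0.4],
            [1.1, 0.9, 1.7],
        ]
    )


def make_records(cell_rows):
    """Assemble a minimal bias-records frame from per-cell row specs.

    ``cell_rows`` maps (k, rho2_yy, rho_xx, n) -> list of bias values; the
    value is written to all six bias columns, one predictor per record.
    """
    frames = []
    for cell_id, ((k, ryy, rxx, n), values) in enumerate(cell_rows.items()):
        df = pd.DataFrame(
            {
                "cell_id": cell_id,
                "rep": np.arange(len(values)),
                "predictor": 1,
                "k": k,
                "rho2_yy": ryy,
                "rho_xx": rxx,
                "n": n,
                "r2s_undefined": False,
            }
        )
        for col in BIAS_COLUMNS:
            df[col] = values
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


@pytest.fixture
def full_grid_zero_records():
    """One zero-bias record per design cell (135 rows)."""
    return make_records(
        {
            (c.spec.k, c.spec.rho2_yy, c.spec.rho_xx, c.n): [0.0]
            for c in design_grid()
        }
    )
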