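import numpy as np
import pandas as pd
import pytest

from smlmq import LocalizationTable


@pytest.fixture
def uniform_table():
    """Factory: CSR localization table on a square field, seeded."""

    def make(n=1000, field_nm=10_000.0, frames_total=1000, seed=0, z=None):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(
            {
                "frame": rng.integers(0, frames_total, n),
                "x_nm": rng.uniform(0, field_nm, n),
                "y_nm": rng.uniform(0, field_nm, n),
                "z_nm": np.zeros(n) if z is None else z(rng, n),
                "sigma_nm": np.full(n, 130.0),
                "photons": np.full(n, 250.0),
                "background": np.zeros(n),
                "precision_nm": np.full(n, 20.0),
            }
        )
        return LocalizationTable(
            df, camera_pixel_nm=100.0, field_width_nm=field_nm,
            field_height_nm=field_nm, frames_total=frames_total,
        )

    return make
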