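import numpy as np
import pytest

import sobpbio as sb
from sobpbio.synthgen import SyntheticRadbioParams, synth_alpha_beta_table


@pytest.fixture(scope="session")
def scc_table():
    return synth_alpha_beta_table(SyntheticRadbioParams(sb.SCC))


@pytest.fixture(scope="session")
def chordoma_table():
    return synth_alpha_beta_table(SyntheticRadbioParams(sb.CHORDOMA))


@pytest.fixture(scope="session")
def shallow_proton_setup():
    """Designed 2-3 cm proton SOBP (2 Gy plateau), reused across tests."""
    return sb.build_standard_sobp("p", (2.0, 3.0))


@pytest.fixture(scope="session")
def shallow_carbon_setup():
    return sb.build_standard_sobp("C", (2.0, 3.0))


def smooth_random_profile(rng, grid, base=1.0, amplitude=0.5, smooth_slices=8.0):
    """Positive, smooth random profile for gamma-oracle comparisons."""
    from scipy.ndimage import gaussian_filter1d

    noise = gaussian_filter1d(rng.standard_normal(grid.n_slices), smooth_slices)
    scale = np.max(np.abs(noise)) or 1.0
    values = base + amplitude * noise / scale
    return sb.DoseProfile(grid, np.clip(values, 0.05, None), unit_tag="normalized")
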