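import numpy as np
import pytest

from mfkit.dictionary import build_dictionary, build_parameter_grid
from mfkit.protocol import AcquisitionScheme, build_clinical_scheme, build_hcp_mgh_scheme


@pytest.fixture(scope="session")
def hcp_scheme():
    return build_hcp_mgh_scheme(seed=0)


@pytest.fixture(scope="session")
def clinical_scheme():
    return build_clinical_scheme(seed=0)


@pytest.fixture(scope="session")
def tiny_scheme():
    """Small two-shell scheme (fast tests): 1 b=0 + 12 + 12 directions."""
    from mfkit.protocol import repulsion_directions

    d1 = repulsion_directions(12, seed=1)
    d2 = repulsion_directions(12, seed=2)
    dirs = np.concatenate([np.zeros((1, 3)), d1, d2])
    bvals = np.concatenate([[0.0], np.full(12, 1000.0), np.full(12, 3000.0)])
    return AcquisitionScheme(
        directions=dirs, bvalues=bvals, delta_small=12.9, delta_big=21.8
    )


@pytest.fixture(scope="session")
def full_dictionary(hcp_scheme):
    """Default 380-atom analytic dictionary on the research scheme."""
    return build_dictionary(build_parameter_grid(), hcp_scheme)


@pytest.fixture(scope="session")
def small_dictionary(hcp_scheme):
    """5x2 = 10-atom dictionary for exhaustive-search tests."""
    grid = build_parameter_grid(n_fvf=5, fvf_lo=0.1, fvf_hi=0.7, n_dex=2,
                                dex_lo=0.8, dex_hi=2.0)
    return build_dictionary(grid, hcp_scheme)


@pytest.fixture(scope="session")
def tiny_dictionary(tiny_scheme):
    """10-atom dictionary on the small scheme (fastest)."""
    grid = build_parameter_grid(n_fvf=5, fvf_lo=0.1, fvf_hi=0.7, n_dex=2,
                                dex_lo=0.8, dex_hi=2.0)
    return build_dictionary(grid, tiny_scheme)
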