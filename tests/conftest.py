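import warnings

import numpy as np
import pytest

from ampscat import caille, cd, sdp, synth


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    """Library-level UserWarnings (overfill reports, unassigned peaks) are
    part of normal operation in stress tests; keep the output readable."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture(scope="session")
def basis():
    return cd.BasisSet.bundled()


@pytest.fixture(scope="session")
def stack():
    """Small fluid-phase stack used across the diffuse-scattering tests."""
    return synth.default_stack()


@pytest.fixture(scope="session")
def fit_window():
    return [(0.08, 0.33, 0.02, 0.25)]


@pytest.fixture(scope="session")
def control_sdp():
    return synth.default_sdp_model()


@pytest.fixture(scope="session")
def le53_envelope():
    seq = "RRRRRRWWWWVV"
    return sdp.PeptideEnvelope(
        placement="hydrocarbon", z=9.0, sigma=4.0,
        n_electrons=sdp.peptide_electrons(seq),
        volume=sdp.peptide_volume(seq), per_lipid=1.0 / 75.0)


@pytest.fixture(scope="session")
def elasticity_init(stack):
    return caille.StackModel(K_C=12.0, B=5e-7, N_layers=stack.N_layers,
                             L_r=stack.L_r, D=stack.D)
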