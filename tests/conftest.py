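import numpy as np
import pytest

from tcrdyn import make_toy_complex
from tcrdyn.synthetic import ModeSpec, sample_ensemble

SMALL_SIZES = {"groove": 20, "Valpha": 8, "Vbeta": 8, "Calpha": 8, "Cbeta": 7}


@pytest.fixture(scope="session")
def toy_complex():
    """Small Calpha-only complex: 60 atoms, 9-mer peptide."""
    return make_toy_complex(SMALL_SIZES, "SLLMWITQC", seed=11)


@pytest.fixture(scope="session")
def toy_modes(toy_complex):
    """Three planted orthonormal modes on the toy complex."""
    top, ref = toy_complex
    rng = np.random.default_rng(7)
    q, _ = np.linalg.qr(rng.normal(size=(3 * top.n_atoms, 3)))
    return [(q[:, 0], 1.0), (q[:, 1], 0.5), (q[:, 2], 0.1)]


@pytest.fixture(scope="session")
def gaussian_ensemble(toy_complex, toy_modes):
    top, ref = toy_complex
    spec = ModeSpec(modes=toy_modes, epsilon=1e-6)
    return sample_ensemble(top, ref, spec, n_frames=2000, seed=13)
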