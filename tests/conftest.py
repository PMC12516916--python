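import numpy as np
import pytest

from dimerqa.fixtures import make_confidence, make_dimer, perturb


@pytest.fixture
def dimer():
    """Deterministic 60+60 dimer with an 8-residue contact patch per chain."""
    return make_dimer(n_a=60, n_b=60, interface_width=8, seed=42)


@pytest.fixture
def confidence(dimer):
    return make_confidence(dimer, quality=0.8, noise_sd=0.05, seed=7)


def random_case(seed: int, max_len: int = 45):
    """A small random dimer + decoy + confidence record for oracle checks."""
    rng = np.random.default_rng(seed)
    n_a = int(rng.integers(25, max_len))
    n_b = int(rng.integers(25, max_len))
    width = int(rng.integers(3, 9))
    ref = make_dimer(n_a=n_a, n_b=n_b, interface_width=width, seed=seed)
    m = float(rng.uniform(0.0, 1.0))
    decoy = perturb(ref, rotation_deg=60.0 * m, translation_ang=5.0 * m,
                    seed=seed, axis=(0, 0, 1), translation_dir=(1, 0, 0))
    conf = make_confidence(decoy, quality=1.0 - m, noise_sd=0.05, seed=seed + 9999)
    return ref, decoy, conf
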