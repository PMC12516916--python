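"""Shared helper: apply one global rigid-body transform to a whole model."""

from copy import deepcopy

import numpy as np

from dimerqa.fixtures import _rotation_matrix
from dimerqa.model import StructureModel


def rigid_copy(model: StructureModel, seed: int = 0) -> StructureModel:
    rng = np.random.default_rng(seed)
    R = _rotation_matrix(rng.normal(size=3), float(rng.uniform(20, 160)))
    t = rng.uniform(-25, 25, 3)
    out = deepcopy(model)
    for res in out.iter_residues():
        res.atoms = [(n, R @ xyz + t) for n, xyz in res.atoms]
    return out
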