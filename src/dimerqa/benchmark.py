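"""Desk-scale synthetic benchmark: graded decoys scored both ways.

For each synthetic target a latent quality q ~ U(0, 1) drives a rigid-body
decoy (in-plane rotation plus register slide of the second chain, so the
chains stay in contact while the interface degrades) and a confidence record
whose pLDDT/PAE/ipTM track q.  Each decoy is then evaluated reference-free
(score panel) and reference-based (DockQ against the unperturbed target),
yielding a labeled table on which the calibration machinery can be run
end-to-end.  This emulates the statistical structure of a prediction
benchmark — scores correlated with true quality, labels from DockQ — at a
size that runs in seconds.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .calibration import LabeledScoreTable
from .fixtures import make_confidence, make_dimer, perturb
from .model import Method
from .reference_eval import dockq
from .scores import score_model

#: decoy geometry at full degradation (magnitude m = 1 − q)
MAX_ROTATION_DEG = 60.0
MAX_SLIDE_ANG = 5.0


def make_benchmark(
    n_models: int = 200,
    seed: int = 0,
    noise_sd: float = 0.05,
    method: Method = Method.CF_T,
    cutoff: float = 5.0,
    with_voroif: bool = True,
) -> LabeledScoreTable:
    """Generate a labeled synthetic benchmark table.

    Columns: the full score panel, ``voroif`` (synthetic interface-accuracy
    estimate tracking q), ``dockq`` (computed against the reference), the
    derived ``label``, and ``quality`` (the latent truth, for validation
    only — nothing downstream may use it for fitting).
    """
    rng = np.random.default_rng(seed)
    score_sets, dockqs, qualities = [], [], []
    for i in range(n_models):
        sub = int(rng.integers(0, 2**31 - 1))
        q = float(rng.uniform(0.0, 1.0))
        n_a = int(rng.integers(55, 71))
        n_b = int(rng.integers(55, 71))
        width = int(rng.integers(6, 11))
        reference = make_dimer(n_a=n_a, n_b=n_b, interface_width=width, seed=sub)
        m = 1.0 - q
        decoy = perturb(
            reference,
            rotation_deg=MAX_ROTATION_DEG * m,
            translation_ang=MAX_SLIDE_ANG * m,
            seed=sub,
            axis=(0.0, 0.0, 1.0),
            translation_dir=(1.0, 0.0, 0.0),
        )
        decoy.model_id = f"bench_{i:04d}"
        conf = make_confidence(decoy, quality=q, noise_sd=noise_sd, seed=sub ^ 0x5EED, method=method)
        voroif = float(np.clip(q + rng.normal(0.0, noise_sd), 0.0, 1.0)) if with_voroif else None
        s = score_model(decoy, conf, cutoff=cutoff, voroif=voroif, allow_non_interacting=True)
        d = dockq(decoy, reference)
        score_sets.append(s)
        dockqs.append(d.dockq)
        qualities.append(q)
    table = LabeledScoreTable.from_records(score_sets, dockqs)
    table.frame["quality"] = qualities
    return table


def score_quality_correlations(table: LabeledScoreTable) -> pd.Series:
    """PCC of each panel score (and any combined columns) with the latent
    quality; PAE-family correlations are reported on the sign-flipped score so
    larger is better everywhere."""
    from .calibration import pcc
    from .combined import LOWER_IS_BETTER

    q = table.frame["quality"].to_numpy(dtype=float)
    out = {}
    for col in ("plddt", "pae", "iplddt", "ipae", "ptm", "iptm",
                "model_confidence", "pdockq2", "voroif", "unweighted", "c2qscore"):
        if col in table.frame.columns and table.frame[col].notna().all():
            v = table.frame[col].to_numpy(dtype=float)
            out[col] = pcc(-v if col in LOWER_IS_BETTER else v, q)
    return pd.Series(out)
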