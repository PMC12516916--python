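"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as plain double loops / closed forms, deliberately
ignoring the package's own code paths (k-d trees, SVD Kabsch, vectorized
means), so that agreement is a genuine dual-route check.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

from dimerqa.model import BACKBONE_ATOMS, StructureModel


def brute_contacts(model: StructureModel, chain_a: str, chain_b: str, cutoff: float) -> set:
    """All-pairs heavy-atom scan: contact iff min distance strictly < cutoff."""
    contacts = set()
    for ra in model.chain(chain_a).residues:
        xa = ra.atom_coords()
        for rb in model.chain(chain_b).residues:
            xb = rb.atom_coords()
            dmin = np.sqrt(((xa[:, None, :] - xb[None, :, :]) ** 2).sum(-1)).min()
            if dmin < cutoff:
                contacts.add((ra.seq_index, rb.seq_index))
    return contacts


def brute_iplddt(plddt: np.ndarray, contacts: set) -> float:
    residues = sorted({i for i, _ in contacts} | {j for _, j in contacts})
    return sum(plddt[i] for i in residues) / len(residues)


def brute_ipae(pae: np.ndarray, contacts: set) -> float:
    total, n = 0.0, 0
    for i, j in contacts:
        total += pae[i, j] + pae[j, i]
        n += 2
    return total / n


def brute_interface_bfactor(model: StructureModel, contacts: set) -> float:
    by_index = {r.seq_index: r for r in model.iter_residues()}
    residues = sorted({i for i, _ in contacts} | {j for _, j in contacts})
    return sum(by_index[i].bfactor for i in residues) / len(residues)


def brute_fnat(model: StructureModel, reference: StructureModel, cutoff: float = 5.0) -> float:
    """Native-contact recovery assuming identical chain order and 1:1 residue
    correspondence by position (true for same-topology synthetic decoys)."""
    a, b = reference.chain_ids()
    native = brute_contacts(reference, a, b, cutoff)
    ma, mb = model.chain_ids()
    model_c = brute_contacts(model, ma, mb, cutoff)
    return len(native & model_c) / len(native)


def _backbone(model: StructureModel, chain_id: str) -> np.ndarray:
    pts = []
    for res in model.chain(chain_id).residues:
        for name in BACKBONE_ATOMS:
            x = res.atom(name)
            if x is not None:
                pts.append(x)
    return np.asarray(pts)


def _superpose(P: np.ndarray, Q: np.ndarray):
    """Independent rigid fit via scipy Rotation.align_vectors."""
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    rot, _ = Rotation.align_vectors(Q - qc, P - pc)
    return rot, pc, qc


def brute_lrms(model: StructureModel, reference: StructureModel) -> float:
    """Receptor = longer reference chain (ties → first); superpose receptors,
    RMSD over ligand backbone."""
    ra, rb = reference.chain_ids()
    rec, lig = (ra, rb) if len(reference.chain(ra)) >= len(reference.chain(rb)) else (rb, ra)
    order = {ra: 0, rb: 1}
    ma, mb = model.chain_ids()
    mrec, mlig = (ma, mb) if order[rec] == 0 else (mb, ma)
    rot, pc, qc = _superpose(_backbone(model, mrec), _backbone(reference, rec))
    lm = rot.apply(_backbone(model, mlig) - pc) + qc
    lr = _backbone(reference, lig)
    return float(np.sqrt(np.mean(np.sum((lm - lr) ** 2, axis=1))))


def brute_irms(model: StructureModel, reference: StructureModel, cutoff: float = 10.0) -> float:
    """Backbone RMSD over native interface residues after superposing on them."""
    a, b = reference.chain_ids()
    native = brute_contacts(reference, a, b, cutoff)
    iface = sorted({i for i, _ in native} | {j for _, j in native})
    ref_res = {r.seq_index: r for r in reference.iter_residues()}
    mod_res = list(model.iter_residues())
    pm, pr = [], []
    for i in iface:
        for name in BACKBONE_ATOMS:
            xr = ref_res[i].atom(name)
            xm = mod_res[i].atom(name)
            if xr is not None and xm is not None:
                pr.append(xr)
                pm.append(xm)
    pm, pr = np.asarray(pm), np.asarray(pr)
    rot, pc, qc = _superpose(pm, pr)
    fitted = rot.apply(pm - pc) + qc
    return float(np.sqrt(np.mean(np.sum((fitted - pr) ** 2, axis=1))))


def brute_pdockq2(plddt: np.ndarray, pae: np.ndarray, contacts: set) -> float:
    """Straight-line transcription of the published pDockQ2 formula."""
    residues = sorted({i for i, _ in contacts} | {j for _, j in contacts})
    mean_plddt = sum(plddt[i] for i in residues) / len(residues)
    terms = []
    for i, j in contacts:
        terms.append(1.0 / (1.0 + (pae[i, j] / 10.0) ** 2))
        terms.append(1.0 / (1.0 + (pae[j, i] / 10.0) ** 2))
    x = mean_plddt * (sum(terms) / len(terms))
    return 1.31 / (1.0 + np.exp(-0.075 * (x - 84.733))) + 0.005
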