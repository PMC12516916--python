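"""Synthetic dimers, rigid-body decoys, and dialect-faithful confidence records.

The generator does not aim at physically realistic protein geometry: chains
are idealized strand-like backbones (N, CA, C, O, CB at fixed local offsets,
small seeded jitter) laid out so that a contiguous patch of exactly
``interface_width`` residues per chain sits within 5 Å of the partner chain
while every other residue stays clear of it.  What matters downstream is
well-defined contacts, graded rigid-body decoys, and confidence records whose
pLDDT/PAE/ipTM degrade consistently with decoy quality — the statistical
skeleton of a prediction benchmark, not its physics.

All randomness flows from one seeded generator per call; the same seed gives
bit-identical output.
"""

from __future__ import annotations

import json
from copy import deepcopy
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import gemmi
import numpy as np

from .errors import DimerQAError
from .interface import find_interface
from .model import Chain, ConfidenceBundle, Dialect, Method, ONE_TO_THREE, Residue, StructureModel

PAE_CEILING = 31.75  # Å, matches the prediction records' PAE cap

# local heavy-atom offsets relative to CA (idealized, compact); the CB points
# toward +z, i.e. across the interface for chain A.  Chain B is built with the
# z components mirrored so its CBs point back at chain A: contact at the patch
# goes through the facing CB pair (≈3.9 Å) while every neighboring residue
# pair stays beyond the 5 Å cutoff.
_ATOM_OFFSETS = {
    "N": np.array([-0.8, 0.5, 0.3]),
    "CA": np.array([0.0, 0.0, 0.0]),
    "C": np.array([0.8, 0.5, -0.3]),
    "O": np.array([0.9, 1.6, -0.4]),
    "CB": np.array([0.0, -0.9, 1.1]),
}
_CA_SPACING = 3.8    # Å along the chain
_IFACE_RISE = 6.1    # Å vertical CA–CA separation of the two chains at the patch
_RAMP = 4.0          # Å lateral step pushing non-patch residues apart
_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class DecoyLadder:
    """A reference dimer plus rigid-body decoys of strictly increasing
    perturbation magnitude; decoy 0 is the reference itself."""

    reference: StructureModel
    decoys: list[tuple[float, StructureModel, ConfidenceBundle]]
    seed: int


def _build_chain(
    chain_id: str,
    ca_positions: np.ndarray,
    names: Sequence[str],
    bfactors: np.ndarray,
    jitter: np.ndarray,
    flip_z: bool = False,
) -> Chain:
    zsign = -1.0 if flip_z else 1.0
    residues = []
    k = 0
    for i, (ca, name) in enumerate(zip(ca_positions, names)):
        atoms = []
        for atom_name, off in _ATOM_OFFSETS.items():
            atoms.append((atom_name, ca + off * np.array([1.0, 1.0, zsign]) + jitter[k]))
            k += 1
        residues.append(
            Residue(
                seq_index=-1,
                auth_number=i + 1,
                name=name,
                atoms=atoms,
                bfactor=float(bfactors[i]),
            )
        )
    return Chain(chain_id=chain_id, residues=residues)


def make_dimer(
    n_a: int = 60,
    n_b: int = 60,
    interface_width: int = 8,
    seed: int = 0,
) -> StructureModel:
    """Generate a two-chain model with a contiguous contact patch of exactly
    ``interface_width`` residues per chain at the 5 Å heavy-atom cutoff.

    Chain A runs along x; chain B runs parallel 4.3 Å above it over the patch
    and ramps away laterally outside it.  Residue names are random, so the
    two chains look heterodimeric to sequence-identity chain mapping.
    """
    if n_a < 1 or n_b < 1:
        raise ValueError("chain lengths must be positive")
    if interface_width < 1 or interface_width > min(n_a, n_b):
        raise ValueError("interface_width must be within both chain lengths")
    rng = np.random.default_rng(seed)
    names_a = [ONE_TO_THREE[c] for c in rng.choice(list(_AA), n_a)]
    names_b = [ONE_TO_THREE[c] for c in rng.choice(list(_AA), n_b)]
    bfac_a = rng.uniform(20.0, 80.0, n_a)
    bfac_b = rng.uniform(20.0, 80.0, n_b)

    i0 = n_a // 2 - interface_width // 2
    j0 = n_b // 2 - interface_width // 2

    for attempt in range(5):
        amp = 0.08 / (attempt + 1)
        jit_a = rng.uniform(-amp, amp, (n_a * len(_ATOM_OFFSETS), 3))
        jit_b = rng.uniform(-amp, amp, (n_b * len(_ATOM_OFFSETS), 3))

        ca_a = np.zeros((n_a, 3))
        ca_a[:, 0] = _CA_SPACING * np.arange(n_a)
        ca_b = np.zeros((n_b, 3))
        for j in range(n_b):
            x = _CA_SPACING * (i0 + (j - j0))
            if j < j0:
                y = _RAMP * (j0 - j)
            elif j >= j0 + interface_width:
                y = _RAMP * (j - (j0 + interface_width - 1))
            else:
                y = 0.0
            ca_b[j] = (x, y, _IFACE_RISE)

        model = StructureModel(
            model_id=f"dimer_s{seed}",
            chains=[
                _build_chain("A", ca_a, names_a, bfac_a, jit_a),
                _build_chain("B", ca_b, names_b, bfac_b, jit_b, flip_z=True),
            ],
            source_dialect=Dialect.GENERIC_REFERENCE,
        )
        model.reindex()
        iface = find_interface(model, "A", "B", 5.0)
        want_a = set(range(i0, i0 + interface_width))
        want_b = set(range(n_a + j0, n_a + j0 + interface_width))
        if iface.residues_a == want_a and iface.residues_b == want_b:
            model.validate()
            return model
    raise DimerQAError(
        f"could not realize an exact {interface_width}-residue patch "
        f"(n_a={n_a}, n_b={n_b}, seed={seed})"
    )


def _rotation_matrix(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    t = np.deg2rad(angle_deg)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(t) * K + (1 - np.cos(t)) * (K @ K)


def perturb(
    model: StructureModel,
    rotation_deg: float,
    translation_ang: float,
    seed: int = 0,
    axis: Optional[Sequence[float]] = None,
    translation_dir: Optional[Sequence[float]] = None,
) -> StructureModel:
    """Rigid-body decoy: rotate/translate the second chain about the interface
    centroid, leaving the first chain untouched.

    Rotation axis and translation direction default to seeded random unit
    vectors; pass them explicitly for controlled decoy geometry.
    """
    if len(model.chains) != 2:
        raise ValueError("perturb expects a dimer")
    rng = np.random.default_rng(seed)

    def unit(v):
        v = np.asarray(v, dtype=float) if v is not None else rng.normal(size=3)
        return v / np.linalg.norm(v)

    axis_v = unit(axis)
    trans_v = unit(translation_dir)
    a, b = model.chain_ids()
    iface = find_interface(model, a, b, 5.0)
    by_index = {r.seq_index: r for r in model.iter_residues()}
    if iface.residues:
        pts = np.concatenate([by_index[i].atom_coords() for i in sorted(iface.residues)])
    else:  # already-separated chains: pivot about chain B's own centroid
        pts = np.concatenate([r.atom_coords() for r in model.chain(b).residues])
    centroid = pts.mean(axis=0)

    R = _rotation_matrix(axis_v, rotation_deg)
    out = deepcopy(model)
    out.model_id = f"{model.model_id}_r{rotation_deg:g}_t{translation_ang:g}"
    for res in out.chain(b).residues:
        res.atoms = [
            (name, R @ (xyz - centroid) + centroid + translation_ang * trans_v)
            for name, xyz in res.atoms
        ]
    return out


def make_confidence(
    model: StructureModel,
    quality: float,
    noise_sd: float = 0.05,
    seed: int = 0,
    method: Method = Method.UNKNOWN,
) -> ConfidenceBundle:
    """Confidence record whose statistics track a latent model quality in [0, 1].

    pLDDT ~ clipped N(40 + 55·q, 100·noise_sd); inter-chain PAE ~ clipped
    N(28·(1−q) + 2, 30·noise_sd); intra-chain PAE stays low; ipTM is q plus
    noise; pTM shares ipTM's noise component (correlation ≈ 0.8 at fixed q).
    ``noise_sd`` is a unitless dial scaled to each score's natural range.
    """
    if not (0.0 <= quality <= 1.0):
        raise ValueError(f"quality={quality} outside [0, 1]")
    rng = np.random.default_rng(seed)
    n = model.n_residues
    n_a = len(model.chains[0])

    plddt = np.clip(rng.normal(40.0 + 55.0 * quality, 100.0 * noise_sd + 1e-12, n), 0.0, 100.0)
    inter_mean = 28.0 * (1.0 - quality) + 2.0
    intra_mean = 1.5 + 2.5 * (1.0 - quality)
    pae = rng.normal(intra_mean, 30.0 * noise_sd + 1e-12, (n, n))
    pae[:n_a, n_a:] += inter_mean - intra_mean
    pae[n_a:, :n_a] += inter_mean - intra_mean
    pae = np.clip(pae, 0.0, PAE_CEILING)

    e_shared = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
    e_own = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
    iptm = float(np.clip(quality + e_shared, 0.0, 1.0))
    ptm = float(np.clip(quality + 0.8 * e_shared + 0.6 * e_own, 0.0, 1.0))
    return ConfidenceBundle(plddt=plddt, pae=pae, ptm=ptm, iptm=iptm, method=method)


def make_ladder(
    n_steps: int = 10,
    seed: int = 0,
    max_rotation: float = 90.0,
    max_translation: float = 0.0,
    noise_sd: float = 0.02,
    **dimer_kwargs,
) -> DecoyLadder:
    """Reference dimer plus a rigid-rotation decoy ladder of increasing
    magnitude (decoy 0 is the reference)."""
    reference = make_dimer(seed=seed, **dimer_kwargs)
    magnitudes = np.linspace(0.0, 1.0, n_steps)
    decoys = []
    for k, m in enumerate(magnitudes):
        decoy = perturb(
            reference, rotation_deg=max_rotation * m,
            translation_ang=max_translation * m,
            seed=seed, axis=(0.0, 0.0, 1.0), translation_dir=(1.0, 0.0, 0.0),
        )
        conf = make_confidence(
            decoy, quality=1.0 - m, noise_sd=noise_sd, seed=seed + 1000 + k
        )
        decoys.append((float(m), decoy, conf))
    return DecoyLadder(reference=reference, decoys=decoys, seed=seed)


# ---------------------------------------------------------------------------
# dialect-faithful file output


def _to_gemmi(model: StructureModel, bfactor_from_plddt: bool) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = model.model_id
    gm = gemmi.Model(1)
    for chain in model.chains:
        gc = gemmi.Chain(chain.chain_id)
        for res in chain.residues:
            gr = gemmi.Residue()
            gr.name = res.name
            gr.seqid = gemmi.SeqId(res.auth_number, " ")
            b = res.plddt if (bfactor_from_plddt and res.plddt is not None) else res.bfactor
            for name, xyz in res.atoms:
                at = gemmi.Atom()
                at.name = name
                at.pos = gemmi.Position(*xyz)
                at.element = gemmi.Element("N" if name == "N" else "O" if name == "O" else "C")
                at.occ = 1.0
                at.b_iso = float(b)
                gr.add_atom(at)
            gc.add_residue(gr)
        gm.add_chain(gc)
    st.add_model(gm)
    st.setup_entities()
    return st


def write_fixture(
    model: StructureModel,
    confidence: ConfidenceBundle,
    dialect: Dialect,
    out_dir: str | Path,
) -> tuple[Path, Path]:
    """Write (structure file, confidence JSON) in one prediction dialect.

    ColabFold: PDB (pLDDT in the B-factor column, as the predictor writes it)
    plus a scores JSON.  AF3: mmCIF plus a confidence JSON whose per-residue
    pLDDT is expanded to atom level and whose PAE carries token maps.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    confidence.check_against(model)
    plddt = confidence.plddt
    mdl = deepcopy(model)
    for res, v in zip(mdl.iter_residues(), plddt):
        res.plddt = float(v)

    if dialect == Dialect.COLABFOLD:
        struct_path = out_dir / f"{model.model_id}.pdb"
        _to_gemmi(mdl, bfactor_from_plddt=True).write_pdb(str(struct_path))
        conf_path = out_dir / f"{model.model_id}_scores.json"
        record = {
            "plddt": [round(float(v), 4) for v in plddt],
            "pae": [[round(float(v), 4) for v in row] for row in confidence.pae],
            "ptm": round(float(confidence.ptm), 6),
            "iptm": round(float(confidence.iptm), 6),
            "max_pae": PAE_CEILING,
        }
    elif dialect == Dialect.AF3:
        struct_path = out_dir / f"{model.model_id}.cif"
        _to_gemmi(mdl, bfactor_from_plddt=True).make_mmcif_document().write_file(str(struct_path))
        atom_plddts, chain_ids, res_ids = [], [], []
        for chain in mdl.chains:
            for res in chain.residues:
                atom_plddts.extend([round(float(res.plddt), 4)] * len(res.atoms))
                chain_ids.append(chain.chain_id)
                res_ids.append(res.auth_number)
        conf_path = out_dir / f"{model.model_id}_confidences.json"
        record = {
            "atom_plddts": atom_plddts,
            "pae": [[round(float(v), 4) for v in row] for row in confidence.pae],
            "token_chain_ids": chain_ids,
            "token_res_ids": res_ids,
            "ptm": round(float(confidence.ptm), 6),
            "iptm": round(float(confidence.iptm), 6),
        }
    else:
        raise ValueError(f"no fixture writer for dialect {dialect}")
    conf_path.write_text(json.dumps(record))
    return struct_path, conf_path


def write_reference(model: StructureModel, out_dir: str | Path) -> Path:
    """Write a reference structure as PDB (B-factor channel preserved)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / f"{model.model_id}_ref.pdb"
    _to_gemmi(model, bfactor_from_plddt=False).write_pdb(str(path))
    return path
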