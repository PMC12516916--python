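"""Reference-based model quality: DockQ and CAPRI classification.

DockQ combines three CAPRI-derived components into one value in [0, 1]:

* **fnat** — fraction of native inter-chain residue contacts (5 Å heavy-atom)
  reproduced by the model;
* **iRMS** — backbone RMSD over the native interface residues (10 Å
  heavy-atom interface) after superposing on those residues;
* **LRMS** — backbone RMSD of the ligand chain after superposing the model's
  receptor chain (the longer reference chain) onto the reference receptor.

DockQ = (fnat + 1/(1+(iRMS/1.5)²) + 1/(1+(LRMS/8.5)²)) / 3, with CAPRI class
boundaries 0.23 / 0.49 / 0.80 (inclusive on the lower edge).  Scaling
constants, cutoffs and the N/CA/C/O backbone definition follow the original
DockQ publication.  Residue correspondence between model and reference comes
from a global sequence alignment per mapped chain, not from author numbering,
because predictors renumber residues from 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from Bio import Align

from .errors import DimerQAError
from .interface import find_interface
from .model import BACKBONE_ATOMS, Residue, StructureModel

logger = logging.getLogger(__name__)

D1 = 1.5   # Å, iRMS half-saturation scale
D2 = 8.5   # Å, LRMS half-saturation scale
FNAT_CONTACT_CUTOFF = 5.0        # Å, heavy-atom
IRMS_INTERFACE_CUTOFF = 10.0     # Å, heavy-atom
CLASS_BOUNDS = (0.23, 0.49, 0.80)
LOW_IDENTITY = 0.30


@dataclass
class ChainMap:
    """Model→reference chain correspondence with per-chain residue alignments."""

    pairs: tuple[tuple[str, str], ...]          # ((model_chain, ref_chain), ...)
    identities: tuple[float, ...]
    ambiguous: bool
    # per mapped pair: list of (model Residue, reference Residue) aligned pairs
    residue_pairs: dict[tuple[str, str], list[tuple[Residue, Residue]]]


@dataclass
class DockQResult:
    fnat: float
    irms: float
    lrms: float
    dockq: float
    capri_class: str
    chain_map: ChainMap


def capri_class(dockq_value: float, bounds: Sequence[float] = CLASS_BOUNDS) -> str:
    """CAPRI quality class; boundaries are inclusive on the lower edge."""
    lo, mid, hi = bounds
    if dockq_value >= hi:
        return "high"
    if dockq_value >= mid:
        return "medium"
    if dockq_value >= lo:
        return "acceptable"
    return "incorrect"


def dockq_from_components(fnat_value: float, irms_value: float, lrms_value: float) -> float:
    return float(
        (
            fnat_value
            + 1.0 / (1.0 + (irms_value / D1) ** 2)
            + 1.0 / (1.0 + (lrms_value / D2) ** 2)
        )
        / 3.0
    )


def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1.0
    a.mismatch_score = 0.0
    a.open_gap_score = -0.6
    a.extend_gap_score = -0.1
    return a


def _align_pair(
    model: StructureModel, reference: StructureModel, mc: str, rc: str
) -> tuple[float, list[tuple[Residue, Residue]]]:
    """Globally align one chain pair; return identity fraction and the aligned
    residue pairs (all aligned columns, mismatches included)."""
    sm = model.sequence(mc)
    sr = reference.sequence(rc)
    aln = _aligner().align(sm, sr)[0]
    res_m = model.chain(mc).residues
    res_r = reference.chain(rc).residues
    pairs: list[tuple[Residue, Residue]] = []
    n_id = 0
    for (ms, me), (rs, re_) in zip(*aln.aligned):
        for i, j in zip(range(ms, me), range(rs, re_)):
            pairs.append((res_m[i], res_r[j]))
            if sm[i] == sr[j]:
                n_id += 1
    identity = n_id / min(len(sm), len(sr)) if min(len(sm), len(sr)) else 0.0
    return identity, pairs


def map_chains(
    model: StructureModel,
    reference: StructureModel,
    allow_low_identity: bool = False,
) -> ChainMap:
    """Pair model chains with reference chains by maximizing summed global
    sequence identity over both permutations of a dimer."""
    if len(model.chains) != 2 or len(reference.chains) != 2:
        raise DimerQAError("chain mapping expects 2-chain model and reference")
    ma, mb = model.chain_ids()
    ra, rb = reference.chain_ids()
    candidates = [((ma, ra), (mb, rb)), ((ma, rb), (mb, ra))]
    scored = []
    for perm in candidates:
        idents, aligned = [], {}
        for mc, rc in perm:
            ident, pairs = _align_pair(model, reference, mc, rc)
            idents.append(ident)
            aligned[(mc, rc)] = pairs
        scored.append((sum(idents), perm, tuple(idents), aligned))
    best = max(scored, key=lambda s: s[0])
    ambiguous = abs(scored[0][0] - scored[1][0]) < 1e-9
    if ambiguous:
        best = scored[0]  # ties broken by the first (identity-order) permutation
        logger.warning("chain mapping ambiguous (homodimer-like); using first permutation")
    _, perm, idents, aligned = best
    if min(idents) < LOW_IDENTITY:
        msg = (
            f"best chain mapping has identity {min(idents):.2f} < {LOW_IDENTITY:.0%} "
            f"on at least one chain"
        )
        if not allow_low_identity:
            raise DimerQAError(msg + "; pass allow_low_identity=True to proceed")
        logger.warning(msg)
    return ChainMap(
        pairs=perm, identities=idents, ambiguous=ambiguous, residue_pairs=aligned
    )


def _to_ref_index(chain_map: ChainMap) -> dict[int, int]:
    """model seq_index → reference seq_index over aligned residue pairs."""
    out: dict[int, int] = {}
    for pairs in chain_map.residue_pairs.values():
        for mres, rres in pairs:
            out[mres.seq_index] = rres.seq_index
    return out


def fnat(
    model: StructureModel, reference: StructureModel, chain_map: ChainMap
) -> float:
    """Fraction of native inter-chain contacts present in the model."""
    (mc_a, rc_a), (mc_b, rc_b) = chain_map.pairs
    native = find_interface(reference, rc_a, rc_b, FNAT_CONTACT_CUTOFF).contact_pairs
    if not native:
        raise DimerQAError("reference has no inter-chain contacts at the fnat cutoff")
    model_contacts = find_interface(model, mc_a, mc_b, FNAT_CONTACT_CUTOFF).contact_pairs
    to_ref = _to_ref_index(chain_map)
    mapped = {
        (to_ref[i], to_ref[j])
        for i, j in model_contacts
        if i in to_ref and j in to_ref
    }
    return len(mapped & set(native)) / len(native)


def _kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid fit of P onto Q (rotation + translation, no
    reflection): returns (R, t) with R @ p + t ≈ q."""
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return R, qc - R @ pc


def _backbone_pairs(
    pairs: list[tuple[Residue, Residue]]
) -> tuple[np.ndarray, np.ndarray]:
    """Matched backbone coordinates (model, reference) over aligned residues."""
    pm, pr = [], []
    for mres, rres in pairs:
        for name in BACKBONE_ATOMS:
            xm, xr = mres.atom(name), rres.atom(name)
            if xm is not None and xr is not None:
                pm.append(xm)
                pr.append(xr)
    return np.asarray(pm, dtype=float), np.asarray(pr, dtype=float)


def _rmsd(P: np.ndarray, Q: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((P - Q) ** 2, axis=1))))


def _receptor_ligand(chain_map: ChainMap, reference: StructureModel):
    """Receptor = longer reference chain; ties go to the first mapped pair."""
    (p0, p1) = chain_map.pairs
    len0 = len(reference.chain(p0[1]))
    len1 = len(reference.chain(p1[1]))
    return (p0, p1) if len0 >= len1 else (p1, p0)


def lrms(
    model: StructureModel, reference: StructureModel, chain_map: ChainMap
) -> float:
    """Ligand backbone RMSD after superposing the receptor chains."""
    rec_pair, lig_pair = _receptor_ligand(chain_map, reference)
    rec_m, rec_r = _backbone_pairs(chain_map.residue_pairs[rec_pair])
    lig_m, lig_r = _backbone_pairs(chain_map.residue_pairs[lig_pair])
    if len(rec_m) < 3 or len(lig_m) < 3:
        raise DimerQAError("fewer than 3 mappable backbone atoms for LRMS")
    R, t = _kabsch(rec_m, rec_r)
    return _rmsd(lig_m @ R.T + t, lig_r)


def irms(
    model: StructureModel, reference: StructureModel, chain_map: ChainMap
) -> float:
    """Backbone RMSD over native interface residues (10 Å definition) after
    superposing on exactly those residues."""
    (mc_a, rc_a), (mc_b, rc_b) = chain_map.pairs
    iface = find_interface(reference, rc_a, rc_b, IRMS_INTERFACE_CUTOFF)
    if not iface.contact_pairs:
        raise DimerQAError("reference has no interface at the iRMS cutoff")
    ref_iface = iface.residues
    pairs = [
        (mres, rres)
        for chain_pairs in chain_map.residue_pairs.values()
        for mres, rres in chain_pairs
        if rres.seq_index in ref_iface
    ]
    pm, pr = _backbone_pairs(pairs)
    if len(pm) < 3:
        raise DimerQAError("fewer than 3 mappable interface backbone atoms for iRMS")
    R, t = _kabsch(pm, pr)
    return _rmsd(pm @ R.T + t, pr)


def dockq(
    model: StructureModel,
    reference: StructureModel,
    chain_map: Optional[ChainMap] = None,
    allow_low_identity: bool = False,
) -> DockQResult:
    """Full DockQ evaluation of a dimer model against a reference dimer."""
    if chain_map is None:
        chain_map = map_chains(model, reference, allow_low_identity=allow_low_identity)
    f = fnat(model, reference, chain_map)
    i = irms(model, reference, chain_map)
    l = lrms(model, reference, chain_map)
    value = dockq_from_components(f, i, l)
    return DockQResult(
        fnat=f, irms=i, lrms=l, dockq=value,
        capri_class=capri_class(value), chain_map=chain_map,
    )


def extract_pair(assembly: StructureModel, chain_a: str, chain_b: str) -> StructureModel:
    """Copy one chain pair out of a larger assembly as a standalone dimer."""
    from copy import deepcopy

    sub = StructureModel(
        model_id=f"{assembly.model_id}_{chain_a}{chain_b}",
        chains=[deepcopy(assembly.chain(chain_a)), deepcopy(assembly.chain(chain_b))],
        source_dialect=assembly.source_dialect,
    )
    sub.reindex()
    return sub


def multi_config_dockq(
    model: StructureModel,
    reference_assembly: StructureModel,
    candidate_pairs: Sequence[tuple[str, str]],
    allow_low_identity: bool = False,
) -> tuple[dict[tuple[str, str], DockQResult], tuple[str, str]]:
    """DockQ against every candidate chain-pair configuration of an assembly.

    When a target dimer's chains have homologous counterparts in the assembly,
    multiple spatial configurations exist and the model may match any of them;
    the per-configuration results and the best pair are returned.  A model
    below the 'acceptable' bound in every configuration is incorrect-in-all.
    """
    if not candidate_pairs:
        raise DimerQAError("no candidate chain pairs supplied")
    results: dict[tuple[str, str], DockQResult] = {}
    for a, b in candidate_pairs:
        ref = extract_pair(reference_assembly, a, b)
        results[(a, b)] = dockq(model, ref, allow_low_identity=allow_low_identity)
    best = max(results, key=lambda k: results[k].dockq)
    if results[best].dockq < CLASS_BOUNDS[0]:
        logger.warning("model is incorrect in every candidate configuration")
    return results, best
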