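"""Readers for predicted models and reference structures.

Two prediction dialects are supported:

* **ColabFold** — a PDB model plus a JSON scores record with fields
  ``plddt`` (per residue), ``pae`` (N×N), ``ptm``, ``iptm`` and optionally
  ``max_pae``.
* **AlphaFold3** — an mmCIF model plus a JSON confidence record with fields
  ``atom_plddts`` (per atom, file order), ``pae`` (token×token),
  ``token_chain_ids``, ``token_res_ids``, ``ptm``, ``iptm``.

Both are mapped onto the same :class:`~dimerqa.model.StructureModel` /
:class:`~dimerqa.model.ConfidenceBundle` pair.  Cleaning rules applied to every
file: hydrogens, waters and non-amino-acid groups are dropped; alternate
locations are resolved to the highest-occupancy atom (ties broken by file
order); the per-residue B-factor is the mean over the residue's kept heavy
atoms.  Predicted per-residue pLDDT is always taken from the confidence
record, never from the coordinate file's B-factor column, so that the two
dialects behave identically downstream.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import gemmi
import numpy as np

from .errors import ConsistencyError, ParseError
from .model import Chain, ConfidenceBundle, Dialect, Method, Residue, StructureModel

logger = logging.getLogger(__name__)

_REQUIRED_CF_FIELDS = ("plddt", "pae", "ptm", "iptm")
_REQUIRED_AF3_FIELDS = ("atom_plddts", "pae", "token_chain_ids", "token_res_ids", "ptm", "iptm")


def _is_amino_acid(res: gemmi.Residue) -> bool:
    info = gemmi.find_tabulated_residue(res.name)
    return info is not None and info.is_amino_acid()


def _select_altlocs(res: gemmi.Residue) -> list[gemmi.Atom]:
    """One atom per name: highest occupancy wins, ties go to file order."""
    best: dict[str, gemmi.Atom] = {}
    for atom in res:
        if atom.is_hydrogen():
            continue
        prev = best.get(atom.name)
        if prev is None or atom.occ > prev.occ:
            best[atom.name] = atom
    # dict preserves first-seen order, which is file order
    return list(best.values())


def _convert_structure(
    st: gemmi.Structure, model_id: str, dialect: Dialect
) -> tuple[StructureModel, list[int]]:
    """Convert the first gemmi model; also return per-residue heavy-atom counts
    over the *raw* file order (protein residues only), used for AF3 pLDDT
    aggregation."""
    if len(st) == 0:
        raise ParseError(f"{model_id}: no models in file")
    chains: list[Chain] = []
    atom_counts: list[int] = []
    dropped: list[str] = []
    for gchain in st[0]:
        residues: list[Residue] = []
        for gres in gchain:
            if gres.is_water() or not _is_amino_acid(gres):
                dropped.append(f"{gchain.name}/{gres.name}{gres.seqid.num}")
                continue
            atoms = _select_altlocs(gres)
            if not atoms:
                continue
            coords = [(a.name, np.array([a.pos.x, a.pos.y, a.pos.z])) for a in atoms]
            bfac = float(np.mean([a.b_iso for a in atoms]))
            residues.append(
                Residue(
                    seq_index=-1,
                    auth_number=gres.seqid.num,
                    name=gres.name,
                    atoms=coords,
                    bfactor=max(bfac, 0.0),
                )
            )
            atom_counts.append(len(atoms))
        if residues:
            chains.append(Chain(chain_id=gchain.name, residues=residues))
    if dropped:
        logger.warning("%s: dropped %d non-protein/solvent groups (e.g. %s)",
                       model_id, len(dropped), ", ".join(dropped[:5]))
    model = StructureModel(model_id=model_id, chains=chains, source_dialect=dialect)
    model.reindex()
    model.validate()
    return model, atom_counts


def _read_gemmi(path: str | Path) -> gemmi.Structure:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"file not found: {path}")
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"could not parse structure {path}: {exc}") from exc
    st.setup_entities()
    return st


def _load_json(path: str | Path, required: tuple[str, ...]) -> dict:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"file not found: {path}")
    try:
        record = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"invalid JSON in {path}: {exc}") from exc
    if isinstance(record, list):  # some ColabFold variants wrap in a list
        record = record[0]
    missing = [f for f in required if f not in record]
    if missing:
        raise ParseError(f"{path}: confidence record is missing field(s) {missing}")
    return record


def read_colabfold(
    model_file: str | Path,
    scores_file: str | Path,
    method: Method = Method.UNKNOWN,
) -> tuple[StructureModel, ConfidenceBundle]:
    """Read a ColabFold PDB model and its JSON scores record."""
    model, _ = _convert_structure(
        _read_gemmi(model_file), Path(model_file).stem, Dialect.COLABFOLD
    )
    record = _load_json(scores_file, _REQUIRED_CF_FIELDS)
    bundle = ConfidenceBundle(
        plddt=np.asarray(record["plddt"], dtype=float),
        pae=np.asarray(record["pae"], dtype=float),
        ptm=float(record["ptm"]),
        iptm=float(record["iptm"]),
        method=method,
    )
    bundle.check_against(model)
    for res, value in zip(model.iter_residues(), bundle.plddt):
        res.plddt = float(value)
    return model, bundle


def read_af3(
    model_file: str | Path,
    confidence_file: str | Path,
    method: Method = Method.AF3,
) -> tuple[StructureModel, ConfidenceBundle]:
    """Read an AlphaFold3 mmCIF model and its JSON confidence record.

    Atom-level pLDDT is aggregated to per-residue values by an unweighted mean
    over the residue's heavy atoms.  Token rows/columns of the PAE matrix are
    mapped to residues via ``token_chain_ids``/``token_res_ids``; non-protein
    tokens are dropped with a warning.
    """
    model, atom_counts = _convert_structure(
        _read_gemmi(model_file), Path(model_file).stem, Dialect.AF3
    )
    record = _load_json(confidence_file, _REQUIRED_AF3_FIELDS)

    atom_plddts = np.asarray(record["atom_plddts"], dtype=float)
    n_atoms = int(sum(atom_counts))
    if atom_plddts.shape[0] != n_atoms:
        raise ConsistencyError(
            f"atom_plddts has {atom_plddts.shape[0]} entries but the structure "
            f"has {n_atoms} heavy atoms"
        )
    # unweighted mean over each residue's heavy atoms
    plddt = np.empty(len(atom_counts))
    pos = 0
    for i, cnt in enumerate(atom_counts):
        plddt[i] = atom_plddts[pos : pos + cnt].mean()
        pos += cnt

    chain_ids = list(record["token_chain_ids"])
    res_ids = [int(r) for r in record["token_res_ids"]]
    if len(chain_ids) != len(res_ids):
        raise ConsistencyError("token_chain_ids and token_res_ids differ in length")
    pae = np.asarray(record["pae"], dtype=float)
    if pae.shape != (len(chain_ids), len(chain_ids)):
        raise ConsistencyError(
            f"token-level PAE shape {pae.shape} does not match {len(chain_ids)} tokens"
        )

    residue_keys = {
        (c.chain_id, r.auth_number): r.seq_index
        for c in model.chains
        for r in c.residues
    }
    keep: list[int] = []
    order: list[int] = []
    n_dropped = 0
    for t, key in enumerate(zip(chain_ids, res_ids)):
        if key in residue_keys:
            keep.append(t)
            order.append(residue_keys[key])
        else:
            n_dropped += 1
    if n_dropped:
        logger.warning("%s: dropped %d non-protein tokens from PAE", model.model_id, n_dropped)
    if sorted(order) != list(range(model.n_residues)):
        raise ConsistencyError("token map does not cover every protein residue exactly once")
    # reorder token axes into concatenated residue order
    sub = pae[np.ix_(keep, keep)]
    inv = np.argsort(order)
    pae_res = sub[np.ix_(inv, inv)]

    bundle = ConfidenceBundle(
        plddt=plddt,
        pae=pae_res,
        ptm=float(record["ptm"]),
        iptm=float(record["iptm"]),
        method=method,
    )
    bundle.check_against(model)
    for res, value in zip(model.iter_residues(), bundle.plddt):
        res.plddt = float(value)
    return model, bundle


def read_reference(model_file: str | Path, require_dimer: bool = True) -> StructureModel:
    """Read a reference structure (PDB or mmCIF) with the same cleaning rules
    as predictions; the B-factor channel is preserved and per-residue pLDDT is
    left unset."""
    model, _ = _convert_structure(
        _read_gemmi(model_file), Path(model_file).stem, Dialect.GENERIC_REFERENCE
    )
    if require_dimer and len(model.chains) < 2:
        raise ParseError(
            f"{model.model_id}: reference has {len(model.chains)} protein chain(s); "
            "a dimer reference needs at least 2"
        )
    return model
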