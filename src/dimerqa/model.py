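"""In-memory data model for predicted dimer structures and their confidence records.

A :class:`StructureModel` holds protein chains only (heavy atoms, no solvent or
hetero groups); residues carry a B-factor channel (mean over heavy atoms) and an
optional per-residue pLDDT channel filled from the predictor's confidence record.
All matrix-valued confidence data (PAE) is indexed by the 0-based *concatenated*
residue index, i.e. position in chain order across the whole model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator, Optional, Sequence

import numpy as np

from .errors import ConsistencyError

BACKBONE_ATOMS = ("N", "CA", "C", "O")


class Dialect(str, Enum):
    COLABFOLD = "colabfold"
    AF3 = "af3"
    GENERIC_REFERENCE = "generic_reference"


class Method(str, Enum):
    """Prediction-method regime: ColabFold with/without templates, AlphaFold3."""

    CF_T = "CF-T"
    CF_F = "CF-F"
    AF3 = "AF3"
    UNKNOWN = "unknown"


@dataclass
class Residue:
    seq_index: int          # 0-based position in the concatenated model sequence
    auth_number: int        # residue number as written in the file
    name: str               # 3-letter code
    atoms: list[tuple[str, np.ndarray]]
    bfactor: float = 0.0
    plddt: Optional[float] = None

    def atom_coords(self) -> np.ndarray:
        return np.array([xyz for _, xyz in self.atoms], dtype=float)

    def atom(self, name: str) -> Optional[np.ndarray]:
        for a, xyz in self.atoms:
            if a == name:
                return xyz
        return None

    def validate(self) -> None:
        if not self.atoms:
            raise ConsistencyError(f"residue {self.name}{self.auth_number} has no heavy atoms")
        if not np.isfinite(self.atom_coords()).all():
            raise ConsistencyError(f"non-finite coordinates in residue {self.name}{self.auth_number}")
        if self.bfactor < 0:
            raise ConsistencyError("negative B-factor")
        if self.plddt is not None and not (0.0 <= self.plddt <= 100.0):
            raise ConsistencyError(f"pLDDT {self.plddt} outside [0, 100]")


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)

    def validate(self) -> None:
        nums = [r.auth_number for r in self.residues]
        if any(b <= a for a, b in zip(nums, nums[1:])):
            raise ConsistencyError(
                f"chain {self.chain_id}: residue numbers not strictly increasing"
            )
        for r in self.residues:
            r.validate()


@dataclass
class StructureModel:
    model_id: str
    chains: list[Chain]
    source_dialect: Dialect = Dialect.GENERIC_REFERENCE

    @property
    def n_residues(self) -> int:
        return sum(len(c) for c in self.chains)

    def iter_residues(self) -> Iterator[Residue]:
        for chain in self.chains:
            yield from chain.residues

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"chain {chain_id!r} not found; have {[c.chain_id for c in self.chains]}")

    def chain_ids(self) -> list[str]:
        return [c.chain_id for c in self.chains]

    def sequence(self, chain_id: str) -> str:
        """One-letter sequence of a chain (X for non-standard residues)."""
        return "".join(_THREE_TO_ONE.get(r.name, "X") for r in self.chain(chain_id).residues)

    def reindex(self) -> None:
        """Assign 0-based concatenated seq_index in chain order."""
        for i, res in enumerate(self.iter_residues()):
            res.seq_index = i

    def validate(self) -> None:
        for c in self.chains:
            c.validate()
        idx = [r.seq_index for r in self.iter_residues()]
        if idx != list(range(self.n_residues)):
            raise ConsistencyError("seq_index is not the 0-based concatenated order")


@dataclass
class ConfidenceBundle:
    """Per-model confidence record: pLDDT vector, PAE matrix, pTM/ipTM scalars.

    ``pae[i, j]`` is the expected positional error (Å) of residue *j* when the
    prediction is aligned on residue *i*; it need not be symmetric and the
    diagonal keeps whatever the file stored.
    """

    plddt: np.ndarray
    pae: np.ndarray
    ptm: float
    iptm: float
    method: Method = Method.UNKNOWN

    def __post_init__(self) -> None:
        self.plddt = np.asarray(self.plddt, dtype=float)
        self.pae = np.asarray(self.pae, dtype=float)
        n = self.plddt.shape[0]
        if self.plddt.ndim != 1:
            raise ConsistencyError("plddt must be a vector")
        if self.pae.shape != (n, n):
            raise ConsistencyError(
                f"pae shape {self.pae.shape} does not match plddt length {n}"
            )
        if np.any(self.plddt < 0) or np.any(self.plddt > 100):
            raise ConsistencyError("plddt values outside [0, 100]")
        if np.any(self.pae < 0):
            raise ConsistencyError("negative PAE values")
        for name, v in (("ptm", self.ptm), ("iptm", self.iptm)):
            if not (0.0 <= v <= 1.0):
                raise ConsistencyError(f"{name}={v} outside [0, 1]")

    @property
    def n_residues(self) -> int:
        return int(self.plddt.shape[0])

    def check_against(self, model: StructureModel) -> None:
        if self.n_residues != model.n_residues:
            raise ConsistencyError(
                f"confidence record covers {self.n_residues} residues but the "
                f"structure has {model.n_residues}"
            )


_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}


def concatenated_coords(model: StructureModel, atoms: Sequence[str] | None = None) -> np.ndarray:
    """Stack heavy-atom coordinates; optionally restrict to named atoms."""
    out = []
    for res in model.iter_residues():
        for name, xyz in res.atoms:
            if atoms is None or name in atoms:
                out.append(xyz)
    return np.array(out, dtype=float)
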