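"""Reference-free per-model score panel.

Scores computed here: global pLDDT/PAE means, their interface-restricted
versions ipLDDT/iPAE, the AlphaFold-Multimer *model confidence*
(0.8·ipTM + 0.2·pTM), and pDockQ2.  pTM and ipTM are pass-through values from
the predictor's record — they are never recomputed from the PAE matrix.  A
VoroIF-GNN interface score, when available, is accepted as an external input
and copied through untouched.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import EmptyInterfaceError
from .interface import DEFAULT_CONTACT_CUTOFF, InterfaceResult, find_interface, is_interacting
from .model import ConfidenceBundle, Method, StructureModel

# pDockQ2 sigmoid constants and PAE damping scale, transcribed from the
# pDockQ2 publication (Zhu et al. 2023, Bioinformatics 39:btad424).
PDOCKQ2_L = 1.31
PDOCKQ2_X0 = 84.733
PDOCKQ2_K = 0.075
PDOCKQ2_B = 0.005
PDOCKQ2_D0 = 10.0  # Å


@dataclass
class ScoreSet:
    """The full reference-free panel for one model at one interface cutoff."""

    model_id: str
    method: Method
    plddt_global: float
    pae_global: float
    iplddt: float
    ipae: float
    ptm: float
    iptm: float
    model_confidence: float
    pdockq2: float
    voroif: Optional[float] = None
    cutoff: float = DEFAULT_CONTACT_CUTOFF

    COLUMNS = (
        "model_id", "method", "plddt", "pae", "iplddt", "ipae",
        "ptm", "iptm", "model_confidence", "pdockq2", "voroif",
    )

    def as_row(self) -> dict:
        return {
            "model_id": self.model_id,
            "method": self.method.value,
            "plddt": self.plddt_global,
            "pae": self.pae_global,
            "iplddt": self.iplddt,
            "ipae": self.ipae,
            "ptm": self.ptm,
            "iptm": self.iptm,
            "model_confidence": self.model_confidence,
            "pdockq2": self.pdockq2,
            "voroif": self.voroif if self.voroif is not None else np.nan,
        }


def global_plddt(confidence: ConfidenceBundle) -> float:
    """Mean pLDDT over all residues."""
    if confidence.plddt.size == 0:
        raise ValueError("empty pLDDT vector")
    return float(confidence.plddt.mean())


def global_pae(confidence: ConfidenceBundle) -> float:
    """Mean PAE over all matrix entries, diagonal included."""
    if confidence.pae.size == 0:
        raise ValueError("empty PAE matrix")
    return float(confidence.pae.mean())


def iplddt(confidence: ConfidenceBundle, iface: InterfaceResult) -> float:
    """Mean pLDDT over the interface residues of both chains."""
    if not iface.contact_pairs:
        raise EmptyInterfaceError(
            "interface pLDDT undefined for an empty interface; "
            "the model may be non-interacting at this cutoff"
        )
    idx = sorted(iface.residues)
    return float(confidence.plddt[idx].mean())


def ipae(
    confidence: ConfidenceBundle,
    iface: InterfaceResult,
    mode: str = "contacts",
) -> float:
    """Mean inter-chain PAE over the interface.

    ``mode='contacts'`` (default) averages ``pae[i, j]`` and ``pae[j, i]`` over
    the contact pairs, both matrix orientations equally weighted.
    ``mode='cross'`` averages over the full cross-product of interface
    residues instead — provided for sensitivity checks, since "interface PAE"
    admits both readings.
    """
    if not iface.contact_pairs:
        raise EmptyInterfaceError("interface PAE undefined for an empty interface")
    if mode == "contacts":
        ii = np.fromiter((i for i, _ in iface.contact_pairs), dtype=int)
        jj = np.fromiter((j for _, j in iface.contact_pairs), dtype=int)
    elif mode == "cross":
        a = np.array(sorted(iface.residues_a), dtype=int)
        b = np.array(sorted(iface.residues_b), dtype=int)
        ii, jj = map(np.ravel, np.meshgrid(a, b, indexing="ij"))
    else:
        raise ValueError(f"unknown iPAE mode {mode!r}")
    return float((confidence.pae[ii, jj].sum() + confidence.pae[jj, ii].sum()) / (2 * ii.size))


def model_confidence(ptm: float, iptm: float) -> float:
    """AlphaFold-Multimer ranking confidence: 0.8·ipTM + 0.2·pTM."""
    for name, v in (("ptm", ptm), ("iptm", iptm)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name}={v} outside [0, 1]")
    return 0.8 * iptm + 0.2 * ptm


def pdockq2(confidence: ConfidenceBundle, iface: InterfaceResult) -> float:
    """pDockQ2: sigmoid of mean interface pLDDT damped by inter-chain PAE.

    x = <pLDDT>_iface · <1 / (1 + (PAE_ij / d0)^2)>_contacts with d0 = 10 Å,
    mapped through L / (1 + exp(-k (x - x0))) + b using the published
    constants (L=1.31, x0=84.733, k=0.075, b=0.005).  Both PAE orientations of
    each contact enter the damping average.
    """
    if not iface.contact_pairs:
        raise EmptyInterfaceError("pDockQ2 undefined for an empty interface")
    mean_plddt = iplddt(confidence, iface)
    ii = np.fromiter((i for i, _ in iface.contact_pairs), dtype=int)
    jj = np.fromiter((j for _, j in iface.contact_pairs), dtype=int)
    pae_vals = np.concatenate([confidence.pae[ii, jj], confidence.pae[jj, ii]])
    damp = float(np.mean(1.0 / (1.0 + (pae_vals / PDOCKQ2_D0) ** 2)))
    x = mean_plddt * damp
    return PDOCKQ2_L / (1.0 + np.exp(-PDOCKQ2_K * (x - PDOCKQ2_X0))) + PDOCKQ2_B


def score_model(
    model: StructureModel,
    confidence: ConfidenceBundle,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    voroif: Optional[float] = None,
    allow_non_interacting: bool = False,
) -> ScoreSet:
    """Assemble the full score panel for a heterodimer at one interface cutoff."""
    confidence.check_against(model)
    if len(model.chains) != 2:
        raise ValueError(f"score panel expects a dimer, got {len(model.chains)} chains")
    if not allow_non_interacting and not is_interacting(model, cutoff):
        raise EmptyInterfaceError(
            f"{model.model_id}: fewer than 3 interface residues per chain at "
            f"{cutoff} Å; pass allow_non_interacting=True to score anyway"
        )
    a, b = model.chain_ids()
    iface = find_interface(model, a, b, cutoff)
    return ScoreSet(
        model_id=model.model_id,
        method=confidence.method,
        plddt_global=global_plddt(confidence),
        pae_global=global_pae(confidence),
        iplddt=iplddt(confidence, iface),
        ipae=ipae(confidence, iface),
        ptm=confidence.ptm,
        iptm=confidence.iptm,
        model_confidence=model_confidence(confidence.ptm, confidence.iptm),
        pdockq2=pdockq2(confidence, iface),
        voroif=voroif,
        cutoff=cutoff,
    )
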