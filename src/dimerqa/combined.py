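"""Score normalization, the combined scores, and cutoff-based classification.

ipLDDT and iPAE are rescaled so that every score lives on [0, 1] with 1 the
optimal outcome; pTM/ipTM/VoroIF already do.  Two combinations are defined:

* the **unweighted combined score** — the plain mean of the normalized scores;
* the **C2Qscore** — an affine combination ``dot(weights, scores) + bias``
  whose weights come from a linear regression against DockQ.  It is *not*
  clamped: fitted combinations can legitimately leave [0, 1].

Classification against per-method cutoffs is inclusive (``>=`` for
higher-is-better scores, ``<=`` for the PAE family).  The ipTM "gray zone"
(0.6–0.8) flag reproduces the AlphaFold server guidance under which a
calibrated cutoff is most useful.
"""

from __future__ import annotations

import logging
import tomllib
import warnings
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np

from .model import Method
from .scores import ScoreSet

logger = logging.getLogger(__name__)

DEFAULT_IPAE_MAX = 31.75  # Å, the PAE ceiling of the prediction records

#: scores where larger values mean better models; the PAE family is inverted
HIGHER_IS_BETTER = {
    "plddt", "iplddt", "ptm", "iptm", "model_confidence", "pdockq2",
    "voroif", "c2qscore", "unweighted",
}
LOWER_IS_BETTER = {"pae", "ipae"}

COMBINABLE = ("iplddt", "ipae", "ptm", "iptm", "voroif")

GRAY_ZONE = (0.6, 0.8)


@dataclass
class NormalizedScores:
    """The five combinable scores on a common [0, 1] scale, 1 = optimal."""

    iplddt_n: float
    ipae_n: float
    ptm_n: float
    iptm_n: float
    voroif_n: Optional[float] = None

    def as_dict(self, include_missing: bool = False) -> dict[str, float]:
        d = {
            "iplddt": self.iplddt_n,
            "ipae": self.ipae_n,
            "ptm": self.ptm_n,
            "iptm": self.iptm_n,
        }
        if self.voroif_n is not None or include_missing:
            d["voroif"] = self.voroif_n
        return d


@dataclass
class C2QWeights:
    """Fitted combination: weights over normalized scores, bias, and the
    normalization ceiling they were fitted with."""

    weights: dict[str, float]
    bias: float
    ipae_max: float = DEFAULT_IPAE_MAX
    method: Method = Method.UNKNOWN
    cutoff: Optional[float] = None

    def __post_init__(self) -> None:
        unknown = set(self.weights) - set(COMBINABLE)
        if unknown:
            raise ValueError(f"unknown score names in weights: {sorted(unknown)}")


class GrayZoneFlag(str, Enum):
    HIGH_CONF = "high_conf"
    GRAY = "gray"
    LIKELY_FAILED = "likely_failed"


@dataclass(frozen=True)
class Classification:
    label: str            # "correct" | "incorrect"
    score_used: str
    value: float
    cutoff: float


@dataclass
class CutoffProfile:
    """Per-(score, method) decision cutoffs, loadable from a TOML config."""

    cutoffs: dict[Method, dict[str, float]] = field(default_factory=dict)
    weights: dict[Method, C2QWeights] = field(default_factory=dict)
    gray_zone: tuple[float, float] = GRAY_ZONE
    dockq_class_bounds: tuple[float, float, float] = (0.23, 0.49, 0.80)

    def cutoff_for(self, score_name: str, method: Method) -> float:
        try:
            return self.cutoffs[method][score_name]
        except KeyError:
            available = {m.value: sorted(d) for m, d in self.cutoffs.items()}
            raise KeyError(
                f"no cutoff for score {score_name!r} under method {method.value!r}; "
                f"available: {available}"
            ) from None


def normalize(scores: ScoreSet, ipae_max: float = DEFAULT_IPAE_MAX) -> NormalizedScores:
    """Map the combinable scores onto [0, 1] with 1 optimal.

    ipLDDT is divided by 100; iPAE is inverted as 1 − min(iPAE, max)/max so 0 Å
    maps to 1 and anything at or beyond the ceiling maps to 0; unit-interval
    scores pass through (clamped).
    """
    if ipae_max <= 0:
        raise ValueError(f"ipae_max must be positive, got {ipae_max}")
    clip = lambda v: float(np.clip(v, 0.0, 1.0))
    return NormalizedScores(
        iplddt_n=clip(scores.iplddt / 100.0),
        ipae_n=clip(1.0 - min(scores.ipae, ipae_max) / ipae_max),
        ptm_n=clip(scores.ptm),
        iptm_n=clip(scores.iptm),
        voroif_n=clip(scores.voroif) if scores.voroif is not None else None,
    )


def unweighted_combined(n: NormalizedScores) -> float:
    """Arithmetic mean of the normalized scores that are present."""
    values = list(n.as_dict().values())
    if len(values) < 2:
        raise ValueError("unweighted combination needs at least 2 scores")
    return float(np.mean(values))


def c2qscore(n: NormalizedScores, w: C2QWeights) -> float:
    """Affine combined complex quality score: dot(weights, scores) + bias.

    If VoroIF carries weight but is absent from the input, the remaining
    weights are renormalized to preserve their relative proportions and a
    warning tags the result as C2Qscore(noVoroIF); the score is never silently
    computed with a substituted 0.
    """
    present = n.as_dict()
    weights = dict(w.weights)
    missing = [k for k in weights if k not in present and weights[k] != 0.0]
    if missing:
        if missing != ["voroif"]:
            raise ValueError(f"weighted score(s) missing without fallback: {missing}")
        dropped = weights.pop("voroif")
        rest = sum(weights.values())
        if rest == 0:
            raise ValueError("cannot reweight: all remaining weights are zero")
        weights = {k: v * (rest + dropped) / rest for k, v in weights.items()}
        warnings.warn(
            "VoroIF unavailable; remaining weights renormalized — reporting "
            "C2Qscore(noVoroIF)", stacklevel=2,
        )
    return float(sum(weights.get(k, 0.0) * present[k] for k in present if k in weights) + w.bias)


def classify(
    value: float, score_name: str, method: Method, cutoffs: CutoffProfile
) -> Classification:
    """Correct/incorrect call for one score value under the per-method cutoff."""
    cut = cutoffs.cutoff_for(score_name, method)
    if score_name in LOWER_IS_BETTER:
        ok = value <= cut
    elif score_name in HIGHER_IS_BETTER:
        ok = value >= cut
    else:
        raise KeyError(f"unknown score name {score_name!r}")
    return Classification(
        label="correct" if ok else "incorrect",
        score_used=score_name, value=float(value), cutoff=float(cut),
    )


def grayzone_flag(iptm: float) -> GrayZoneFlag:
    """AlphaFold-server ipTM guidance: >0.8 high confidence, <0.6 likely
    failed, 0.6–0.8 the gray zone where a calibrated cutoff is needed."""
    if not (0.0 <= iptm <= 1.0):
        raise ValueError(f"iptm={iptm} outside [0, 1]")
    lo, hi = GRAY_ZONE
    if iptm > hi:
        return GrayZoneFlag.HIGH_CONF
    if iptm < lo:
        return GrayZoneFlag.LIKELY_FAILED
    return GrayZoneFlag.GRAY


# ---------------------------------------------------------------------------
# config I/O

_METHOD_SECTIONS = {"cf-t": Method.CF_T, "cf-f": Method.CF_F, "af3": Method.AF3}


def load_profile(path: str | Path | None = None) -> CutoffProfile:
    """Load a cutoff/weight profile from TOML; ``None`` loads the shipped
    defaults (published decision thresholds + weights refit on synthetic
    data)."""
    if path is None:
        text = resources.files("dimerqa").joinpath("data/defaults.toml").read_text()
    else:
        text = Path(path).read_text()
    raw = tomllib.loads(text)
    profile = CutoffProfile()
    gz = raw.get("gray_zone")
    if gz:
        profile.gray_zone = (float(gz["low"]), float(gz["high"]))
    dq = raw.get("dockq_class_bounds")
    if dq:
        profile.dockq_class_bounds = tuple(float(x) for x in dq)
    for section, method in _METHOD_SECTIONS.items():
        entry = raw.get(section)
        if not entry:
            continue
        profile.cutoffs[method] = {k: float(v) for k, v in entry.get("cutoffs", {}).items()}
        if "weights" in entry:
            profile.weights[method] = C2QWeights(
                weights={k: float(v) for k, v in entry["weights"].items()},
                bias=float(entry.get("bias", 0.0)),
                ipae_max=float(entry.get("ipae_max", DEFAULT_IPAE_MAX)),
                method=method,
                cutoff=profile.cutoffs[method].get("c2qscore"),
            )
    return profile


def save_profile(profile: CutoffProfile, path: str | Path) -> None:
    """Write a profile as TOML (inverse of :func:`load_profile`)."""
    lines = ["# dimerqa cutoff/weight profile", ""]
    lines.append(f"dockq_class_bounds = {list(profile.dockq_class_bounds)}")
    lines.append("")
    lines.append("[gray_zone]")
    lines.append(f"low = {profile.gray_zone[0]}")
    lines.append(f"high = {profile.gray_zone[1]}")
    lines.append("")
    for section, method in _METHOD_SECTIONS.items():
        if method not in profile.cutoffs and method not in profile.weights:
            continue
        w = profile.weights.get(method)
        if w is not None:
            lines.append(f"[{section}]")
            lines.append(f"bias = {w.bias!r}")
            lines.append(f"ipae_max = {w.ipae_max!r}")
            lines.append("")
            lines.append(f"[{section}.weights]")
            for k, v in w.weights.items():
                lines.append(f"{k} = {v!r}")
            lines.append("")
        if method in profile.cutoffs:
            lines.append(f"[{section}.cutoffs]")
            for k, v in sorted(profile.cutoffs[method].items()):
                lines.append(f"{k} = {v!r}")
            lines.append("")
    Path(path).write_text("\n".join(lines))
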