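"""Statistical calibration of the score panel against DockQ ground truth.

Given a table of per-model scores labeled correct/incorrect by DockQ
(correct ⇔ DockQ ≥ 0.23), this module provides: Pearson correlation, stepped
ROC analysis with maximum-distance-from-diagonal cutoff selection, AUC,
confusion metrics, Wilcoxon signed-rank comparisons, exhaustive equal-weight
subset search, and ordinary/Lasso least-squares fitting of the combined
score.  The end-to-end :func:`calibrate_pipeline` reproduces the full
per-method calibration: per-score cutoffs, regression weights, and a cutoff
for the fitted combined score.

Cutoff candidates advance on a score-family grid (pLDDT family: 5; PAE
family: 1 Å; unit-interval scores: 0.05) anchored at the score's theoretical
minimum (0), while AUC is computed threshold-free by trapezoidal integration
over all distinct score values, so it is invariant under strictly monotone
rescaling.  PAE-family scores are negated internally so one higher-is-better
code path serves every score; selected cutoffs are mapped back to the
original scale.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import Lasso, LinearRegression
from sklearn.metrics import roc_auc_score

from .combined import (
    COMBINABLE,
    DEFAULT_IPAE_MAX,
    C2QWeights,
    CutoffProfile,
    LOWER_IS_BETTER,
    NormalizedScores,
    c2qscore,
    unweighted_combined,
)
from .errors import CalibrationError
from .model import Method
from .reference_eval import CLASS_BOUNDS
from .scores import ScoreSet

CORRECT_DOCKQ = CLASS_BOUNDS[0]  # label boundary: DockQ >= 0.23 is "correct"

#: §-style cutoff-grid step per score family
GRID_STEPS = {
    "plddt": 5.0, "iplddt": 5.0,
    "pae": 1.0, "ipae": 1.0,
}
DEFAULT_GRID_STEP = 0.05


@dataclass
class LabeledScoreTable:
    """Rows of (model_id, method, score panel, dockq, label)."""

    frame: pd.DataFrame

    REQUIRED = ("model_id", "dockq")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.frame.columns:
                raise CalibrationError(f"labeled table is missing column {col!r}")
        if self.frame["dockq"].isna().any():
            raise CalibrationError("labeled table has missing DockQ values")
        self.frame = self.frame.copy()
        self.frame["label"] = self.frame["dockq"] >= CORRECT_DOCKQ

    @classmethod
    def from_records(
        cls, score_sets: Sequence[ScoreSet], dockq_values: Sequence[float]
    ) -> "LabeledScoreTable":
        if len(score_sets) != len(dockq_values):
            raise CalibrationError("score sets and DockQ values differ in length")
        rows = []
        for s, d in zip(score_sets, dockq_values):
            row = s.as_row()
            row["dockq"] = float(d)
            rows.append(row)
        return cls(pd.DataFrame(rows))

    @property
    def labels(self) -> np.ndarray:
        return self.frame["label"].to_numpy(dtype=bool)

    def scores(self, name: str) -> np.ndarray:
        if name not in self.frame.columns:
            raise CalibrationError(f"no score column {name!r} in table")
        return self.frame[name].to_numpy(dtype=float)


@dataclass
class RocResult:
    points: pd.DataFrame        # columns cutoff, tpr, fpr — ordered by cutoff
    auc: float
    best_cutoff: float
    best_distance: float        # max TPR − FPR (distance from diagonal × √2)
    score_name: str
    reliable: bool = True


@dataclass
class ConfusionMetrics:
    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    precision: Optional[float]
    recall: Optional[float]
    specificity: Optional[float]


@dataclass
class WsrResult:
    p_value: float
    statistic: float
    n_informative: int
    degenerate: bool
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return not self.degenerate and self.p_value < self.alpha


@dataclass
class CalibrationResult:
    method: Method
    per_score: dict[str, RocResult]
    cutoffs: dict[str, float]
    weights: C2QWeights
    c2q_roc: RocResult
    report: pd.DataFrame
    wsr_vs_unweighted: WsrResult

    def as_profile(self) -> CutoffProfile:
        profile = CutoffProfile()
        profile.cutoffs[self.method] = dict(self.cutoffs)
        profile.weights[self.method] = self.weights
        return profile


def pcc(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson product-moment correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise CalibrationError("pcc expects two equal-length vectors")
    if x.size < 3:
        raise CalibrationError("pcc needs at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise CalibrationError("correlation undefined for a constant vector")
    return float(stats.pearsonr(x, y).statistic)


def _orient(values: np.ndarray, score_name: str) -> np.ndarray:
    """Flip PAE-family scores so that higher always means better."""
    return -values if score_name in LOWER_IS_BETTER else values


def _grid(values: np.ndarray, score_name: str) -> np.ndarray:
    """Candidate cutoffs on the score family's step grid (original scale)."""
    step = GRID_STEPS.get(score_name, DEFAULT_GRID_STEP)
    # anchor at the theoretical minimum (0 for every score family); scores
    # that can go negative (fitted combinations) anchor at a grid point
    # at or below their observed minimum
    lo = 0.0 if values.min() >= 0 else math.floor(values.min() / step) * step
    hi = math.ceil(values.max() / step) * step + step
    n = int(round((hi - lo) / step)) + 1
    return lo + step * np.arange(n)


def roc(table: LabeledScoreTable, score_name: str) -> RocResult:
    """Stepped ROC curve with max-distance-from-diagonal cutoff selection.

    The chosen cutoff maximizes TPR − FPR over the grid; ties go to the most
    permissive cutoff.  AUC is threshold-free (trapezoidal over all distinct
    scores).  Tables whose AUC is indistinguishable from chance (≤ 0.6) are
    flagged unreliable.
    """
    labels = table.labels
    if labels.all() or not labels.any():
        raise CalibrationError("ROC needs both correct and incorrect labels")
    values = table.scores(score_name)
    if np.ptp(values) == 0:
        raise CalibrationError(f"score {score_name!r} is constant; ROC undefined")
    oriented = _orient(values, score_name)
    pos, neg = labels.sum(), (~labels).sum()

    cutoffs = _grid(values, score_name)
    oriented_cut = np.sort(_orient(cutoffs, score_name))
    # prediction is positive iff oriented score >= oriented cutoff (inclusive)
    pred = oriented[None, :] >= oriented_cut[:, None]
    tpr = (pred & labels[None, :]).sum(axis=1) / pos
    fpr = (pred & ~labels[None, :]).sum(axis=1) / neg
    j = tpr - fpr
    best_i = int(np.flatnonzero(j == j.max())[0])  # ties → most permissive
    best_oriented = oriented_cut[best_i]
    best_cutoff = -best_oriented if score_name in LOWER_IS_BETTER else best_oriented

    original_cut = -oriented_cut[::-1] if score_name in LOWER_IS_BETTER else oriented_cut
    original_tpr = tpr[::-1] if score_name in LOWER_IS_BETTER else tpr
    original_fpr = fpr[::-1] if score_name in LOWER_IS_BETTER else fpr
    points = pd.DataFrame({"cutoff": original_cut, "tpr": original_tpr, "fpr": original_fpr})

    auc = float(roc_auc_score(labels, oriented))
    return RocResult(
        points=points,
        auc=auc,
        best_cutoff=float(best_cutoff),
        best_distance=float(j[best_i]),
        score_name=score_name,
        reliable=auc > 0.6,
    )


def confusion(
    table: LabeledScoreTable, score_name: str, cutoff: float
) -> ConfusionMetrics:
    """Confusion counts and derived metrics at one decision cutoff."""
    labels = table.labels
    oriented = _orient(table.scores(score_name), score_name)
    c = -cutoff if score_name in LOWER_IS_BETTER else cutoff
    pred = oriented >= c
    tp = int((pred & labels).sum())
    tn = int((~pred & ~labels).sum())
    fp = int((pred & ~labels).sum())
    fn = int((~pred & labels).sum())
    total = tp + tn + fp + fn
    return ConfusionMetrics(
        tp=tp, tn=tn, fp=fp, fn=fn,
        accuracy=(tp + tn) / total,
        precision=tp / (tp + fp) if (tp + fp) else None,
        recall=tp / (tp + fn) if (tp + fn) else None,
        specificity=tn / (tn + fp) if (tn + fp) else None,
    )


def wsr_test(a: Sequence[float], b: Sequence[float], alpha: float = 0.05) -> WsrResult:
    """Two-sided Wilcoxon signed-rank test for paired samples."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise CalibrationError("wsr_test expects two equal-length vectors")
    d = a - b
    n_inf = int(np.count_nonzero(d))
    if n_inf == 0:
        return WsrResult(p_value=1.0, statistic=0.0, n_informative=0, degenerate=True, alpha=alpha)
    if n_inf < 6:
        raise CalibrationError(f"wsr_test needs >= 6 informative pairs, got {n_inf}")
    res = stats.wilcoxon(a, b, alternative="two-sided")
    return WsrResult(
        p_value=float(res.pvalue), statistic=float(res.statistic),
        n_informative=n_inf, degenerate=False, alpha=alpha,
    )


def normalized_frame(
    table: LabeledScoreTable, ipae_max: float = DEFAULT_IPAE_MAX
) -> pd.DataFrame:
    """Per-row normalized combinable scores (columns named as in COMBINABLE)."""
    f = table.frame
    out = pd.DataFrame(index=f.index)
    out["iplddt"] = (f["iplddt"] / 100.0).clip(0, 1)
    out["ipae"] = (1.0 - f["ipae"].clip(upper=ipae_max) / ipae_max).clip(0, 1)
    out["ptm"] = f["ptm"].clip(0, 1)
    out["iptm"] = f["iptm"].clip(0, 1)
    if "voroif" in f.columns and f["voroif"].notna().all():
        out["voroif"] = f["voroif"].clip(0, 1)
    return out


def subset_search(
    table: LabeledScoreTable,
    candidate_scores: Sequence[str] = COMBINABLE,
    ipae_max: float = DEFAULT_IPAE_MAX,
) -> pd.DataFrame:
    """Exhaustive equal-weight subset search ranked by PCC with DockQ.

    Every non-empty subset of the candidates (2^k − 1) is averaged with equal
    weights and correlated against DockQ; the full leaderboard is returned,
    best first.
    """
    norm = normalized_frame(table, ipae_max)
    missing = [c for c in candidate_scores if c not in norm.columns]
    if missing:
        raise CalibrationError(f"candidates not available/normalizable: {missing}")
    y = table.frame["dockq"].to_numpy(dtype=float)
    rows = []
    for r in range(1, len(candidate_scores) + 1):
        for subset in itertools.combinations(candidate_scores, r):
            mean = norm[list(subset)].mean(axis=1).to_numpy()
            rows.append({"subset": "+".join(subset), "k": r, "pcc": pcc(mean, y)})
    board = pd.DataFrame(rows).sort_values("pcc", ascending=False, ignore_index=True)
    return board


def _design_matrix(
    table: LabeledScoreTable, features: Sequence[str], ipae_max: float
) -> np.ndarray:
    norm = normalized_frame(table, ipae_max)
    missing = [f for f in features if f not in norm.columns]
    if missing:
        raise CalibrationError(f"features not available: {missing}")
    return norm[list(features)].to_numpy(dtype=float)


def _check_rank(X: np.ndarray, features: Sequence[str]) -> None:
    Xc = X - X.mean(axis=0)
    rank = np.linalg.matrix_rank(Xc)
    if rank < X.shape[1]:
        # name the features involved in exact collinearity via QR pivoting
        _, R = np.linalg.qr(Xc)
        bad = [features[i] for i in range(X.shape[1]) if abs(R[i, i]) < 1e-10 * max(1, abs(R[0, 0]))]
        raise CalibrationError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
            f"collinear feature(s): {bad or list(features)}"
        )


def fit_linear(
    table: LabeledScoreTable,
    features: Sequence[str] = COMBINABLE,
    target: str = "dockq",
    ipae_max: float = DEFAULT_IPAE_MAX,
    method: Method = Method.UNKNOWN,
) -> C2QWeights:
    """Ordinary least-squares fit of normalized scores to the target."""
    X = _design_matrix(table, features, ipae_max)
    y = table.frame[target].to_numpy(dtype=float)
    if X.shape[0] <= X.shape[1]:
        raise CalibrationError(
            f"need more rows ({X.shape[0]}) than features ({X.shape[1]}) to fit"
        )
    _check_rank(X, features)
    reg = LinearRegression().fit(X, y)
    return C2QWeights(
        weights=dict(zip(features, (float(c) for c in reg.coef_))),
        bias=float(reg.intercept_),
        ipae_max=ipae_max,
        method=method,
    )


def fit_lasso(
    table: LabeledScoreTable,
    features: Sequence[str] = COMBINABLE,
    target: str = "dockq",
    penalty: float = 0.01,
    ipae_max: float = DEFAULT_IPAE_MAX,
    method: Method = Method.UNKNOWN,
) -> C2QWeights:
    """L1-penalized least squares; penalty 0 reduces to the OLS fit."""
    if penalty < 0:
        raise CalibrationError(f"penalty must be >= 0, got {penalty}")
    if penalty == 0:
        return fit_linear(table, features, target, ipae_max, method)
    X = _design_matrix(table, features, ipae_max)
    y = table.frame[target].to_numpy(dtype=float)
    if X.shape[0] <= X.shape[1]:
        raise CalibrationError("need more rows than features to fit")
    reg = Lasso(alpha=penalty, max_iter=100_000).fit(X, y)
    return C2QWeights(
        weights=dict(zip(features, (float(c) for c in reg.coef_))),
        bias=float(reg.intercept_),
        ipae_max=ipae_max,
        method=method,
    )


def combined_columns(
    table: LabeledScoreTable, weights: C2QWeights
) -> pd.DataFrame:
    """Add per-row unweighted and fitted combined scores to a copy of the table."""
    norm = normalized_frame(table, weights.ipae_max)
    frame = table.frame.copy()
    uw, c2 = [], []
    for _, row in norm.iterrows():
        n = NormalizedScores(
            iplddt_n=row["iplddt"], ipae_n=row["ipae"],
            ptm_n=row["ptm"], iptm_n=row["iptm"],
            voroif_n=row["voroif"] if "voroif" in norm.columns else None,
        )
        uw.append(unweighted_combined(n))
        c2.append(c2qscore(n, weights))
    frame["unweighted"] = uw
    frame["c2qscore"] = c2
    return frame


def calibrate_pipeline(
    table: LabeledScoreTable,
    method: Method,
    score_names: Sequence[str] = ("iplddt", "ipae", "ptm", "iptm", "model_confidence", "pdockq2"),
    features: Sequence[str] = COMBINABLE,
    ipae_max: float = DEFAULT_IPAE_MAX,
) -> CalibrationResult:
    """End-to-end per-method calibration.

    Runs the stepped ROC per raw score, fits the regression-based combined
    score, runs ROC on it, and reports AUC/accuracy/precision per score plus
    a Wilcoxon signed-rank comparison of the fitted vs unweighted combined
    score (paired on per-model absolute deviation from DockQ).
    """
    usable_features = list(features)
    if "voroif" in usable_features and (
        "voroif" not in table.frame.columns or table.frame["voroif"].isna().any()
    ):
        usable_features.remove("voroif")
    usable_scores = [
        s for s in score_names
        if s in table.frame.columns and table.frame[s].notna().all()
    ]

    per_score: dict[str, RocResult] = {}
    cutoffs: dict[str, float] = {}
    rows = []
    for name in usable_scores:
        r = roc(table, name)
        per_score[name] = r
        cutoffs[name] = r.best_cutoff
        cm = confusion(table, name, r.best_cutoff)
        rows.append(
            {"score": name, "auc": r.auc, "cutoff": r.best_cutoff,
             "accuracy": cm.accuracy, "precision": cm.precision,
             "reliable": r.reliable}
        )

    weights = fit_linear(table, usable_features, ipae_max=ipae_max, method=method)
    with_combined = combined_columns(table, weights)
    ext = LabeledScoreTable(with_combined)
    c2q_roc = roc(ext, "c2qscore")
    weights.cutoff = c2q_roc.best_cutoff
    cutoffs["c2qscore"] = c2q_roc.best_cutoff
    cm = confusion(ext, "c2qscore", c2q_roc.best_cutoff)
    rows.append(
        {"score": "c2qscore", "auc": c2q_roc.auc, "cutoff": c2q_roc.best_cutoff,
         "accuracy": cm.accuracy, "precision": cm.precision, "reliable": c2q_roc.reliable}
    )
    uw_roc = roc(ext, "unweighted")
    cutoffs["unweighted"] = uw_roc.best_cutoff
    cmu = confusion(ext, "unweighted", uw_roc.best_cutoff)
    rows.append(
        {"score": "unweighted", "auc": uw_roc.auc, "cutoff": uw_roc.best_cutoff,
         "accuracy": cmu.accuracy, "precision": cmu.precision, "reliable": uw_roc.reliable}
    )
    per_score["unweighted"] = uw_roc

    y = with_combined["dockq"].to_numpy(dtype=float)
    wsr = wsr_test(
        np.abs(with_combined["c2qscore"].to_numpy() - y),
        np.abs(with_combined["unweighted"].to_numpy() - y),
    )
    return CalibrationResult(
        method=method,
        per_score=per_score,
        cutoffs=cutoffs,
        weights=weights,
        c2q_roc=c2q_roc,
        report=pd.DataFrame(rows),
        wsr_vs_unweighted=wsr,
    )
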