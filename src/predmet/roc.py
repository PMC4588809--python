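"""ROC analysis of cross-validated score patterns.

The discriminating pattern extracted by OPLS-DA is summarized per sample by
its cross-validated predictive score — the position on the predictive axis
assigned by a model that never saw the sample.  Treating that score as a
diagnostic marker gives a ROC curve and an AUROCC whose optimism is held in
check by the cross-validation: on null data the cross-validated AUC falls
back toward 0.5 where the in-sample score would not.

AUC uses the all-pairs definition (concordant + half of tied pairs over
n_pos * n_neg, the Mann-Whitney identity); the confidence interval is a
stratified percentile bootstrap.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

from .chemometrics import CVResult, _encode_y

__all__ = ["RocResult", "roc_auc", "roc_ci", "roc_points", "evaluate_pattern", "format_roc_summary"]


@dataclasses.dataclass
class RocResult:
    """AUROCC with a 95% bootstrap CI and the ROC curve points."""

    auc: float
    ci: tuple[float, float]
    curve: np.ndarray  # (fpr, tpr) rows, both non-decreasing, (0,0) -> (1,1)
    n_boot: int
    seed: int

    def summary(self) -> str:
        return format_roc_summary(self.auc, self.ci)

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "ci_lower": self.ci[0],
            "ci_upper": self.ci[1],
            "n_boot": self.n_boot,
            "seed": self.seed,
            "curve": self.curve.tolist(),
        }


def format_roc_summary(auc: float, ci: tuple[float, float]) -> str:
    """Render ``AUC (lower-upper)`` with three decimals, en-dash separated."""
    return f"{auc:.3f} ({ci[0]:.3f}–{ci[1]:.3f})"


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve by the rank (all-pairs) definition.

    ``auc = (concordant + 0.5 * tied) / (n_pos * n_neg)`` over every
    positive-negative pair.  Orientation is taken as given: scores below 0.5
    are reported as-is, not flipped.
    """
    y = _encode_y(labels)
    s = np.asarray(scores, dtype=float)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(s)
    r1 = ranks[y == 1].sum()
    u = r1 - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def roc_points(scores, labels) -> np.ndarray:
    """ROC curve points (fpr, tpr), from (0, 0) to (1, 1)."""
    y = _encode_y(labels)
    fpr, tpr, _ = _sk_roc_curve(y, np.asarray(scores, dtype=float))
    return np.column_stack([fpr, tpr])


def roc_ci(
    scores, labels, n_boot: int = 1000, seed: int = 0
) -> tuple[float, float]:
    """95% percentile bootstrap CI for the AUC, stratified by class.

    Resampling happens within each class so no replicate ever loses a class.
    When every replicate separates perfectly the interval degenerates to
    (1.0, 1.0).
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    y = _encode_y(labels)
    s = np.asarray(scores, dtype=float)
    idx1 = np.flatnonzero(y == 1)
    idx0 = np.flatnonzero(y == 0)
    rng = np.random.default_rng(seed)
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        r1 = rng.choice(idx1, size=len(idx1), replace=True)
        r0 = rng.choice(idx0, size=len(idx0), replace=True)
        sel = np.concatenate([r1, r0])
        aucs[b] = roc_auc(s[sel], y[sel])
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    return float(lo), float(min(hi, 1.0))


def evaluate_pattern(
    cv: CVResult, labels, n_boot: int = 1000, seed: int = 0
) -> RocResult:
    """ROC of the cross-validated predictive scores — never in-sample scores."""
    auc = roc_auc(cv.tcv, labels)
    ci = roc_ci(cv.tcv, labels, n_boot=n_boot, seed=seed)
    curve = roc_points(cv.tcv, labels)
    return RocResult(auc=auc, ci=ci, curve=curve, n_boot=n_boot, seed=seed)
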