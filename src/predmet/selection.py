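"""Variable selection on OPLS-DA weights and per-feature annotation.

The selection rule keeps the features whose predictive weight ``w*`` lies
outside the band ``mean(w*) +/- 2 SD(w*)`` computed over the signed weights
of the all-features model — a single extraction step, not iterated.  The
final model is a plain refit on the reduced table with fresh scaling,
cross-validation and CV-ANOVA.

Per-feature annotation is reporting only and never gates selection: a
Mann-Whitney U test (exact for small groups without ties, tie- and
continuity-corrected normal approximation otherwise) plus an elevated/
lowered arrow from class medians on the unscaled data.
"""

from __future__ import annotations

import dataclasses
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .chemometrics import (
    CVResult,
    OPLSModel,
    cross_validate,
    cv_anova,
    fit_opls,
    scale,
)
from .tables import FeatureTable

__all__ = [
    "SelectionResult",
    "select_features",
    "refit_final",
    "mann_whitney",
    "annotate_direction",
]

# exact null enumeration is used up to this smaller-group size (no ties)
EXACT_MAX_N = 8


@dataclasses.dataclass
class SelectionResult:
    """Initial model, the selected feature set, the refit final model and the
    per-feature annotation table (w*, arrow, U, p, significance star)."""

    initial_model: OPLSModel
    selected: list
    final_model: OPLSModel
    final_cv: CVResult
    per_feature: pd.DataFrame


def select_features(model: OPLSModel) -> list:
    """Features with ``w*`` outside ``mean +/- 2 SD`` of the signed weights.

    Raises if nothing is selected — a sign that the weight distribution is
    degenerate and the threshold needs review.
    """
    w = np.asarray(model.w_star, dtype=float)
    if len(w) < 3:
        raise ValueError("selection needs a model on at least 3 features")
    m, s = w.mean(), w.std(ddof=1)
    mask = (w < m - 2 * s) | (w > m + 2 * s)
    if not mask.any():
        raise ValueError(
            "w* +/- 2 SD selected no features; review the selection threshold"
        )
    return [model.feature_ids[j] for j in np.flatnonzero(mask)]


def refit_final(
    table: FeatureTable,
    y,
    selected: list,
    A_orth: int = 0,
    k: int = 7,
    mode: str = "uv",
) -> tuple[OPLSModel, CVResult]:
    """Refit on the selected features: full model + k-fold CV + CV-ANOVA.

    ``table`` must be the raw (unscaled) table; scaling is refit on the
    reduced feature set and inside every cross-validation split.
    """
    if not selected:
        raise ValueError("selected feature set is empty")
    sub = table.subset_features(selected)
    model = fit_opls(scale(sub, mode), y, A_orth=A_orth)
    cv = cross_validate(sub, y, A_orth=A_orth, k=k, mode=mode)
    cv_anova(cv, y)
    return model, cv


def _exact_u_sf_table(n1: int, n2: int) -> np.ndarray:
    """Null distribution of U for group sizes (n1, n2) without ties.

    Entry ``u`` holds the number of labelings with that U; standard
    ballot-counting recurrence.
    """
    max_u = n1 * n2
    # f[k][u]: number of ways to place k group-A ranks giving U = u
    f = np.zeros((n1 + 1, max_u + 1))
    f[0, 0] = 1.0
    for i in range(1, n1 + n2 + 1):  # add ranks one at a time
        new = f.copy()
        for kk in range(min(i, n1), 0, -1):
            # assigning rank i to group A beats every group-B item seen so far
            shift = i - kk  # number of B items among the first i ranks
            new[kk, shift:] += f[kk - 1, : max_u + 1 - shift]
        f = new
    return f[n1]


def mann_whitney(a, b) -> tuple[float, float]:
    """Mann-Whitney U with a two-sided p-value.

    ``U`` counts pairs ``(a_i, b_j)`` with ``a_i > b_j`` plus half the ties.
    The p-value is exact (full enumeration of the null distribution) when
    the smaller group has at most 8 values and there are no ties; otherwise
    the normal approximation with tie correction and continuity correction
    is used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = len(a), len(b)
    gt = (a[:, None] > b[None, :]).sum()
    eq = (a[:, None] == b[None, :]).sum()
    u = float(gt) + 0.5 * float(eq)

    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if min(n1, n2) <= EXACT_MAX_N and not has_ties:
        counts = _exact_u_sf_table(n1, n2)
        total = comb(n1 + n2, n1)
        u_int = int(round(u))
        lo = min(u_int, n1 * n2 - u_int)
        p = 2.0 * counts[: lo + 1].sum() / total
        return u, float(min(p, 1.0))

    mean_u = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1)) if n > 1 else 0.0
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var_u <= 0:
        return u, 1.0
    diff = u - mean_u
    cc = 0.5 * np.sign(diff)  # continuity correction toward the mean
    z = (diff - cc) / np.sqrt(var_u)
    p = 2.0 * stats.norm.sf(abs(z))
    return u, float(min(p, 1.0))


def annotate_direction(
    table: FeatureTable, y, selected: list
) -> pd.DataFrame:
    """Elevated/lowered arrows for the selected features.

    Compares class medians on the unscaled table: up-arrow if the class coded
    1 has the larger median, down-arrow otherwise; exact ties are flagged
    ambiguous.
    """
    from .chemometrics import _encode_y

    y01 = _encode_y(y)
    rows = []
    for fid in selected:
        v = table.X[fid].to_numpy(dtype=float)
        m1 = np.median(v[y01 == 1])
        m0 = np.median(v[y01 == 0])
        if m1 > m0:
            rows.append({"feature_id": fid, "direction": "up", "ambiguous": False})
        elif m1 < m0:
            rows.append({"feature_id": fid, "direction": "down", "ambiguous": False})
        else:
            rows.append({"feature_id": fid, "direction": "tie", "ambiguous": True})
    return pd.DataFrame(rows).set_index("feature_id")


def run_selection(
    table: FeatureTable,
    y,
    A_orth: int = 0,
    k: int = 7,
    mode: str = "uv",
    alpha: float = 0.05,
    bh_correct: bool = False,
) -> SelectionResult:
    """Full selection pass: fit, select, refit, annotate.

    Mann-Whitney p-values annotate every selected feature; they never gate
    selection.  ``bh_correct`` optionally applies Benjamini-Hochberg to the
    annotation p-values (off by default: the per-feature p-values are
    reported uncorrected).
    """
    from .chemometrics import _encode_y

    y01 = _encode_y(y)
    initial = fit_opls(scale(table, mode), y, A_orth=A_orth)
    selected = select_features(initial)
    final_model, final_cv = refit_final(table, y, selected, A_orth=A_orth, k=k, mode=mode)
    arrows = annotate_direction(table, y, selected)
    w_map = dict(zip(initial.feature_ids, initial.w_star))
    rows = []
    for fid in selected:
        v = table.X[fid].to_numpy(dtype=float)
        u, p = mann_whitney(v[y01 == 1], v[y01 == 0])
        rows.append(
            {
                "feature_id": fid,
                "w_star": w_map[fid],
                "direction": arrows.loc[fid, "direction"],
                "U": u,
                "p_mw": p,
                "retention_index": table.feature_meta.get("retention_index", pd.Series(dtype=float)).get(fid),
                "putative_id": table.feature_meta.get("putative_id", pd.Series(dtype=object)).get(fid),
            }
        )
    per_feature = pd.DataFrame(rows).set_index("feature_id")
    p_for_star = per_feature["p_mw"].to_numpy(dtype=float)
    if bh_correct and len(p_for_star):
        order = np.argsort(p_for_star)
        m = len(p_for_star)
        adj = np.empty(m)
        prev = 1.0
        for rank_rev, idx in enumerate(order[::-1]):
            rank = m - rank_rev
            prev = min(prev, p_for_star[idx] * m / rank)
            adj[idx] = prev
        p_for_star = adj
        per_feature["p_adj"] = adj
    per_feature["significant"] = p_for_star < alpha
    return SelectionResult(
        initial_model=initial,
        selected=selected,
        final_model=final_model,
        final_cv=final_cv,
        per_feature=per_feature,
    )
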