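"""End-to-end study orchestration: curation, comparisons, reporting.

A study is a curated feature table plus a list of two-class comparisons
(diagnosis, grade, survival groups).  Each comparison runs the same chain:
scale -> initial OPLS-DA -> w*-band feature selection -> final refit with
seven-fold cross-validation and CV-ANOVA -> ROC of the cross-validated
scores -> a per-feature report table.  The whole run is a pure function of
the inputs, the configuration and the seed.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .chemometrics import pca_overview, select_orthogonal
from .roc import evaluate_pattern
from .selection import run_selection
from .tables import FeatureTable, read_feature_table

__all__ = [
    "ComparisonSpec",
    "SURVIVAL_PRESETS",
    "curate",
    "assign_survival_classes",
    "run_comparison",
    "run_study",
    "load_config",
    "render_report",
]

# Named survival-dichotomy presets (months).  Glioblastoma contrasts deaths
# within 4 months against survival of at least 3 years; oligodendroglioma
# contrasts deaths within 2 years against survival beyond 3 years (strict).
SURVIVAL_PRESETS = {
    "gbm": {"short_max": 4.0, "long_min": 36.0, "long_inclusive": True},
    "oligodendroglioma": {"short_max": 24.0, "long_min": 36.0, "long_inclusive": False},
}


@dataclasses.dataclass
class ComparisonSpec:
    """One two-class comparison over the curated table.

    ``class_column``/``classes`` define the groups directly, or
    ``survival`` (dict or preset name) dichotomizes ``survival_months``.
    ``subset`` optionally restricts samples by metadata equality first.
    """

    name: str
    class_column: str | None = None
    classes: tuple | None = None  # (class0_label, class1_label)
    survival: dict | str | None = None
    subset: dict = dataclasses.field(default_factory=dict)
    scaling: str = "uv"
    k_folds: int = 7
    max_orth: int = 2
    alpha: float = 0.05
    n_boot: int = 1000


def curate(
    table: FeatureTable,
    near_zero_fraction: float = 0.5,
    artifact_rel_var: float = 1e-12,
    outlier_iqr_fences: float = 5.0,
    max_flagged_fraction: float = 0.25,
) -> tuple[FeatureTable, list[dict]]:
    """Automated data curation; every action is logged with a reason code.

    Three screens, in order:

    1. *artifact features* — near-constant columns (relative variance below
       ``artifact_rel_var``) are dropped;
    2. *failed samples* — samples flagged ``is_failed`` by internal-standard
       normalization, or in which more than ``near_zero_fraction`` of
       features collapse to near zero (under 1% of the feature median), are
       dropped — the signature of a failed derivatization;
    3. *gross outliers* — samples whose scores on the first two principal
       components sit more than ``outlier_iqr_fences`` interquartile ranges
       from the median score are dropped.  This robust fence targets gross
       analytical deviations only; the Hotelling-T² 95% ellipse from
       :func:`~predmet.chemometrics.pca_overview` remains the interactive
       screening diagnostic (on well-behaved data it flags ~5% of samples by
       construction, which is not an exclusion criterion).

    Aborts when more than ``max_flagged_fraction`` of samples would be
    dropped — a sign of mis-scaled input rather than a few bad runs.
    """
    log: list[dict] = []
    out = table.copy()

    X = out.values()
    col_mean = X.mean(axis=0)
    col_var = X.var(axis=0)
    rel_var = col_var / np.where(col_mean**2 > 0, col_mean**2, 1.0)
    artifact = rel_var < artifact_rel_var
    if artifact.any():
        for fid in out.X.columns[artifact]:
            log.append({"action": "drop_feature", "id": str(fid), "reason": "artifact_near_constant"})
        out = out.subset_features(list(out.X.columns[~artifact]))

    X = out.values()
    med = np.median(X, axis=0)
    med = np.where(med > 0, med, 1.0)
    near_zero = (X < 0.01 * med).mean(axis=1)
    failed = near_zero > near_zero_fraction
    if "is_failed" in out.sample_meta.columns:
        failed = failed | out.sample_meta["is_failed"].fillna(False).to_numpy(dtype=bool)
    failed_ids = list(out.X.index[failed])

    keep = out.subset_samples(list(out.X.index[~failed]))
    outlier_ids: list[str] = []
    if keep.n_samples >= 5 and keep.n_features >= 2:
        # robust fence in score space of a log-scale PCA
        logged = keep.copy()
        logged.X = np.log(logged.X.clip(lower=1e-12))
        from .chemometrics import scale as _scale

        scores, _, _, _ = pca_overview(_scale(logged, "uv"), n_components=2)
        for axis in scores.columns:
            v = scores[axis]
            q1, q3 = v.quantile([0.25, 0.75])
            iqr = max(q3 - q1, 1e-12)
            fence_lo = v.median() - outlier_iqr_fences * iqr
            fence_hi = v.median() + outlier_iqr_fences * iqr
            outlier_ids.extend(v.index[(v < fence_lo) | (v > fence_hi)])
        outlier_ids = sorted(set(map(str, outlier_ids)))

    n_flagged = len(failed_ids) + len(outlier_ids)
    if n_flagged > max_flagged_fraction * table.n_samples:
        raise ValueError(
            f"curation would drop {n_flagged}/{table.n_samples} samples; "
            "check input scaling and units"
        )
    for sid in failed_ids:
        log.append({"action": "drop_sample", "id": str(sid), "reason": "failed_derivatization"})
    for sid in outlier_ids:
        log.append({"action": "drop_sample", "id": str(sid), "reason": "score_space_outlier"})
    drop = set(map(str, failed_ids)) | set(outlier_ids)
    kept_ids = [s for s in out.X.index if str(s) not in drop]
    return out.subset_samples(kept_ids), log


def assign_survival_classes(
    meta: pd.DataFrame,
    short_max: float,
    long_min: float,
    long_inclusive: bool = True,
    column: str = "survival_months",
) -> pd.Series:
    """Dichotomize survival time into short/long classes.

    Survival ``<= short_max`` months is *short* (coded 0); survival
    ``>= long_min`` (or strictly ``> long_min`` when ``long_inclusive`` is
    False) is *long* (coded 1).  Samples strictly between the cut points are
    excluded (NaN in the returned series).
    """
    if short_max >= long_min:
        raise ValueError("short_max must be below long_min")
    surv = meta[column].astype(float)
    labels = pd.Series(np.nan, index=meta.index, dtype=float)
    labels[surv <= short_max] = 0.0
    labels[surv >= long_min if long_inclusive else surv > long_min] = 1.0
    if (labels == 0).sum() == 0 or (labels == 1).sum() == 0:
        raise ValueError("survival dichotomy left a class empty")
    return labels


def _comparison_labels(table: FeatureTable, spec: ComparisonSpec) -> tuple[FeatureTable, np.ndarray]:
    """Resolve a ComparisonSpec into a sample subset and 0/1 labels."""
    work = table
    for col, val in spec.subset.items():
        keep = work.sample_meta[work.sample_meta[col] == val].index
        work = work.subset_samples(list(keep))
    if spec.survival is not None:
        preset = (
            SURVIVAL_PRESETS[spec.survival] if isinstance(spec.survival, str) else dict(spec.survival)
        )
        labels = assign_survival_classes(
            work.sample_meta,
            short_max=preset["short_max"],
            long_min=preset["long_min"],
            long_inclusive=preset.get("long_inclusive", True),
        )
        keep = labels.dropna().index
        work = work.subset_samples(list(keep))
        y = labels.loc[keep].to_numpy(dtype=int)
    elif spec.class_column is not None:
        col = work.sample_meta[spec.class_column]
        if spec.classes is not None:
            c0, c1 = spec.classes
        else:
            uniq = sorted(col.dropna().unique(), key=str)
            if len(uniq) != 2:
                raise ValueError(
                    f"column {spec.class_column!r} has {len(uniq)} levels; "
                    "specify `classes`"
                )
            c0, c1 = uniq
        keep = col[col.isin([c0, c1])].index
        work = work.subset_samples(list(keep))
        y = (work.sample_meta[spec.class_column] == c1).to_numpy(dtype=int)
    else:
        raise ValueError("comparison needs either class_column or survival")
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError(f"comparison {spec.name!r} has an empty class")
    return work, y


def run_comparison(
    table: FeatureTable, spec: ComparisonSpec, seed: int = 0
) -> dict:
    """Run one comparison on a curated table; returns a report section."""
    work, y = _comparison_labels(table, spec)
    try:
        a_orth = select_orthogonal(
            work, y, max_orth=spec.max_orth, k=spec.k_folds, mode=spec.scaling
        )
        sel = run_selection(
            work, y, A_orth=a_orth, k=spec.k_folds, mode=spec.scaling, alpha=spec.alpha
        )
        roc = evaluate_pattern(sel.final_cv, y, n_boot=spec.n_boot, seed=seed)
    except ValueError as err:
        raise ValueError(f"comparison {spec.name!r}: {err}") from err
    per_feature = sel.per_feature.reset_index().to_dict(orient="records")
    return {
        "name": spec.name,
        "n_samples": int(len(y)),
        "n_class0": int((y == 0).sum()),
        "n_class1": int((y == 1).sum()),
        "A_pred": 1,
        "A_orth": int(a_orth),
        "R2X": sel.final_model.R2X,
        "R2Y": sel.final_model.R2Y,
        "Q2": sel.final_cv.Q2,
        "p_cvanova": sel.final_cv.p_cvanova,
        "n_selected": len(sel.selected),
        "selected": list(map(str, sel.selected)),
        "auc": roc.auc,
        "auc_ci": [roc.ci[0], roc.ci[1]],
        "roc_summary": roc.summary(),
        "tcv": sel.final_cv.tcv.tolist(),
        "sample_ids": list(map(str, work.X.index)),
        "labels": y.tolist(),
        "per_feature": per_feature,
    }


def load_config(path: str | Path) -> dict:
    """Load and validate a study configuration (YAML)."""
    import yaml

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    cfg = yaml.safe_load(path.read_text())
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    bad = [k for k in cfg if k not in {"tables", "comparisons", "seed", "defaults"}]
    if bad:
        raise ValueError(f"unknown config keys: {bad}")
    if "tables" not in cfg or not isinstance(cfg["tables"], dict) or not cfg["tables"]:
        raise ValueError("config needs a non-empty `tables` mapping")
    for name, prefix in cfg["tables"].items():
        if not Path(prefix).with_suffix(".tsv").exists():
            raise FileNotFoundError(
                f"table {name!r}: missing file {Path(prefix).with_suffix('.tsv')}"
            )
    cfg.setdefault("comparisons", [])
    cfg.setdefault("seed", 0)
    cfg.setdefault("defaults", {})
    for comp in cfg["comparisons"]:
        missing = {"name", "table"} - set(comp)
        if missing:
            raise ValueError(f"comparison missing keys: {sorted(missing)}")
        if comp["table"] not in cfg["tables"]:
            raise ValueError(f"comparison {comp['name']!r} references unknown table")
    return cfg


def run_study(config: str | Path | dict, out_dir: str | Path | None = None) -> dict:
    """Execute a full study: curate every table, run every comparison.

    ``config`` is a path to a YAML file or an equivalent dict.  Returns the
    report; when ``out_dir`` is given the report tree is also written there
    (``report.json`` plus one per-feature TSV per comparison).
    """
    cfg = load_config(config) if not isinstance(config, dict) else config
    seed = int(cfg.get("seed", 0))
    defaults = cfg.get("defaults", {})
    tables: dict[str, FeatureTable] = {}
    curation_log: dict[str, list] = {}
    for name, prefix in cfg["tables"].items():
        raw = read_feature_table(prefix)
        curated, log = curate(raw)
        tables[name] = curated
        curation_log[name] = log
    report: dict = {
        "seed": seed,
        "curation": curation_log,
        "tables": {
            name: {"n_samples": t.n_samples, "n_features": t.n_features}
            for name, t in tables.items()
        },
        "comparisons": [],
    }
    for i, comp_cfg in enumerate(cfg.get("comparisons", [])):
        comp_cfg = {**defaults, **comp_cfg}
        spec = ComparisonSpec(
            name=comp_cfg["name"],
            class_column=comp_cfg.get("class_column"),
            classes=tuple(comp_cfg["classes"]) if comp_cfg.get("classes") else None,
            survival=comp_cfg.get("survival"),
            subset=comp_cfg.get("subset", {}),
            scaling=comp_cfg.get("scaling", "uv"),
            k_folds=int(comp_cfg.get("k_folds", 7)),
            max_orth=int(comp_cfg.get("max_orth", 2)),
            alpha=float(comp_cfg.get("alpha", 0.05)),
            n_boot=int(comp_cfg.get("n_boot", 1000)),
        )
        section = run_comparison(tables[comp_cfg["table"]], spec, seed=seed + i)
        section["table"] = comp_cfg["table"]
        report["comparisons"].append(section)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
        for section in report["comparisons"]:
            pd.DataFrame(section["per_feature"]).to_csv(
                out_dir / f"{section['name']}_features.tsv", sep="\t", index=False
            )
    return report


def render_report(report: dict) -> str:
    """Human-readable markdown rendering of a study report."""
    lines = ["# Study report", ""]
    for name, log in report.get("curation", {}).items():
        lines.append(f"## Curation — {name}")
        if not log:
            lines.append("no exclusions")
        for entry in log:
            lines.append(f"- {entry['action']} `{entry['id']}`: {entry['reason']}")
        lines.append("")
    for sec in report.get("comparisons", []):
        lines.append(f"## {sec['name']} ({sec['table']})")
        lines.append(
            f"n = {sec['n_class0']} vs {sec['n_class1']}; "
            f"A = {sec['A_pred']} + {sec['A_orth']} + 0, "
            f"R2X = {sec['R2X']:.3g}, R2Y = {sec['R2Y']:.3g}, "
            f"Q2 = {sec['Q2']:.3g}, p = {sec['p_cvanova']:.3g}"
        )
        lines.append(f"AUROCC = {sec['roc_summary']}")
        lines.append(f"{sec['n_selected']} selected features:")
        lines.append("")
        lines.append("| feature | RI | putative id | direction | U | p |")
        lines.append("|---|---|---|---|---|---|")
        for row in sec["per_feature"]:
            star = " *" if row.get("significant") else ""
            ri = row.get("retention_index")
            ri_s = "-" if ri is None or (isinstance(ri, float) and np.isnan(ri)) else f"{ri:.1f}"
            pid = row.get("putative_id") or "-"
            arrow = {"up": "↑", "down": "↓"}.get(row.get("direction"), "~")
            lines.append(
                f"| {row['feature_id']} | {ri_s} | {pid} | {arrow}{star} "
                f"| {row['U']:.1f} | {row['p_mw']:.3g} |"
            )
        lines.append("")
    return "\n".join(lines)
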