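"""Feature tables: the samples x features matrix of normalized relative
concentrations plus sample and feature metadata.

The feature table is the central exchange object of the pipeline: curve
resolution produces one, the chemometric models consume one.  It wraps a
pandas DataFrame ``X`` (rows = samples, columns = resolved features) together
with a sample-metadata frame (class labels, survival time, curation flags)
and a feature-metadata frame (retention index, putative identity).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["FeatureTable", "read_feature_table", "write_feature_table"]


@dataclasses.dataclass
class FeatureTable:
    """Samples x features matrix with metadata sidecars.

    Parameters
    ----------
    X : pandas.DataFrame
        Relative concentrations, one row per sample, one column per feature.
    sample_meta : pandas.DataFrame
        Indexed like ``X``; free-form columns (``group``, ``diagnosis``,
        ``survival_months``, curation flags ...).
    feature_meta : pandas.DataFrame
        Indexed like ``X.columns``; typically ``retention_index`` and
        ``putative_id``.
    scaling_state : str
        One of ``raw``, ``centered``, ``uv``, ``pareto``.  Models require a
        scaled table; the scaling vectors are kept so the same transform can
        be applied to held-out samples.
    """

    X: pd.DataFrame
    sample_meta: pd.DataFrame = None
    feature_meta: pd.DataFrame = None
    scaling_state: str = "raw"
    center_: np.ndarray | None = None
    scale_: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.sample_meta is None:
            self.sample_meta = pd.DataFrame(index=self.X.index)
        if self.feature_meta is None:
            self.feature_meta = pd.DataFrame(index=self.X.columns)
        if not self.X.index.is_unique:
            raise ValueError("sample ids must be unique")
        if not self.X.columns.is_unique:
            raise ValueError("feature ids must be unique")
        if not self.X.index.equals(self.sample_meta.index):
            self.sample_meta = self.sample_meta.reindex(self.X.index)
        if not self.X.columns.equals(self.feature_meta.index):
            self.feature_meta = self.feature_meta.reindex(self.X.columns)

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def values(self) -> np.ndarray:
        return self.X.to_numpy(dtype=float)

    def subset_samples(self, ids) -> "FeatureTable":
        """Return a new table restricted to the given sample ids (order kept)."""
        return FeatureTable(
            X=self.X.loc[ids].copy(),
            sample_meta=self.sample_meta.loc[ids].copy(),
            feature_meta=self.feature_meta.copy(),
            scaling_state=self.scaling_state,
            center_=None if self.center_ is None else self.center_.copy(),
            scale_=None if self.scale_ is None else self.scale_.copy(),
        )

    def subset_features(self, ids) -> "FeatureTable":
        """Return a new table restricted to the given feature ids (order kept)."""
        cols = self.X.columns
        keep = [c for c in cols if c in set(ids)]  # preserve original column order
        pos = [cols.get_loc(c) for c in keep]
        return FeatureTable(
            X=self.X[keep].copy(),
            sample_meta=self.sample_meta.copy(),
            feature_meta=self.feature_meta.loc[keep].copy(),
            scaling_state=self.scaling_state,
            center_=None if self.center_ is None else self.center_[pos].copy(),
            scale_=None if self.scale_ is None else self.scale_[pos].copy(),
        )

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            X=self.X.copy(),
            sample_meta=self.sample_meta.copy(),
            feature_meta=self.feature_meta.copy(),
            scaling_state=self.scaling_state,
            center_=None if self.center_ is None else self.center_.copy(),
            scale_=None if self.scale_ is None else self.scale_.copy(),
        )


def write_feature_table(table: FeatureTable, prefix: str | Path) -> tuple[Path, Path]:
    """Write ``<prefix>.tsv`` (matrix) and ``<prefix>.meta.tsv`` (sample metadata).

    Feature metadata, when present, goes to ``<prefix>.features.tsv``.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    matrix_path = prefix.with_suffix(".tsv")
    meta_path = prefix.with_suffix(".meta.tsv")
    table.X.to_csv(matrix_path, sep="\t", index_label="sample_id")
    table.sample_meta.to_csv(meta_path, sep="\t", index_label="sample_id")
    if len(table.feature_meta.columns):
        table.feature_meta.to_csv(
            prefix.with_suffix(".features.tsv"), sep="\t", index_label="feature_id"
        )
    return matrix_path, meta_path


def read_feature_table(prefix: str | Path) -> FeatureTable:
    """Read a table written by :func:`write_feature_table`."""
    prefix = Path(prefix)
    matrix_path = prefix.with_suffix(".tsv")
    meta_path = prefix.with_suffix(".meta.tsv")
    if not matrix_path.exists():
        raise FileNotFoundError(str(matrix_path))
    X = pd.read_csv(matrix_path, sep="\t", index_col="sample_id")
    X.index.name = None
    X.columns.name = None
    if meta_path.exists():
        sample_meta = pd.read_csv(meta_path, sep="\t", index_col="sample_id")
        sample_meta.index.name = None
    else:
        sample_meta = pd.DataFrame(index=X.index)
    fpath = prefix.with_suffix(".features.tsv")
    feature_meta = None
    if fpath.exists():
        feature_meta = pd.read_csv(fpath, sep="\t", index_col="feature_id")
        feature_meta.index.name = None
    return FeatureTable(X=X, sample_meta=sample_meta, feature_meta=feature_meta)
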