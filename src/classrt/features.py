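"""Molecular descriptor computation, cleaning, and feature selection.

Descriptors are the RDKit 2D block (~210 columns: constitutional counts,
topological indices, autocorrelations, VSA families, logP/MR estimates),
computed once per unique canonical SMILES so enumeration duplicates are
bit-identical to their parents. Columns that are non-finite for any row, or
constant across the table, are masked with a reason.

Selection is a deterministic cascade: drop zero-variance columns, collapse
highly correlated pairs (|Pearson r| > 0.95, keeping the member better
correlated with retention time), then rank by univariate |correlation to
rt| and keep the top max(10, n_rows/5).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit.Chem import Descriptors

from .chemio import DatasetTable, mol_from_smiles
from .errors import ClassRTError, ConfigurationError, DatasetTooSmallError

FEATURE_SETS = ("standard_2d",)


@dataclass
class FeatureMatrix:
    """Descriptor values row-aligned with the source table, plus a column mask."""

    frame: pd.DataFrame  # all computed columns, one row per record
    mask: dict[str, str] = field(default_factory=dict)  # name -> drop reason
    failed_rows: list[str] = field(default_factory=list)  # record ids

    @property
    def retained(self) -> pd.DataFrame:
        keep = [c for c in self.frame.columns if c not in self.mask]
        return self.frame[keep]


@dataclass(frozen=True)
class SelectionConfig:
    corr_threshold: float = 0.95
    min_keep: int = 10
    rows_per_feature: int = 5


@dataclass
class SelectionReport:
    n_input: int
    n_after_variance: int
    n_after_correlation: int
    n_final: int
    selected_names: list[str]


_DESCRIPTOR_CACHE: dict[str, dict[str, float]] = {}


def descriptor_names() -> list[str]:
    return [name for name, _ in Descriptors.descList]


def _descriptor_row(canonical_smiles: str) -> dict[str, float]:
    cached = _DESCRIPTOR_CACHE.get(canonical_smiles)
    if cached is None:
        mol = mol_from_smiles(canonical_smiles)
        cached = Descriptors.CalcMolDescriptors(mol, missingVal=np.nan)
        _DESCRIPTOR_CACHE[canonical_smiles] = cached
    return cached


def compute_descriptors(
    table: DatasetTable, set_name: str = "standard_2d"
) -> FeatureMatrix:
    """RDKit 2D descriptor matrix for a molecule table.

    Deterministic, graph-invariant (two renderings of one molecule get the
    same row), and cached per canonical SMILES. Columns with any non-finite
    value are masked ``nonfinite``; constant columns are masked
    ``zero-variance``. A molecule the descriptor engine rejects is dropped
    from the matrix and listed in ``failed_rows``.
    """
    if set_name not in FEATURE_SETS:
        raise ConfigurationError(f"unknown descriptor set {set_name!r}")
    rows, index, failed = [], [], []
    for rec in table.records:
        try:
            rows.append(_descriptor_row(rec.smiles_canonical))
            index.append(rec.id)
        except (ClassRTError, ValueError, RuntimeError):
            failed.append(rec.id)
    if not rows:
        raise ConfigurationError("descriptor computation failed for every record")
    frame = pd.DataFrame(rows, index=index, dtype=float)
    mask: dict[str, str] = {}
    values = frame.to_numpy()
    finite = np.isfinite(values).all(axis=0)
    for j, col in enumerate(frame.columns):
        if not finite[j]:
            mask[col] = "nonfinite"
        elif np.nanmax(values[:, j]) == np.nanmin(values[:, j]):
            mask[col] = "zero-variance"
    return FeatureMatrix(frame=frame, mask=mask, failed_rows=failed)


def _abs_corr(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return 0.0
    return abs(float(np.corrcoef(x, y)[0, 1]))


def select_features(
    X: FeatureMatrix,
    y: np.ndarray,
    cfg: SelectionConfig = SelectionConfig(),
    effective_rows: int | None = None,
) -> SelectionReport:
    """Variance → correlation-collapse → univariate-ranking cascade.

    Pure function of (matrix, target, config); ties in the target-correlation
    ranking break on lexicographic column name so the selected list is
    platform-stable. ``effective_rows`` caps the final feature count by the
    number of *independent* samples — enumeration duplicates share their
    parent's descriptor row, so counting raw rows would inflate the budget
    and overfit exactly when augmentation is heaviest.
    """
    frame = X.retained
    y = np.asarray(y, dtype=float)
    if len(frame) < 10:
        raise DatasetTooSmallError("select_features needs at least 10 rows")
    if len(y) != len(frame):
        raise ConfigurationError("target length does not match matrix rows")

    n_input = len(X.frame.columns)
    # stage 1: zero-variance (also re-checked here in case mask was cleared)
    cols = [c for c in frame.columns if frame[c].std() > 0]
    n_after_variance = len(cols)
    if not cols:
        raise ConfigurationError(
            "all columns eliminated at the variance stage; relax thresholds"
        )

    target_corr = {c: _abs_corr(frame[c].to_numpy(), y) for c in cols}
    # stage 2: collapse |r| > threshold pairs, keeping the better-correlated
    # member (tie -> lexicographic name). Greedy over a priority ordering.
    ordered = sorted(cols, key=lambda c: (-target_corr[c], c))
    corr = frame[cols].corr().abs()
    kept: list[str] = []
    for c in ordered:
        if all(corr.loc[c, k] <= cfg.corr_threshold for k in kept):
            kept.append(c)
    n_after_correlation = len(kept)

    n_rows = effective_rows if effective_rows is not None else len(frame)
    n_final = min(n_after_correlation, max(cfg.min_keep, n_rows // cfg.rows_per_feature))
    selected = sorted(kept, key=lambda c: (-target_corr[c], c))[:n_final]
    if not selected:
        raise ConfigurationError("all columns eliminated; relax thresholds")
    return SelectionReport(
        n_input=n_input,
        n_after_variance=n_after_variance,
        n_after_correlation=n_after_correlation,
        n_final=len(selected),
        selected_names=selected,
    )


@dataclass
class Scaler:
    """Per-feature standardization with train-set statistics."""

    mean: np.ndarray
    scale: np.ndarray  # std, zeros replaced by 1

    @classmethod
    def fit(cls, X: np.ndarray) -> "Scaler":
        mean = X.mean(axis=0)
        scale = X.std(axis=0)
        scale[scale == 0] = 1.0
        return cls(mean=mean, scale=scale)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.scale


def feature_block(
    table: DatasetTable, selected_names: list[str], set_name: str = "standard_2d"
) -> np.ndarray:
    """Descriptor values for ``selected_names`` only, in the given order.

    Used at prediction time: the stored name list guarantees query features
    are computed identically to training features.
    """
    fm = compute_descriptors(table, set_name)
    if fm.failed_rows:
        raise ConfigurationError(
            f"descriptor failure for records: {fm.failed_rows[:5]}"
        )
    missing = [c for c in selected_names if c not in fm.frame.columns]
    if missing:
        raise ConfigurationError(f"descriptor set lacks columns {missing[:5]}")
    return fm.frame[selected_names].to_numpy(dtype=float)
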