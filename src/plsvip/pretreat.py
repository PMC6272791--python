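"""Descriptor pretreatment: constant, low-variance and correlation filters.

Raw descriptor pools (e.g. a DRAGON export) carry columns that are constant
for every molecule, columns with negligible spread, and heavily redundant
pairs.  The three filters below are applied in that order; the correlation
filter is a deterministic greedy left-to-right scan (keep a column iff its
|Pearson r| with every previously kept column stays within the threshold).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PretreatLog",
    "read_descriptor_csv",
    "read_activity_csv",
    "drop_constant_descriptors",
    "drop_low_sd_descriptors",
    "drop_correlated_descriptors",
    "pretreat_pipeline",
]

DEFAULT_SD_MIN = 0.001
DEFAULT_R_MAX = 0.90


@dataclass
class PretreatLog:
    """Accounting of every removed column and why."""

    removed_constant: list[str] = field(default_factory=list)
    removed_low_sd: list[str] = field(default_factory=list)
    removed_correlated: list[tuple[str, str, float]] = field(default_factory=list)
    n_in: int = 0
    n_out: int = 0

    def to_lines(self) -> list[str]:
        lines = [f"{n}\tconstant\t\t" for n in self.removed_constant]
        lines += [f"{n}\tlow_sd\t\t" for n in self.removed_low_sd]
        lines += [f"{n}\tcorrelated\t{k}\t{r:.6f}" for n, k, r in self.removed_correlated]
        return lines


def _validate_table(X: pd.DataFrame) -> None:
    if X.shape[0] < 2 or X.shape[1] < 1:
        raise ValueError("descriptor table needs >= 2 compounds and >= 1 descriptor")
    if X.columns.duplicated().any():
        raise ValueError("duplicate descriptor names")
    if X.index.duplicated().any():
        raise ValueError("duplicate compound ids")
    if X.isna().any().any():
        raise ValueError("missing values in descriptor table")


def read_descriptor_csv(path) -> pd.DataFrame:
    """Load a descriptor CSV (first column compound id, header row names).

    Rows containing missing cells are rejected rather than imputed.
    """
    X = pd.read_csv(path, index_col=0)
    try:
        X = X.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric descriptor value: {exc}") from exc
    _validate_table(X)
    return X


def read_activity_csv(path) -> pd.Series:
    """Load an activity CSV with columns (id, CI); returns an id-indexed Series."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("activity CSV needs (id, value) columns")
    s = df.set_index(df.columns[0])[df.columns[1]].astype(float)
    if s.isna().any():
        raise ValueError("missing activity values")
    return s


def drop_constant_descriptors(X: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Remove columns taking a single value across all compounds."""
    _validate_table(X)
    vals = X.values
    constant = (vals.min(axis=0) == vals.max(axis=0))
    removed = [str(c) for c in X.columns[constant]]
    if len(removed) == X.shape[1]:
        raise ValueError("every descriptor is constant; table unusable")
    return X.loc[:, ~constant], removed


def drop_low_sd_descriptors(
    X: pd.DataFrame, sd_min: float = DEFAULT_SD_MIN
) -> tuple[pd.DataFrame, list[str]]:
    """Remove columns whose sample SD (ddof=1) is strictly below ``sd_min``."""
    _validate_table(X)
    sds = X.values.std(axis=0, ddof=1)
    low = sds < sd_min
    removed = [str(c) for c in X.columns[low]]
    if len(removed) == X.shape[1]:
        raise ValueError("every descriptor fell below the SD threshold")
    return X.loc[:, ~low], removed


def drop_correlated_descriptors(
    X: pd.DataFrame, r_max: float = DEFAULT_R_MAX
) -> tuple[pd.DataFrame, list[tuple[str, str, float]]]:
    """Greedy removal so that every surviving pair has |Pearson r| <= r_max.

    Scans columns left to right; a column is kept iff its absolute
    correlation with every previously kept column does not exceed the
    threshold (strict ``>`` removal, so a pair at exactly r_max survives).
    Returns (table, [(removed, kept_partner, r), ...]).
    """
    _validate_table(X)
    vals = X.values
    if np.any(vals.std(axis=0) == 0):
        raise ValueError("constant column encountered; correlation undefined")
    R = np.corrcoef(vals, rowvar=False)
    if X.shape[1] == 1:
        return X, []
    kept: list[int] = []
    removed: list[tuple[str, str, float]] = []
    for j in range(X.shape[1]):
        partner = None
        for i in kept:
            if abs(R[i, j]) > r_max:
                partner = i
                break
        if partner is None:
            kept.append(j)
        else:
            removed.append((str(X.columns[j]), str(X.columns[partner]), float(R[partner, j])))
    return X.iloc[:, kept], removed


def pretreat_pipeline(
    X: pd.DataFrame,
    sd_min: float = DEFAULT_SD_MIN,
    r_max: float = DEFAULT_R_MAX,
) -> tuple[pd.DataFrame, PretreatLog]:
    """Constant filter, then SD filter, then correlation filter.

    The log accounts for every removed column; the operation is idempotent.
    """
    log = PretreatLog(n_in=X.shape[1])
    X1, log.removed_constant = drop_constant_descriptors(X)
    X2, log.removed_low_sd = drop_low_sd_descriptors(X1, sd_min=sd_min)
    X3, log.removed_correlated = drop_correlated_descriptors(X2, r_max=r_max)
    log.n_out = X3.shape[1]
    assert log.n_out == log.n_in - len(log.removed_constant) - len(log.removed_low_sd) - len(log.removed_correlated)
    return X3, log
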