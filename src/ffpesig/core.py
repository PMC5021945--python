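"""Shared containers and error types.

Expression data flows through the pipeline as genes x samples
:class:`pandas.DataFrame` objects; :class:`ExpressionMatrix` is a thin
wrapper that additionally records which platform produced the matrix and
whether values are raw counts or log2 intensities.  All analysis
functions accept either the wrapper or a bare DataFrame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class FFPESigError(Exception):
    """Base class for all errors raised by this package."""


class ConfigurationError(FFPESigError):
    """An invalid parameter value; the message names the offending field."""


class DataError(FFPESigError):
    """Malformed or inconsistent input data."""


@dataclass
class ExpressionMatrix:
    """A genes x samples expression matrix with provenance tags.

    Parameters
    ----------
    data:
        Numeric DataFrame, rows indexed by gene (or probe) id, columns by
        sample id.
    platform:
        Free-text platform tag, e.g. ``"counter"`` or ``"array"``.
    scale:
        ``"raw-count"`` for integer counts, ``"log2"`` for log2 values.
    """

    data: pd.DataFrame
    platform: str = ""
    scale: str = "log2"

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> pd.Index:
        return self.data.columns

    def to_tsv(self, path) -> None:
        df = self.data.copy()
        df.index.name = "gene_id"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, platform: str = "", scale: str = "log2") -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df, platform=platform, scale=scale)


def as_frame(matrix) -> pd.DataFrame:
    """Return the underlying DataFrame of a matrix-like argument."""
    if isinstance(matrix, ExpressionMatrix):
        return matrix.data
    if isinstance(matrix, pd.DataFrame):
        return matrix
    raise TypeError(f"expected ExpressionMatrix or DataFrame, got {type(matrix).__name__}")


@dataclass(frozen=True)
class ControlSet:
    """Disjoint control-gene id sets for the targeted count platform."""

    positive: frozenset = field(default_factory=frozenset)
    negative: frozenset = field(default_factory=frozenset)
    housekeeping: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        pos, neg, hk = map(frozenset, (self.positive, self.negative, self.housekeeping))
        object.__setattr__(self, "positive", pos)
        object.__setattr__(self, "negative", neg)
        object.__setattr__(self, "housekeeping", hk)
        if pos & neg or pos & hk or neg & hk:
            raise DataError("control classes must be disjoint gene sets")

    @property
    def all(self) -> frozenset:
        return self.positive | self.negative | self.housekeeping


# Canonical clinical-table column names used throughout the package.
CLINICAL_COLUMNS = (
    "os_time_months",
    "os_event",
    "dfs_time_months",
    "dfs_event",
    "batch",
)

ENDPOINTS = ("OS", "DFS")


def endpoint_columns(endpoint: str) -> tuple[str, str]:
    """Map an endpoint label to its (time, event) clinical columns."""
    key = endpoint.upper()
    if key == "OS":
        return "os_time_months", "os_event"
    if key == "DFS":
        return "dfs_time_months", "dfs_event"
    raise ConfigurationError(f"endpoint must be 'OS' or 'DFS', got {endpoint!r}")


def validate_survival_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check a clinical survival table for the invariants the pipeline relies on.

    Times must be strictly positive and finite; event flags must be 0/1.
    Returns the table unchanged.
    """
    missing = [c for c in CLINICAL_COLUMNS if c not in table.columns]
    if missing:
        raise DataError(f"survival table missing columns: {missing}")
    for tcol in ("os_time_months", "dfs_time_months"):
        t = table[tcol].to_numpy(float)
        if not np.all(np.isfinite(t)) or np.any(t <= 0):
            raise DataError(f"{tcol} must be strictly positive and finite")
    for ecol in ("os_event", "dfs_event"):
        e = table[ecol].to_numpy()
        if not np.isin(e, (0, 1)).all():
            raise DataError(f"{ecol} must be binary 0/1")
    return table
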