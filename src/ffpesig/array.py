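"""Gene-level summarization and normalization of probe-level array data.

Follows the RMA recipe for intensities that are already on a log scale:
quantile normalization across samples, Tukey median-polish
summarization of multi-row probe sets, removal of probes mapping to
multiple genes, and — where several probe sets interrogate one gene —
retention of the probe set with the largest interquartile range across
samples.  Convolution background correction of scanner optics is out of
scope (vendor-summarized input is assumed log-scale).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .core import DataError, as_frame

__all__ = [
    "quantile_normalize",
    "median_polish_summarize",
    "drop_multigene_probes",
    "collapse_by_iqr",
    "summarize_array",
]


def quantile_normalize(matrix) -> pd.DataFrame:
    """Force every sample (column) onto the common distribution of row-rank means.

    Within-column rank order is preserved; ties are broken by row
    position (stable sort), which makes the operation idempotent and
    guarantees every column ends up with the identical sorted multiset.
    A single-column matrix is returned unchanged with a warning.
    """
    df = as_frame(matrix)
    vals = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        raise DataError("quantile_normalize requires finite values")
    if df.shape[1] < 2:
        warnings.warn("quantile_normalize: single sample, returning input unchanged")
        return df.copy()
    order = np.argsort(vals, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(vals, order, axis=0)
    reference = sorted_vals.mean(axis=1)
    out = np.empty_like(vals)
    np.put_along_axis(out, order, reference[:, None], axis=0)
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def median_polish_summarize(probe_rows, *, tol: float = 1e-8, max_iter: int = 20) -> pd.Series:
    """Summarize the probe rows of one probe set into a per-sample value.

    Fits the additive model value[probe, sample] = overall + row + column
    by Tukey's iterated median sweeps and returns overall + column
    effects.  A single probe row is returned unchanged.
    """
    df = as_frame(probe_rows)
    x = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(x)):
        raise DataError("median_polish_summarize requires finite values")
    if x.shape[0] == 1:
        return pd.Series(x[0], index=df.columns)

    z = x.copy()
    overall = 0.0
    row_eff = np.zeros(x.shape[0])
    col_eff = np.zeros(x.shape[1])
    prev_abs = np.abs(z).sum()
    for _ in range(max_iter):
        rm = np.median(z, axis=1)
        z -= rm[:, None]
        row_eff += rm
        delta = np.median(col_eff)
        col_eff -= delta
        overall += delta
        cm = np.median(z, axis=0)
        z -= cm[None, :]
        col_eff += cm
        delta = np.median(row_eff)
        row_eff -= delta
        overall += delta
        cur_abs = np.abs(z).sum()
        if abs(prev_abs - cur_abs) <= tol * max(prev_abs, 1.0):
            break
        prev_abs = cur_abs
    return pd.Series(overall + col_eff, index=df.columns)


def drop_multigene_probes(matrix, probe_map: dict) -> pd.DataFrame:
    """Remove probe rows whose probe maps to two or more genes."""
    df = as_frame(matrix)
    missing = [p for p in df.index if p not in probe_map]
    if missing:
        raise DataError(f"probes missing from probe map: {missing[:10]}")
    keep = [p for p in df.index if len(set(probe_map[p])) == 1]
    return df.loc[keep]


def _iqr(row: np.ndarray) -> float:
    q1, q3 = np.percentile(row, [25, 75], method="midpoint")
    return float(q3 - q1)


def collapse_by_iqr(candidates: dict) -> pd.DataFrame:
    """Per gene, keep the candidate row with the largest interquartile range.

    ``candidates`` maps gene id -> DataFrame of summarized candidate rows
    (indexed by probe/probe-set id).  Exact IQR ties are broken by the
    lexicographically smallest probe id; the result is therefore
    invariant to candidate order.  Output has one row per gene.
    """
    rows = {}
    for gene, frame in candidates.items():
        frame = as_frame(frame)
        if frame.shape[0] == 0:
            raise DataError(f"gene {gene!r} has no candidate rows")
        frame = frame.sort_index()
        iqrs = frame.apply(lambda r: _iqr(r.to_numpy(dtype=float)), axis=1)
        rows[gene] = frame.loc[iqrs.idxmax()]
    out = pd.DataFrame(rows).T
    out.index.name = "gene_id"
    return out


def summarize_array(probes, probe_map: dict, *, quantile: bool = True) -> pd.DataFrame:
    """Probe matrix -> gene-level matrix.

    Quantile-normalizes (optional), drops multi-gene probes, then
    collapses multiple probes per gene by largest IQR.  Probe sets that
    span several rows should be median-polished into single candidate
    rows before calling this function.
    """
    df = as_frame(probes)
    if quantile and df.shape[1] >= 2:
        df = quantile_normalize(df)
    df = drop_multigene_probes(df, probe_map)
    by_gene: dict[str, list] = {}
    for probe in df.index:
        (gene,) = set(probe_map[probe])
        by_gene.setdefault(gene, []).append(probe)
    candidates = {g: df.loc[ps] for g, ps in by_gene.items()}
    return collapse_by_iqr(candidates)
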