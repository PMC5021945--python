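"""Cross-platform agreement between matched expression profiles.

Agreement is quantified four ways, mirroring how paired-platform
studies are usually reported: per-pair (sample-wise) correlation over
the common genes, per-gene correlation over the matched pairs with a
percentile-bootstrap CI on the mean, sign concordance of univariate
log hazard ratios, and a one-sided two-sample Kolmogorov-Smirnov
comparison of the -log10 p-value distributions from the two screens
(does one platform's p-value CDF lie above the other's, i.e. carry
less survival signal?).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import DataError, ConfigurationError, as_frame

__all__ = [
    "samplewise_correlation",
    "genewise_correlation",
    "pairwise_correlation_matrix",
    "bootstrap_mean_ci",
    "hr_direction_concordance",
    "ks_compare_neglog10p",
    "KSComparison",
    "DirectionConcordance",
]

PAIR_COLUMNS = ("sample_a", "sample_b", "replicate_type")


def _validate_pairs(pairs: pd.DataFrame, matA: pd.DataFrame, matB: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PAIR_COLUMNS if c not in pairs.columns]
    if missing:
        raise DataError(f"pair map missing columns: {missing}")
    if pairs["sample_a"].duplicated().any() or pairs["sample_b"].duplicated().any():
        raise DataError("each sample may appear in at most one pair")
    bad_a = [s for s in pairs["sample_a"] if s not in matA.columns]
    bad_b = [s for s in pairs["sample_b"] if s not in matB.columns]
    if bad_a or bad_b:
        raise DataError(f"paired samples absent from matrices: {bad_a + bad_b}")
    return pairs


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, bool]:
    """Raw-formula Pearson r; constant input yields (nan, undefined=True)."""
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc * xc).sum() * (yc * yc).sum())
    if denom == 0.0:
        return float("nan"), True
    return float((xc * yc).sum() / denom), False


def _rank(v: np.ndarray) -> np.ndarray:
    # average ranks (midranks) for Spearman
    order = np.argsort(v, kind="stable")
    ranks = np.empty(v.size, dtype=float)
    sv = v[order]
    i = 0
    while i < v.size:
        j = i
        while j + 1 < v.size and sv[j + 1] == sv[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def _corr(x: np.ndarray, y: np.ndarray, method: str) -> tuple[float, bool]:
    if method == "pearson":
        return _pearson(x, y)
    if method == "spearman":
        return _pearson(_rank(x), _rank(y))
    raise ConfigurationError(f"unknown correlation method {method!r}")


def _paired_blocks(matA, matB, pairs, common_genes):
    A = as_frame(matA)
    B = as_frame(matB)
    pairs = _validate_pairs(pairs, A, B)
    if common_genes is None:
        common_genes = A.index.intersection(B.index)
    common_genes = pd.Index(common_genes)
    subA = A.loc[common_genes, list(pairs["sample_a"])].to_numpy(dtype=float)
    subB = B.loc[common_genes, list(pairs["sample_b"])].to_numpy(dtype=float)
    return subA, subB, pairs, common_genes


def samplewise_correlation(matA, matB, pairs: pd.DataFrame, common_genes=None, *,
                           method: str = "pearson") -> pd.DataFrame:
    """Per-pair correlation across the common genes.

    Returns one row per pair with columns ``sample_a, sample_b,
    replicate_type, r, undefined``.  Genes are not filtered for
    variance; an all-constant profile is flagged undefined.
    """
    subA, subB, pairs, genes = _paired_blocks(matA, matB, pairs, common_genes)
    if len(genes) < 3:
        raise DataError("samplewise correlation requires at least 3 common genes")
    rows = []
    for k in range(subA.shape[1]):
        r, und = _corr(subA[:, k], subB[:, k], method)
        rows.append(r if not und else np.nan)
    out = pairs.reset_index(drop=True).copy()
    out["r"] = rows
    out["undefined"] = out["r"].isna()
    return out


def genewise_correlation(matA, matB, pairs: pd.DataFrame, common_genes=None, *,
                         method: str = "pearson") -> pd.DataFrame:
    """Per-gene correlation across the matched sample pairs."""
    subA, subB, pairs, genes = _paired_blocks(matA, matB, pairs, common_genes)
    if len(pairs) < 3:
        raise DataError("genewise correlation requires at least 3 pairs")
    rows = []
    for g in range(subA.shape[0]):
        r, und = _corr(subA[g], subB[g], method)
        rows.append(r if not und else np.nan)
    out = pd.DataFrame({"r": rows}, index=genes)
    out["undefined"] = out["r"].isna()
    out.index.name = "gene"
    return out


def pairwise_correlation_matrix(matA, matB, pairs: pd.DataFrame, common_genes=None) -> pd.DataFrame:
    """Full cross-platform sample x sample Pearson matrix (heatmap input)."""
    subA, subB, pairs, genes = _paired_blocks(matA, matB, pairs, common_genes)
    if len(genes) < 3:
        raise DataError("pairwise correlation requires at least 3 common genes")
    a = subA - subA.mean(axis=0)
    b = subB - subB.mean(axis=0)
    na = np.sqrt((a * a).sum(axis=0))
    nb = np.sqrt((b * b).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        c = (a.T @ b) / np.outer(na, nb)
    return pd.DataFrame(c, index=list(pairs["sample_a"]), columns=list(pairs["sample_b"]))


def bootstrap_mean_ci(values, n_boot: int = 1000, level: float = 0.95, seed=None):
    """Percentile bootstrap of the mean: ``(mean, lower, upper)``.

    Deterministic given ``seed``; NaN values are rejected.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise DataError("bootstrap_mean_ci requires at least 2 values")
    if np.any(~np.isfinite(v)):
        raise DataError("bootstrap_mean_ci: values must be finite (drop undefined correlations first)")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, v.size, size=(n_boot, v.size))
    means = v[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return float(v.mean()), float(lo), float(hi)


@dataclass(frozen=True)
class DirectionConcordance:
    n_same_sign: int
    n_opposite_sign: int
    n_degenerate: int

    @property
    def total(self) -> int:
        return self.n_same_sign + self.n_opposite_sign + self.n_degenerate


def hr_direction_concordance(resA: pd.DataFrame, resB: pd.DataFrame) -> DirectionConcordance:
    """Compare the sign of per-gene log hazard ratios across two screens.

    Genes that are degenerate or have log HR exactly 0 on either side
    are counted separately; the three counts partition the gene universe.
    """
    if set(resA.index) != set(resB.index):
        raise DataError("screen results cover different gene universes")
    b = resB.loc[resA.index]
    lhA = resA["log_hr"].to_numpy(dtype=float)
    lhB = b["log_hr"].to_numpy(dtype=float)
    degA = resA["degenerate"].to_numpy(dtype=bool) if "degenerate" in resA else np.zeros(lhA.size, bool)
    degB = b["degenerate"].to_numpy(dtype=bool) if "degenerate" in b else np.zeros(lhB.size, bool)
    deg = degA | degB | (lhA == 0) | (lhB == 0)
    same = (~deg) & (np.sign(lhA) == np.sign(lhB))
    opp = (~deg) & ~same
    return DirectionConcordance(int(same.sum()), int(opp.sum()), int(deg.sum()))


@dataclass(frozen=True)
class KSComparison:
    statistic: float
    p_value: float
    alternative: str


def ks_compare_neglog10p(pA, pB, alternative: str = "first_above") -> KSComparison:
    """One-sided two-sample KS comparison of -log10 p-value distributions.

    ``alternative="first_above"`` tests whether the CDF of -log10(pA)
    lies above that of -log10(pB) (i.e. sample A carries less signal);
    ``"second_above"`` tests the reverse.  The statistic is the sup of
    the signed CDF difference in the alternative's direction over all
    pooled jump points, and the asymptotic one-sided p-value is
    exp(-2 m n D^2 / (m + n)).
    """
    if alternative not in ("first_above", "second_above"):
        raise ConfigurationError("alternative must be 'first_above' or 'second_above'")
    a = np.asarray(pA, dtype=float)
    b = np.asarray(pB, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DataError("both p-value vectors must be non-empty")
    for v in (a, b):
        if np.any(~np.isfinite(v)) or np.any(v <= 0) or np.any(v > 1):
            raise DataError("p-values must lie in (0, 1]")
    x = -np.log10(a)
    y = -np.log10(b)
    pooled = np.union1d(x, y)
    fx = np.searchsorted(np.sort(x), pooled, side="right") / x.size
    fy = np.searchsorted(np.sort(y), pooled, side="right") / y.size
    diff = fx - fy if alternative == "first_above" else fy - fx
    d = max(float(diff.max()), 0.0)
    m, n = x.size, y.size
    p = float(min(1.0, np.exp(-2.0 * m * n * d * d / (m + n))))
    return KSComparison(statistic=d, p_value=p, alternative=alternative)
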