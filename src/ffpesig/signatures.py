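"""Multi-gene prognostic signature evaluation.

A signature is a published gene list in which each gene carries the
direction of its expression change in poor-outcome tumors.  Evaluation
on a new cohort proceeds in four steps:

1. (optional) discordance filtering — drop genes whose fitted
   univariate log hazard ratio in *this* cohort contradicts the
   published direction (up must have log HR > 0, down < 0);
2. risk score — per-gene median-centering across samples, sign-flip of
   "down" genes so higher always means higher predicted risk, then the
   per-sample mean over signature genes;
3. median split into high- and low-risk groups (ties at the threshold
   go low, then the tied samples with the largest ids move high until
   the groups differ by at most one);
4. Kaplan-Meier curves per group and a two-group log-rank test per
   endpoint within the five-year window.

Because step 1 reuses the evaluation cohort's own hazard estimates, the
filtered result is optimistically biased; the unfiltered evaluation is
therefore always produced alongside by the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import DataError, ConfigurationError, as_frame, endpoint_columns, validate_survival_table
from .survival import apply_horizon, km_estimate, logrank_two_group, screen_genes, KMCurve

__all__ = [
    "SignatureDefinition",
    "RiskGrouping",
    "filter_discordant_genes",
    "risk_score",
    "median_split",
    "evaluate_signature",
    "risk_group_overlap",
    "SignatureEvaluation",
]


@dataclass(frozen=True)
class SignatureDefinition:
    """A named gene list with per-gene expected direction in poor-outcome tumors."""

    name: str
    genes: tuple
    direction: dict = field(default_factory=dict)  # gene -> "up" | "down"
    source: str = ""

    def __post_init__(self):
        genes = tuple(self.genes)
        if len(set(genes)) != len(genes):
            raise DataError(f"signature {self.name!r}: duplicate genes")
        bad = {g: d for g, d in self.direction.items() if d not in ("up", "down")}
        if bad:
            raise DataError(f"signature {self.name!r}: directions must be 'up'/'down', got {bad}")
        extra = set(self.direction) - set(genes)
        if extra:
            raise DataError(f"signature {self.name!r}: directions for unknown genes {sorted(extra)}")
        object.__setattr__(self, "genes", genes)

    @property
    def undirected_genes(self) -> tuple:
        """Genes without direction information (kept but flagged downstream)."""
        return tuple(g for g in self.genes if g not in self.direction)


@dataclass
class RiskGrouping:
    """Median-split risk-group assignment."""

    scores: pd.Series                  # per-sample risk score
    group: pd.Series                   # per-sample "high" | "low"
    threshold: float

    @property
    def n_high(self) -> int:
        return int((self.group == "high").sum())

    @property
    def n_low(self) -> int:
        return int((self.group == "low").sum())


def filter_discordant_genes(sig: SignatureDefinition, screen: pd.DataFrame) -> SignatureDefinition:
    """Drop signature genes whose fitted hazard direction contradicts the published one.

    ``screen`` is a per-gene Cox screen result (columns ``log_hr``,
    ``degenerate``) for the chosen endpoint.  Genes absent from the
    screen or degenerate are dropped; genes lacking direction
    information are kept.  Raises if nothing survives.
    """
    kept, dropped = [], []
    for g in sig.genes:
        if g not in screen.index:
            dropped.append(g)
            continue
        row = screen.loc[g]
        if bool(row.get("degenerate", False)):
            dropped.append(g)
            continue
        d = sig.direction.get(g)
        if d is None:
            kept.append(g)  # no direction info: kept, flagged via undirected_genes
        elif (d == "up" and row["log_hr"] > 0) or (d == "down" and row["log_hr"] < 0):
            kept.append(g)
        else:
            dropped.append(g)
    if not kept:
        raise DataError(
            f"signature {sig.name!r}: no gene survives direction filtering; "
            "use the unfiltered variant"
        )
    return SignatureDefinition(
        name=sig.name,
        genes=tuple(kept),
        direction={g: sig.direction[g] for g in kept if g in sig.direction},
        source=sig.source,
    )


def risk_score(matrix, sig: SignatureDefinition, *, flip_down_genes: bool = True) -> pd.Series:
    """Average of median-normalized signature-gene expression per sample.

    Each gene is centered at its across-sample median; genes annotated
    "down" are sign-flipped (configurable) so that a higher score always
    denotes higher predicted risk.
    """
    df = as_frame(matrix)
    present = [g for g in sig.genes if g in df.index]
    if not present:
        raise DataError(f"signature {sig.name!r}: no signature gene present in the matrix")
    sub = df.loc[present].astype(float)
    centered = sub.sub(sub.median(axis=1), axis=0)
    if flip_down_genes:
        flip = np.array([-1.0 if sig.direction.get(g) == "down" else 1.0 for g in present])
        centered = centered.mul(flip, axis=0)
    return centered.mean(axis=0)


def median_split(scores: pd.Series) -> RiskGrouping:
    """Split samples at the median score into high- and low-risk groups.

    Scores above the median go high, below go low.  Scores exactly at
    the median are assigned low, then the threshold-tied samples with
    the largest sample ids are moved to high until the group sizes
    differ by at most one.  Order-invariant and deterministic.
    """
    scores = pd.Series(scores).astype(float)
    if scores.size < 2:
        raise DataError("median_split requires at least 2 samples")
    if scores.nunique() == 1:
        raise DataError("all scores identical: no median split possible")
    threshold = float(scores.median())
    group = pd.Series(
        np.where(scores > threshold, "high", "low"), index=scores.index, dtype=object
    )
    tied = sorted(scores.index[scores == threshold])
    while tied and (group == "low").sum() - (group == "high").sum() > 1:
        group[tied.pop()] = "high"
    return RiskGrouping(scores=scores, group=group, threshold=threshold)


@dataclass
class EndpointResult:
    endpoint: str
    chi_square: float
    p_value: float
    km_high: KMCurve
    km_low: KMCurve


@dataclass
class SignatureEvaluation:
    """Result of evaluating one signature on one cohort/platform."""

    signature: str
    filtered: bool
    genes_used: tuple
    genes_dropped: tuple
    undirected_genes: tuple
    grouping: RiskGrouping
    endpoints: dict  # endpoint -> EndpointResult

    def summary(self) -> dict:
        return {
            "signature": self.signature,
            "filtered": self.filtered,
            "n_genes_used": len(self.genes_used),
            "n_genes_dropped": len(self.genes_dropped),
            "genes_used": list(self.genes_used),
            "genes_dropped": list(self.genes_dropped),
            "n_high": self.grouping.n_high,
            "n_low": self.grouping.n_low,
            **{
                f"logrank_p_{ep.lower()}": res.p_value
                for ep, res in self.endpoints.items()
            },
        }


def evaluate_signature(matrix, sig: SignatureDefinition, table: pd.DataFrame, *,
                       endpoints=("OS", "DFS"), filtered: bool = True,
                       screen: pd.DataFrame | None = None,
                       filter_endpoint: str = "DFS", horizon_months: float = 60.0,
                       flip_down_genes: bool = True,
                       fdr_threshold: float = 0.05) -> SignatureEvaluation:
    """Full signature evaluation: filter, score, split, KM + log-rank.

    When ``filtered`` is true the direction filter uses ``screen`` (a
    Cox screen for ``filter_endpoint``), computing it from the same
    cohort when not supplied — the circularity this introduces is
    deliberate and should be read alongside the unfiltered variant.
    """
    df = as_frame(matrix)
    validate_survival_table(table)
    if set(df.columns) != set(table.index):
        raise DataError("matrix samples and survival table disagree")
    table = table.loc[df.columns]

    dropped: tuple = ()
    used_sig = sig
    if filtered:
        if screen is None:
            screen = screen_genes(df, table, filter_endpoint,
                                  horizon_months=horizon_months, fdr_threshold=fdr_threshold)
        used_sig = filter_discordant_genes(sig, screen)
        dropped = tuple(g for g in sig.genes if g not in used_sig.genes)

    scores = risk_score(df, used_sig, flip_down_genes=flip_down_genes)
    grouping = median_split(scores)
    capped = apply_horizon(table, horizon_months)
    high = grouping.group == "high"

    results = {}
    for ep in endpoints:
        tcol, ecol = endpoint_columns(ep)
        t = capped[tcol].to_numpy()
        e = capped[ecol].to_numpy()
        chi, p = logrank_two_group(high.to_numpy().astype(int), t, e)
        results[ep.upper()] = EndpointResult(
            endpoint=ep.upper(),
            chi_square=chi,
            p_value=p,
            km_high=km_estimate(t[high.to_numpy()], e[high.to_numpy()]),
            km_low=km_estimate(t[~high.to_numpy()], e[~high.to_numpy()]),
        )
    present = [g for g in used_sig.genes if g in df.index]
    return SignatureEvaluation(
        signature=sig.name,
        filtered=filtered,
        genes_used=tuple(present),
        genes_dropped=dropped,
        undirected_genes=used_sig.undirected_genes,
        grouping=grouping,
        endpoints=results,
    )


def risk_group_overlap(groupingA: RiskGrouping, groupingB: RiskGrouping) -> float:
    """Fraction of samples assigned the same risk group by two groupings."""
    a, b = groupingA.group, groupingB.group
    if set(a.index) != set(b.index):
        raise DataError("risk groupings cover different sample universes")
    return float((a == b.loc[a.index]).mean())
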