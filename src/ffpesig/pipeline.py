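"""End-to-end orchestration of the two-platform evaluation.

Stage order mirrors the analysis the package implements: count-platform
QC and normalization, array summarization, restriction to the common
gene/sample universe, per-platform batch adjustment with negative
clamping, univariate Cox screening of both endpoints on both platforms,
cross-platform concordance, and multi-gene signature evaluation
(filtered and unfiltered).  Outputs are a pure function of
(inputs, config); re-running reproduces every artifact byte-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io
from .batch import clamp_negative, combat_adjust
from .concordance import (bootstrap_mean_ci, genewise_correlation,
                          hr_direction_concordance, ks_compare_neglog10p,
                          pairwise_correlation_matrix, samplewise_correlation)
from .core import DataError, as_frame
from .counter import QCThresholds, compute_qc, filter_samples, normalize_counts
from .array import summarize_array
from .signatures import evaluate_signature, risk_group_overlap
from .survival import screen_genes

log = logging.getLogger("ffpesig")

__all__ = ["PipelineConfig", "run_pipeline", "intersect_common"]


@dataclass
class PipelineConfig:
    """Paths and thresholds for one pipeline run.

    Threshold defaults are the field-standard printed cutoffs: minimum
    average count 1000, maximum missing rate 0.20, FDR 0.05, log-rank
    alpha 0.05, five-year (60 month) horizon.
    """

    counts: str = "counts.tsv"
    controls: str = "controls.tsv"
    probes: str = "probes.tsv"
    probe_map: str = "probe_map.tsv"
    clinical: str = "clinical.tsv"
    pairs: str = "pairs.tsv"
    signatures_gmt: str = "signatures.gmt"
    directions: str = "directions.tsv"

    qc: QCThresholds = field(default_factory=QCThresholds)
    horizon_months: float = 60.0
    fdr_threshold: float = 0.05
    logrank_alpha: float = 0.05
    n_boot: int = 1000
    seed: int = 0
    flip_down_genes: bool = True
    filter_endpoint: str = "DFS"
    parametric_shrinkage: bool = True

    def __post_init__(self):
        if self.horizon_months <= 0:
            raise DataError("horizon_months must be positive")
        for name in ("fdr_threshold", "logrank_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise DataError(f"{name} must lie in (0, 1)")
        if self.n_boot < 1:
            raise DataError("n_boot must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        qc = raw.pop("qc", None)
        cfg = cls(**raw)
        if qc:
            cfg.qc = QCThresholds(**qc)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def intersect_common(matA, matB, pairs: pd.DataFrame):
    """Restrict both matrices to shared genes and to matched sample pairs.

    Returns ``(matA', matB', common_genes, pairs')`` where ``pairs'``
    keeps only rows whose both samples survived upstream filtering.
    """
    A, B = as_frame(matA), as_frame(matB)
    genes = A.index.intersection(B.index)
    if len(genes) == 0:
        raise DataError("no genes are shared between the two platforms")
    keep = pairs[pairs["sample_a"].isin(A.columns) & pairs["sample_b"].isin(B.columns)]
    if keep.empty:
        raise DataError("no matched sample pair survives filtering on both platforms")
    return (A.loc[genes, list(keep["sample_a"])],
            B.loc[genes, list(keep["sample_b"])],
            list(genes), keep.reset_index(drop=True))


def _read_probe_map(path) -> dict:
    df = pd.read_csv(path, sep="\t")
    if not {"probe_id", "gene_ids"} <= set(df.columns):
        raise DataError(f"{path}: expected columns probe_id, gene_ids")
    return {r.probe_id: tuple(str(r.gene_ids).split(",")) for r in df.itertuples()}


def _stage(name, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as exc:
        raise DataError(f"pipeline stage {name!r} failed: {exc}") from exc


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run every stage and write the artifact directory.

    Returns a dict of the in-memory results keyed by artifact name.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    counts = io.read_expression_tsv(config.counts)
    controls = io.read_controls_tsv(config.controls)
    probes = io.read_expression_tsv(config.probes)
    probe_map = _read_probe_map(config.probe_map)
    clinical = io.read_clinical_tsv(config.clinical)
    pairs = io.read_pairs_tsv(config.pairs)
    signatures = io.read_signatures(config.signatures_gmt, config.directions)

    # --- counter platform ---------------------------------------------------
    report = _stage("counter_qc", compute_qc, counts, controls, config.qc)
    report.to_tsv(outdir / "qc_report.tsv")
    kept = _stage("counter_qc", filter_samples, counts, report)
    log.info("counter_qc: %d/%d samples pass", kept.shape[1], counts.shape[1])
    counter_log2 = _stage("counter_normalize", normalize_counts, kept, controls)

    # --- array platform -----------------------------------------------------
    array_log2 = _stage("array_prep", summarize_array, probes, probe_map)
    log.info("array_prep: %d probes -> %d genes x %d samples",
             probes.shape[0], *array_log2.shape)

    # --- common universe ----------------------------------------------------
    cA, cB, common_genes, pairs_kept = _stage(
        "intersect_common", intersect_common, counter_log2, array_log2, pairs)
    log.info("intersect_common: %d genes, %d pairs", len(common_genes), len(pairs_kept))

    # --- batch adjustment (per platform) ------------------------------------
    batch = clinical["batch"]
    pair_lookup = dict(zip(pairs_kept["sample_b"], pairs_kept["sample_a"]))
    batch_b = pd.Series({s: batch.get(pair_lookup.get(s, s)) for s in cB.columns})
    adjA = clamp_negative(_stage("batch_adjust", combat_adjust, cA,
                                 batch.loc[cA.columns], config.parametric_shrinkage))
    adjB = clamp_negative(_stage("batch_adjust", combat_adjust, cB,
                                 batch_b, config.parametric_shrinkage))
    io.write_expression_tsv(adjA, outdir / "expression_counter.tsv")
    io.write_expression_tsv(adjB, outdir / "expression_array.tsv")

    # --- survival screening -------------------------------------------------
    clinA = clinical.loc[adjA.columns]
    clinB = clinical.loc[[pair_lookup.get(s, s) for s in adjB.columns]].copy()
    clinB.index = adjB.columns
    screens = {}
    for platform, mat, clin in (("counter", adjA, clinA), ("array", adjB, clinB)):
        for ep in ("OS", "DFS"):
            screens[(platform, ep)] = _stage(
                f"screen_{platform}_{ep}", screen_genes, mat, clin, ep,
                horizon_months=config.horizon_months, fdr_threshold=config.fdr_threshold)
    cox_all = pd.concat(
        [df.assign(platform=p) for (p, _), df in screens.items()]
    )
    cox_all.to_csv(outdir / "cox_results.tsv", sep="\t")

    # --- concordance --------------------------------------------------------
    conc = {"n_common_genes": len(common_genes), "n_pairs": int(len(pairs_kept))}
    sw = samplewise_correlation(adjA, adjB, pairs_kept)
    sw_sp = samplewise_correlation(adjA, adjB, pairs_kept, method="spearman")
    gw = genewise_correlation(adjA, adjB, pairs_kept)
    for label, frame in (("samplewise_pearson", sw), ("samplewise_spearman", sw_sp),
                         ("genewise_pearson", gw)):
        vals = frame["r"].dropna().to_numpy()
        mean, lo, hi = bootstrap_mean_ci(vals, n_boot=config.n_boot, seed=config.seed)
        conc[label] = {"mean": mean, "ci_lower": lo, "ci_upper": hi,
                       "min": float(vals.min()), "max": float(vals.max()),
                       "n_undefined": int(frame["undefined"].sum())}
    conc["samplewise_pearson"]["per_pair"] = sw["r"].round(6).tolist()
    for ep in ("OS", "DFS"):
        ks = ks_compare_neglog10p(screens[("counter", ep)]["p_value"],
                                  screens[("array", ep)]["p_value"],
                                  alternative="first_above")
        dc = hr_direction_concordance(screens[("counter", ep)], screens[("array", ep)])
        conc[f"ks_{ep.lower()}"] = {"statistic": ks.statistic, "p_value": ks.p_value,
                                    "alternative": "counter CDF above array"}
        conc[f"direction_{ep.lower()}"] = {"same": dc.n_same_sign,
                                           "opposite": dc.n_opposite_sign,
                                           "degenerate": dc.n_degenerate}
        conc[f"n_significant_{ep.lower()}"] = {
            p: int(screens[(p, ep)]["significant"].sum()) for p in ("counter", "array")}
    pairwise_correlation_matrix(adjA, adjB, pairs_kept).round(6).to_csv(
        outdir / "pairwise_correlation.tsv", sep="\t")
    (outdir / "concordance.json").write_text(json.dumps(conc, indent=1, sort_keys=True))

    # --- signatures ---------------------------------------------------------
    sig_report = {}
    groupings = {}
    for sig in signatures:
        sig_report[sig.name] = {}
        for platform, mat, clin in (("counter", adjA, clinA), ("array", adjB, clinB)):
            entry = {}
            for filtered in (True, False):
                key = "filtered" if filtered else "unfiltered"
                try:
                    ev = evaluate_signature(
                        mat, sig, clin, filtered=filtered,
                        screen=screens[(platform, config.filter_endpoint.upper())] if filtered else None,
                        filter_endpoint=config.filter_endpoint,
                        horizon_months=config.horizon_months,
                        flip_down_genes=config.flip_down_genes,
                        fdr_threshold=config.fdr_threshold)
                except DataError as exc:
                    entry[key] = {"error": str(exc)}
                    continue
                entry[key] = ev.summary()
                if filtered:
                    groupings[(sig.name, platform)] = ev.grouping
                    for ep, res in ev.endpoints.items():
                        km = pd.concat([res.km_high.to_frame().assign(group="high"),
                                        res.km_low.to_frame().assign(group="low")])
                        km.to_csv(outdir / f"km_{sig.name}_{platform}_{ep.lower()}.tsv",
                                  sep="\t", index=False)
            sig_report[sig.name][platform] = entry
        both = [groupings.get((sig.name, p)) for p in ("counter", "array")]
        if all(g is not None for g in both):
            ga, gb = both
            gb_renamed = gb.group.copy()
            gb_renamed.index = [pair_lookup.get(s, s) for s in gb_renamed.index]
            common = ga.group.index.intersection(gb_renamed.index)
            if len(common):
                sig_report[sig.name]["risk_group_overlap"] = float(
                    (ga.group.loc[common] == gb_renamed.loc[common]).mean())
    (outdir / "signature_report.json").write_text(json.dumps(sig_report, indent=1, sort_keys=True))

    run_log = {"config": _jsonable(config.to_dict()), "seed": config.seed,
               "stages": {"counter_samples_pass": int(kept.shape[1]),
                          "common_genes": len(common_genes),
                          "pairs": int(len(pairs_kept))}}
    (outdir / "run_log.json").write_text(json.dumps(run_log, indent=1, sort_keys=True))
    return {"qc": report, "counter": adjA, "array": adjB, "screens": screens,
            "concordance": conc, "signatures": sig_report}


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    return obj
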