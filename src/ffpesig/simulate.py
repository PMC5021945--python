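"""Synthetic matched two-platform cohorts with known prognostic structure.

The generator emulates the study design this package analyzes: one
latent log2 expression layer shared by both platforms, rendered once as
negative-binomial counts with spike-in controls (targeted count
platform) and once as probe-level intensities with multi-probe genes
(genome-wide array platform), plus Cox-model survival for two
correlated endpoints and additive per-gene batch effects.

Latent layer.  z[g, s] = mu_g + gamma[g, batch(s)] + noise_sd * w[g, s]
with per-gene means mu_g drawn once, per-gene batch offsets gamma with
sd ``batch_shift_sd`` and standardized biological variation w.

Prognostic structure.  Prognostic signature genes in real cohorts are
co-expressed members of transcriptional programs, and what a univariate
screen estimates is each gene's *marginal* hazard association.  The
generator therefore draws one latent per-sample risk factor
u ~ N(0, 1), gives every prognostic gene g the standardized form

    w_g = d_g * (sqrt(rho) * u + sqrt(1 - rho) * eps_g),   d_g in {-1, +1},

with module correlation rho (``module_corr``), and lets the hazard act
on the factor:

    h(t | s) = baseline_hazard * exp((log_hr_magnitude / sqrt(rho)) * u_s),

so that each prognostic gene's marginal log hazard ratio per standard
deviation of expression is d_g * log_hr_magnitude.  Were the effects
instead additive over independent genes, the per-gene marginal signal
would shrink like 1/sqrt(n_prognostic) and no univariate screen could
recover a realistic signature.  Event times are exponential given the
linear predictor; censoring is independent uniform, calibrated at the
baseline hazard to the requested censoring fraction; OS and DFS share
the linear predictor but use independent draws.

Randomness.  One root :class:`numpy.random.SeedSequence` keyed by
``seed`` is spawned into named substreams in fixed order (latent,
survival, counts, array, signature), so every render operation is
bit-reproducible regardless of call order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields

import numpy as np
import pandas as pd
from scipy import optimize

from .core import ConfigurationError, ControlSet, DataError

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulatedCohort",
    "simulate_latent_expression",
    "simulate_survival",
    "render_count_platform",
    "render_array_platform",
    "make_signature",
    "simulate_cohort",
]

# fixed spike-in ladder (arbitrary concentration units, highest first)
POSITIVE_LADDER = (128.0, 32.0, 8.0, 2.0, 0.5, 0.125)
_SUBSTREAMS = ("latent", "survival", "counts", "array", "signature")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated cohort.

    Defaults mirror the paired-cohort geometry this package targets: 42
    matched samples, 516 signature genes of which 50 are prognostic with
    marginal |log HR| 1 per sd, seven housekeeping controls, two
    processing batches, and a five-year-scale exponential baseline
    (0.01 events/month, median survival ~69 months).
    """

    n_samples: int = 42
    n_genes: int = 516
    n_prognostic: int = 50
    log_hr_magnitude: float = 1.0
    baseline_hazard: float = 0.01          # events per month
    censor_rate: float = 0.3
    n_batches: int = 2
    batch_shift_sd: float = 0.5            # log2 units, per gene x batch
    count_dispersion: float = 0.1
    n_probes_per_gene: int = 2
    n_pos_controls: int = 6
    n_neg_controls: int = 8
    n_housekeeping: int = 7
    frac_low_quality: float = 0.2
    seed: int = 0
    # latent-layer shape
    noise_sd: float = 1.0                  # biological sd of latent log2 expression
    module_corr: float = 0.5               # co-expression of prognostic genes
    mean_log2: float = 8.0
    mean_log2_sd: float = 1.5
    # count rendering
    count_scale: float = 8.0               # counts per unit 2^z at efficiency 1
    neg_control_mean: float = 15.0
    low_quality_efficiency: float = 0.02
    # array rendering
    array_noise_sd: float = 0.3
    probe_affinity_sd: float = 1.0
    n_multigene_probes: int = 4

    def __post_init__(self):
        pos_int = ["n_samples", "n_genes", "n_batches", "n_probes_per_gene"]
        nonneg_int = ["n_prognostic", "n_pos_controls", "n_neg_controls",
                      "n_housekeeping", "n_multigene_probes"]
        pos_real = ["log_hr_magnitude", "baseline_hazard", "count_dispersion",
                    "count_scale", "mean_log2_sd", "low_quality_efficiency"]
        nonneg_real = ["batch_shift_sd", "noise_sd", "array_noise_sd",
                       "probe_affinity_sd", "neg_control_mean"]
        unit = ["censor_rate", "frac_low_quality"]
        for name in pos_int:
            if not isinstance(getattr(self, name), (int, np.integer)) or getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be a positive integer")
        for name in nonneg_int:
            if not isinstance(getattr(self, name), (int, np.integer)) or getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be a non-negative integer")
        for name in pos_real:
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"{name} must be strictly positive")
        for name in nonneg_real:
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        for name in unit:
            if not 0 <= getattr(self, name) <= 1:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.n_prognostic > self.n_genes:
            raise ConfigurationError("n_prognostic must not exceed n_genes")
        if not 0 < self.module_corr <= 1:
            raise ConfigurationError("module_corr must lie in (0, 1]")

    def rng(self, stream: str) -> np.random.Generator:
        """Named substream generator; order of _SUBSTREAMS is the contract."""
        children = np.random.SeedSequence(self.seed).spawn(len(_SUBSTREAMS))
        return np.random.default_rng(children[_SUBSTREAMS.index(stream)])

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}


@dataclass
class GroundTruth:
    """What the generator knows and downstream stages must recover."""

    gene_ids: tuple
    sample_ids: tuple
    prognostic_gene_ids: frozenset
    true_log_hr: dict                      # gene -> signed marginal log HR per sd
    true_direction: dict                   # gene -> "up" | "down"
    batch_assignments: dict                # sample -> batch label
    batch_offsets: pd.DataFrame            # genes x batches, log2 units
    linear_predictor: pd.Series            # per-sample Cox linear predictor
    risk_factor: pd.Series                 # latent u per sample
    low_quality_samples: frozenset = frozenset()

    def __post_init__(self):
        for g, lhr in self.true_log_hr.items():
            want = "up" if lhr > 0 else "down"
            if self.true_direction.get(g) != want:
                raise DataError(f"direction of {g} inconsistent with sign of its log HR")


def _ids(prefix: str, n: int, width: int = 4) -> list:
    return [f"{prefix}{i + 1:0{width}d}" for i in range(n)]


def simulate_latent_expression(config: SimulationConfig):
    """Draw the latent log2 matrix and its ground truth.

    Returns ``(latent, truth)`` where ``latent`` is a genes x samples
    DataFrame.  Deterministic given ``config`` (including seed).
    """
    rng = config.rng("latent")
    genes = _ids("G", config.n_genes)
    samples = _ids("S", config.n_samples, width=3)
    batches = [f"B{(i % config.n_batches) + 1}" for i in range(config.n_samples)]

    mu = rng.normal(config.mean_log2, config.mean_log2_sd, config.n_genes)
    gamma = rng.normal(0.0, config.batch_shift_sd, (config.n_genes, config.n_batches))
    u = rng.normal(0.0, 1.0, config.n_samples)
    w = rng.normal(0.0, 1.0, (config.n_genes, config.n_samples))

    prog_idx = rng.choice(config.n_genes, size=config.n_prognostic, replace=False)
    signs = rng.choice([-1.0, 1.0], size=config.n_prognostic)
    rho = config.module_corr
    if config.n_prognostic:
        eps = rng.normal(0.0, 1.0, (config.n_prognostic, config.n_samples))
        w[prog_idx] = signs[:, None] * (np.sqrt(rho) * u + np.sqrt(1.0 - rho) * eps)

    batch_col = np.array([int(b[1:]) - 1 for b in batches])
    z = mu[:, None] + gamma[:, batch_col] + config.noise_sd * w
    latent = pd.DataFrame(z, index=genes, columns=samples)

    if config.n_prognostic and config.log_hr_magnitude > 0:
        eta = (config.log_hr_magnitude / np.sqrt(rho)) * u
    else:
        eta = np.zeros(config.n_samples)

    n_lq = int(round(config.frac_low_quality * config.n_samples))
    lq = rng.choice(config.n_samples, size=n_lq, replace=False) if n_lq else np.array([], dtype=int)

    truth = GroundTruth(
        gene_ids=tuple(genes),
        sample_ids=tuple(samples),
        prognostic_gene_ids=frozenset(np.array(genes)[prog_idx]),
        true_log_hr={genes[i]: float(s * config.log_hr_magnitude)
                     for i, s in zip(prog_idx, signs)},
        true_direction={genes[i]: ("up" if s > 0 else "down")
                        for i, s in zip(prog_idx, signs)},
        batch_assignments=dict(zip(samples, batches)),
        batch_offsets=pd.DataFrame(gamma, index=genes,
                                   columns=[f"B{b + 1}" for b in range(config.n_batches)]),
        linear_predictor=pd.Series(eta, index=samples),
        risk_factor=pd.Series(u, index=samples),
        low_quality_samples=frozenset(np.array(samples)[lq]),
    )
    return latent, truth


def _uniform_censor_bound(baseline_hazard: float, censor_rate: float) -> float:
    """Upper bound u of Uniform(0, u) censoring hitting the target fraction.

    For T ~ Exp(lambda), C ~ U(0, u): P(C < T) = (1 - exp(-lambda u)) / (lambda u),
    which decreases from 1 to 0 in u; solved for the baseline hazard.
    """
    target = censor_rate

    def f(x):
        return (1.0 - np.exp(-x)) / x - target

    x = optimize.brentq(f, 1e-9, 1e9)
    return x / baseline_hazard


def simulate_survival(latent: pd.DataFrame, truth: GroundTruth,
                      config: SimulationConfig) -> pd.DataFrame:
    """Draw OS and DFS outcomes from the cohort's linear predictor.

    Event times are exponential with rate baseline_hazard * exp(eta_s);
    censoring is independent uniform; both endpoints use independent
    draws of the same mechanism.  Times are in months, strictly positive.
    """
    missing = [g for g in truth.prognostic_gene_ids if g not in latent.index]
    if missing:
        raise DataError(f"prognostic genes absent from latent matrix: {missing[:10]}")
    rng = config.rng("survival")
    samples = list(latent.columns)
    eta = truth.linear_predictor.loc[samples].to_numpy()
    rate = config.baseline_hazard * np.exp(eta)

    def endpoint():
        t_event = rng.exponential(1.0 / rate)
        if config.censor_rate <= 0:
            c = np.full(len(samples), np.inf)
        elif config.censor_rate >= 1:
            c = rng.uniform(1e-6, 1e-3, len(samples))  # before any event
        else:
            u = _uniform_censor_bound(config.baseline_hazard, config.censor_rate)
            c = rng.uniform(0.0, u, len(samples))
        time = np.minimum(t_event, c)
        event = (t_event <= c).astype(int)
        return np.maximum(time, 1e-6), event

    os_t, os_e = endpoint()
    dfs_t, dfs_e = endpoint()
    table = pd.DataFrame({
        "os_time_months": os_t,
        "os_event": os_e,
        "dfs_time_months": dfs_t,
        "dfs_event": dfs_e,
        "batch": [truth.batch_assignments[s] for s in samples],
    }, index=pd.Index(samples, name="sample_id"))
    return table


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with var = mean + dispersion * mean^2 (Poisson limit)."""
    mean = np.maximum(mean, 1e-12)
    if dispersion < 1e-8:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    return rng.negative_binomial(size, size / (size + mean))


def render_count_platform(latent: pd.DataFrame, config: SimulationConfig):
    """Render the latent layer as raw nCounter-style counts with controls.

    Endogenous counts are negative binomial with mean
    ``count_scale * 2^z`` times a per-sample efficiency; a fraction
    ``frac_low_quality`` of samples (recorded in the ground truth) gets
    efficiency ``low_quality_efficiency``, low enough to fail both QC
    thresholds.  Positive controls follow a fixed spike-in ladder,
    negative controls a low constant background, and housekeeping genes
    low-variance latent rows.  Returns ``(counts, ControlSet)``.
    """
    if not np.all(np.isfinite(latent.to_numpy())):
        raise DataError("latent matrix must be finite")
    rng = config.rng("counts")
    _, truth = simulate_latent_expression(config)  # reproduce low-quality assignment
    n = latent.shape[1]
    efficiency = rng.lognormal(0.0, 0.15, n)
    lq_mask = np.array([s in truth.low_quality_samples for s in latent.columns])
    efficiency[lq_mask] = config.low_quality_efficiency

    endo_mean = config.count_scale * np.power(2.0, latent.to_numpy()) * efficiency
    counts = _nb_draw(rng, endo_mean, config.count_dispersion)
    frames = [pd.DataFrame(counts, index=latent.index, columns=latent.columns)]

    pos_ids = _ids("POS_", config.n_pos_controls, width=1)
    if config.n_pos_controls:
        ladder = np.array([POSITIVE_LADDER[i % len(POSITIVE_LADDER)]
                           for i in range(config.n_pos_controls)])
        pos_mean = config.count_scale * 32.0 * ladder[:, None] * efficiency[None, :]
        frames.append(pd.DataFrame(_nb_draw(rng, pos_mean, config.count_dispersion),
                                   index=pos_ids, columns=latent.columns))
    neg_ids = _ids("NEG_", config.n_neg_controls, width=1)
    if config.n_neg_controls:
        neg_mean = np.full((config.n_neg_controls, n), config.neg_control_mean)
        frames.append(pd.DataFrame(_nb_draw(rng, neg_mean, config.count_dispersion),
                                   index=neg_ids, columns=latent.columns))
    hk_ids = _ids("HK_", config.n_housekeeping, width=1)
    if config.n_housekeeping:
        hk_mu = rng.normal(config.mean_log2 + 1.0, 0.3, config.n_housekeeping)
        hk_z = hk_mu[:, None] + rng.normal(0.0, 0.05, (config.n_housekeeping, n))
        hk_mean = config.count_scale * np.power(2.0, hk_z) * efficiency
        frames.append(pd.DataFrame(_nb_draw(rng, hk_mean, config.count_dispersion),
                                   index=hk_ids, columns=latent.columns))

    out = pd.concat(frames).astype(int)
    controls = ControlSet(positive=frozenset(pos_ids), negative=frozenset(neg_ids),
                          housekeeping=frozenset(hk_ids))
    return out, controls


def render_array_platform(latent: pd.DataFrame, config: SimulationConfig):
    """Render the latent layer as probe-level array intensities.

    Each gene emits ``n_probes_per_gene`` probe rows
    z + affinity + noise, with probe j's noise sd scaled by (1 + j) so
    sibling probes differ in variability; ``n_multigene_probes``
    additional probes are mapped to two genes each to exercise the
    multi-gene drop rule.  Returns ``(probes, probe_map)`` where
    ``probe_map`` maps probe id -> tuple of gene ids.
    """
    if config.n_probes_per_gene < 1:
        raise ConfigurationError("n_probes_per_gene must be >= 1")
    rng = config.rng("array")
    genes = list(latent.index)
    n_genes, n = latent.shape
    z = latent.to_numpy()

    rows, ids, probe_map = [], [], {}
    for j in range(config.n_probes_per_gene):
        affinity = rng.normal(0.0, config.probe_affinity_sd, n_genes)
        noise = rng.normal(0.0, config.array_noise_sd * (1 + j), (n_genes, n))
        rows.append(z + affinity[:, None] + noise)
        for g in genes:
            pid = f"{g}_ps{j + 1}"
            ids.append(pid)
            probe_map[pid] = (g,)
    probes = np.vstack(rows)

    if config.n_multigene_probes:
        extra = []
        for k in range(config.n_multigene_probes):
            g1, g2 = rng.choice(n_genes, size=2, replace=False)
            pid = f"MULTI_ps{k + 1}"
            ids.append(pid)
            probe_map[pid] = (genes[g1], genes[g2])
            extra.append(0.5 * (z[g1] + z[g2]) +
                         rng.normal(0.0, config.array_noise_sd, n))
        probes = np.vstack([probes, np.array(extra)])

    return pd.DataFrame(probes, index=ids, columns=latent.columns), probe_map


def make_signature(truth: GroundTruth, n_true: int, n_noise: int, seed: int,
                   name: str = "synthetic-signature"):
    """Build a signature of known prognostic and noise genes.

    ``n_true`` genes are drawn from the prognostic set with their true
    directions; ``n_noise`` non-prognostic genes get random directions.
    Deterministic given ``seed``.
    """
    from .signatures import SignatureDefinition

    prog = sorted(truth.prognostic_gene_ids)
    if n_true > len(prog):
        raise ConfigurationError(
            f"n_true={n_true} exceeds the {len(prog)} prognostic genes available")
    other = sorted(set(truth.gene_ids) - truth.prognostic_gene_ids)
    if n_noise > len(other):
        raise ConfigurationError(
            f"n_noise={n_noise} exceeds the {len(other)} non-prognostic genes available")
    rng = np.random.default_rng(seed)
    chosen_true = list(rng.choice(prog, size=n_true, replace=False)) if n_true else []
    chosen_noise = list(rng.choice(other, size=n_noise, replace=False)) if n_noise else []
    direction = {g: truth.true_direction[g] for g in chosen_true}
    direction.update({g: ("up" if rng.random() < 0.5 else "down") for g in chosen_noise})
    return SignatureDefinition(
        name=name,
        genes=tuple(chosen_true + chosen_noise),
        direction=direction,
        source="synthetic ground truth",
    )


@dataclass
class SimulatedCohort:
    """Everything one simulation run produces."""

    config: SimulationConfig
    latent: pd.DataFrame
    truth: GroundTruth
    counts: pd.DataFrame
    controls: ControlSet
    probes: pd.DataFrame
    probe_map: dict
    clinical: pd.DataFrame


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Run the full generator: latent layer, both platforms, survival."""
    latent, truth = simulate_latent_expression(config)
    clinical = simulate_survival(latent, truth, config)
    counts, controls = render_count_platform(latent, config)
    probes, probe_map = render_array_platform(latent, config)
    return SimulatedCohort(config=config, latent=latent, truth=truth,
                           counts=counts, controls=controls,
                           probes=probes, probe_map=probe_map, clinical=clinical)
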