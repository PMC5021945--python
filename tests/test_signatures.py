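"""Tests for multi-gene signature scoring, splitting and evaluation."""

import numpy as np
import pandas as pd
import pytest

from ffpesig import (SignatureDefinition, SimulationConfig, evaluate_signature,
                     filter_discordant_genes, km_estimate, logrank_two_group,
                     make_signature, median_split, risk_group_overlap, risk_score,
                     simulate_latent_expression, simulate_survival)
from ffpesig.core import DataError
from ffpesig.signatures import RiskGrouping

from conftest import clinical_frame, make_survival


def screen_frame(entries):
    """entries: {gene: (log_hr, degenerate)}"""
    return pd.DataFrame(
        {"log_hr": [v[0] for v in entries.values()],
         "degenerate": [v[1] for v in entries.values()]},
        index=list(entries))


class TestFilterDiscordant:
    SIG = SignatureDefinition(
        name="toy", genes=("up_ok", "up_bad", "down_ok", "down_bad", "nodir", "absent"),
        direction={"up_ok": "up", "up_bad": "up", "down_ok": "down", "down_bad": "down"})

    def test_rule_table(self):
        screen = screen_frame({
            "up_ok": (0.8, False), "up_bad": (-0.3, False),
            "down_ok": (-0.5, False), "down_bad": (0.2, False),
            "nodir": (0.1, False),
        })
        out = filter_discordant_genes(self.SIG, screen)
        assert set(out.genes) == {"up_ok", "down_ok", "nodir"}
        assert out.undirected_genes == ("nodir",)

    def test_degenerate_genes_dropped(self):
        screen = screen_frame({g: (0.5 if "up" in g else -0.5, g == "up_ok")
                               for g in self.SIG.genes})
        out = filter_discordant_genes(self.SIG, screen)
        assert "up_ok" not in out.genes and "up_bad" in out.genes

    def test_empty_result_is_explicit_error(self):
        sig = SignatureDefinition(name="t", genes=("a",), direction={"a": "up"})
        with pytest.raises(DataError, match="unfiltered"):
            filter_discordant_genes(sig, screen_frame({"a": (-1.0, False)}))

    def test_never_grows_the_gene_list(self, rng):
        for _ in range(20):
            lhrs = {g: (rng.normal(), False) for g in self.SIG.genes}
            try:
                out = filter_discordant_genes(self.SIG, screen_frame(lhrs))
            except DataError:
                continue
            assert len(out.genes) <= len(self.SIG.genes)
            assert set(out.genes) <= set(self.SIG.genes)


class TestRiskScore:
    def test_hand_computed_two_gene_score(self):
        mat = pd.DataFrame({"s1": [1.0, 4.0], "s2": [2.0, 6.0], "s3": [3.0, 8.0]},
                           index=["g1", "g2"])
        sig = SignatureDefinition(name="t", genes=("g1", "g2"),
                                  direction={"g1": "up", "g2": "up"})
        np.testing.assert_allclose(risk_score(mat, sig), [-1.5, 0.0, 1.5])

    def test_single_gene_score_is_centered_flipped_row(self):
        mat = pd.DataFrame({"s1": [5.0], "s2": [1.0], "s3": [3.0]}, index=["g"])
        sig = SignatureDefinition(name="t", genes=("g",), direction={"g": "down"})
        np.testing.assert_allclose(risk_score(mat, sig), [-2.0, 2.0, 0.0])
        np.testing.assert_allclose(
            risk_score(mat, sig, flip_down_genes=False), [2.0, -2.0, 0.0])

    def test_invariant_to_constant_and_per_gene_shifts(self, rng):
        mat = pd.DataFrame(rng.normal(size=(4, 6)), index=list("abcd"))
        sig = SignatureDefinition(name="t", genes=("a", "c"),
                                  direction={"a": "up", "c": "down"})
        base = risk_score(mat, sig)
        np.testing.assert_allclose(risk_score(mat + 11.0, sig), base, atol=1e-12)
        shifted = mat.copy()
        shifted.loc["a"] += 3.7
        np.testing.assert_allclose(risk_score(shifted, sig), base, atol=1e-12)

    def test_no_gene_present_rejected(self, rng):
        mat = pd.DataFrame(rng.normal(size=(2, 3)), index=["x", "y"])
        sig = SignatureDefinition(name="t", genes=("z",))
        with pytest.raises(DataError, match="no signature gene"):
            risk_score(mat, sig)


class TestMedianSplit:
    def test_even_cohort_with_distinct_scores_splits_in_half(self, rng):
        scores = pd.Series(rng.normal(size=42), index=[f"S{i}" for i in range(42)])
        grouping = median_split(scores)
        assert grouping.n_high == 21 and grouping.n_low == 21

    def test_median_sample_goes_low(self):
        grouping = median_split(pd.Series({"a": -1.5, "b": 0.0, "c": 1.5}))
        assert grouping.group["b"] == "low" and grouping.group["c"] == "high"

    def test_threshold_ties_rebalanced_deterministically(self):
        grouping = median_split(pd.Series({"a": 1.0, "b": 2.0, "c": 2.0, "d": 3.0}))
        assert grouping.n_high == 2 and grouping.n_low == 2
        assert grouping.group["c"] == "high" and grouping.group["b"] == "low"

    def test_order_invariance(self, rng):
        scores = pd.Series(rng.normal(size=15), index=[f"S{i}" for i in range(15)])
        a = median_split(scores).group
        b = median_split(scores.sample(frac=1.0, random_state=3)).group
        pd.testing.assert_series_equal(a.sort_index(), b.sort_index())

    def test_group_sizes_never_differ_by_more_than_one(self, rng):
        for _ in range(25):
            n = int(rng.integers(2, 30))
            scores = pd.Series(rng.integers(0, 4, n).astype(float),
                               index=[f"S{i}" for i in range(n)])
            if scores.nunique() == 1:
                continue
            g = median_split(scores)
            assert abs(g.n_high - g.n_low) <= 1

    def test_identical_scores_rejected(self):
        with pytest.raises(DataError, match="identical"):
            median_split(pd.Series([2.0, 2.0, 2.0]))


class TestEvaluateSignature:
    def test_single_gene_unfiltered_matches_direct_computation(self, rng):
        n = 40
        x, t, e = make_survival(n, seed=5, beta=0.8)
        mat = pd.DataFrame([x], index=["g"], columns=[f"S{i:03d}" for i in range(n)])
        table = clinical_frame(t, e)
        sig = SignatureDefinition(name="t", genes=("g",), direction={"g": "up"})
        ev = evaluate_signature(mat, sig, table, filtered=False)
        # direct: median-split the centered row and run the log-rank by hand
        grouping = median_split(pd.Series(x - np.median(x), index=mat.columns))
        chi, p = logrank_two_group((grouping.group == "high").astype(int).to_numpy(),
                                   np.minimum(t, 60.0), e * (t <= 60.0))
        assert ev.endpoints["OS"].chi_square == pytest.approx(chi, abs=1e-12)
        assert ev.endpoints["OS"].p_value == pytest.approx(p, abs=1e-12)

    def test_filtering_reports_dropped_genes(self):
        cfg = SimulationConfig(n_samples=200, n_genes=60, n_prognostic=10,
                               batch_shift_sd=0.0, seed=31)
        latent, truth = simulate_latent_expression(cfg)
        table = simulate_survival(latent, truth, cfg)
        sig = make_signature(truth, n_true=8, n_noise=0, seed=1)
        # invert half the annotations: the inverted genes contradict the
        # fitted hazards and drop, the concordant half stays
        flipped = dict(sig.direction)
        for g in sig.genes[:4]:
            flipped[g] = "down" if flipped[g] == "up" else "up"
        half_bad = SignatureDefinition(name="hb", genes=sig.genes, direction=flipped)
        ev = evaluate_signature(latent, half_bad, table, filtered=True)
        assert len(ev.genes_dropped) >= 3
        assert set(ev.genes_used) | set(ev.genes_dropped) == set(sig.genes)
        # fully inverted annotations leave nothing and must error clearly
        inverted = SignatureDefinition(
            name="inv", genes=sig.genes,
            direction={g: ("down" if d == "up" else "up")
                       for g, d in sig.direction.items()})
        with pytest.raises(DataError, match="unfiltered"):
            evaluate_signature(latent, inverted, table, filtered=True)

    def test_concordant_strong_signature_keeps_all_genes(self):
        cfg = SimulationConfig(n_samples=400, n_genes=60, n_prognostic=10,
                               batch_shift_sd=0.0, seed=32)
        latent, truth = simulate_latent_expression(cfg)
        table = simulate_survival(latent, truth, cfg)
        sig = make_signature(truth, n_true=8, n_noise=0, seed=2)
        ev = evaluate_signature(latent, sig, table, filtered=True)
        assert ev.genes_dropped == ()

    def test_filtered_beats_unfiltered_on_half_inverted_signature(self):
        # invert half the direction annotations: filtering should purge the
        # inverted genes and give a lower log-rank p on average
        wins = 0
        reps = 20
        for seed in range(reps):
            cfg = SimulationConfig(n_samples=150, n_genes=40, n_prognostic=10,
                                   batch_shift_sd=0.0, seed=100 + seed)
            latent, truth = simulate_latent_expression(cfg)
            table = simulate_survival(latent, truth, cfg)
            sig = make_signature(truth, n_true=10, n_noise=0, seed=seed)
            flipped = dict(sig.direction)
            for g in sig.genes[:5]:
                flipped[g] = "down" if flipped[g] == "up" else "up"
            half_bad = SignatureDefinition(name="hb", genes=sig.genes, direction=flipped)
            pf = evaluate_signature(latent, half_bad, table, filtered=True
                                    ).endpoints["DFS"].p_value
            pu = evaluate_signature(latent, half_bad, table, filtered=False
                                    ).endpoints["DFS"].p_value
            wins += pf < pu
        assert wins > reps / 2


class TestRiskGroupOverlap:
    def _grouping(self, labels):
        idx = [f"S{i}" for i in range(len(labels))]
        return RiskGrouping(scores=pd.Series(0.0, index=idx),
                            group=pd.Series(labels, index=idx), threshold=0.0)

    def test_identity_and_swap(self):
        a = self._grouping(["high", "low", "high", "low"])
        b = self._grouping(["low", "high", "low", "high"])
        assert risk_group_overlap(a, a) == 1.0
        assert risk_group_overlap(a, b) == 0.0

    def test_independent_balanced_groupings_overlap_half(self, rng):
        n, reps = 42, 500
        overlaps = []
        for _ in range(reps):
            la = rng.permutation(["high"] * 21 + ["low"] * 21)
            lb = rng.permutation(["high"] * 21 + ["low"] * 21)
            overlaps.append(risk_group_overlap(self._grouping(la), self._grouping(lb)))
        assert np.mean(overlaps) == pytest.approx(0.5, abs=0.02)

    def test_universe_mismatch_rejected(self):
        a = self._grouping(["high", "low"])
        b = RiskGrouping(scores=pd.Series(0.0, index=["X", "Y"]),
                         group=pd.Series(["high", "low"], index=["X", "Y"]),
                         threshold=0.0)
        with pytest.raises(DataError):
            risk_group_overlap(a, b)


class TestNullSignatureCalibration:
    def test_noise_signature_logrank_p_uniform_over_replicates(self):
        # a signature of non-prognostic genes is independent of survival,
        # so its evaluation p-values are U(0,1) across replicates
        from scipy import stats
        pvals = []
        for seed in range(200):
            cfg = SimulationConfig(n_samples=60, n_genes=25, n_prognostic=5,
                                   batch_shift_sd=0.0, seed=2000 + seed)
            latent, truth = simulate_latent_expression(cfg)
            table = simulate_survival(latent, truth, cfg)
            sig = make_signature(truth, n_true=0, n_noise=8, seed=seed)
            ev = evaluate_signature(latent, sig, table, filtered=False)
            pvals.append(ev.endpoints["DFS"].p_value)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01
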