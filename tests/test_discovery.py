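"""Differential-methylation engine and selection funnel.

Every statistical component is checked against an independent oracle:
per-probe OLS against hand-solved normal equations, the empirical-Bayes
hyperparameters against a bisection solver of the moment equations (and
against limma run through Rscript), BH against a hand step-up computation,
and the funnel stages against traced fixtures.
"""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import brentq
from scipy.special import digamma, polygamma

from episig import (PipelineConfig, SimConfig, bh_adjust, call_dmps,
                    probe_auc, prune_correlated, rank_candidates, roc_select,
                    simulate_cohort, simulate_manifest)
from episig.discovery import (DiscoveryError, derive_episignature,
                              estimate_prior, fit_linear_models, moderate,
                              trigamma_inverse)
from episig.preprocess import MValueMatrix


def mmat(values, samples=None):
    values = np.atleast_2d(np.asarray(values, float))
    return MValueMatrix(pd.DataFrame(
        values, index=[f"cg{i}" for i in range(values.shape[0])],
        columns=samples or [f"s{j}" for j in range(values.shape[1])]))


class TestLinearModels:
    def test_coefficient_is_group_mean_difference_without_covariates(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=(20, 10))
        labels = np.array([True] * 4 + [False] * 6)
        fit = fit_linear_models(mmat(y), labels)
        expected = y[:, :4].mean(axis=1) - y[:, 4:].mean(axis=1)
        assert np.allclose(fit["coef"], expected, atol=1e-12)
        assert fit["df_resid"].iloc[0] == 8  # n - 2

    def test_matches_normal_equations_oracle_with_covariate(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=(3, 8))
        labels = np.array([True] * 4 + [False] * 4)
        cov = pd.DataFrame({"cell": rng.normal(size=8)},
                           index=[f"s{j}" for j in range(8)])
        fit = fit_linear_models(mmat(y), labels, cov)
        x = np.column_stack([np.ones(8), labels.astype(float), cov["cell"]])
        for g in range(3):
            # Independent oracle: solve X'X b = X'y directly.
            beta_hat = np.linalg.solve(x.T @ x, x.T @ y[g])
            resid = y[g] - x @ beta_hat
            s2 = resid @ resid / (8 - 3)
            assert fit["coef"].iloc[g] == pytest.approx(beta_hat[1], abs=1e-10)
            assert fit["sigma2"].iloc[g] == pytest.approx(s2, abs=1e-10)

    def test_collinear_covariate_reported(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=(5, 8))
        labels = np.array([True] * 4 + [False] * 4)
        cov = pd.DataFrame({"dup": labels.astype(float)},
                           index=[f"s{j}" for j in range(8)])
        with pytest.raises(DiscoveryError, match="collinear.*dup"):
            fit_linear_models(mmat(y), labels, cov)


class TestModeration:
    def make_fit(self, s2, coef=None, df=10.0, unscaled=0.5):
        n = len(s2)
        return pd.DataFrame({
            "coef": coef if coef is not None else np.ones(n),
            "sigma2": s2,
            "df_resid": df,
            "stdev_unscaled": unscaled,
        }, index=[f"cg{i}" for i in range(n)])

    def test_equal_variances_give_no_shrinkage_of_the_statistic(self):
        fit = self.make_fit(np.full(50, 0.3))
        params, tests = moderate(fit)
        # All sample variances equal: the posterior variance equals the
        # common variance and t matches the ordinary t numerically.
        assert np.allclose(params.s_post_sq, 0.3, rtol=1e-10)
        ordinary = fit["coef"] / (np.sqrt(fit["sigma2"]) * fit["stdev_unscaled"])
        assert np.allclose(tests["t_mod"], ordinary, rtol=1e-10)

    def test_d0_zero_override_recovers_ordinary_t(self):
        rng = np.random.default_rng(3)
        fit = self.make_fit(rng.uniform(0.1, 2.0, 40),
                            coef=rng.normal(size=40))
        _, tests = moderate(fit, d0_override=0)
        from scipy import stats as sps
        ordinary = fit["coef"] / (np.sqrt(fit["sigma2"]) * fit["stdev_unscaled"])
        assert np.allclose(tests["t_mod"], ordinary, rtol=1e-12)
        assert np.allclose(tests["p_value"],
                           2 * sps.t.sf(np.abs(ordinary), 10), rtol=1e-12)

    def test_hyperparameters_match_independent_moment_solver(self):
        # 50-probe fixture drawn from the scaled-F model with known truth.
        rng = np.random.default_rng(4)
        d0_true, s0_true, df = 6.0, 0.25, 12.0
        sigma_g2 = d0_true * s0_true / rng.chisquare(d0_true, 50)
        s2 = sigma_g2 * rng.chisquare(df, 50) / df
        d0, s0 = estimate_prior(s2, df)

        # Independent oracle: solve the same moment equations by bisection.
        e = np.log(s2) - digamma(df / 2) + np.log(df / 2)
        evar = e.var(ddof=1) - polygamma(1, df / 2)
        assert evar > 0
        half_d0 = brentq(lambda x: polygamma(1, x) - evar, 1e-6, 1e8,
                         xtol=1e-12)
        d0_oracle = 2 * half_d0
        s0_oracle = np.exp(e.mean() + digamma(half_d0) - np.log(half_d0))
        assert d0 == pytest.approx(d0_oracle, abs=1e-6)
        assert s0 == pytest.approx(s0_oracle, abs=1e-6)
        # And the estimate is in the neighbourhood of the generating truth.
        assert 2.0 < d0 < 20.0

    def test_trigamma_inverse_is_inverse(self):
        for y in (1e-5, 0.01, 0.3, 2.0, 50.0):
            x = trigamma_inverse(y)
            assert polygamma(1, x) == pytest.approx(y, rel=1e-7)

    def test_infinite_d0_uses_pooled_prior_variance(self):
        rng = np.random.default_rng(5)
        fit = self.make_fit(rng.uniform(0.1, 2.0, 40))
        params, tests = moderate(fit, d0_override=np.inf)
        assert np.isinf(params.d0)
        assert np.allclose(params.s_post_sq, params.s0_sq)

    def test_all_zero_variances_error(self):
        fit = self.make_fit(np.zeros(20))
        with pytest.raises(DiscoveryError, match="zero"):
            moderate(fit)

    def test_agrees_with_limma_through_rscript(self, tmp_path):
        """Dual-route check: the moderated t machinery against limma."""
        rng = np.random.default_rng(6)
        n_probes, n = 60, 12
        labels = np.array([1] * 6 + [0] * 6, dtype=float)
        cov = rng.normal(size=n)
        y = rng.normal(size=(n_probes, n)) * \
            rng.uniform(0.5, 2.0, size=(n_probes, 1))
        y[:10, :6] += 1.5
        np.savetxt(tmp_path / "m.tsv", y, delimiter="\t")
        np.savetxt(tmp_path / "design.tsv",
                   np.column_stack([np.ones(n), labels, cov]), delimiter="\t")
        script = textwrap.dedent("""
            suppressMessages(library(limma))
            m <- as.matrix(read.table("m.tsv", sep="\\t"))
            design <- as.matrix(read.table("design.tsv", sep="\\t"))
            fit <- eBayes(lmFit(m, design))
            out <- cbind(fit$t[, 2], fit$p.value[, 2])
            write.table(out, "limma_out.tsv", sep="\\t",
                        row.names=FALSE, col.names=FALSE)
            writeLines(c(as.character(fit$df.prior),
                         as.character(fit$s2.prior)), "limma_prior.txt")
        """)
        (tmp_path / "run.R").write_text(script)
        subprocess.run(["Rscript", "run.R"], cwd=tmp_path, check=True,
                       capture_output=True)
        limma = np.loadtxt(tmp_path / "limma_out.tsv", delimiter="\t")
        prior = (tmp_path / "limma_prior.txt").read_text().split()

        fit = fit_linear_models(
            mmat(y), labels.astype(bool),
            pd.DataFrame({"cov": cov}, index=[f"s{j}" for j in range(n)]))
        params, tests = moderate(fit)
        assert np.allclose(tests["t_mod"], limma[:, 0], rtol=1e-6)
        assert np.allclose(tests["p_value"], limma[:, 1], rtol=1e-6)
        assert params.d0 == pytest.approx(float(prior[0]), rel=1e-4)
        assert params.s0_sq == pytest.approx(float(prior[1]), rel=1e-4)


class TestBH:
    def test_hand_computed_step_up(self):
        q = bh_adjust([0.01, 0.02, 0.03])
        assert np.allclose(q, [0.03, 0.03, 0.03])

    def test_equal_and_singleton_inputs_unchanged(self):
        assert np.allclose(bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])
        assert np.allclose(bh_adjust([0.07]), [0.07])

    @given(st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=2,
                    max_size=30))
    def test_permutation_equivariance_and_monotonicity(self, ps):
        p = np.array(ps)
        q = bh_adjust(p)
        assert np.all(q >= p - 1e-15)
        assert q.max() <= 1.0
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(p))
        assert np.allclose(bh_adjust(p[perm]), q[perm])
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)


class TestCallDmps:
    def stats_of(self, delta, q):
        n = len(delta)
        return pd.DataFrame({"delta_beta": delta, "q_value": q,
                             "p_value": q}, index=[f"cg{i}" for i in range(n)])

    def test_thresholds_are_strict(self):
        stats = self.stats_of([0.10, 0.101, 0.2], [0.001, 0.01, 0.009])
        # delta exactly 0.10 excluded; q exactly 0.01 excluded.
        assert call_dmps(stats) == ["cg2"]

    def test_hypomethylated_probes_pass_on_absolute_effect(self):
        stats = self.stats_of([-0.15], [0.001])
        assert call_dmps(stats) == ["cg0"]


class TestRankCandidates:
    def test_product_score_ordering(self):
        stats = pd.DataFrame({
            "delta_beta": [0.2, 0.1], "p_value": [1e-4, 1e-6],
        }, index=["A", "B"])
        # A: 0.2*4 = 0.8 beats B: 0.1*6 = 0.6.
        assert rank_candidates(stats, 2) == ["A", "B"]

    def test_zero_effect_ranks_last_and_ties_break_by_p(self):
        stats = pd.DataFrame({
            "delta_beta": [0.0, 0.1, 0.2], "p_value": [1e-9, 1e-8, 1e-4],
        }, index=["Z", "X", "Y"])
        assert rank_candidates(stats, 3) == ["X", "Y", "Z"]
        tie = pd.DataFrame({
            "delta_beta": [0.2, 0.1], "p_value": [1e-2, 1e-4],
        }, index=["A", "B"])
        # Equal scores (0.2*2 == 0.1*4): smaller p first.
        assert rank_candidates(tie, 2) == ["B", "A"]

    def test_oversized_request_returns_all_with_warning(self):
        stats = pd.DataFrame({"delta_beta": [0.1], "p_value": [0.01]},
                             index=["A"])
        with pytest.warns(UserWarning):
            assert rank_candidates(stats, 10) == ["A"]


class TestRocSelect:
    def test_perfect_separation_and_known_auc(self):
        b = pd.DataFrame(
            [[0.9, 0.8, 0.1, 0.2],     # perfect
             [0.8, 0.6, 0.7, 0.5]],    # 3 of 4 concordant pairs
            index=["P", "Q"], columns=list("abcd"))
        labels = [True, True, False, False]
        auc = probe_auc(b, labels)
        assert auc["P"] == 1.0
        assert auc["Q"] == 0.75

    def test_all_tied_values_give_half(self):
        b = pd.DataFrame([[0.5] * 6], index=["P"], columns=list("abcdef"))
        assert probe_auc(b, [True, True, True, False, False, False])["P"] == 0.5

    @given(st.lists(st.integers(min_value=0, max_value=1000), min_size=6,
                    max_size=12))
    def test_auc_invariant_under_monotone_transform(self, vals):
        v = np.array(vals) / 1000.0
        labels = np.arange(len(v)) % 2 == 0
        b1 = pd.DataFrame([v], index=["P"])
        b2 = pd.DataFrame([np.exp(3 * v)], index=["P"])  # strictly monotone
        assert probe_auc(b1, labels)["P"] == \
            pytest.approx(probe_auc(b2, labels)["P"], abs=1e-12)

    def test_hypo_and_hyper_compete_symmetrically(self):
        b = pd.DataFrame(
            [[0.1, 0.2, 0.8, 0.9],      # AUC 0 (hypo, perfect separation)
             [0.6, 0.42, 0.4, 0.45]],   # AUC 0.75
            index=["hypo", "weak"], columns=list("abcd"))
        labels = [True, True, False, False]
        assert roc_select(b, labels, ["weak", "hypo"], 1) == ["hypo"]


class TestPruneCorrelated:
    def test_duplicate_probe_removed(self):
        rng = np.random.default_rng(11)
        v = rng.random(20)
        b = pd.DataFrame([v, v, rng.random(20)], index=["A", "B", "C"])
        assert prune_correlated(b, ["A", "B", "C"], 0.9) == ["A", "C"]

    def test_independent_probes_kept(self):
        rng = np.random.default_rng(12)
        b = pd.DataFrame(rng.random((2, 50)), index=["A", "B"])
        assert prune_correlated(b, ["A", "B"], 0.9) == ["A", "B"]

    def test_chain_keeps_first_and_third(self):
        # A~B and B~C above the threshold, A~C below it (positive
        # semi-definiteness forces r_AC >= 2 r^2 - 1, so ~0.86 here):
        # the greedy scan prunes B and keeps {A, C}.
        rng = np.random.default_rng(13)
        n = 5000
        b_common = rng.normal(size=n)
        r = 0.93
        a = r * b_common + np.sqrt(1 - r * r) * rng.normal(size=n)
        c = r * b_common + np.sqrt(1 - r * r) * rng.normal(size=n)
        frame = pd.DataFrame([a, b_common, c], index=["A", "B", "C"])
        corr = np.corrcoef(frame)
        assert abs(corr[0, 1]) > 0.9 and abs(corr[1, 2]) > 0.9
        assert abs(corr[0, 2]) < 0.9
        assert prune_correlated(frame, ["A", "B", "C"], 0.9) == ["A", "C"]

    def test_constant_probe_kept_with_warning(self):
        b = pd.DataFrame([[0.5] * 10, np.linspace(0, 1, 10)],
                         index=["const", "B"])
        with pytest.warns(UserWarning, match="constant"):
            kept = prune_correlated(b, ["const", "B"], 0.9)
        assert kept == ["const", "B"]


class TestDerivedSignature:
    def test_null_cohorts_yield_empty_dmp_sets(self):
        # Control-only generation: the discovery stage should find nothing
        # at FDR < 0.01 in nearly all seeds.
        empty = 0
        n_seeds = 20
        for seed in range(n_seeds):
            cfg = SimConfig(n_probes=2000, n_controls=120, n_signal_probes=0,
                            n_other_disorders=0, seed=1000 + seed)
            man = simulate_manifest(cfg)
            beta, sheet, _ = simulate_cohort(cfg, man)
            res = derive_episignature(beta, sheet, man,
                                      PipelineConfig(seed=seed))
            if res.funnel["n_dmps"] == 0:
                empty += 1
        assert empty >= int(0.95 * n_seeds)

    def test_high_snr_recovery_and_directionality(self):
        cfg = SimConfig(n_probes=4000, n_controls=120, n_signal_probes=100,
                        delta_beta_range=(0.25, 0.30), noise_sd=0.10,
                        failure_rate=0.0, n_other_disorders=0, seed=21)
        man = simulate_manifest(cfg)
        beta, sheet, truth = simulate_cohort(cfg, man)
        res = derive_episignature(beta, sheet, man, PipelineConfig(seed=21))
        dmps = set(call_dmps(res.stats))
        planted = set(truth.signal_probe_ids)
        assert dmps == planted  # all recovered, none false at this SNR
        sel = res.stats[res.stats["selected"]]
        assert len(sel) > 0
        assert (sel["delta_beta"] > 0).mean() > 0.96
        assert set(sel.index) <= planted

    def test_same_seed_reproduces_identical_probe_list(self, study_cohort):
        cfg, man, beta, sheet, _ = study_cohort
        a = derive_episignature(beta, sheet, man, PipelineConfig(seed=5))
        b = derive_episignature(beta, sheet, man, PipelineConfig(seed=5))
        assert a.model.probe_ids == b.model.probe_ids
        pd.testing.assert_frame_equal(a.stats, b.stats)
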