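"""Differential methylation and the episignature selection funnel.

The statistical core: per-probe linear models of M-values on case status
plus covariates, empirical-Bayes variance moderation (the per-probe residual
variance is shrunk toward a prior estimated across all probes by method of
moments on the log variances), Benjamini-Hochberg FDR control, and the
three-stage probe-selection funnel — rank by |delta beta| x (-log10 p),
keep the top probes by ROC area, then greedily remove probes whose pairwise
Pearson correlation with an already-kept probe exceeds the threshold.

Effect sizes (delta beta) are reported on the beta scale, where the "10%
methylation difference" threshold is meaningful, while test statistics are
computed on the variance-stabilised M scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import digamma, polygamma
from statsmodels.stats.multitest import multipletests

from .config import PipelineConfig
from .io import BetaMatrix, ProbeAnnotation, SampleSheet
from .model import EpisignatureModel
from .preprocess import (MatchedCohort, MValueMatrix, beta_to_m,
                         drop_failed_probes, estimate_cell_proportions,
                         filter_arrays, filter_probes, match_controls)


class DiscoveryError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Per-probe linear models


def fit_linear_models(m: MValueMatrix, is_case: Sequence[bool],
                      covariates: pd.DataFrame | None = None) -> pd.DataFrame:
    """Ordinary least squares of each probe's M-values on case status.

    The design matrix is [intercept, case indicator, covariates...]. Returns
    a per-probe frame with the case coefficient, residual variance
    ``sigma2``, residual degrees of freedom and the unscaled standard error
    of the coefficient (sqrt of the corresponding diagonal of (X'X)^-1).
    """
    y = m.values.to_numpy(dtype=float)          # probes x samples
    labels = np.asarray(is_case, dtype=bool)
    n = y.shape[1]
    if labels.shape != (n,):
        raise DiscoveryError("labels length must match sample count")
    if labels.sum() < 2 or (~labels).sum() < 2:
        raise DiscoveryError("need at least 2 samples per group")
    cols = [np.ones(n), labels.astype(float)]
    names = ["intercept", "case"]
    if covariates is not None:
        cov = covariates.loc[list(m.sample_ids)]
        for c in cov.columns:
            cols.append(cov[c].to_numpy(dtype=float))
            names.append(str(c))
    x = np.column_stack(cols)
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # Identify offending columns by rank growth.
        bad = []
        kept: list[int] = []
        for j in range(x.shape[1]):
            if np.linalg.matrix_rank(x[:, kept + [j]]) == len(kept):
                bad.append(names[j])
            else:
                kept.append(j)
        raise DiscoveryError(f"collinear design columns: {bad}")
    xtx_inv = np.linalg.inv(x.T @ x)
    pinv = xtx_inv @ x.T
    coefs = y @ pinv.T                          # probes x params
    resid = y - coefs @ x.T
    df_resid = n - x.shape[1]
    sigma2 = (resid ** 2).sum(axis=1) / df_resid
    return pd.DataFrame({
        "coef": coefs[:, 1],
        "sigma2": sigma2,
        "df_resid": float(df_resid),
        "stdev_unscaled": float(np.sqrt(xtx_inv[1, 1])),
    }, index=m.values.index)


# ---------------------------------------------------------------------------
# Empirical-Bayes moderation


@dataclass
class ModerationParams:
    """Hyperparameters and posterior variances of the moderation step.

    ``d0`` is the prior degrees of freedom (``inf`` when the moment
    estimator finds no excess variability in the log sample variances) and
    ``s0_sq`` the prior variance. The posterior variance per probe is
    ``(d0 * s0_sq + d_g * s_g_sq) / (d0 + d_g)``.
    """

    d0: float
    s0_sq: float
    s_post_sq: np.ndarray = field(repr=False)


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (monotone, convex)."""
    if y <= 0:
        raise ValueError("trigamma_inverse needs y > 0")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(polygamma(2, x))
        x += dif
        if -dif / x < 1e-8:
            break
    return x


def estimate_prior(sigma2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of the scaled-F prior on sample variances.

    Works on ``e = log(s^2) - digamma(df/2) + log(df/2)``; the excess of
    var(e) over trigamma(df/2) determines the prior degrees of freedom, and
    the mean of ``e`` the prior variance. Returns ``(d0, s0_sq)`` with
    ``d0 = inf`` when the excess is non-positive.
    """
    s2 = np.asarray(sigma2, dtype=float)
    if len(s2) < 10:
        raise DiscoveryError("need >= 10 probes to estimate the prior")
    if np.all(s2 <= 0):
        raise DiscoveryError("all residual variances are zero")
    z = np.log(np.maximum(s2, 1e-300))
    if np.ptp(z) == 0:
        # Degenerate case: all sample variances identical. The chi-square
        # sampling model is evidently absent, so the prior is the common
        # variance itself (no log-scale unbiasing correction).
        return np.inf, float(s2[0])
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s0_sq = float(np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_sq = float(np.exp(emean))
    return d0, s0_sq


def moderate(fit: pd.DataFrame,
             d0_override: float | None = None) -> tuple[ModerationParams,
                                                        pd.DataFrame]:
    """Moderated t-statistics with empirical-Bayes variance shrinkage.

    ``fit`` is the output of :func:`fit_linear_models`. With
    ``d0_override=0`` the ordinary t-test is recovered; with
    ``d0_override=inf`` every probe is tested against the common prior
    variance. Two-sided p-values use ``d0 + d_g`` degrees of freedom
    (normal tail when infinite).
    """
    s2 = fit["sigma2"].to_numpy(dtype=float)
    df = float(fit["df_resid"].iloc[0])
    if d0_override is not None:
        d0 = float(d0_override)
        _, s0_sq = estimate_prior(s2, df) if d0 != 0 else (None, float("nan"))
    else:
        d0, s0_sq = estimate_prior(s2, df)
    if d0 == 0:
        s_post = s2.copy()
    elif np.isinf(d0):
        if np.isnan(s0_sq):
            _, s0_sq = estimate_prior(s2, df)
        s_post = np.full_like(s2, s0_sq)
    else:
        s_post = (d0 * s0_sq + df * s2) / (d0 + df)
    se = np.sqrt(s_post) * fit["stdev_unscaled"].to_numpy(dtype=float)
    t = fit["coef"].to_numpy(dtype=float) / se
    df_total = d0 + df
    if np.isinf(df_total):
        p = 2.0 * sps.norm.sf(np.abs(t))
    else:
        p = 2.0 * sps.t.sf(np.abs(t), df_total)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    out = pd.DataFrame({"t_mod": t, "p_value": p}, index=fit.index)
    return ModerationParams(d0=d0, s0_sq=s0_sq, s_post_sq=s_post), out


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, clipped at 1."""
    p = np.asarray(p, dtype=float)
    if len(p) == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise DiscoveryError("p-values must be in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Funnel stages


def call_dmps(stats: pd.DataFrame, fdr_max: float = 0.01,
              delta_min: float = 0.10) -> list[str]:
    """Probes with |delta beta| strictly above ``delta_min`` and BH q
    strictly below ``fdr_max`` ("> 10%" and "< 0.01" read literally)."""
    mask = (stats["delta_beta"].abs() > delta_min) & (stats["q_value"] < fdr_max)
    return list(stats.index[mask])


def rank_candidates(stats: pd.DataFrame, n: int = 1000) -> list[str]:
    """Top ``n`` probes by the effect-size x significance product
    ``|delta beta| * (-log10 p)``; ties broken by smaller p, then probe id."""
    score = stats["delta_beta"].abs() * (-np.log10(stats["p_value"]))
    order = np.lexsort((stats.index.to_numpy(),
                        stats["p_value"].to_numpy(), -score.to_numpy()))
    ranked = list(stats.index[order])
    if n > len(ranked):
        warnings.warn(f"requested {n} candidates but only {len(ranked)} probes")
        return ranked
    return ranked[:n]


def probe_auc(beta: pd.DataFrame, is_case: Sequence[bool]) -> pd.Series:
    """Per-probe ROC area of beta as a case score (rank-sum identity,
    midrank tie handling). AUC is invariant to monotone transforms."""
    labels = np.asarray(is_case, dtype=bool)
    n1 = int(labels.sum())
    n0 = int((~labels).sum())
    if n1 == 0 or n0 == 0:
        raise DiscoveryError("both classes must be present for ROC analysis")
    ranks = sps.rankdata(beta.to_numpy(dtype=float), axis=1)
    rank_sum = ranks[:, labels].sum(axis=1)
    auc = (rank_sum - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    return pd.Series(auc, index=beta.index)


def roc_select(beta: pd.DataFrame, is_case: Sequence[bool],
               candidates: Sequence[str], n: int = 500) -> list[str]:
    """Keep the ``n`` candidates with the largest ``max(auc, 1 - auc)``.

    Hypo- and hypermethylated probes compete symmetrically. Ties preserve
    the incoming candidate order (i.e. the ranking-product order).
    """
    candidates = list(candidates)
    if not candidates:
        return []
    auc = probe_auc(beta.loc[candidates], is_case)
    separation = np.maximum(auc.to_numpy(), 1.0 - auc.to_numpy())
    order = np.argsort(-separation, kind="stable")
    return [candidates[i] for i in order[:min(n, len(candidates))]]


def prune_correlated(beta: pd.DataFrame, ranked_probes: Sequence[str],
                     r_max: float = 0.9) -> list[str]:
    """Greedy scan in rank order: keep a probe iff its Pearson |r| with
    every already-kept probe is <= ``r_max`` (computed across all samples).

    Constant probes (undefined r) are kept with a warning.
    """
    kept: list[str] = []
    kept_z: list[np.ndarray] = []
    n = beta.shape[1]
    for pid in ranked_probes:
        v = beta.loc[pid].to_numpy(dtype=float)
        sd = v.std()
        if sd == 0:
            warnings.warn(f"probe {pid} is constant; correlation undefined, kept")
            kept.append(pid)
            continue
        z = (v - v.mean()) / (sd * np.sqrt(n))
        if kept_z:
            r = np.abs(np.vstack(kept_z) @ z)
            if np.any(r > r_max):
                continue
        kept.append(pid)
        kept_z.append(z)
    return kept


# ---------------------------------------------------------------------------
# End-to-end derivation


@dataclass
class DiscoveryResult:
    model: EpisignatureModel
    stats: pd.DataFrame
    matched: MatchedCohort
    funnel: dict[str, Any]
    moderation: ModerationParams


def derive_episignature(beta: BetaMatrix, sheet: SampleSheet,
                        ann: ProbeAnnotation, config: PipelineConfig,
                        cell_reference: pd.DataFrame | None = None,
                        case_ids: Sequence[str] | None = None
                        ) -> DiscoveryResult:
    """Run the full discovery pipeline and return the trained signature.

    Stages: probe QC filter -> array failure filter -> 7:1 matched-control
    selection -> M-value transform -> per-probe linear models with
    cell-proportion covariates -> empirical-Bayes moderated t -> BH FDR ->
    (optional DMP effect/FDR prefilter) -> rank-by-product -> ROC selection
    -> correlation pruning. Per-probe case/control medians are stored for
    downstream concordance scoring. Deterministic given inputs and seed.

    ``case_ids`` restricts the case set (used by leave-one-out validation);
    by default all ``case`` samples in the sheet are used.
    """
    beta_f, removed = filter_probes(beta, ann)
    dropped_arrays: list[str] = []
    if beta_f.detection_failure is not None:
        beta_f, dropped_arrays = filter_arrays(beta_f, config.failure_rate_max)

    surviving = set(beta_f.sample_ids)
    all_cases = [s for s in sheet.ids_of("case") if s in surviving]
    if case_ids is not None:
        all_cases = [s for s in case_ids if s in surviving]
    pool_ids = [s for s in sheet.ids_of("control") if s in surviving]
    if len(all_cases) < 2:
        raise DiscoveryError("need at least 2 case samples")
    matched = match_controls(sheet.rows_for(all_cases),
                             sheet.rows_for(pool_ids),
                             ratio=config.control_ratio, seed=config.seed)
    analysis_samples = matched.case_ids + matched.control_ids
    analysis = drop_failed_probes(beta_f.subset(samples=analysis_samples))

    m = beta_to_m(analysis, config.epsilon)
    is_case = np.array([s in set(matched.case_ids) for s in analysis.sample_ids])

    covariates = None
    props = sheet.cell_proportions()
    if props is not None:
        props = props.loc[analysis.sample_ids]
    elif cell_reference is not None:
        props = estimate_cell_proportions(analysis, cell_reference)
    if props is not None and props.shape[1] >= 2:
        # Proportions sum to one; drop the last column to keep the design
        # full rank alongside the intercept.
        covariates = props.iloc[:, :-1]

    fit = fit_linear_models(m, is_case, covariates)
    moderation, tests = moderate(fit)
    q = bh_adjust(tests["p_value"].to_numpy())

    vals = analysis.values.to_numpy(dtype=float)
    delta_beta = vals[:, is_case].mean(axis=1) - vals[:, ~is_case].mean(axis=1)

    stats = pd.DataFrame({
        "delta_beta": delta_beta,
        "t_mod": tests["t_mod"],
        "p_value": tests["p_value"],
        "q_value": q,
    }, index=analysis.values.index)
    rank_p = stats["q_value"] if config.rank_uses_adjusted_p else stats["p_value"]
    stats["rank_score"] = stats["delta_beta"].abs() * (-np.log10(rank_p))

    universe = stats
    n_dmps = None
    if config.dmp_prefilter:
        dmps = call_dmps(stats, config.fdr_max, config.delta_beta_min)
        n_dmps = len(dmps)
        universe = stats.loc[dmps]

    rank_input = universe.copy()
    if config.rank_uses_adjusted_p:
        rank_input = rank_input.assign(p_value=rank_input["q_value"])
    # After the prefilter the universe is often smaller than the candidate
    # budget; that is expected, not worth a warning here.
    candidates = rank_candidates(
        rank_input, min(config.n_candidates, len(universe))) \
        if len(universe) else []
    stats["auc"] = np.nan
    if candidates:
        stats.loc[candidates, "auc"] = probe_auc(
            analysis.values.loc[candidates], is_case)
        shortlist = roc_select(analysis.values, is_case, candidates,
                               config.n_roc)
        final = prune_correlated(analysis.values, shortlist, config.r_max)
    else:
        shortlist, final = [], []
    stats["selected"] = stats.index.isin(final)

    sub = analysis.values.loc[final] if final else analysis.values.iloc[:0]
    case_median = sub.loc[:, is_case].median(axis=1).to_numpy() \
        if final else np.empty(0)
    control_median = sub.loc[:, ~is_case].median(axis=1).to_numpy() \
        if final else np.empty(0)

    model = EpisignatureModel(
        probe_ids=list(final),
        case_median=case_median,
        control_median=control_median,
        thresholds={
            "fdr_max": config.fdr_max,
            "delta_beta_min": config.delta_beta_min,
            "n_candidates": config.n_candidates,
            "n_roc": config.n_roc,
            "r_max": config.r_max,
            "control_ratio": config.control_ratio,
            "dmp_prefilter": config.dmp_prefilter,
        },
        seed=config.seed,
    )
    funnel = {
        "probes_removed_by_flag": removed,
        "arrays_dropped": dropped_arrays,
        "n_analyzed_probes": int(stats.shape[0]),
        "n_dmps": n_dmps,
        "n_candidates": len(candidates),
        "n_roc": len(shortlist),
        "n_final": len(final),
        "candidate_ids": list(candidates),
        "roc_ids": list(shortlist),
    }
    return DiscoveryResult(model=model, stats=stats, matched=matched,
                           funnel=funnel, moderation=moderation)
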