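"""Quality filtering, matched-control selection, M-values, cell proportions.

This is the stage between a normalized beta matrix and differential
analysis: drop flagged probes (sex chromosomes, cross-reactive, SNP
overlap), drop arrays with more than the allowed detection-failure rate,
select sex-matched / age-nearest controls at a fixed ratio per case,
variance-stabilise betas to M-values, and estimate blood cell-type
proportions by constrained projection onto reference profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .config import PROBE_FLAGS
from .io import BetaMatrix, ProbeAnnotation, SampleSheet


class PreprocessError(ValueError):
    pass


@dataclass
class MValueMatrix:
    """Probes x samples matrix of M-values (log2 beta ratios)."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values.to_numpy())):
            raise PreprocessError("M-values must be finite")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class MatchedCohort:
    """Result of ratio-matched control selection."""

    case_ids: list[str]
    control_ids: list[str]
    match_table: dict[str, list[str]]


def filter_probes(beta: BetaMatrix, ann: ProbeAnnotation
                  ) -> tuple[BetaMatrix, dict[str, int]]:
    """Remove probes flagged sex_chromosome / cross_reactive / snp_overlap.

    Returns the filtered matrix and the count removed per flag (a probe
    carrying several flags counts once per flag).
    """
    t = ann.indexed()
    missing = [p for p in beta.probe_ids if p not in t.index]
    if missing:
        raise PreprocessError(
            f"{len(missing)} matrix probe(s) missing from manifest, "
            f"first: {missing[0]!r}")
    flags = t.loc[beta.probe_ids, "flags"]
    flag_sets = flags.str.split(";").apply(lambda fs: {f for f in fs if f})
    removed = {f: int(flag_sets.apply(lambda s, f=f: f in s).sum())
               for f in PROBE_FLAGS}
    keep = [p for p, s in zip(beta.probe_ids, flag_sets) if not s]
    if not keep:
        raise PreprocessError("no probes survive filtering")
    if len(keep) == len(beta.probe_ids):
        return beta, removed
    return beta.subset(probes=keep), removed


def filter_arrays(beta: BetaMatrix, max_failure: float = 0.05
                  ) -> tuple[BetaMatrix, list[str]]:
    """Drop samples whose detection-failure fraction strictly exceeds
    ``max_failure`` ("more than 5%" read literally: exactly 5% is kept)."""
    if beta.detection_failure is None:
        raise PreprocessError("detection_failure matrix required")
    rates = beta.detection_failure.mean(axis=0)
    dropped = [s for s in beta.sample_ids if rates[s] > max_failure]
    keep = [s for s in beta.sample_ids if rates[s] <= max_failure]
    if not keep:
        raise PreprocessError("all samples exceed the failure-rate threshold")
    if not dropped:
        return beta, []
    return beta.subset(samples=keep), dropped


def match_controls(cases: SampleSheet, pool: SampleSheet, ratio: int = 7,
                   seed: int | None = None) -> MatchedCohort:
    """Select ``ratio`` controls per case, matching sex exactly and age by
    nearest neighbour, sampling without replacement.

    Cases are processed in lexicographic sample-id order; age ties are
    broken by lexicographic control id. The procedure is fully
    deterministic and invariant to pool row order — ``seed`` is accepted for
    interface symmetry with the stochastic stages but is unused.
    """
    case_ids = sorted(cases.sample_ids)
    pool_t = pool.table.set_index("sample_id")
    overlap = set(case_ids) & set(pool_t.index)
    if overlap:
        raise PreprocessError(f"pool overlaps cases: {sorted(overlap)[:3]}")
    available = pool_t.copy()
    case_t = cases.table.set_index("sample_id")
    match_table: dict[str, list[str]] = {}
    for cid in case_ids:
        sex = case_t.loc[cid, "sex"]
        age = float(case_t.loc[cid, "age"])
        candidates = available[available["sex"] == sex]
        if len(candidates) < ratio:
            raise PreprocessError(
                f"insufficient same-sex controls for case {cid!r}: "
                f"need {ratio}, have {len(candidates)}")
        ranked = candidates.assign(_dist=(candidates["age"] - age).abs())
        ranked = ranked.iloc[np.lexsort((ranked.index.to_numpy(),
                                         ranked["_dist"].to_numpy()))]
        take = list(ranked.index[:ratio])
        match_table[cid] = take
        available = available.drop(index=take)
    control_ids = [c for cid in case_ids for c in match_table[cid]]
    return MatchedCohort(case_ids=case_ids, control_ids=control_ids,
                         match_table=match_table)


def beta_to_m(beta: BetaMatrix, epsilon: float = 1e-6) -> MValueMatrix:
    """M = log2(b / (1 - b)) with b clipped into [epsilon, 1 - epsilon]."""
    b = np.clip(beta.values.to_numpy(dtype=float), epsilon, 1.0 - epsilon)
    m = np.log2(b / (1.0 - b))
    return MValueMatrix(pd.DataFrame(m, index=beta.values.index,
                                     columns=beta.values.columns))


def m_to_beta(m: MValueMatrix) -> BetaMatrix:
    """Inverse of :func:`beta_to_m` (exact on the open clipped interval)."""
    x = 2.0 ** m.values.to_numpy(dtype=float)
    return BetaMatrix(pd.DataFrame(x / (1.0 + x), index=m.values.index,
                                   columns=m.values.columns))


def estimate_cell_proportions(beta: BetaMatrix,
                              reference: pd.DataFrame) -> pd.DataFrame:
    """Per-sample cell-type proportions by non-negative least squares.

    ``reference`` is a cell type x probe frame of mean beta profiles; at
    least 50 of its probes must be present in the matrix. Each sample's
    betas at the shared probes are projected onto the reference profiles
    under non-negativity and the solution is renormalised to sum to 1.
    """
    shared = [p for p in reference.columns if p in set(beta.probe_ids)]
    if len(shared) < 50:
        raise PreprocessError(
            f"reference covers only {len(shared)} matrix probes (need >= 50)")
    a = reference[shared].to_numpy(dtype=float).T      # probes x cell types
    if np.linalg.matrix_rank(a) < a.shape[1]:
        raise PreprocessError("rank-deficient cell reference")
    sub = beta.values.loc[shared]
    out = np.empty((sub.shape[1], a.shape[1]))
    for j, s in enumerate(sub.columns):
        coef, _ = nnls(a, sub[s].to_numpy(dtype=float))
        total = coef.sum()
        out[j] = coef / total if total > 0 else np.full(a.shape[1],
                                                        1.0 / a.shape[1])
    return pd.DataFrame(out, index=list(sub.columns),
                        columns=list(reference.index))


def pca_qc(m: MValueMatrix, n_components: int = 2
           ) -> tuple[pd.DataFrame, list[str]]:
    """Advisory sample QC projection.

    Projects samples onto the top principal components of the sample-wise
    covariance of M-values and flags samples whose distance from the
    centroid in that subspace exceeds 3 standard deviations of the
    distances. No sample is excluded automatically.
    """
    x = m.values.to_numpy(dtype=float).T            # samples x probes
    if x.shape[0] < 3:
        raise PreprocessError("need at least 3 samples for the QC projection")
    centered = x - x.mean(axis=0, keepdims=True)
    if np.allclose(centered, 0):
        raise PreprocessError("constant matrix: no variance to project")
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    k = min(n_components, len(s))
    coords = u[:, :k] * s[:k]
    dist = np.linalg.norm(coords, axis=1)
    sd = dist.std(ddof=1) if len(dist) > 1 else 0.0
    flagged = [sid for sid, d in zip(m.sample_ids, dist)
               if sd > 0 and (d - dist.mean()) > 3 * sd]
    frame = pd.DataFrame(coords, index=m.sample_ids,
                         columns=[f"PC{i + 1}" for i in range(k)])
    return frame, flagged


def drop_failed_probes(beta: BetaMatrix) -> BetaMatrix:
    """Drop probes with any flagged detection failure across samples.

    The pipeline drops rather than imputes: a probe whose value failed in
    any retained sample is removed before differential analysis.
    """
    if beta.detection_failure is None:
        return beta
    keep = beta.detection_failure.sum(axis=1) == 0
    kept = [p for p, k in zip(beta.probe_ids, keep) if k]
    if not kept:
        raise PreprocessError("no probes without detection failures")
    out = beta.subset(probes=kept)
    return BetaMatrix(out.values, None)
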