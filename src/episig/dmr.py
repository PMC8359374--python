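"""Differentially methylated region calling with p-value combination.

Probe-level statistics are aggregated into regions by a transparent
seed-and-extend rule: maximal runs of consecutive probes on one chromosome
with inter-probe gaps of at most 1 kb form candidate regions; a candidate
is reported when it contains at least five CpGs, its unweighted mean beta
difference reaches 10%, and its BH-adjusted Fisher-combined p-value falls
below 0.01. Stouffer's combination is reported alongside Fisher's for each
region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import IntervalSet, ProbeAnnotation
from .simulate import SimulationTruth


class DMRError(ValueError):
    pass


@dataclass
class DMR:
    """A called region: >= 5 CpGs within 1 kb gaps, |mean delta beta| >= 10%."""

    chrom: str
    start: int          # 0-based, inclusive
    end: int            # 0-based, exclusive
    n_cpgs: int
    mean_delta_beta: float
    direction: str      # "hyper" | "hypo"
    fisher_p: float
    fisher_q: float
    stouffer_p: float
    member_probe_ids: list[str]


def fisher_combine(p: np.ndarray | list[float]) -> float:
    """Fisher's method: X = -2 sum(ln p) ~ chi-square with 2k df under the
    null; a p of exactly 1 contributes nothing to X."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise DMRError("cannot combine an empty p-value vector")
    if np.any((p <= 0) | (p > 1)):
        raise DMRError("p-values must be in (0, 1]")
    x = -2.0 * np.log(p).sum()
    return float(sps.chi2.sf(x, 2 * p.size))


def stouffer_combine(p: np.ndarray | list[float],
                     weights: np.ndarray | None = None) -> float:
    """Stouffer's method: Z = sum(w_i z_i) / sqrt(sum w_i^2) with
    z_i = Phi^-1(1 - p_i); one-sided recombination 1 - Phi(Z)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise DMRError("cannot combine an empty p-value vector")
    if np.any((p <= 0) | (p >= 1)):
        raise DMRError("Stouffer combination needs p strictly in (0, 1)")
    z = sps.norm.isf(p)
    w = np.ones_like(p) if weights is None else np.asarray(weights, float)
    if w.shape != p.shape:
        raise DMRError("weights must match p-values")
    big_z = (w * z).sum() / np.sqrt((w ** 2).sum())
    return float(sps.norm.sf(big_z))


def find_dmrs(stats: pd.DataFrame, ann: ProbeAnnotation, min_cpgs: int = 5,
              max_gap: int = 1000, delta_min: float = 0.10,
              p_max: float = 0.01) -> list[DMR]:
    """Seed-and-extend DMR calling over probe-level statistics.

    ``stats`` must be indexed by probe id with ``delta_beta`` and
    ``p_value`` columns (the discovery stage's per-probe table). Candidate
    runs are maximal gap-limited probe chains per chromosome with at least
    ``min_cpgs`` members; Fisher-combined run p-values are BH-adjusted
    across all candidates, and a run is reported iff its adjusted p is
    strictly below ``p_max`` and |mean delta beta| >= ``delta_min``.
    """
    from .discovery import bh_adjust

    ann_idx = ann.indexed()
    missing = [p for p in stats.index if p not in ann_idx.index]
    if missing:
        raise DMRError(f"{len(missing)} probe(s) lack annotation, "
                       f"first: {missing[0]!r}")
    merged = stats.join(ann_idx[["chrom", "position"]])

    candidates: list[dict] = []
    for chrom, grp in merged.groupby("chrom", sort=True):
        if not grp["position"].is_monotonic_increasing:
            warnings.warn(f"annotation not position-sorted on {chrom}; sorting")
        g = grp.sort_values("position")
        gaps = g["position"].diff().fillna(0)
        run_id = (gaps > max_gap).cumsum()
        for _, run in g.groupby(run_id):
            if len(run) < min_cpgs:
                continue
            candidates.append(dict(
                chrom=str(chrom),
                start=int(run["position"].min()),
                end=int(run["position"].max()) + 1,
                n_cpgs=len(run),
                mean_delta=float(run["delta_beta"].mean()),
                # Floor at the smallest normal float: the chi-square tail
                # underflows to 0 for very strong regions.
                fisher_p=max(fisher_combine(run["p_value"].to_numpy()),
                             np.finfo(float).tiny),
                stouffer_p=stouffer_combine(
                    np.clip(run["p_value"].to_numpy(), 1e-300, 1 - 1e-16)),
                members=list(run.index),
            ))
    if not candidates:
        return []
    qs = bh_adjust([c["fisher_p"] for c in candidates])
    out = []
    for c, q in zip(candidates, qs):
        if q < p_max and abs(c["mean_delta"]) >= delta_min:
            out.append(DMR(
                chrom=c["chrom"], start=c["start"], end=c["end"],
                n_cpgs=c["n_cpgs"], mean_delta_beta=c["mean_delta"],
                direction="hyper" if c["mean_delta"] > 0 else "hypo",
                fisher_p=c["fisher_p"], fisher_q=float(q),
                stouffer_p=c["stouffer_p"], member_probe_ids=c["members"]))
    return out


def dmrs_to_intervals(dmrs: list[DMR], name: str = "dmrs") -> IntervalSet:
    rows = [(d.chrom, d.start, d.end, d.direction) for d in dmrs]
    return IntervalSet(name, pd.DataFrame(
        rows, columns=["chrom", "start", "end", "label"]))


def write_dmr_bed(dmrs: list[DMR], path) -> None:
    """BED6+ output: chrom, start, end, name, -log10 fisher_p, strand '.',
    then n_cpgs, mean_delta_beta, stouffer_p."""
    with open(path, "w") as fh:
        for i, d in enumerate(dmrs, start=1):
            score = -np.log10(max(d.fisher_p, 1e-300))
            fh.write("\t".join([
                d.chrom, str(d.start), str(d.end), f"DMR_{i:04d}",
                f"{score:.4f}", ".", str(d.n_cpgs),
                f"{d.mean_delta_beta:.6f}", f"{d.stouffer_p:.6g}"]) + "\n")


def dmr_recovery_report(dmrs: list[DMR],
                        truth: SimulationTruth) -> dict[str, float]:
    """Sensitivity / precision / direction accuracy against planted regions.

    A planted region counts as recovered when any called DMR overlaps it by
    at least 1 bp; a called DMR counts as a true positive under the same
    rule. Direction accuracy is the share of truth-matched calls whose
    direction agrees with the sign of the planted effects in that region.
    """
    planted = truth.signal_regions.intervals
    n_planted = len(planted)
    n_called = len(dmrs)
    if n_called == 0:
        return dict(sensitivity=0.0, precision=float("nan"),
                    direction_accuracy=float("nan"),
                    n_called=0, n_planted=n_planted)
    delta = truth.signal_delta
    recovered = np.zeros(n_planted, dtype=bool)
    tp = 0
    dir_ok = 0
    dir_total = 0
    for d in dmrs:
        hit_any = False
        for i, row in planted.iterrows():
            if row["chrom"] == d.chrom and d.start < row["end"] \
                    and row["start"] < d.end:
                recovered[i] = True
                hit_any = True
        if hit_any:
            tp += 1
            member_signs = [np.sign(delta[p]) for p in d.member_probe_ids
                            if p in delta]
            if member_signs:
                dir_total += 1
                want = "hyper" if np.mean(member_signs) > 0 else "hypo"
                dir_ok += int(want == d.direction)
    return dict(
        sensitivity=float(recovered.mean()) if n_planted else float("nan"),
        precision=tp / n_called,
        direction_accuracy=(dir_ok / dir_total) if dir_total else float("nan"),
        n_called=n_called, n_planted=n_planted)
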