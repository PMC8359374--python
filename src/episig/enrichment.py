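"""Feature-category and interval-overlap enrichment.

Three analyses share a 2x2 Fisher-exact core: gene-region enrichment of
signature probes against the array background, DMR enrichment against
gene-region feature tracks using a strict ">50% of DMR length" overlap rule
with a length-matched random-placement null, and a GIGGLE-style combo score
(sign(ln OR) * |log2 OR| * (-log10 p)) for DMRs against chromatin-state
tracks across many reference epigenomes, compared state-to-state with
pairwise Wilcoxon rank-sum tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import CHROMATIN_STATES
from .io import IntervalSet, ProbeAnnotation


class EnrichmentError(ValueError):
    pass


@dataclass
class EnrichmentResult:
    """A 2x2-derived enrichment for one feature category or track."""

    feature: str
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p_two_tailed: float
    combo_score: float
    direction: str       # "enriched" | "depleted"


# ---------------------------------------------------------------------------
# 2x2 machinery


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Sample odds ratio and two-tailed Fisher exact p for [[a, b], [c, d]].

    The two-tailed p sums hypergeometric probabilities of all tables with
    the observed margins whose probability does not exceed the observed
    table's. OR is a*d / (b*c), with 0 and inf as sentinels.
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise EnrichmentError("table entries must be non-negative integers")
    if a + b + c + d == 0:
        raise EnrichmentError("all-zero table")
    _, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if b * c == 0:
        odds = 1.0 if a * d == 0 else float("inf")
    else:
        odds = (a * d) / (b * c)
    return float(odds), float(p)


def _combo(odds: float, p: float, table: tuple[int, int, int, int]) -> float:
    """Signed GIGGLE-style combo score.

    Zero cells make the raw OR 0 or infinite; the magnitude then uses the
    Haldane-corrected OR (0.5 added to each cell) while the sign keeps the
    raw direction. An OR of exactly 1 scores 0.
    """
    if odds == 1.0:
        return 0.0
    a, b, c, d = table
    if odds == 0.0 or np.isinf(odds):
        odds_h = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        sign = 1.0 if odds_h > 1 else -1.0
        mag_or = odds_h
    else:
        sign = 1.0 if odds > 1.0 else -1.0
        mag_or = odds
    neglogp = -np.log10(max(p, 1e-300))
    return float(sign * abs(np.log2(mag_or)) * neglogp)


# ---------------------------------------------------------------------------
# Interval helpers (0-based half-open throughout)


def _merged_arrays(ivals: IntervalSet) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, grp in ivals.intervals.groupby("chrom"):
        g = grp.sort_values("start")
        starts, ends = [], []
        for s, e in zip(g["start"], g["end"]):
            if ends and s <= ends[-1]:
                ends[-1] = max(ends[-1], e)
            else:
                starts.append(s)
                ends.append(e)
        out[chrom] = (np.asarray(starts), np.asarray(ends))
    return out


def _overlap_bp(chrom: str, start: int, end: int,
                merged: dict[str, tuple[np.ndarray, np.ndarray]]) -> int:
    if chrom not in merged:
        return 0
    starts, ends = merged[chrom]
    lo = np.searchsorted(ends, start, side="right")
    hi = np.searchsorted(starts, end, side="left")
    if hi <= lo:
        return 0
    s = np.maximum(starts[lo:hi], start)
    e = np.minimum(ends[lo:hi], end)
    return int((e - s).sum())


def count_overlapping(query: IntervalSet, reference: IntervalSet) -> int:
    """Number of query intervals overlapping the reference by >= 1 bp."""
    merged = _merged_arrays(reference)
    n = 0
    for row in query.intervals.itertuples(index=False):
        if _overlap_bp(row.chrom, row.start, row.end, merged) > 0:
            n += 1
    return n


# ---------------------------------------------------------------------------
# Signature probe gene-region enrichment


def probe_category_enrichment(signature_probes: list[str],
                              ann: ProbeAnnotation,
                              background_probes: list[str] | None = None
                              ) -> pd.DataFrame:
    """Fisher enrichment of signature probes per gene-region category.

    The background defaults to every probe in the manifest (pass the
    analyzed probe set to restrict it). For each category the 2x2 contrasts
    signature membership against the rest of the background. Significance
    tiers: '*' p < 0.01, '**' p < 1e-3, '***' p < 1e-6; BH-adjusted q
    across categories is reported alongside (the tiers are annotations on
    the raw p).
    """
    from .discovery import bh_adjust

    if not signature_probes:
        raise EnrichmentError("empty signature probe set")
    t = ann.indexed()
    bg = list(background_probes) if background_probes is not None \
        else list(t.index)
    missing = set(signature_probes) - set(bg)
    if missing:
        raise EnrichmentError(
            f"signature probes not in background: {sorted(missing)[:3]}")
    cat = t.loc[bg, "region_category"]
    sig = pd.Index(signature_probes)
    rows = []
    for category in sorted(cat.unique()):
        in_cat = set(cat.index[cat == category])
        a = len([p for p in sig if p in in_cat])
        b = len(sig) - a
        c = len(in_cat) - a
        d = len(bg) - len(sig) - c
        odds, p = fisher_exact_2x2(a, b, c, d)
        rows.append(dict(
            feature=category, a=a, b=b, c=c, d=d, odds_ratio=odds,
            p_two_tailed=p, combo_score=_combo(odds, p, (a, b, c, d)),
            direction="enriched" if odds >= 1 else "depleted",
            tier="***" if p < 1e-6 else "**" if p < 1e-3
            else "*" if p < 0.01 else ""))
    out = pd.DataFrame(rows)
    out["q_value"] = bh_adjust(out["p_two_tailed"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# DMR vs feature-track enrichment


def dmr_feature_enrichment(dmrs: IntervalSet,
                           features: dict[str, IntervalSet],
                           extents: dict[str, int],
                           min_overlap_fraction: float = 0.5,
                           n_random: int = 1000,
                           seed: int = 0) -> pd.DataFrame:
    """Per-category Fisher enrichment of DMRs against feature tracks.

    A DMR hits a category iff strictly more than ``min_overlap_fraction``
    of its length is covered by the category's intervals (50% exactly is
    not a hit). The background rate comes from ``n_random`` seeded,
    length-matched intervals placed uniformly over the genome extent.
    Tiers follow the region-level scale: '*' p < 0.05, '**' p < 0.01,
    '***' p < 0.001.
    """
    from .discovery import bh_adjust

    if len(dmrs) == 0:
        raise EnrichmentError("no DMRs supplied")
    for row in dmrs.intervals.itertuples(index=False):
        if row.chrom not in extents or row.end > extents[row.chrom]:
            raise EnrichmentError(
                f"DMR {row.chrom}:{row.start}-{row.end} outside genome extent")
    rng = np.random.default_rng(seed)
    chroms = sorted(extents)
    lengths = np.array([extents[c] for c in chroms], dtype=float)
    chrom_p = lengths / lengths.sum()
    dmr_lens = (dmrs.intervals["end"] - dmrs.intervals["start"]).to_numpy()

    # One shared null placement for every category.
    null_rows = []
    for i in range(n_random):
        ln = int(dmr_lens[i % len(dmr_lens)])
        chrom = chroms[int(rng.choice(len(chroms), p=chrom_p))]
        max_start = max(extents[chrom] - ln, 1)
        s = int(rng.integers(0, max_start))
        null_rows.append((chrom, s, s + ln))

    def hit_count(intervals, merged) -> int:
        n = 0
        for chrom, s, e in intervals:
            frac = _overlap_bp(chrom, s, e, merged) / (e - s)
            if frac > min_overlap_fraction:
                n += 1
        return n

    dmr_tuples = [(r.chrom, r.start, r.end)
                  for r in dmrs.intervals.itertuples(index=False)]
    rows = []
    for category in sorted(features):
        merged = _merged_arrays(features[category])
        a = hit_count(dmr_tuples, merged)
        b = len(dmr_tuples) - a
        c = hit_count(null_rows, merged)
        d = len(null_rows) - c
        odds, p = fisher_exact_2x2(a, b, c, d)
        rows.append(dict(
            feature=category, a=a, b=b, c=c, d=d, odds_ratio=odds,
            p_two_tailed=p, combo_score=_combo(odds, p, (a, b, c, d)),
            direction="enriched" if odds >= 1 else "depleted",
            tier="***" if p < 1e-3 else "**" if p < 0.01
            else "*" if p < 0.05 else ""))
    out = pd.DataFrame(rows)
    out["q_value"] = bh_adjust(out["p_two_tailed"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# GIGGLE-style interval enrichment


def giggle_score(query: IntervalSet, reference: IntervalSet,
                 genome_extent: int) -> EnrichmentResult:
    """Interval-overlap enrichment with the combo-score summary.

    The 2x2 is built from overlap counts: ``a`` = query intervals
    overlapping the reference (>= 1 bp), ``b`` = remaining query intervals,
    ``c`` = reference intervals not overlapped, and ``d`` fills the table
    up to the number of placeable interval slots, ``genome_extent`` divided
    by the mean interval length of both sets. The combo score is
    sign(ln OR) * |log2 OR| * (-log10 p).
    """
    if genome_extent <= 0:
        raise EnrichmentError("genome extent must be positive")
    if len(query) == 0 or len(reference) == 0:
        raise EnrichmentError("query and reference must be non-empty")
    a = count_overlapping(query, reference)
    b = len(query) - a
    lens = np.concatenate([
        (query.intervals["end"] - query.intervals["start"]).to_numpy(),
        (reference.intervals["end"] - reference.intervals["start"]).to_numpy()])
    mean_len = max(float(lens.mean()), 1.0)
    n_possible = max(int(genome_extent / mean_len), a + b + 1)
    c = max(len(reference) - a, 0)
    d = max(n_possible - a - b - c, 1)
    odds, p = fisher_exact_2x2(a, b, c, d)
    return EnrichmentResult(
        feature=reference.name, a=a, b=b, c=c, d=d, odds_ratio=odds,
        p_two_tailed=p, combo_score=_combo(odds, p, (a, b, c, d)),
        direction="enriched" if odds >= 1 else "depleted")


# ---------------------------------------------------------------------------
# Chromatin-state profile across epigenomes


def wilcoxon_rank_sum(x, y, exact_below: int = 50) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact enumeration (via the Mann-Whitney null distribution) when the
    combined sample is smaller than ``exact_below`` and tie-free; otherwise
    the normal approximation with midranks and tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise EnrichmentError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    if np.all(combined == combined[0]):
        return 1.0
    has_ties = len(np.unique(combined)) < combined.size
    method = "exact" if (combined.size < exact_below and not has_ties) \
        else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


def chromatin_state_profile(dmrs: IntervalSet,
                            epigenomes: list[IntervalSet],
                            genome_extent: int
                            ) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Combo-score distributions per chromatin state across epigenomes.

    Each epigenome contributes one combo score per state (0, flagged via
    NaN->0 substitution, when a state is absent from that epigenome). State
    score distributions are compared by pairwise two-sided Wilcoxon
    rank-sum tests with BH adjustment. Returns (scores, per-state medians,
    pairwise comparison table).
    """
    from .discovery import bh_adjust

    if len(epigenomes) < 2:
        raise EnrichmentError("need at least 2 epigenomes")
    rows = {}
    for epi in epigenomes:
        tracks = epi.by_label()
        scores = {}
        for state in CHROMATIN_STATES:
            if state not in tracks or len(tracks[state]) == 0:
                scores[state] = 0.0
            else:
                scores[state] = giggle_score(
                    dmrs, tracks[state], genome_extent).combo_score
        rows[epi.name] = scores
    score_df = pd.DataFrame.from_dict(rows, orient="index")[list(CHROMATIN_STATES)]
    medians = score_df.median(axis=0)

    pair_rows = []
    states = list(CHROMATIN_STATES)
    for i in range(len(states)):
        for j in range(i + 1, len(states)):
            p = wilcoxon_rank_sum(score_df[states[i]], score_df[states[j]])
            pair_rows.append(dict(state_a=states[i], state_b=states[j],
                                  p_value=p))
    pairwise = pd.DataFrame(pair_rows)
    pairwise["q_value"] = bh_adjust(pairwise["p_value"].to_numpy())
    return score_df, medians, pairwise
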