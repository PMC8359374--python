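"""Synthetic EPIC-like cohorts with known planted truth.

This module is the pipeline's test bed: it emulates the statistical
structure of normalized blood methylation arrays — bimodal per-probe
baselines (promoter-proximal probes near beta ~0.1, gene-body/intergenic
probes near ~0.85), blood cell-type composition confounding, age/sex
structure, logit-scale Gaussian noise — and plants a known case signature
(hypermethylating by default, concentrated at promoter CpG clusters) plus
confounder cohorts carrying disjoint signatures. Chromatin-state
segmentations over the 15-state vocabulary are generated so that Active-TSS
segments genuinely cover the promoter clusters where case signal is planted.

Everything is driven by a single seed: identical ``(config, seed)`` yield
bit-identical manifests, cohorts and epigenomes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .config import (CHROMATIN_STATES, PROBE_FLAGS, PROMOTER_CATEGORIES,
                     REGION_CATEGORIES, SimConfig)
from .io import BetaMatrix, IntervalSet, ProbeAnnotation, SampleSheet

_CELL_TYPE_NAMES = ("neutrophil", "cd4_t", "cd8_t", "b_cell", "monocyte", "nk_cell")

# Beta-value headroom: planted effects never push the target mean closer
# than this to 0 or 1, and baselines are clipped to the same band.
_BETA_FLOOR = 0.02
_BETA_CEIL = 0.98


class SimulationError(ValueError):
    pass


@dataclass
class SimulationTruth:
    """Ground truth behind a simulated cohort.

    ``signal_delta`` maps each planted probe to its realized signed
    beta-scale effect; ``signal_regions`` are the planted DMR intervals
    (0-based half-open); ``cell_reference`` is the cell type x probe
    mean-beta profile matrix; ``confounder_signatures`` maps each
    other-disorder pool name to its (disjoint) planted probe set.
    """

    signal_probe_ids: list[str]
    signal_delta: dict[str, float]
    signal_regions: IntervalSet
    cell_reference: pd.DataFrame
    per_sample_proportions: pd.DataFrame
    confounder_signatures: dict[str, list[str]] = field(default_factory=dict)
    vus_carriers: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps({
            "signal_probe_ids": self.signal_probe_ids,
            "signal_delta": self.signal_delta,
            "signal_regions": self.signal_regions.intervals.to_dict("records"),
            "cell_reference": {
                "index": list(self.cell_reference.index),
                "columns": list(self.cell_reference.columns),
                "values": self.cell_reference.to_numpy().tolist(),
            },
            "per_sample_proportions": {
                "index": list(self.per_sample_proportions.index),
                "columns": list(self.per_sample_proportions.columns),
                "values": self.per_sample_proportions.to_numpy().tolist(),
            },
            "confounder_signatures": self.confounder_signatures,
            "vus_carriers": self.vus_carriers,
        })

    @classmethod
    def from_json(cls, text: str) -> "SimulationTruth":
        d = json.loads(text)
        return cls(
            signal_probe_ids=d["signal_probe_ids"],
            signal_delta={k: float(v) for k, v in d["signal_delta"].items()},
            signal_regions=IntervalSet(
                "planted_regions", pd.DataFrame(
                    d["signal_regions"],
                    columns=["chrom", "start", "end", "label"])),
            cell_reference=pd.DataFrame(
                d["cell_reference"]["values"],
                index=d["cell_reference"]["index"],
                columns=d["cell_reference"]["columns"]),
            per_sample_proportions=pd.DataFrame(
                d["per_sample_proportions"]["values"],
                index=d["per_sample_proportions"]["index"],
                columns=d["per_sample_proportions"]["columns"]),
            confounder_signatures={k: list(v) for k, v
                                   in d["confounder_signatures"].items()},
            vus_carriers=list(d.get("vus_carriers", [])),
        )


# ---------------------------------------------------------------------------
# Manifest


def simulate_manifest(config: SimConfig) -> ProbeAnnotation:
    """Generate an EPIC-like probe manifest on synthetic chromosomes.

    Probes are laid out as a mixture of CpG-island-like clusters (5-12
    probes, 50-500 bp intra-cluster gaps) carrying promoter-proximal
    categories, and isolated probes (>2 kb apart) carrying Body/3'UTR/IGR
    categories. The number of clustered probes is fixed so that the marginal
    category frequencies match ``config.category_frequencies``; per-probe
    categories are then drawn independently from the conditional
    distributions, so empirical marginals are multinomial around the
    configured values. A ``flag_fraction`` share of probes receives one QC
    flag (sex_chromosome / cross_reactive / snp_overlap, uniformly).
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    freqs = config.category_frequencies
    prom = [c for c in REGION_CATEGORIES if c in PROMOTER_CATEGORIES]
    nonprom = [c for c in REGION_CATEGORIES if c not in PROMOTER_CATEGORIES]
    p_prom = sum(freqs[c] for c in prom)
    prom_probs = np.array([freqs[c] for c in prom]) / p_prom
    nonprom_probs = np.array([freqs[c] for c in nonprom]) / (1.0 - p_prom)

    n = config.n_probes
    n_clustered = int(round(p_prom * n))

    # Cluster sizes 5-12; last cluster absorbs the remainder.
    sizes: list[int] = []
    remaining = n_clustered
    while remaining > 0:
        s = int(rng.integers(5, 13))
        if remaining - s < 5:
            s = remaining
        sizes.append(s)
        remaining -= s

    # Events = clusters (as units) + isolated probes, shuffled, then laid
    # out across chromosomes in contiguous chunks.
    events: list[int] = [1] * (n - n_clustered) + sizes  # 1 == isolated
    order = rng.permutation(len(events))
    events = [events[i] for i in order]
    chunks = np.array_split(np.arange(len(events)), config.n_chromosomes)

    rows = []
    probe_counter = 0
    for ci, chunk in enumerate(chunks):
        chrom = f"chr{ci + 1}"
        pos = int(rng.integers(5_000, 15_000))
        for ev_idx in chunk:
            size = events[ev_idx]
            if size == 1:
                cats = [nonprom[i] for i in
                        rng.choice(len(nonprom), size=1, p=nonprom_probs)]
                positions = [pos]
            else:
                gaps = rng.integers(50, 501, size=size - 1)
                positions = [pos]
                for g in gaps:
                    positions.append(positions[-1] + int(g))
                cats = [prom[i] for i in
                        rng.choice(len(prom), size=size, p=prom_probs)]
            for p, c in zip(positions, cats):
                rows.append((f"cg{probe_counter:08d}", chrom, int(p), c))
                probe_counter += 1
            pos = positions[-1] + int(rng.integers(2_001, 20_001))

    table = pd.DataFrame(rows, columns=["probe_id", "chrom", "position",
                                        "region_category"])
    flagged = rng.random(n) < config.flag_fraction
    which = rng.integers(0, len(PROBE_FLAGS), size=n)
    table["flags"] = [PROBE_FLAGS[w] if f else "" for f, w in zip(flagged, which)]
    return ProbeAnnotation(table)


def probe_clusters(ann: ProbeAnnotation, max_gap: int = 1000,
                   min_size: int = 5) -> list[pd.DataFrame]:
    """Maximal runs of probes with inter-probe gaps <= ``max_gap`` bp.

    Returns one position-sorted frame (probe_id, chrom, position,
    region_category, flags) per run of at least ``min_size`` probes.
    """
    out = []
    for _, grp in ann.table.groupby("chrom", sort=True):
        g = grp.sort_values("position").reset_index(drop=True)
        gaps = g["position"].diff().fillna(0)
        run_id = (gaps > max_gap).cumsum()
        for _, run in g.groupby(run_id):
            if len(run) >= min_size:
                out.append(run.reset_index(drop=True))
    return out


def chromosome_extents(ann: ProbeAnnotation, margin: int = 10_000) -> dict[str, int]:
    """Per-chromosome length implied by the manifest (last probe + margin)."""
    return {chrom: int(grp["position"].max()) + margin
            for chrom, grp in ann.table.groupby("chrom")}


def category_intervals_from_manifest(ann: ProbeAnnotation,
                                     pad: int = 200) -> dict[str, IntervalSet]:
    """Merged +-``pad`` bp windows around probes, per gene-region category."""
    out = {}
    for cat, grp in ann.table.groupby("region_category"):
        rows = []
        for chrom, g in grp.groupby("chrom"):
            pos = np.sort(g["position"].to_numpy())
            start, end = None, None
            for p in pos:
                s, e = max(0, int(p) - pad), int(p) + pad + 1
                if start is None:
                    start, end = s, e
                elif s <= end:
                    end = max(end, e)
                else:
                    rows.append((chrom, start, end, cat))
                    start, end = s, e
            if start is not None:
                rows.append((chrom, start, end, cat))
        out[cat] = IntervalSet(cat, pd.DataFrame(
            rows, columns=["chrom", "start", "end", "label"]))
    return out


# ---------------------------------------------------------------------------
# Cohort


def _base_proportions(k: int) -> np.ndarray:
    if k <= len(_CELL_TYPE_NAMES):
        w = np.array([0.55, 0.25, 0.08, 0.05, 0.04, 0.03][:k])
    else:
        w = 0.5 ** np.arange(k)
    return w / w.sum()


def _cell_type_names(k: int) -> list[str]:
    if k <= len(_CELL_TYPE_NAMES):
        return list(_CELL_TYPE_NAMES[:k])
    return [f"cell_type_{i + 1}" for i in range(k)]


def _pick_signal(rng: np.ndarray, config: SimConfig, ann_t: pd.DataFrame,
                 baseline: np.ndarray, exclude: set[str]) -> tuple[
                     list[str], dict[str, float], list[tuple[str, int, int]]]:
    """Choose signal probes and realized deltas for one planted signature.

    Roughly ``fraction_signal_in_regions`` of the probes are whole promoter
    clusters (each becoming one planted region, all members sharing a
    direction); the remainder are scattered singles with promoter-category
    probes upweighted by ``promoter_bias``. Effects are feasibility-checked:
    a probe is only eligible for a direction if the target mean stays inside
    [0.02, 0.98] at the minimum effect size, and the drawn magnitude is
    truncated to the available headroom (never below the configured
    minimum).
    """
    lo, hi = config.delta_beta_range
    base = pd.Series(baseline, index=ann_t["probe_id"].to_numpy())
    unflagged = ann_t.loc[ann_t["flags"] == "", "probe_id"]
    eligible_ids = [p for p in unflagged if p not in exclude]
    eligible = set(eligible_ids)

    def headroom_ok(pid: str, sign: int) -> bool:
        b = base[pid]
        target = b + sign * lo
        return _BETA_FLOOR <= target <= _BETA_CEIL

    def realized(pid: str, sign: int, mag: float) -> float:
        b = base[pid]
        target = float(np.clip(b + sign * mag, _BETA_FLOOR, _BETA_CEIL))
        return target - b

    chosen: list[str] = []
    delta: dict[str, float] = {}
    regions: list[tuple[str, int, int]] = []

    n_target = config.n_signal_probes
    n_region_target = int(round(config.fraction_signal_in_regions * n_target))

    if n_region_target > 0:
        clusters = probe_clusters(
            ProbeAnnotation(ann_t), max_gap=1000, min_size=5)
        rng.shuffle(clusters)
        placed = 0
        for run in clusters:
            if placed >= n_region_target:
                break
            sign = 1 if rng.random() < config.fraction_hyper else -1
            members = [p for p in run["probe_id"]
                       if p in eligible and headroom_ok(p, sign)]
            if len(members) < 6:
                continue
            mags = rng.uniform(lo, hi, size=len(members))
            for pid, m in zip(members, mags):
                delta[pid] = realized(pid, sign, float(m))
                chosen.append(pid)
                eligible.discard(pid)
            sub = run[run["probe_id"].isin(members)]
            regions.append((str(run["chrom"].iloc[0]),
                            int(sub["position"].min()),
                            int(sub["position"].max()) + 1))
            placed += len(members)

    n_scatter = n_target - len(chosen)
    if n_scatter > 0:
        signs = np.where(rng.random(n_scatter) < config.fraction_hyper, 1, -1)
        mags = rng.uniform(lo, hi, size=n_scatter)
        pool = [p for p in eligible_ids if p in eligible]
        cat = ann_t.set_index("probe_id")["region_category"]
        weights = np.array([config.promoter_bias
                            if cat[p] in PROMOTER_CATEGORIES else 1.0
                            for p in pool])
        # Weighted random order (Efraimidis-Spirakis keys); walk it taking
        # the first feasible probe for each drawn (sign, magnitude) pair.
        keys = rng.random(len(pool)) ** (1.0 / weights)
        ranked = list(np.argsort(-keys))
        it = iter(ranked)
        for sign, mag in zip(signs, mags):
            placed_one = False
            for i in it:
                pid = pool[i]
                if pid in eligible and headroom_ok(pid, int(sign)):
                    delta[pid] = realized(pid, int(sign), float(mag))
                    chosen.append(pid)
                    eligible.discard(pid)
                    placed_one = True
                    break
            if not placed_one:
                raise SimulationError(
                    "requested signal probes exceed available (promoter) probes")
    return chosen, delta, regions


def simulate_cohort(config: SimConfig, manifest: ProbeAnnotation
                    ) -> tuple[BetaMatrix, SampleSheet, SimulationTruth]:
    """Generate beta values, a sample sheet, and the planted truth.

    Per-sample betas follow ``expit(logit(mixture baseline) + group effect +
    background shift + N(0, noise_sd))`` where the mixture baseline is the
    sample's cell-proportion-weighted average of cell-type reference
    profiles. Cases carry the planted case signature; each other-disorder
    pool carries its own signature on probes disjoint from the case's and
    from each other's; optional VUS samples either carry the case signature
    (the first half, recorded in ``truth.vus_carriers``) or no effect.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    ann_t = manifest.table
    n_probes = len(ann_t)
    probe_ids = ann_t["probe_id"].to_numpy()

    # Bimodal baselines: promoter probes are mostly unmethylated.
    is_prom = ann_t["region_category"].isin(PROMOTER_CATEGORIES).to_numpy()
    low_prob = np.where(is_prom, 0.85, 0.15)
    take_low = rng.random(n_probes) < low_prob
    baseline = np.where(take_low, rng.beta(5, 45, n_probes),
                        rng.beta(17, 3, n_probes))
    baseline = np.clip(baseline, _BETA_FLOOR, _BETA_CEIL)

    # Cell-type reference profiles: logit-scale offsets, larger on a
    # "cell-variable" probe subset; this is what makes covariate adjustment
    # in the discovery stage consequential.
    k = config.n_cell_types
    variable = rng.random(n_probes) < config.cell_variable_fraction
    offset_sd = np.where(variable, config.cell_variable_sd, config.cell_stable_sd)
    offsets = rng.normal(0.0, 1.0, size=(k, n_probes)) * offset_sd
    ref_beta = expit(logit(baseline)[None, :] + offsets)
    cell_names = _cell_type_names(k)
    cell_reference = pd.DataFrame(ref_beta, index=cell_names, columns=probe_ids)

    # Planted effects are anchored to the expected control-group mixture
    # beta (not the raw baseline): at cell-variable probes the two differ,
    # and the recorded delta must match what a case-vs-control mean
    # difference actually measures.
    mix0 = np.clip(_base_proportions(k) @ ref_beta, _BETA_FLOOR, _BETA_CEIL)

    # Planted signatures: case first, then disjoint confounder pools.
    exclude: set[str] = set()
    signal_ids, signal_delta, region_tuples = _pick_signal(
        rng, config, ann_t, mix0, exclude)
    exclude |= set(signal_ids)
    confounder_sigs: dict[str, list[str]] = {}
    for d in range(config.n_other_disorders):
        pool_name = f"disorder_{d + 1}"
        scatter_cfg = SimConfig(**{**config.__dict__,
                                   "fraction_signal_in_regions": 0.0})
        ids_d, delta_d, _ = _pick_signal(rng, scatter_cfg, ann_t, mix0, exclude)
        confounder_sigs[pool_name] = ids_d
        exclude |= set(ids_d)
        confounder_sigs[pool_name + "__delta"] = delta_d  # type: ignore[assignment]

    # Samples: cases, control pool (half F, half M so matching always has
    # headroom), confounder pools, optional VUS.
    samples: list[dict] = []
    for i in range(config.n_cases):
        samples.append(dict(sample_id=f"Case_{i + 1:02d}", group="case",
                            sex="F" if rng.random() < 0.5 else "M",
                            age=float(rng.integers(6, 31)), disorder=""))
    half = config.n_controls // 2
    for i in range(config.n_controls):
        samples.append(dict(sample_id=f"Control_{i + 1:03d}", group="control",
                            sex="F" if i < half else "M",
                            age=float(rng.integers(5, 41)), disorder=""))
    for d in range(config.n_other_disorders):
        for i in range(config.other_disorder_size):
            samples.append(dict(sample_id=f"Dis{d + 1}_{i + 1:02d}",
                                group="other_disorder",
                                sex="F" if rng.random() < 0.5 else "M",
                                age=float(rng.integers(5, 41)),
                                disorder=f"disorder_{d + 1}"))
    vus_carriers: list[str] = []
    for i in range(config.n_vus):
        sid = f"VUS_{i + 1:02d}"
        if i < (config.n_vus + 1) // 2:
            vus_carriers.append(sid)
        samples.append(dict(sample_id=sid, group="vus",
                            sex="F" if rng.random() < 0.5 else "M",
                            age=float(rng.integers(6, 31)), disorder=""))
    sheet_t = pd.DataFrame(samples)
    n_samples = len(sheet_t)

    # Cell mixtures: Dirichlet draws; cases (and carrier VUS) get a shifted
    # mean composition so cell confounding correlates with case status.
    props0 = _base_proportions(k)
    shift = np.zeros(k)
    shift[0] = config.case_cell_shift
    props_case = (props0 + shift) / (1.0 + config.case_cell_shift)
    alpha0 = props0 * config.cell_concentration
    alpha_case = props_case * config.cell_concentration
    shifted = sheet_t["group"].eq("case").to_numpy() | \
        sheet_t["sample_id"].isin(vus_carriers).to_numpy()
    props = np.empty((n_samples, k))
    for i in range(n_samples):
        props[i] = rng.dirichlet(alpha_case if shifted[i] else alpha0)
    prop_df = pd.DataFrame(props, index=sheet_t["sample_id"], columns=cell_names)

    # Group effects on the logit scale, per probe.
    pid_index = pd.Index(probe_ids)
    base_s = pd.Series(mix0, index=pid_index)

    def effect_vector(delta: dict[str, float]) -> np.ndarray:
        eff = np.zeros(n_probes)
        if delta:
            idx = pid_index.get_indexer(list(delta.keys()))
            b = base_s.iloc[idx].to_numpy()
            target = b + np.array(list(delta.values()))
            eff[idx] = logit(target) - logit(b)
        return eff

    case_eff = effect_vector(signal_delta)
    disorder_eff = {name: effect_vector(confounder_sigs[name + "__delta"])  # type: ignore[index]
                    for name in confounder_sigs if not name.endswith("__delta")}
    for key in [kk for kk in confounder_sigs if kk.endswith("__delta")]:
        del confounder_sigs[key]

    mix = props @ ref_beta                      # (samples, probes)
    z = logit(np.clip(mix, 1e-12, 1 - 1e-12))
    for i, row in enumerate(sheet_t.itertuples(index=False)):
        if row.group == "case" or row.sample_id in vus_carriers:
            z[i] += case_eff
        elif row.group == "other_disorder":
            z[i] += disorder_eff[row.disorder]
    z += config.background_shift
    z += rng.normal(0.0, config.noise_sd, size=z.shape)
    beta_values = expit(z).T                    # (probes, samples)

    values = pd.DataFrame(beta_values, index=probe_ids,
                          columns=sheet_t["sample_id"].to_numpy())
    failure = None
    if config.failure_rate > 0:
        failure = pd.DataFrame(
            rng.random(values.shape) < config.failure_rate,
            index=values.index, columns=values.columns)
    beta = BetaMatrix(values, failure)

    sheet_full = pd.concat(
        [sheet_t.reset_index(drop=True),
         prop_df.reset_index(drop=True)], axis=1)
    sheet = SampleSheet(sheet_full)

    regions = IntervalSet("planted_regions", pd.DataFrame(
        [(c, s, e, "signal") for c, s, e in region_tuples],
        columns=["chrom", "start", "end", "label"]))
    truth = SimulationTruth(
        signal_probe_ids=signal_ids,
        signal_delta=signal_delta,
        signal_regions=regions,
        cell_reference=cell_reference,
        per_sample_proportions=prop_df,
        confounder_signatures=confounder_sigs,
        vus_carriers=vus_carriers,
    )
    return beta, sheet, truth


# ---------------------------------------------------------------------------
# Chromatin-state epigenomes


_GAP_STATE_WEIGHTS = {
    "Quiescent": 0.45,
    "Weak Transcription": 0.10,
    "Strong Transcription": 0.06,
    "Heterochromatin": 0.08,
    "Enhancers": 0.07,
    "Weak Repressed PolyComb": 0.08,
    "Repressed PolyComb": 0.04,
    "Transcription at 5' and 3'": 0.02,
    "Genic Enhancers": 0.03,
    "ZNF genes and repeats": 0.02,
    "Bivalent enhancers": 0.02,
    "Flanking bivalent TSS enhancers": 0.01,
    "Bivalent poised TSS": 0.01,
    "Flanking Active TSS": 0.01,
}


def simulate_epigenomes(config: SimConfig, manifest: ProbeAnnotation,
                        n_epigenomes: int | None = None) -> list[IntervalSet]:
    """Generate per-epigenome 15-state segmentations of the synthetic genome.

    Each epigenome partitions every chromosome exactly (each base covered by
    one state). Promoter CpG clusters are covered by an Active TSS core
    (probability 0.75 per epigenome, else a bivalent/flanking promoter
    state) with Flanking Active TSS shoulders; the rest of the genome is
    filled with 2-20 kb segments drawn from a quiescent-dominated state
    distribution. This makes planted promoter DMRs genuinely enriched for
    Active TSS and depleted for Quiescent.
    """
    n_epi = config.n_epigenomes if n_epigenomes is None else n_epigenomes
    if n_epi < 1:
        raise SimulationError("need at least one epigenome")
    extents = chromosome_extents(manifest)
    for chrom, ext in extents.items():
        if ext <= 0:
            raise SimulationError(f"zero-length chromosome {chrom}")
    clusters = probe_clusters(manifest, max_gap=1000, min_size=5)
    windows: dict[str, list[tuple[int, int]]] = {c: [] for c in extents}
    for run in clusters:
        chrom = str(run["chrom"].iloc[0])
        windows[chrom].append((int(run["position"].min()),
                               int(run["position"].max()) + 1))
    for chrom in windows:
        windows[chrom].sort()

    gap_states = list(_GAP_STATE_WEIGHTS)
    gap_probs = np.array(list(_GAP_STATE_WEIGHTS.values()))
    gap_probs = gap_probs / gap_probs.sum()

    epigenomes = []
    for e in range(n_epi):
        rng = np.random.default_rng([config.seed, 2, e])
        rows = []

        def fill_gap(chrom: str, start: int, end: int) -> None:
            pos = start
            while pos < end:
                seg = int(rng.integers(2_000, 20_001))
                stop = min(pos + seg, end)
                state = gap_states[int(rng.choice(len(gap_states), p=gap_probs))]
                rows.append((chrom, pos, stop, state))
                pos = stop

        for chrom in sorted(extents):
            length = extents[chrom]
            cursor = 0
            for (ws, we) in windows[chrom]:
                core_s = max(0, ws - int(rng.integers(100, 400)))
                core_e = min(length, we + int(rng.integers(100, 400)))
                flank = int(rng.integers(200, 601))
                flank_s = max(cursor, core_s - flank)
                flank_e = min(length, core_e + flank)
                if flank_s > cursor:
                    fill_gap(chrom, cursor, flank_s)
                u = rng.random()
                core_state = ("Active TSS" if u < 0.75 else
                              "Bivalent poised TSS" if u < 0.87 else
                              "Flanking Active TSS")
                if flank_s < core_s:
                    rows.append((chrom, flank_s, core_s, "Flanking Active TSS"))
                rows.append((chrom, core_s, core_e, core_state))
                if core_e < flank_e:
                    rows.append((chrom, core_e, flank_e, "Flanking Active TSS"))
                cursor = flank_e
            if cursor < length:
                fill_gap(chrom, cursor, length)
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])
        epigenomes.append(IntervalSet(f"epigenome_{e + 1:03d}", df))
    return epigenomes


# ---------------------------------------------------------------------------
# Convenience output for the CLI


def write_cohort(outdir: str | Path, beta: BetaMatrix, sheet: SampleSheet,
                 manifest: ProbeAnnotation, truth: SimulationTruth,
                 epigenomes: list[IntervalSet] | None = None) -> None:
    from . import io as _io
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fail = outdir / "detection_failure.tsv" if beta.detection_failure is not None else None
    _io.write_beta_matrix(beta, outdir / "beta.tsv", fail)
    _io.write_sample_sheet(sheet, outdir / "samples.tsv")
    _io.write_manifest(manifest, outdir / "manifest.tsv")
    (outdir / "truth.json").write_text(truth.to_json())
    if epigenomes:
        epi_dir = outdir / "epigenomes"
        epi_dir.mkdir(exist_ok=True)
        for epi in epigenomes:
            _io.write_bed(epi, epi_dir / f"{epi.name}.bed")
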