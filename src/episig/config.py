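"""Closed vocabularies and configuration objects for the pipeline.

Two configuration dataclasses are exposed: :class:`PipelineConfig` gathers
every analysis threshold (probe/array QC, the matched-control ratio, the
discovery-funnel sizes, DMR criteria, interval-overlap fraction and the
classifier train fraction), and :class:`SimConfig` gathers the synthetic
cohort generator's knobs. Both serialise to/from YAML so that a run is fully
described by one inspectable file plus a seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

#: Gene-region categories used by EPIC-style probe manifests.
REGION_CATEGORIES: tuple[str, ...] = (
    "TSS200", "TSS1500", "5'UTR", "1stExon", "Body", "3'UTR", "IGR",
)

#: Categories treated as promoter-proximal (low baseline methylation).
PROMOTER_CATEGORIES: tuple[str, ...] = ("TSS200", "TSS1500", "5'UTR", "1stExon")

#: QC flags that cause a probe to be excluded before analysis.
PROBE_FLAGS: tuple[str, ...] = ("sex_chromosome", "cross_reactive", "snp_overlap")

#: Allowed sample group labels.
GROUPS: tuple[str, ...] = ("case", "control", "vus", "other_disorder")

SEXES: tuple[str, ...] = ("F", "M")

#: The 15-state chromatin vocabulary of the Roadmap Epigenomics segmentations.
CHROMATIN_STATES: tuple[str, ...] = (
    "Active TSS",
    "Flanking Active TSS",
    "Transcription at 5' and 3'",
    "Strong Transcription",
    "Weak Transcription",
    "Genic Enhancers",
    "Enhancers",
    "ZNF genes and repeats",
    "Heterochromatin",
    "Bivalent poised TSS",
    "Flanking bivalent TSS enhancers",
    "Bivalent enhancers",
    "Repressed PolyComb",
    "Weak Repressed PolyComb",
    "Quiescent",
)


class ConfigError(ValueError):
    """Raised when a configuration value is outside its valid range."""


@dataclass
class PipelineConfig:
    """Analysis thresholds; defaults follow the published episignature workflow.

    Parameters
    ----------
    failure_rate_max:
        Arrays with a probe detection-failure fraction strictly above this
        value are dropped (default 0.05, i.e. "more than 5%").
    control_ratio:
        Matched controls selected per case (default 7).
    fdr_max, delta_beta_min:
        Differentially methylated probe criteria: BH-adjusted q strictly below
        ``fdr_max`` and |mean beta difference| strictly above ``delta_beta_min``.
    n_candidates, n_roc, r_max:
        The selection funnel: top ``n_candidates`` probes by the
        |delta beta| x (-log10 p) product, the ``n_roc`` best of those by ROC
        area, then greedy removal of probes with pairwise Pearson |r| >
        ``r_max``.
    dmr_min_cpgs, dmr_max_gap, dmr_p_max:
        Region criteria: at least ``dmr_min_cpgs`` probes with inter-probe
        gaps of at most ``dmr_max_gap`` bp, combined (BH-adjusted Fisher)
        p below ``dmr_p_max``.
    overlap_fraction_min:
        A DMR counts as hitting a feature track when strictly more than this
        fraction of its length is covered.
    train_fraction:
        Share of each control / confounder pool used to train the MVP
        classifier; all case samples are always in the training set.
    dmp_prefilter:
        Restrict the funnel to probes meeting the DMP effect/FDR criteria
        before ranking. This reconciles the probe-selection funnel with the
        fact that the final signature probes all satisfy the DMP thresholds.
    rank_uses_adjusted_p:
        Use BH-adjusted rather than raw p in the ranking product.
    epsilon:
        Clipping constant for the logit transform of beta values.
    """

    failure_rate_max: float = 0.05
    control_ratio: int = 7
    fdr_max: float = 0.01
    delta_beta_min: float = 0.10
    n_candidates: int = 1000
    n_roc: int = 500
    r_max: float = 0.9
    dmr_min_cpgs: int = 5
    dmr_max_gap: int = 1000
    dmr_p_max: float = 0.01
    overlap_fraction_min: float = 0.5
    train_fraction: float = 0.75
    dmp_prefilter: bool = True
    rank_uses_adjusted_p: bool = False
    epsilon: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not 0.0 <= self.failure_rate_max <= 1.0:
            raise ConfigError("failure_rate_max must be in [0, 1]")
        if self.control_ratio < 1:
            raise ConfigError("control_ratio must be >= 1")
        for name in ("fdr_max", "delta_beta_min", "dmr_p_max",
                     "overlap_fraction_min", "train_fraction", "r_max"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ConfigError(f"{name} must be in (0, 1], got {v}")
        if self.n_candidates < 1 or self.n_roc < 1:
            raise ConfigError("funnel sizes must be positive")
        if self.n_roc > self.n_candidates:
            raise ConfigError("n_roc cannot exceed n_candidates")
        if self.dmr_min_cpgs < 2:
            raise ConfigError("dmr_min_cpgs must be >= 2")
        if self.dmr_max_gap < 1:
            raise ConfigError("dmr_max_gap must be >= 1 bp")
        if not 0.0 < self.epsilon < 0.5:
            raise ConfigError("epsilon must be in (0, 0.5)")


def _default_category_frequencies() -> dict[str, float]:
    # Marginal frequencies loosely mirroring the EPIC manifest composition.
    return {
        "TSS200": 0.10,
        "TSS1500": 0.12,
        "5'UTR": 0.08,
        "1stExon": 0.05,
        "Body": 0.35,
        "3'UTR": 0.05,
        "IGR": 0.25,
    }


@dataclass
class SimConfig:
    """Synthetic EPIC-like cohort generator settings.

    The defaults define the desk-scale study geometry used throughout the
    test-bed: 20,000 probes on two synthetic chromosomes, 8 cases against a
    200-sample control pool (so that 7:1 matching yields 56 controls), two
    confounder ("other disorder") cohorts of 20 samples each with planted
    signatures disjoint from the case signature, 300 case signal probes with
    beta-scale effect sizes drawn uniformly from [0.10, 0.20], and
    logit-scale Gaussian noise with standard deviation 0.15.
    """

    n_probes: int = 20_000
    n_chromosomes: int = 2
    n_cases: int = 8
    n_controls: int = 200
    n_other_disorders: int = 2
    other_disorder_size: int = 20
    n_vus: int = 0
    n_signal_probes: int = 300
    delta_beta_range: tuple[float, float] = (0.10, 0.20)
    fraction_hyper: float = 1.0
    fraction_signal_in_regions: float = 0.5
    promoter_bias: float = 5.0
    noise_sd: float = 0.15
    background_shift: float = 0.0
    n_cell_types: int = 6
    cell_concentration: float = 25.0
    case_cell_shift: float = 0.05
    cell_variable_fraction: float = 0.10
    cell_variable_sd: float = 1.0
    cell_stable_sd: float = 0.25
    flag_fraction: float = 0.02
    failure_rate: float = 0.001
    category_frequencies: dict[str, float] = field(
        default_factory=_default_category_frequencies)
    n_epigenomes: int = 127
    seed: int = 0

    def __post_init__(self) -> None:
        self.delta_beta_range = tuple(self.delta_beta_range)  # type: ignore[assignment]
        self.validate()

    def validate(self) -> None:
        if self.n_probes < 100:
            raise ConfigError(
                "n_probes must be >= 100 (too small for the selection funnel)")
        for name in ("n_chromosomes", "n_cases", "n_controls", "n_cell_types"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be positive")
        if self.n_other_disorders < 0 or self.other_disorder_size < 0:
            raise ConfigError("confounder cohort sizes must be non-negative")
        if not 0.0 <= self.fraction_hyper <= 1.0:
            raise ConfigError("fraction_hyper must be in [0, 1]")
        lo, hi = self.delta_beta_range
        if not (0.0 < lo <= hi < 1.0):
            raise ConfigError("delta_beta_range must satisfy 0 < lo <= hi < 1")
        if self.n_signal_probes < 0:
            raise ConfigError("n_signal_probes must be non-negative")
        if not 0.0 <= self.flag_fraction < 1.0:
            raise ConfigError("flag_fraction must be in [0, 1)")
        if not 0.0 <= self.failure_rate < 1.0:
            raise ConfigError("failure_rate must be in [0, 1)")
        freqs = self.category_frequencies
        if set(freqs) != set(REGION_CATEGORIES):
            raise ConfigError("category_frequencies must cover every region category")
        total = sum(freqs.values())
        if abs(total - 1.0) > 1e-6:
            raise ConfigError(f"category_frequencies must sum to 1, got {total}")


def _to_dict(cfg: Any) -> dict[str, Any]:
    d = dataclasses.asdict(cfg)
    if "delta_beta_range" in d:
        d["delta_beta_range"] = list(d["delta_beta_range"])
    return d


def save_config(cfg: PipelineConfig | SimConfig, path: str | Path) -> None:
    """Write a configuration to YAML."""
    payload = {"kind": type(cfg).__name__, **_to_dict(cfg)}
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def load_config(path: str | Path, kind: type | None = None):
    """Load a :class:`PipelineConfig` or :class:`SimConfig` from YAML.

    The file may carry an explicit ``kind`` key; otherwise ``kind`` must be
    given. Unknown keys raise, so stale configuration files fail loudly.
    """
    data = yaml.safe_load(Path(path).read_text()) or {}
    declared = data.pop("kind", None)
    cls = kind
    if declared is not None:
        cls = {"PipelineConfig": PipelineConfig, "SimConfig": SimConfig}.get(declared)
        if cls is None:
            raise ConfigError(f"unknown config kind {declared!r}")
    if cls is None:
        raise ConfigError("config kind not declared in file and not given")
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    return cls(**data)
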