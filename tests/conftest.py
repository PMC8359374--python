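import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from episig import (BetaMatrix, PipelineConfig, ProbeAnnotation, SampleSheet,
                    SimConfig, simulate_cohort, simulate_manifest)
from episig.discovery import derive_episignature

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture()
def tiny_beta() -> BetaMatrix:
    values = pd.DataFrame(
        [[0.10, 0.90], [0.50, 0.20], [0.80, 0.60]],
        index=["cgA", "cgB", "cgC"], columns=["s1", "s2"])
    return BetaMatrix(values)


@pytest.fixture()
def tiny_manifest() -> ProbeAnnotation:
    return ProbeAnnotation(pd.DataFrame({
        "probe_id": ["cgA", "cgB", "cgC"],
        "chrom": ["chr1", "chr1", "chr2"],
        "position": [100, 400, 100],
        "region_category": ["TSS200", "Body", "IGR"],
        "flags": ["", "", ""],
    }))


def make_sheet(rows):
    return SampleSheet(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def study_cohort():
    """One desk-scale cohort at the default study geometry."""
    cfg = SimConfig(seed=101)
    manifest = simulate_manifest(cfg)
    beta, sheet, truth = simulate_cohort(cfg, manifest)
    return cfg, manifest, beta, sheet, truth


@pytest.fixture(scope="session")
def study_discovery(study_cohort):
    cfg, manifest, beta, sheet, truth = study_cohort
    return derive_episignature(beta, sheet, manifest, PipelineConfig(seed=101))


@pytest.fixture(scope="session")
def ten_seed_runs():
    """Ten seeded cohorts at the study conditions (hypermethylating-only
    planted signal, 300 probes, 8 cases vs 56 matched controls, logit noise
    sd 0.15) with the full discovery funnel run on each.

    The beta matrices are not retained; downstream tests work from the
    probe statistics, manifests and planted truth.
    """
    runs = []
    for seed in range(1, 11):
        scfg = SimConfig(seed=seed)
        manifest = simulate_manifest(scfg)
        beta, sheet, truth = simulate_cohort(scfg, manifest)
        res = derive_episignature(beta, sheet, manifest,
                                  PipelineConfig(seed=seed))
        runs.append(dict(sim_config=scfg, manifest=manifest, truth=truth,
                         result=res))
    return runs
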