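"""QC filters, matched-control selection, M-values, cell deconvolution."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from episig import (BetaMatrix, ProbeAnnotation, SampleSheet, beta_to_m,
                    estimate_cell_proportions, filter_arrays, filter_probes,
                    m_to_beta, match_controls, pca_qc)
from episig.preprocess import MValueMatrix, PreprocessError, drop_failed_probes
from tests.conftest import make_sheet


def beta_of(values, probes=None, samples=None, failure=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    probes = probes or [f"cg{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    df = pd.DataFrame(values, index=probes, columns=samples)
    fdf = None
    if failure is not None:
        fdf = pd.DataFrame(np.atleast_2d(failure), index=probes,
                           columns=samples)
    return BetaMatrix(df, fdf)


class TestFilterProbes:
    def manifest(self, flags):
        n = len(flags)
        return ProbeAnnotation(pd.DataFrame({
            "probe_id": [f"cg{i}" for i in range(n)],
            "chrom": ["chr1"] * n,
            "position": list(range(0, 100 * n, 100)),
            "region_category": ["Body"] * n,
            "flags": flags,
        }))

    def test_flagged_probes_removed_with_per_reason_counts(self):
        flags = ["", "sex_chromosome", "", "cross_reactive", "snp_overlap",
                 "", "", "", "", ""]
        beta = beta_of(np.full((10, 2), 0.5))
        out, removed = filter_probes(beta, self.manifest(flags))
        assert out.shape == (7, 2)
        assert removed == {"sex_chromosome": 1, "cross_reactive": 1,
                           "snp_overlap": 1}

    def test_no_flags_is_identity(self):
        beta = beta_of(np.full((3, 2), 0.5))
        out, removed = filter_probes(beta, self.manifest(["", "", ""]))
        assert out is beta
        assert sum(removed.values()) == 0

    def test_all_flagged_errors(self):
        beta = beta_of(np.full((2, 2), 0.5))
        with pytest.raises(PreprocessError, match="no probes survive"):
            filter_probes(beta, self.manifest(["sex_chromosome"] * 2))

    def test_probe_missing_from_manifest_errors(self):
        beta = beta_of(np.full((3, 2), 0.5))
        with pytest.raises(PreprocessError, match="missing from manifest"):
            filter_probes(beta, self.manifest(["", ""]))


class TestFilterArrays:
    def test_boundary_is_strict_more_than(self):
        # 6% failures dropped; exactly 5% retained.
        n = 100
        fail = np.zeros((n, 2), dtype=bool)
        fail[:6, 0] = True   # 6%
        fail[:5, 1] = True   # 5%
        beta = beta_of(np.full((n, 2), 0.5), failure=fail)
        out, dropped = filter_arrays(beta, 0.05)
        assert dropped == ["s0"]
        assert out.sample_ids == ["s1"]

    def test_zero_failures_is_identity(self):
        beta = beta_of(np.full((4, 3), 0.5), failure=np.zeros((4, 3), bool))
        out, dropped = filter_arrays(beta)
        assert dropped == []
        assert out is beta

    def test_counts_on_mixed_cohort(self):
        n = 40
        fail = np.zeros((n, 10), dtype=bool)
        fail[:4, 3] = True   # 10%
        fail[:10, 7] = True  # 25%
        beta = beta_of(np.full((n, 10), 0.5), failure=fail)
        out, dropped = filter_arrays(beta, 0.05)
        assert len(out.sample_ids) == 8
        assert set(dropped) == {"s3", "s7"}

    def test_failed_probe_dropping(self):
        fail = np.zeros((3, 2), dtype=bool)
        fail[1, 0] = True
        beta = beta_of(np.full((3, 2), 0.5), failure=fail)
        out = drop_failed_probes(beta)
        assert out.probe_ids == ["cg0", "cg2"]
        assert out.detection_failure is None


class TestMatchControls:
    def cases(self):
        return make_sheet([
            dict(sample_id="caseA", group="case", sex="F", age=10),
            dict(sample_id="caseB", group="case", sex="M", age=20),
        ])

    def test_default_ratio_yields_seven_controls_per_case(self):
        rng = np.random.default_rng(0)
        pool = make_sheet([
            dict(sample_id=f"c{i:03d}", group="control",
                 sex="F" if i < 60 else "M",
                 age=float(rng.integers(5, 40))) for i in range(120)])
        cohort = match_controls(self.cases(), pool, ratio=7)
        assert len(cohort.control_ids) == 14
        assert all(len(v) == 7 for v in cohort.match_table.values())
        assert len(set(cohort.control_ids)) == 14  # without replacement

    def test_forced_solution_when_pool_exactly_fits(self):
        pool = make_sheet(
            [dict(sample_id=f"f{i}", group="control", sex="F", age=10)
             for i in range(7)] +
            [dict(sample_id=f"m{i}", group="control", sex="M", age=20)
             for i in range(7)])
        cohort = match_controls(self.cases(), pool, ratio=7)
        assert sorted(cohort.match_table["caseA"]) == [f"f{i}" for i in range(7)]
        assert sorted(cohort.match_table["caseB"]) == [f"m{i}" for i in range(7)]

    def test_age_ties_break_lexicographically(self):
        case = make_sheet([dict(sample_id="x", group="case", sex="F", age=10)])
        pool = make_sheet([
            dict(sample_id="b", group="control", sex="F", age=12),
            dict(sample_id="a", group="control", sex="F", age=8),
            dict(sample_id="c", group="control", sex="F", age=30),
        ])
        cohort = match_controls(case, pool, ratio=1)
        # |12-10| == |8-10|: lexicographically smaller id wins.
        assert cohort.match_table["x"] == ["a"]

    def test_invariant_to_pool_row_order(self):
        rng = np.random.default_rng(3)
        rows = [dict(sample_id=f"c{i:03d}", group="control",
                     sex="F" if i % 2 else "M",
                     age=float(rng.integers(5, 40))) for i in range(60)]
        pool1 = make_sheet(rows)
        pool2 = make_sheet(list(reversed(rows)))
        a = match_controls(self.cases(), pool1)
        b = match_controls(self.cases(), pool2)
        assert a.match_table == b.match_table

    def test_insufficient_same_sex_errors(self):
        pool = make_sheet([dict(sample_id=f"m{i}", group="control", sex="M",
                                age=10.0) for i in range(20)])
        with pytest.raises(PreprocessError, match="same-sex"):
            match_controls(self.cases(), pool)


class TestMValues:
    @pytest.mark.parametrize("b,m", [(0.5, 0.0), (0.8, 2.0), (0.2, -2.0)])
    def test_known_values(self, b, m):
        out = beta_to_m(beta_of([[b]]))
        assert out.values.iloc[0, 0] == pytest.approx(m, abs=1e-12)

    @given(st.floats(min_value=1e-5, max_value=1 - 1e-5))
    def test_round_trip_identity_inside_clipping_band(self, b):
        beta = beta_of([[b]])
        back = m_to_beta(beta_to_m(beta))
        assert back.values.iloc[0, 0] == pytest.approx(b, abs=1e-12)

    def test_monotone_in_beta(self):
        bs = np.linspace(0.01, 0.99, 25)
        m = beta_to_m(beta_of(bs.reshape(-1, 1))).values.to_numpy().ravel()
        assert np.all(np.diff(m) > 0)

    def test_boundary_values_clipped_finite(self):
        out = beta_to_m(beta_of([[0.0, 1.0]]))
        assert np.all(np.isfinite(out.values.to_numpy()))


class TestCellProportions:
    def reference(self):
        rng = np.random.default_rng(5)
        probes = [f"cg{i}" for i in range(60)]
        return pd.DataFrame(rng.uniform(0.05, 0.95, size=(3, 60)),
                            index=["t1", "t2", "t3"], columns=probes)

    def test_pure_sample_recovers_membership(self):
        ref = self.reference()
        beta = beta_of(ref.loc[["t2"]].to_numpy().T, probes=list(ref.columns),
                       samples=["s"])
        props = estimate_cell_proportions(beta, ref)
        assert props.loc["s", "t2"] == pytest.approx(1.0, abs=1e-8)

    def test_even_mixture_recovered_exactly(self):
        ref = self.reference()
        mix = 0.5 * ref.loc["t1"] + 0.5 * ref.loc["t3"]
        beta = beta_of(mix.to_numpy().reshape(-1, 1),
                       probes=list(ref.columns), samples=["s"])
        props = estimate_cell_proportions(beta, ref)
        assert props.loc["s", "t1"] == pytest.approx(0.5, abs=1e-6)
        assert props.loc["s", "t3"] == pytest.approx(0.5, abs=1e-6)
        assert props.loc["s", "t2"] == pytest.approx(0.0, abs=1e-6)

    def test_output_on_simplex_for_noisy_samples(self):
        ref = self.reference()
        rng = np.random.default_rng(6)
        vals = np.clip(rng.random((60, 5)), 0.01, 0.99)
        beta = beta_of(vals, probes=list(ref.columns))
        props = estimate_cell_proportions(beta, ref)
        assert (props.to_numpy() >= 0).all()
        assert np.allclose(props.sum(axis=1), 1.0, atol=1e-9)

    def test_too_few_shared_probes_errors(self):
        ref = self.reference().iloc[:, :10]
        beta = beta_of(np.full((10, 1), 0.5), probes=list(ref.columns))
        with pytest.raises(PreprocessError, match="50"):
            estimate_cell_proportions(beta, ref)


class TestPcaQc:
    def test_duplicated_sample_gets_identical_coordinates(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(30, 4))
        x[:, 3] = x[:, 0]
        m = MValueMatrix(pd.DataFrame(x, index=[f"cg{i}" for i in range(30)],
                                      columns=["a", "b", "c", "a2"]))
        coords, _ = pca_qc(m)
        assert np.allclose(coords.loc["a"], coords.loc["a2"], atol=1e-9)

    def test_planted_outlier_flagged(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(200, 12)) * 0.3
        x[:60, 11] += 5.0  # +5 SD shift on 30% of probes
        m = MValueMatrix(pd.DataFrame(
            x, index=[f"cg{i}" for i in range(200)],
            columns=[f"s{j}" for j in range(12)]))
        _, flagged = pca_qc(m)
        assert flagged == ["s11"]

    def test_projection_matches_full_eigendecomposition(self):
        # Eckart-Young: the rank-k PCA projection preserves pairwise
        # distances exactly as well as the top-k eigenvectors of the Gram
        # matrix computed independently.
        rng = np.random.default_rng(9)
        x = rng.normal(size=(40, 5))
        m = MValueMatrix(pd.DataFrame(
            x, index=[f"cg{i}" for i in range(40)],
            columns=[f"s{j}" for j in range(5)]))
        coords, _ = pca_qc(m, n_components=2)
        centered = x.T - x.T.mean(axis=0)
        evals, evecs = np.linalg.eigh(centered @ centered.T)
        order = np.argsort(evals)[::-1][:2]
        ref = evecs[:, order] * np.sqrt(evals[order])
        d_pca = np.linalg.norm(coords.to_numpy()[:, None]
                               - coords.to_numpy()[None, :], axis=2)
        d_ref = np.linalg.norm(ref[:, None] - ref[None, :], axis=2)
        assert np.allclose(d_pca, d_ref, atol=1e-9)

    def test_constant_matrix_errors(self):
        m = MValueMatrix(pd.DataFrame(np.zeros((5, 4)),
                                      index=[f"cg{i}" for i in range(5)],
                                      columns=list("abcd")))
        with pytest.raises(PreprocessError, match="constant"):
            pca_qc(m)


class TestFilterCommutation:
    def test_probe_and_array_filters_commute(self):
        rng = np.random.default_rng(10)
        n, s = 60, 6
        flags = ["cross_reactive" if i % 10 == 0 else "" for i in range(n)]
        unflagged = np.array([f == "" for f in flags])
        # Failures only on unflagged probes so the two filters don't
        # interact: the bad array is far above threshold either way.
        fail = np.zeros((n, s), dtype=bool)
        fail[:, 2] = unflagged & (rng.random(n) < 0.5)
        ann = ProbeAnnotation(pd.DataFrame({
            "probe_id": [f"cg{i}" for i in range(n)], "chrom": "chr1",
            "position": range(0, n * 100, 100), "region_category": "Body",
            "flags": flags}))
        beta = beta_of(rng.uniform(0.05, 0.95, (n, s)), failure=fail)
        a = filter_arrays(filter_probes(beta, ann)[0], 0.05)[0]
        b = filter_probes(filter_arrays(beta, 0.05)[0], ann)[0]
        pd.testing.assert_frame_equal(a.values, b.values)
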