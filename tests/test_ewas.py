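import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epiewas import (
    BetaMatrix,
    ValidationError,
    bonferroni,
    pca_qc,
    probe_group_stats,
    probe_t_test,
    run_ewas,
    smooth_p,
)
from conftest import brute_force_smooth, student_oracle, welch_oracle


def _matrix(case_vals, ctrl_vals, probe="cgT"):
    n1, n2 = len(case_vals), len(ctrl_vals)
    cols = [f"case{i}" for i in range(n1)] + [f"ctrl{i}" for i in range(n2)]
    values = pd.DataFrame(
        [list(case_vals) + list(ctrl_vals)],
        index=pd.Index([probe], name="probe_id"),
        columns=cols,
    )
    meta = pd.DataFrame(
        {"group": ["case"] * n1 + ["control"] * n2},
        index=pd.Index(cols, name="sample_id"),
    )
    return BetaMatrix(values, meta)


class TestProbeGroupStats:
    def test_known_means(self):
        bm = _matrix([0.56, 0.54], [0.02, 0.0])
        mc, mk, d = probe_group_stats(bm, "cgT")
        assert (mc, mk) == (0.55, 0.01)
        assert d == pytest.approx(0.54)

    def test_identical_groups_zero_delta(self):
        bm = _matrix([0.3, 0.3], [0.3, 0.3])
        assert probe_group_stats(bm, "cgT")[2] == 0.0

    def test_label_swap_negates_delta(self):
        bm = _matrix([0.5, 0.6], [0.1, 0.2])
        swapped = BetaMatrix(
            bm.values.copy(),
            bm.sample_meta.assign(
                group=bm.sample_meta["group"].map(
                    {"case": "control", "control": "case"}
                )
            ),
        )
        assert probe_group_stats(bm, "cgT")[2] == pytest.approx(
            -probe_group_stats(swapped, "cgT")[2]
        )

    def test_missing_values_excluded(self):
        bm = _matrix([0.5, np.nan], [0.1, 0.3])
        mc, mk, d = probe_group_stats(bm, "cgT")
        assert mc == 0.5 and mk == pytest.approx(0.2)

    def test_all_missing_group_rejected(self):
        bm = _matrix([np.nan, np.nan], [0.1, 0.3])
        with pytest.raises(ValidationError):
            probe_group_stats(bm, "cgT")


class TestProbeTTest:
    def test_identical_groups_p_one(self):
        bm = _matrix([0.2, 0.4, 0.3], [0.2, 0.4, 0.3])
        t, p = probe_t_test(bm, "cgT")
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_separated_groups_tiny_p(self):
        rng = np.random.default_rng(0)
        bm = _matrix(
            rng.normal(0.0, 1e-4, 10).clip(0, 1),
            (1 + rng.normal(0.0, 1e-4, 10)).clip(0, 1),
        )
        _, p = probe_t_test(bm, "cgT")
        assert p < 1e-10

    def test_constant_equal_groups_convention(self):
        bm = _matrix([0.3, 0.3, 0.3], [0.3, 0.3, 0.3])
        t, p = probe_t_test(bm, "cgT")
        assert (t, p) == (0.0, 1.0)

    @pytest.mark.parametrize("variant,oracle", [
        ("welch", welch_oracle), ("student", student_oracle)
    ])
    def test_matches_closed_form(self, variant, oracle):
        rng = np.random.default_rng(123)
        for _ in range(50):
            x = rng.uniform(0, 1, 5)
            y = rng.uniform(0, 1, 5)
            t, p = probe_t_test(_matrix(x, y), "cgT", variant=variant)
            t0, p0 = oracle(x, y)
            assert t == pytest.approx(t0, abs=1e-12)
            assert p == pytest.approx(p0, abs=1e-12)

    def test_insufficient_group_rejected(self):
        bm = _matrix([0.5], [0.1, 0.2])
        with pytest.raises(ValidationError, match="fewer than 2"):
            probe_t_test(bm, "cgT")


class TestBonferroni:
    def test_simple_scaling(self):
        assert bonferroni(1e-5, 100) == pytest.approx(1e-3)

    def test_capped_at_one(self):
        assert bonferroni(0.5, 10) == 1.0

    @settings(max_examples=200, deadline=None)
    @given(st.floats(1e-300, 1.0), st.integers(1, 10**6))
    def test_ratio_equals_m_when_uncapped(self, p, m):
        q = bonferroni(p, m)
        assert q >= p
        if q < 1.0:
            assert q / p == pytest.approx(m, rel=1e-9)


def _rows(neglog, chroms=None, positions=None):
    n = len(neglog)
    return pd.DataFrame(
        {
            "chromosome": chroms if chroms is not None else ["1"] * n,
            "position": positions if positions is not None else range(1, n + 1),
            "neglog10_p": neglog,
        }
    )


class TestSmoothP:
    def test_constant_vector_is_fixed_point(self):
        out = smooth_p(_rows([2.5] * 20), radius=3)
        assert np.allclose(out["neglog10_p_smoothed"], 2.5)

    def test_radius_zero_is_identity(self):
        vals = np.random.default_rng(1).uniform(0, 10, 15)
        out = smooth_p(_rows(vals), radius=0)
        assert np.allclose(out["neglog10_p_smoothed"], vals)

    def test_interior_spike_spreads_to_h_over_7(self):
        vals = np.zeros(21)
        vals[10] = 7.0
        out = smooth_p(_rows(vals), radius=3)
        assert out["neglog10_p_smoothed"][10] == pytest.approx(1.0)
        assert out["neglog10_p_smoothed"][7] == pytest.approx(1.0)
        assert out["neglog10_p_smoothed"][6] == pytest.approx(0.0)

    @pytest.mark.parametrize("radius", range(6))
    def test_equals_brute_force_with_chromosome_boundaries(self, radius):
        rng = np.random.default_rng(radius)
        chroms = ["1"] * 11 + ["2"] * 2 + ["X"] * 7
        positions = list(range(1, 12)) + [5, 9] + list(range(3, 10))
        vals = rng.uniform(0, 50, 20)
        vals[[4, 13]] = np.nan  # untested probes stay out of the window
        out = smooth_p(_rows(vals, chroms, positions), radius=radius)
        expected = brute_force_smooth(vals, chroms, radius)
        np.testing.assert_allclose(
            out["neglog10_p_smoothed"], expected, equal_nan=True
        )

    def test_unsorted_positions_rejected(self):
        with pytest.raises(ValidationError, match="not sorted"):
            smooth_p(_rows([1, 2, 3], positions=[3, 1, 2]), radius=1)

    def test_split_chromosome_block_rejected(self):
        rows = _rows([1, 2, 3], chroms=["1", "2", "1"], positions=[1, 1, 2])
        with pytest.raises(ValidationError, match="not sorted"):
            smooth_p(rows, radius=1)


class TestPcaQc:
    def _clustered_matrix(self, offset=0.4, n_probes=50, seed=0):
        rng = np.random.default_rng(seed)
        base = rng.uniform(0.2, 0.5, size=(n_probes, 1))
        vals = np.clip(base + rng.normal(0, 0.01, size=(n_probes, 20)), 0, 1)
        vals[: n_probes // 3, 10:] += offset  # 30% of probes offset in cluster 2
        vals = np.clip(vals, 0, 1)
        cols = [f"s{i}" for i in range(20)]
        meta = pd.DataFrame(
            {"group": ["case"] * 10 + ["control"] * 10},
            index=pd.Index(cols, name="sample_id"),
        )
        return BetaMatrix(
            pd.DataFrame(vals, index=pd.Index([f"cg{i}" for i in range(n_probes)],
                                              name="probe_id"), columns=cols),
            meta,
        )

    def test_two_clusters_separate_on_ev1(self):
        res = pca_qc(self._clustered_matrix(), k=3)
        ev1 = res.scores["EV1"]
        a, b = ev1.iloc[:10], ev1.iloc[10:]
        assert a.min() > b.max() or b.min() > a.max()

    def test_rank_one_data_first_eigenvalue_dominates(self):
        rng = np.random.default_rng(3)
        u = rng.uniform(0, 1, size=(40, 1))
        w = rng.uniform(0.2, 1.0, size=(1, 12))
        vals = np.clip(u @ w, 0, 1)
        cols = [f"s{i}" for i in range(12)]
        meta = pd.DataFrame({"group": ["case"] * 6 + ["control"] * 6},
                            index=pd.Index(cols, name="sample_id"))
        bm = BetaMatrix(
            pd.DataFrame(vals, index=pd.Index([f"cg{i}" for i in range(40)],
                                              name="probe_id"), columns=cols),
            meta,
        )
        res = pca_qc(bm, k=5)
        assert res.explained_variance_ratio[0] > 0.999

    def test_sample_permutation_invariance_up_to_sign(self):
        bm = self._clustered_matrix(seed=5)
        res = pca_qc(bm, k=2)
        rng = np.random.default_rng(0)
        perm = rng.permutation(bm.sample_ids)
        bm2 = BetaMatrix(bm.values[perm], bm.sample_meta.loc[perm])
        res2 = pca_qc(bm2, k=2)
        for ev in ("EV1", "EV2"):
            a = res.scores.loc[perm, ev].to_numpy()
            b = res2.scores[ev].to_numpy()
            assert np.allclose(a, b, atol=1e-8) or np.allclose(a, -b, atol=1e-8)

    def test_eigenvalues_non_increasing_and_variance_conserved(self):
        bm = self._clustered_matrix(seed=7)
        res = pca_qc(bm, k=19)  # full rank: n_samples - 1
        assert (np.diff(res.eigenvalues) <= 1e-10).all()
        assert res.eigenvalues.sum() == pytest.approx(res.total_variance, rel=1e-8)

    def test_chromosome_restriction(self, small_sim):
        beta, manifest, _, _ = small_sim
        res = pca_qc(beta, k=3, chromosome="1", manifest=manifest)
        assert res.scores.shape == (367, 3)
        with pytest.raises(ValidationError):
            pca_qc(beta, k=3, chromosome="99", manifest=manifest)


class TestRunEwas:
    def test_row_count_and_schema(self, small_sim):
        beta, manifest, _, _ = small_sim
        ewas = run_ewas(beta, manifest)
        assert len(ewas) == len(manifest)
        assert ewas["tested"].all()
        assert (ewas["p_bonferroni"] >= ewas["p_nominal"]).all()
        assert np.allclose(ewas["neglog10_p"], -np.log10(ewas["p_nominal"]))

    def test_epimutated_island_probes_significant(self, small_sim):
        beta, manifest, _, truth = small_sim
        ewas = run_ewas(beta, manifest)
        epi = truth.probes.loc[truth.probes["island_id"] == "CpG:simA", "probe_id"]
        sub = ewas[ewas["probe_id"].isin(epi)]
        assert (sub["p_bonferroni"] < 0.05).all()
        assert (sub["delta_beta"] > 0.3).all()

    def test_missingness_flags_untested(self, small_sim):
        beta, manifest, _, _ = small_sim
        vals = beta.values.copy()
        probe = vals.index[0]
        vals.loc[probe, beta.case_ids[1:]] = np.nan  # one case value left
        crippled = BetaMatrix(vals, beta.sample_meta)
        ewas = run_ewas(crippled, manifest)
        row = ewas[ewas["probe_id"] == probe].iloc[0]
        assert not row["tested"]
        assert np.isnan(row["p_nominal"])
        # Bonferroni factor shrinks by exactly the one untested probe
        tested = ewas[ewas["tested"]]
        ratio = (tested["p_bonferroni"] / tested["p_nominal"]).to_numpy()
        uncapped = tested["p_bonferroni"].to_numpy() < 1.0
        assert np.allclose(ratio[uncapped], len(manifest) - 1)

    def test_group_label_swap_flips_t_sign(self, small_sim):
        beta, manifest, _, _ = small_sim
        swapped = BetaMatrix(
            beta.values.copy(),
            beta.sample_meta.assign(
                group=beta.sample_meta["group"].map(
                    {"case": "control", "control": "case"}
                )
            ),
        )
        a = run_ewas(beta, manifest)
        b = run_ewas(swapped, manifest)
        np.testing.assert_allclose(
            a["delta_beta"], -b["delta_beta"], atol=1e-12
        )
        np.testing.assert_allclose(a["t_stat"], -b["t_stat"], atol=1e-9)
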