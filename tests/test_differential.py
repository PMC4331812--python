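"""Detection filter, normalization, F-test and Storey q-values."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from seedfill.differential import (
    QValueSettings,
    detection_filter,
    ln_median_center,
    storey_q,
    timecourse_ftest,
)
from seedfill.simulate import SimulationSpec, simulate_timecourse

from conftest import make_matrix


class TestDetectionFilter:
    def test_complete_at_one_time_point_is_kept(self, design_2x3):
        vals = np.full((1, 6), np.nan)
        vals[0, :3] = 2.0  # all three replicates at 25 DAF
        m = make_matrix(vals, design_2x3)
        kept, dropped = detection_filter(m)
        assert kept.feature_ids == ["f0"] and dropped == []

    def test_one_missing_rep_at_every_time_point_is_dropped(self, design_2x3):
        vals = np.full((1, 6), 2.0)
        vals[0, 0] = np.nan
        vals[0, 3] = np.nan
        m = make_matrix(vals, design_2x3)
        kept, dropped = detection_filter(m)
        assert kept.shape[0] == 0 and dropped == ["f0"]

    def test_no_missing_values_is_identity(self, design_2x3, rng):
        m = make_matrix(np.exp(rng.normal(size=(5, 6))), design_2x3)
        kept, dropped = detection_filter(m)
        assert dropped == []
        np.testing.assert_array_equal(kept.values.to_numpy(), m.values.to_numpy())


class TestLnMedianCenter:
    def test_known_column(self, design_2x3):
        col = np.array([1.0, np.e, np.e**2])
        vals = np.tile(col[:, None], (1, 6))
        out = ln_median_center(make_matrix(vals, design_2x3))
        np.testing.assert_allclose(
            out.values.to_numpy()[:, 0], [-1.0, 0.0, 1.0], atol=1e-12
        )

    def test_constant_column_becomes_zero(self, design_2x3):
        out = ln_median_center(make_matrix(np.full((3, 6), 7.0), design_2x3))
        np.testing.assert_allclose(out.values.to_numpy(), 0.0, atol=1e-12)

    def test_per_sample_median_is_zero(self, design_2x3, rng):
        m = make_matrix(np.exp(rng.normal(size=(31, 6))), design_2x3)
        out = ln_median_center(m)
        med = np.median(out.values.to_numpy(), axis=0)
        np.testing.assert_allclose(med, 0.0, atol=1e-12)


def _anova_f_oracle(values: np.ndarray, times: np.ndarray, reps: np.ndarray):
    """Balanced two-way ANOVA without interaction, by explicit sums of squares."""
    grand = values.mean()
    ss_time = sum(
        (values[times == t].mean() - grand) ** 2 * (times == t).sum()
        for t in np.unique(times)
    )
    ss_rep = sum(
        (values[reps == r].mean() - grand) ** 2 * (reps == r).sum()
        for r in np.unique(reps)
    )
    ss_tot = ((values - grand) ** 2).sum()
    ss_err = ss_tot - ss_time - ss_rep
    df_t = len(np.unique(times)) - 1
    df_r = len(np.unique(reps)) - 1
    df_e = values.size - 1 - df_t - df_r
    F = (ss_time / df_t) / (ss_err / df_e)
    return F, stats.f.sf(F, df_t, df_e)


class TestTimecourseFtest:
    def test_matches_sum_of_squares_decomposition(self, design_2x3, rng):
        # balanced 2 times x 3 reps, several features
        vals = rng.normal(size=(6, 6))
        m = make_matrix(vals, design_2x3, scale="ln_centered")
        res = timecourse_ftest(m)
        times = np.asarray(design_2x3.time_points)
        reps = np.asarray(design_2x3.replicates)
        for i, fid in enumerate(m.feature_ids):
            F, p = _anova_f_oracle(vals[i], times, reps)
            assert res.loc[fid, "F"] == pytest.approx(F, rel=1e-9)
            assert res.loc[fid, "p"] == pytest.approx(p, rel=1e-9)
        assert (res["df_num"] == 1).all()
        assert (res["df_den"] == 2).all()

    def test_enumerated_small_dataset(self, design_2x3):
        # 2 reps x 3 times worth of printed values, transposed into the
        # 2-time design: use explicit numbers and the oracle
        vals = np.array([[1.0, 2.0, 3.0, 7.0, 9.0, 8.0]])
        m = make_matrix(vals, design_2x3, scale="ln_centered")
        res = timecourse_ftest(m)
        F, p = _anova_f_oracle(vals[0], np.asarray(design_2x3.time_points),
                               np.asarray(design_2x3.replicates))
        assert res["F"].iloc[0] == pytest.approx(F, rel=1e-9)
        # hand decomposition: SS_time=54, SS_rep=3, SS_err=1 -> F=(54/1)/(1/2)
        assert F == pytest.approx(108.0)

    def test_constant_feature_degenerate(self, design_2x3):
        m = make_matrix(np.full((1, 6), 3.3), design_2x3, scale="ln_centered")
        res = timecourse_ftest(m)
        assert res["p"].iloc[0] == 1.0
        assert bool(res["degenerate"].iloc[0])

    def test_single_time_point_rejected(self):
        from seedfill.io import SampleDesign

        d = SampleDesign(("a", "b"), (25.0, 25.0), (1, 2))
        m = make_matrix(np.ones((1, 2)), d, scale="ln_centered")
        with pytest.raises(ValueError, match="two time points"):
            timecourse_ftest(m)

    def test_missing_cells_fit_on_observed_samples(self, design_5x2, rng):
        vals = rng.normal(size=(2, 10))
        vals[0, 0] = np.nan  # one missing replicate
        m = make_matrix(vals, design_5x2, scale="ln_centered")
        res = timecourse_ftest(m)
        assert not res["degenerate"].iloc[0]
        assert res["df_den"].iloc[0] < res["df_den"].iloc[1]

    def test_null_pvalues_uniform(self):
        spec = SimulationSpec(seed=11, n_trans=800, frac_null=1.0)
        _, trans, _ = simulate_timecourse(spec)
        from seedfill.differential import differential_analysis

        res, _, _ = differential_analysis(trans)
        ks = stats.kstest(res["p"], "uniform")
        assert ks.pvalue > 0.01


class TestStoreyQ:
    def test_single_pvalue(self):
        assert storey_q([0.05], QValueSettings("fixed_1"))[0] == pytest.approx(0.05)

    def test_step_down_minimum_hand_example(self):
        q = storey_q([0.01, 0.02, 0.03, 0.04], QValueSettings("fixed_1"))
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_order_invariance(self, rng):
        p = rng.uniform(size=200)
        perm = rng.permutation(200)
        q = storey_q(p)
        q_perm = storey_q(p[perm])
        np.testing.assert_allclose(q_perm, q[perm])

    def test_monotone_in_ranked_p_and_bounded(self, rng):
        p = rng.uniform(size=500) ** 2
        q = storey_q(p)
        assert (q <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_pi0_one_equals_benjamini_hochberg(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=300) ** 3
        q = storey_q(p, QValueSettings("fixed_1"))
        bh = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(q, bh, atol=1e-12)

    def test_lambda_pi0_shrinks_q(self, rng):
        p = np.concatenate([rng.uniform(size=100) * 1e-4, rng.uniform(size=100)])
        q1 = storey_q(p, QValueSettings("fixed_1"))
        q2 = storey_q(p, QValueSettings("lambda_0.5"))
        assert (q2 <= q1 + 1e-12).all()

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            storey_q([])
        with pytest.raises(ValueError):
            storey_q([0.5, 1.5])

    def test_fdr_control_with_ten_percent_signals(self):
        from seedfill.differential import differential_analysis

        fdps = []
        for seed in range(20):
            spec = SimulationSpec(seed=300 + seed, n_trans=600, frac_null=0.9)
            _, trans, truth = simulate_timecourse(spec)
            res, _, _ = differential_analysis(trans)
            sel = res.index[res["q"] < 0.05]
            fdps.append(float(truth.is_null_trans.loc[sel].mean()) if len(sel) else 0.0)
        assert np.mean(fdps) <= 0.075
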