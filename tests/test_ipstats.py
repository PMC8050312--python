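import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

import pincontrol as pc
from pincontrol.common import Condition, Definition, Direction, Group, Limb
from pincontrol.ipstats import (
    CorrelationResult,
    fisher_aggregate,
    fisher_z,
    kinematic_ip_corr,
    kinetic_ip_corr,
    pearson_r,
    results_to_frame,
    summary_table,
)
from pincontrol.kinematics import CoMSeries
from pincontrol.kinetics import CoPSeries


def textbook_pearson(x, y):
    """Independent oracle: the raw textbook formula."""
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxx = sum(v * v for v in x)
    syy = sum(v * v for v in y)
    sxy = sum(a * b for a, b in zip(x, y))
    num = n * sxy - sx * sy
    den = ((n * sxx - sx**2) * (n * syy - sy**2)) ** 0.5
    return num / den


class TestPearson:
    def test_matches_textbook_formula(self, rng):
        x = rng.normal(size=500)
        y = 0.3 * x + rng.normal(size=500)
        assert pearson_r(x, y) == pytest.approx(textbook_pearson(x, y), abs=1e-12)

    def test_matches_scipy(self, rng):
        x = rng.normal(size=200)
        y = rng.normal(size=200)
        assert pearson_r(x, y) == pytest.approx(
            sps.pearsonr(x, y).statistic, abs=1e-12
        )

    def test_zero_variance_raises(self):
        with pytest.raises(pc.DegenerateTrialError, match="zero variance"):
            pearson_r(np.ones(10), np.arange(10.0))

    @given(
        a=st.floats(-5, 5).filter(lambda v: abs(v) > 1e-3),
        b=st.floats(-5, 5),
        c=st.floats(-5, 5).filter(lambda v: abs(v) > 1e-3),
        d=st.floats(-5, 5),
    )
    @settings(max_examples=60, deadline=None)
    def test_scale_offset_invariance(self, a, b, c, d):
        rng = np.random.default_rng(5)
        x = rng.normal(size=100)
        y = rng.normal(size=100) + 0.5 * x
        base = pearson_r(x, y)
        trans = pearson_r(a * x + b, c * y + d)
        assert trans == pytest.approx(np.sign(a * c) * base, abs=1e-9)


class TestKineticCorr:
    def test_noiseless_pendulum_minus_one(self, noiseless_trial):
        res = kinetic_ip_corr(
            noiseless_trial.truth_total_cop,
            noiseless_trial.truth_com,
            Direction.AP,
            limb=Limb.TOTAL,
            condition=Condition.EO,
            group=Group.TPU,
        )
        assert res.r == pytest.approx(-1.0, abs=1e-6)

    def test_constant_series_degenerate(self):
        cop = CoPSeries(x=np.full(100, 0.1), y=np.zeros(100))
        com = CoMSeries(position=np.full((100, 2), 0.05), fs=100.0,
                        acceleration=np.zeros((100, 2)))
        with pytest.raises(pc.DegenerateTrialError):
            kinetic_ip_corr(cop, com, Direction.AP, Limb.TOTAL,
                            Condition.EO, Group.TPU)

    def test_matches_direct_formula(self, default_trial):
        res = kinetic_ip_corr(
            default_trial.truth_total_cop,
            default_trial.truth_com,
            Direction.ML,
            limb=Limb.TOTAL,
            condition=Condition.EO,
            group=Group.TPU,
        )
        d = default_trial.truth_total_cop.y - default_trial.truth_com.position[:, 1]
        acc = default_trial.truth_com.acceleration[:, 1]
        assert res.r == pytest.approx(textbook_pearson(d, acc), abs=1e-12)

    def test_masked_samples_excluded(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=100)
        acc = -x + rng.normal(0, 0.1, 100)
        mask = np.ones(100, bool)
        mask[:10] = False
        xm = x.copy()
        xm[:10] = np.nan
        cop = CoPSeries(x=xm, y=np.zeros(100), valid_mask=mask)
        com = CoMSeries(position=np.zeros((100, 2)), fs=100.0,
                        acceleration=np.column_stack([acc, acc]))
        res = kinetic_ip_corr(cop, com, Direction.AP, Limb.TOTAL,
                              Condition.EO, Group.TPU)
        assert res.n_samples == 90
        assert res.r == pytest.approx(textbook_pearson(x[10:], acc[10:]), abs=1e-12)


class TestKinematicCorr:
    def test_rigid_pendulum_plus_one(self):
        heights = np.array([0.4, 0.8, 1.2, 1.6])
        res = kinematic_ip_corr(heights, 0.05 * heights, Direction.AP,
                                Condition.EO, Group.TPU)
        assert res.r == pytest.approx(1.0, abs=1e-9)

    def test_pure_translation_degenerate(self):
        heights = np.array([0.4, 0.8, 1.2])
        with pytest.raises(pc.DegenerateTrialError):
            kinematic_ip_corr(heights, np.full(3, 0.05), Direction.AP,
                              Condition.EO, Group.TPU)

    def test_matches_direct_formula(self, rng):
        heights = rng.uniform(0.1, 1.8, 20)
        movement = 0.02 * heights + rng.normal(0, 0.002, 20)
        res = kinematic_ip_corr(heights, movement, Direction.ML,
                                Condition.EC, Group.AB_CONSTRAINED)
        assert res.r == pytest.approx(
            textbook_pearson(heights, movement), abs=1e-12
        )


class TestFisher:
    def test_zeros(self):
        mean, lo, hi = fisher_aggregate([0.0, 0.0, 0.0])
        assert mean == 0.0 and lo == pytest.approx(-hi)

    def test_single_value_no_ci(self):
        mean, lo, hi = fisher_aggregate([0.5])
        assert mean == pytest.approx(0.5) and lo is None and hi is None

    def test_matches_arctanh_chain(self):
        rs = [0.2, 0.4, 0.6]
        z = np.arctanh(rs)
        mz = z.mean()
        half = sps.t.ppf(0.975, 2) * z.std(ddof=1) / np.sqrt(3)
        mean, lo, hi = fisher_aggregate(rs)
        assert mean == pytest.approx(np.tanh(mz), abs=1e-12)
        assert lo == pytest.approx(np.tanh(mz - half), abs=1e-12)
        assert hi == pytest.approx(np.tanh(mz + half), abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            fisher_aggregate([])

    def test_unit_r_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            mean, _, _ = fisher_aggregate([1.0, 0.5])
        assert mean < 1.0

    @given(st.floats(-0.999, 0.999))
    @settings(max_examples=100)
    def test_round_trip(self, r):
        assert np.tanh(fisher_z(r)) == pytest.approx(r, abs=1e-12)


def make_results(n_subjects, group, rng, definitions=(Definition.KINETIC,),
                 trials=3):
    out = []
    for s in range(n_subjects):
        for cond in Condition:
            for t in range(trials):
                for direction in Direction:
                    for definition in definitions:
                        limbs = (
                            [Limb.CONSTRAINED, Limb.UNCONSTRAINED, Limb.TOTAL]
                            if definition is Definition.KINETIC
                            else [None]
                        )
                        for limb in limbs:
                            out.append(CorrelationResult(
                                r=float(rng.uniform(-0.9, 0.9)),
                                n_samples=6000,
                                direction=direction,
                                limb=limb,
                                definition=definition,
                                condition=cond,
                                group=group,
                                subject_id=f"{group.value}-S{s}",
                                trial_id=f"{cond.value}-T{t}",
                            ))
    return out


class TestSummaryTable:
    def test_full_design_row_counts(self, rng):
        results = (
            make_results(8, Group.TPU, rng,
                         (Definition.KINETIC, Definition.KINEMATIC))
            + make_results(7, Group.AB_CONSTRAINED, rng,
                           (Definition.KINETIC, Definition.KINEMATIC))
        )
        table = summary_table(results)
        kinetic = table[table.definition == "kinetic"]
        kinematic = table[table.definition == "kinematic"]
        assert len(kinetic) == 2 * 2 * 3 * 3
        assert len(kinematic) == 2 * 2 * 3
        assert set(kinetic.n_subjects) == {8, 7}

    def test_identical_inputs_zero_width(self, rng):
        results = make_results(4, Group.TPU, rng)
        for res in results:
            res.r = 0.42
        table = summary_table(results)
        assert np.allclose(table.mean_r, 0.42, atol=1e-12)
        assert np.allclose(table.ci_low, 0.42, atol=1e-9)
        assert np.allclose(table.ci_high, 0.42, atol=1e-9)

    def test_two_stage_matches_brute_force(self, rng):
        results = make_results(5, Group.TPU, rng)
        table = summary_table(results)
        # brute-force recomputation of one cell
        cell = [
            r for r in results
            if r.direction is Direction.AP and r.limb is Limb.TOTAL
            and r.condition is Condition.EC
        ]
        subj_z = {}
        for r in cell:
            subj_z.setdefault(r.subject_id, []).append(np.arctanh(r.r))
        subj_r = [np.tanh(np.mean(v)) for v in subj_z.values()]
        z = np.arctanh(subj_r)
        expected = np.tanh(np.mean(z))
        got = table[
            (table.direction == "AP") & (table.limb == Limb.TOTAL.value)
            & (table.condition == "EC")
        ].mean_r.iloc[0]
        assert got == pytest.approx(expected, abs=1e-12)

    def test_pooled_mode_differs_in_ci(self, rng):
        # with a balanced design the two pooling orders share the mean but
        # not the confidence interval (different effective sample size)
        results = make_results(5, Group.TPU, rng)
        a = summary_table(results, two_stage=True)
        b = summary_table(results, two_stage=False)
        assert np.allclose(a.mean_r, b.mean_r, atol=1e-12)
        width_a = (a.ci_high - a.ci_low).to_numpy()
        width_b = (b.ci_high - b.ci_low).to_numpy()
        assert not np.allclose(width_a, width_b)

    def test_ci_brackets_mean(self, rng):
        table = summary_table(make_results(6, Group.TPU, rng))
        ok = (table.ci_low <= table.mean_r) & (table.mean_r <= table.ci_high)
        assert ok.all()

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="no correlation"):
            summary_table([])


class TestAnalyzeTrial:
    def test_result_count_and_shape(self, short_trial):
        results = pc.analyze_trial(short_trial.recording)
        assert len(results) == 8  # 6 kinetic + 2 kinematic
        df = results_to_frame(results)
        assert set(df.definition) == {"kinetic", "kinematic"}
        assert df.r.between(-1, 1).all()

    def test_long_format_columns(self, short_trial):
        df = results_to_frame(pc.analyze_trial(short_trial.recording))
        assert {"definition", "direction", "group", "condition", "limb",
                "subject_id", "trial_id", "n_samples", "r"} <= set(df.columns)


class TestPendulumRatio:
    def test_known_ratio_recovered(self, default_trial):
        cfg = default_trial.config
        gh = cfg.pendulum.gravity / cfg.pendulum.com_height
        est = pc.ipstats.estimate_pendulum_ratio(default_trial.recording)
        assert est == pytest.approx(gh, rel=0.15)
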