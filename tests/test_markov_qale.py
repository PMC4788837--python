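import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from qaleplan import markov_qale as mk
from qaleplan.config import Calibration
from qaleplan.prostate_model import ToxicityOutputs, TumorControlOutputs


def constant_life_table(p, start_age=60):
    ages = np.arange(start_age, mk.MAX_AGE + 1)
    return mk.LifeTable(ages=ages, annual_death_prob=np.full(ages.size, p))


def quiet_tc(p_bned=0.75, p_dm_ctrl=0.05, p_dm_fail=0.3):
    return TumorControlOutputs(p_bned_5y=p_bned, p_dm_given_control=p_dm_ctrl,
                               p_dm_given_failure=p_dm_fail, p_lni=0.1)


NO_TOX = ToxicityOutputs(p_rectal=0.0, p_bladder=0.0)


class TestConversions:
    def test_rate_from_cumulative_hand_value(self):
        assert mk.annual_rate_from_cumulative(0.28, 5.0) == pytest.approx(
            -np.log(0.72) / 5, abs=1e-12)

    def test_analytic_inversion(self):
        p = 1 - np.exp(-5.0)
        assert mk.annual_rate_from_cumulative(p, 5.0) == pytest.approx(1.0, abs=1e-12)

    def test_prob_from_rate(self):
        assert mk.annual_prob_from_rate(0.0) == 0.0
        assert mk.annual_prob_from_rate(1.0) == pytest.approx(1 - 1 / np.e, abs=1e-12)

    @pytest.mark.parametrize("bad", [1.0, -0.1, 1.5])
    def test_cumulative_domain(self, bad):
        with pytest.raises(ValueError):
            mk.annual_rate_from_cumulative(bad, 5.0)

    def test_median_rate(self):
        assert mk.rate_from_median(19 / 12) == pytest.approx(np.log(2) * 12 / 19,
                                                             abs=1e-12)
        assert mk.rate_from_median(1e9) == pytest.approx(0.0, abs=1e-9)
        r = mk.rate_from_median(1.6)
        assert np.log(2) / r == pytest.approx(1.6, abs=1e-12)

    @given(st.floats(min_value=0.0, max_value=0.999),
           st.integers(min_value=1, max_value=10))
    def test_cumulative_round_trip(self, p_c, t):
        r = mk.annual_rate_from_cumulative(p_c, float(t))
        back = 1 - np.exp(-r * t)
        assert back == pytest.approx(p_c, abs=1e-12)

    def test_t1_round_trip_identity(self):
        for p in (0.0, 0.2, 0.8):
            r = mk.annual_rate_from_cumulative(p, 1.0)
            assert mk.annual_prob_from_rate(r) == pytest.approx(p, abs=1e-12)


class TestSchedule:
    @pytest.fixture()
    def schedule(self, calib, life_table):
        return mk.build_schedule(quiet_tc(), life_table, 60, calib)

    def test_bf_onset_window_closes(self, schedule):
        m5 = schedule.transition_matrix(5)
        m6 = schedule.transition_matrix(6)
        i, j = mk.STATES.index("POST_RT"), mk.STATES.index("BF_YEAR1")
        assert m5[i, j] > 0
        assert m6[i, j] == 0.0

    def test_late_rate_is_one_third_of_tunnel_rate(self, schedule):
        r_early = -np.log1p(-schedule.p_dm_bf_early_annual)
        r_late = -np.log1p(-schedule.p_dm_bf_late_annual)
        assert r_late == pytest.approx(r_early / 3, rel=1e-12)

    def test_dm_entry_cut_at_15_years(self, schedule):
        j = mk.STATES.index("DM")
        m = schedule.transition_matrix(16)  # starts 15 years post-RT
        for s in ("POST_RT", "BF_YEAR1", "BF_YEAR2", "BF_YEAR3", "BF_LATE"):
            assert m[mk.STATES.index(s), j] == 0.0
        m15 = schedule.transition_matrix(15)
        assert m15[mk.STATES.index("BF_LATE"), j] > 0

    def test_tunnel_states_never_self_transition(self, schedule):
        for t in range(1, schedule.n_cycles + 1):
            m = schedule.transition_matrix(t)
            for s in mk.TUNNEL_STATES:
                assert m[mk.STATES.index(s), mk.STATES.index(s)] == 0.0

    def test_rows_stochastic_every_cycle(self, schedule):
        for t in range(1, schedule.n_cycles + 1):
            m = schedule.transition_matrix(t)
            np.testing.assert_allclose(m.sum(axis=1), 1.0, atol=1e-12)

    def test_life_table_must_cover_horizon(self, calib):
        short = mk.LifeTable(ages=np.arange(60, 80),
                             annual_death_prob=np.full(20, 0.01))
        with pytest.raises(KeyError):
            mk.build_schedule(quiet_tc(), short, 60, calib)


class TestCohort:
    def test_absorbing_free_cohort_stays_put(self, calib):
        lt = constant_life_table(0.0)
        tc = TumorControlOutputs(p_bned_5y=1.0 - 1e-15, p_dm_given_control=0.0,
                                 p_dm_given_failure=0.0, p_lni=0.0)
        trace = mk.run_cohort(mk.build_schedule(tc, lt, 60, calib))
        assert trace.occupancy[-1, mk.STATES.index("POST_RT")] == pytest.approx(1.0)

    def test_constant_hazard_matches_geometric_sum(self, calib):
        p = 0.5
        lt = constant_life_table(p)
        tc = TumorControlOutputs(p_bned_5y=1.0 - 1e-15, p_dm_given_control=0.0,
                                 p_dm_given_failure=0.0, p_lni=0.0)
        trace = mk.run_cohort(mk.build_schedule(tc, lt, 60, calib))
        le = mk.qale(trace, mk.UtilitySet.from_calibration(calib, "all_ones"),
                     NO_TOX).life_expectancy
        assert le == pytest.approx((1 - p) / p, abs=1e-9)

    def test_occupancy_conserved_and_dead_monotone(self, calib, life_table):
        trace = mk.run_cohort(mk.build_schedule(quiet_tc(), life_table, 60, calib))
        np.testing.assert_allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-9)
        dead = trace.occupancy[:, mk.STATES.index("DEAD")]
        assert np.all(np.diff(dead) >= -1e-15)

    def test_monte_carlo_agrees_with_deterministic(self, calib, life_table):
        schedule = mk.build_schedule(quiet_tc(), life_table, 60, calib)
        det = mk.run_cohort(schedule)
        n = 100_000
        mc = mk.run_cohort(schedule, mode="monte_carlo", cohort_size=n, seed=11)
        u = mk.UtilitySet.from_calibration(calib, "all_ones")
        le_det = mk.qale(det, u, NO_TOX).life_expectancy
        le_mc = mk.qale(mc, u, NO_TOX).life_expectancy
        # individual lifetime variance from the deterministic death distribution
        dead = np.concatenate([[0.0], det.occupancy[:, mk.STATES.index("DEAD")]])
        inc = np.diff(dead)
        years = np.arange(det.occupancy.shape[0])  # years lived if dying in cycle t+1
        survivors = 1.0 - dead[-1]
        mean = float(years @ inc + survivors * det.occupancy.shape[0])
        var = float((years - mean) ** 2 @ inc
                    + survivors * (det.occupancy.shape[0] - mean) ** 2)
        se = np.sqrt(var / n)
        assert abs(le_mc - le_det) < 3 * se

    def test_monte_carlo_seed_contract(self, calib, life_table):
        schedule = mk.build_schedule(quiet_tc(), life_table, 60, calib)
        a = mk.run_cohort(schedule, mode="monte_carlo", cohort_size=500, seed=3)
        b = mk.run_cohort(schedule, mode="monte_carlo", cohort_size=500, seed=3)
        np.testing.assert_array_equal(a.occupancy, b.occupancy)

    def test_bad_cohort_size(self, calib, life_table):
        schedule = mk.build_schedule(quiet_tc(), life_table, 60, calib)
        with pytest.raises(ValueError):
            mk.run_cohort(schedule, mode="monte_carlo", cohort_size=0)


class TestQale:
    @pytest.fixture()
    def trace(self, calib, life_table):
        return mk.run_cohort(mk.build_schedule(quiet_tc(), life_table, 60, calib))

    def test_all_ones_equals_life_expectancy(self, trace, calib):
        u = mk.UtilitySet.from_calibration(calib, "all_ones")
        res = mk.qale(trace, u, ToxicityOutputs(p_rectal=0.3, p_bladder=0.2))
        assert res.qale == pytest.approx(res.life_expectancy, abs=1e-12)

    def test_zero_utilities_zero_qale(self, trace):
        u = mk.UtilitySet(state_utilities={s: 0.0 for s in mk.ALIVE_STATES},
                          disutility_rectal=1.0, disutility_bladder=1.0,
                          attitude="population_average")
        assert mk.qale(trace, u, NO_TOX).qale == 0.0

    def test_no_toxicity_removes_complication_penalty(self, trace, calib):
        u = mk.UtilitySet.from_calibration(calib, "population_average")
        res = mk.qale(trace, u, NO_TOX)
        occ = trace.occupancy
        want = sum(
            float(occ[:, mk.STATES.index(s)].sum()) * u.state_utilities[s]
            for s in mk.ALIVE_STATES)
        assert res.qale == pytest.approx(want, abs=1e-12)

    def test_qale_monotone_in_utilities_and_toxicity(self, trace, calib):
        base_u = mk.UtilitySet.from_calibration(calib, "population_average")
        base = mk.qale(trace, base_u, ToxicityOutputs(p_rectal=0.2, p_bladder=0.1))
        worse_tox = mk.qale(trace, base_u,
                            ToxicityOutputs(p_rectal=0.4, p_bladder=0.1))
        assert worse_tox.qale <= base.qale
        better_u = mk.UtilitySet(
            state_utilities={s: min(1.0, u + 0.02)
                             for s, u in base_u.state_utilities.items()},
            disutility_rectal=base_u.disutility_rectal,
            disutility_bladder=base_u.disutility_bladder,
            attitude="population_average")
        assert mk.qale(trace, better_u,
                       ToxicityOutputs(p_rectal=0.2, p_bladder=0.1)).qale >= base.qale

    def test_worse_control_never_extends_life(self, calib, life_table):
        les = []
        for p_bned in (0.9, 0.7, 0.5, 0.3):
            trace = mk.run_cohort(mk.build_schedule(quiet_tc(p_bned=p_bned),
                                                    life_table, 60, calib))
            u = mk.UtilitySet.from_calibration(calib, "all_ones")
            les.append(mk.qale(trace, u, NO_TOX).life_expectancy)
        assert np.all(np.diff(les) <= 1e-12)

    def test_missing_state_utility_rejected(self):
        with pytest.raises(ValueError):
            mk.UtilitySet(state_utilities={"POST_RT": 1.0},
                          disutility_rectal=1.0, disutility_bladder=1.0,
                          attitude="population_average")


class TestLifeTableIo:
    def test_csv_round_trip(self, tmp_path, life_table):
        path = tmp_path / "lt.csv"
        life_table.to_csv(path)
        back = mk.LifeTable.from_csv(path)
        np.testing.assert_array_equal(back.ages, life_table.ages)
        np.testing.assert_allclose(back.annual_death_prob,
                                   life_table.annual_death_prob)

    def test_trace_export(self, tmp_path, calib, life_table):
        trace = mk.run_cohort(mk.build_schedule(quiet_tc(), life_table, 60, calib))
        path = tmp_path / "trace.csv"
        trace.to_csv(path)
        import pandas as pd
        df = pd.read_csv(path, index_col="cycle")
        assert list(df.columns) == list(mk.STATES)
        np.testing.assert_allclose(df.to_numpy(), trace.occupancy)
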