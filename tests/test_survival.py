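"""Caliper volumes, RTV, progression events, and KM/log-rank comparisons."""

import itertools

import numpy as np
import pytest

from synletscreen import simulate
from synletscreen.errors import EndpointError, GroupingError
from synletscreen.survival import (
    SurvivalRecord,
    TumorTrajectory,
    caliper_volume,
    km_logrank,
    pfs_event,
    rtv_series,
)

# Worked 6-animal fixture for the log-rank permutation check: interleaved
# event days, every animal progresses.
FIXTURE_ARM_A = (3.0, 7.0, 28.0)
FIXTURE_ARM_B = (10.0, 17.0, 21.0)


def trajectory(days, volumes, arm="a", animal="m1", **kw):
    # render volumes as L = W cubes of the right volume: V = 0.5 * L^3
    side = (2.0 * np.asarray(volumes, dtype=float)) ** (1.0 / 3.0)
    return TumorTrajectory(
        animal=animal, arm=arm, days=np.asarray(days, float),
        lengths_mm=side, widths_mm=side, **kw,
    )


class TestVolume:
    @pytest.mark.parametrize(
        "length,width,expected",
        [(10.0, 5.0, 125.0), (2.0, 2.0, 4.0), (6.7, 5.5, 101.3375)],
    )
    def test_half_l_w_squared(self, length, width, expected):
        assert caliper_volume(length, width) == pytest.approx(expected)

    def test_swapped_calipers_warn_and_correct(self):
        with pytest.warns(UserWarning, match="swapping"):
            v = caliper_volume(5.0, 10.0)
        assert v == pytest.approx(125.0)


class TestRTV:
    def test_normalized_to_day_zero(self):
        t = trajectory([0, 7, 14], [100.0, 250.0, 1000.0])
        assert [r for _, r in rtv_series(t)] == pytest.approx([1.0, 2.5, 10.0])

    def test_constant_volume_is_unity(self):
        t = trajectory([0, 3, 7], [80.0, 80.0, 80.0])
        assert [r for _, r in rtv_series(t)] == pytest.approx([1.0, 1.0, 1.0])

    def test_missing_day_zero_is_endpoint_error(self):
        t = trajectory([3, 7], [100.0, 200.0])
        with pytest.raises(EndpointError, match="day-0"):
            rtv_series(t)

    def test_exponential_trajectory_matches_growth_rate(self):
        (t,) = simulate.gen_growth_trajectories(
            n_per_arm=1, growth_rates={"v": 0.11}, sigma_log=0.0, seed=1
        )
        for day, rtv in rtv_series(t):
            assert rtv == pytest.approx(np.exp(0.11 * day), rel=1e-9)


class TestPFS:
    def test_event_at_first_crossing(self):
        t = trajectory([0, 7, 14], [100.0, 250.0, 1000.0])
        rec = pfs_event(t)
        assert rec.event and rec.time == 14.0

    def test_censored_at_last_day_without_crossing(self):
        t = trajectory([0, 30, 60], [100.0, 200.0, 400.0])
        rec = pfs_event(t)
        assert not rec.event and rec.time == 60.0

    def test_no_interpolation_before_observed_crossing(self):
        t = trajectory([0, 4], [100.0, 1200.0])
        rec = pfs_event(t)
        assert rec.event and rec.time == 4.0

    def test_censor_day_honored(self):
        t = trajectory([0, 7], [100.0, 300.0], censor_day=16.0, censor_reason="open tumor")
        rec = pfs_event(t)
        assert not rec.event and rec.time == 16.0 and rec.censor_reason == "open tumor"

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            vols = 100.0 * np.cumprod(np.concatenate([[1.0], rng.uniform(0.9, 2.0, 8)]))
            t = trajectory(np.arange(0, 9 * 4, 4), vols)
            times = [pfs_event(t, thr).time for thr in (2.0, 5.0, 10.0, 20.0)]
            assert times == sorted(times)


def _logrank_stat(times, events, groups):
    """Independent brute-force unweighted log-rank chi-square."""
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    groups = np.asarray(groups)
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(times[events]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (groups == groups[0])).sum()
        d = (events & (times == t)).sum()
        d1 = (events & (times == t) & (groups == groups[0])).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var if var > 0 else 0.0


class TestKMLogrank:
    def _records(self, times_a, times_b, events_a=None, events_b=None):
        events_a = events_a or [True] * len(times_a)
        events_b = events_b or [True] * len(times_b)
        recs = [
            SurvivalRecord(f"a{i}", "A", t, e) for i, (t, e) in enumerate(zip(times_a, events_a))
        ]
        recs += [
            SurvivalRecord(f"b{i}", "B", t, e) for i, (t, e) in enumerate(zip(times_b, events_b))
        ]
        return recs

    def test_identical_arms_give_null_statistic(self):
        res = km_logrank(self._records([5, 10, 15], [5, 10, 15]))
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p_value == pytest.approx(1.0)

    def test_arm_label_swap_symmetric(self):
        res1 = km_logrank(self._records(FIXTURE_ARM_A, FIXTURE_ARM_B))
        res2 = km_logrank(self._records(FIXTURE_ARM_B, FIXTURE_ARM_A))
        assert res1.statistic == pytest.approx(res2.statistic)

    def test_km_equals_empirical_survival_without_censoring(self):
        times = [4.0, 8.0, 8.0, 15.0, 21.0]
        recs = [SurvivalRecord(f"m{i}", "A", t, True) for i, t in enumerate(times)]
        recs.append(SurvivalRecord("x", "B", 30.0, True))  # second arm to satisfy the API
        res = km_logrank(recs, arms=("A", "B"))
        curve = res.curves["A"]
        for _, row in curve.iterrows():
            empirical = np.mean(np.asarray(times) > row["time"])
            assert row["survival"] == pytest.approx(empirical, abs=1e-12)

    def test_empty_arm_rejected(self):
        recs = [SurvivalRecord("m", "A", 5.0, True)]
        with pytest.raises(GroupingError):
            km_logrank(recs, arms=("A", "B"))

    def test_p_agrees_with_permutation_oracle(self):
        # 10,000 seeded label permutations of the printed 6-animal fixture;
        # tolerance covers Monte-Carlo error plus the small-sample gap
        # between the chi-square approximation and the exact permutation
        # distribution (only C(6,3) = 20 label splits exist)
        times = np.array(FIXTURE_ARM_A + FIXTURE_ARM_B)
        events = np.ones(6, bool)
        groups = np.array(["A"] * 3 + ["B"] * 3)
        observed = _logrank_stat(times, events, groups)
        rng = np.random.default_rng(0)
        hits = 0
        n_perm = 10_000
        for _ in range(n_perm):
            perm = rng.permutation(6)
            if _logrank_stat(times, events, groups[perm]) >= observed - 1e-12:
                hits += 1
        p_perm = hits / n_perm
        res = km_logrank(self._records(FIXTURE_ARM_A, FIXTURE_ARM_B))
        assert abs(res.p_value - p_perm) < 0.02

    def test_slower_arm_survives_longer(self):
        # distinct growth rates: the slower arm's median PFS must exceed
        # the faster arm's in nearly every seeded replicate
        wins = 0
        for seed in range(100):
            trajectories = simulate.gen_growth_trajectories(
                n_per_arm=6, growth_rates={"fast": 0.12, "slow": 0.06},
                sigma_log=0.1, seed=500 + seed,
            )
            recs = [pfs_event(t) for t in trajectories]
            med = {
                arm: np.median([r.time for r in recs if r.arm == arm])
                for arm in ("fast", "slow")
            }
            wins += med["slow"] > med["fast"]
        assert wins >= 95
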