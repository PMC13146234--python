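"""Eligibility funnel: business hours, fixed OUIs, episode building, dwell screen."""
import datetime as dt
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from smokesense.config import JST, ScenarioConfig
from smokesense.preprocess import (
    apply_dwell_screen,
    build_episodes,
    compute_funnel,
    filter_business_hours,
    identify_fixed_ouis,
    run_preprocess,
)
from smokesense.simulate import generate_scenario

from conftest import flat_rates

ZERO = tuple([0.0] * 24)


def _records(rows):
    """rows: (offset_seconds_from_midnight, device_id, oui, rssi)"""
    base = dt.datetime(2023, 10, 28, tzinfo=JST)
    return pd.DataFrame(
        {
            "timestamp": [base + dt.timedelta(seconds=s) for s, *_ in rows],
            "device_id": [r[1] for r in rows],
            "oui": [r[2] for r in rows],
            "rssi": [r[3] for r in rows],
        }
    )


class TestBusinessHours:
    def test_half_open_boundaries(self):
        rows = _records(
            [
                (9 * 3600 + 59 * 60 + 59, "d1", "A4B1C1", -60),
                (10 * 3600, "d2", "A4B1C1", -60),
                (21 * 3600 + 59 * 60 + 59, "d3", "A4B1C1", -60),
                (22 * 3600, "d4", "A4B1C1", -60),
            ]
        )
        kept = filter_business_hours(rows, (10, 22))
        assert list(kept["device_id"]) == ["d2", "d3"]

    def test_uniform_allday_emission_keeps_half_in_a_12h_window(self):
        # only fixed devices transmitting uniformly over 24 h -> ~50% retained
        cfg = ScenarioConfig(
            smoker_rate_per_hour=ZERO, passerby_rate_per_hour=ZERO
        )
        log, _ = generate_scenario(cfg, seed=2)
        kept = filter_business_hours(log, (10, 22))
        frac = len(kept) / len(log)
        # inter-burst gaps are exponential; the fraction concentrates near 0.5
        assert abs(frac - 0.5) < 0.03


class TestFixedOuis:
    def test_rule_restatement(self):
        rows = _records(
            [
                (3 * 3600, "fix", "00E04C", -70),
                (12 * 3600, "fix", "00E04C", -70),
                (12 * 3600, "ph", "A4B1C1", -60),
            ]
        )
        assert identify_fixed_ouis(rows, (10, 22)) == {"00E04C"}

    def test_simulated_roster_recovered_exactly(self, sim_day, small_scenario):
        log, _ = sim_day
        expected = {d.oui for d in small_scenario.fixed_devices}
        assert identify_fixed_ouis(log, small_scenario.business_hours) == expected

    def test_collateral_exclusion_of_shared_vendor_prefix(self):
        # a phone sharing an OUI with a fixed device is excluded too
        rows = _records(
            [
                (3 * 3600, "fix", "00E04C", -70),
                (12 * 3600, "phone", "00E04C", -60),
                (12 * 3600 + 30, "phone", "00E04C", -61),
            ]
        )
        fixed = identify_fixed_ouis(rows, (10, 22))
        human = rows[~rows["oui"].isin(fixed)]
        assert len(human) == 0

    def test_empty_input(self):
        assert identify_fixed_ouis(_records([]), (10, 22)) == set()


class TestBuildEpisodes:
    def test_single_gap_under_threshold_one_episode(self):
        rows = _records([(0, "d", "A4B1C1", -60), (300, "d", "A4B1C1", -62)])
        eps = build_episodes(rows, gap_threshold_s=600)
        assert len(eps) == 1
        assert eps["dwell_min"].iloc[0] == pytest.approx(5.0)
        assert eps["n_detections"].iloc[0] == 2

    def test_gap_over_threshold_splits_into_singletons_no_episode(self):
        rows = _records([(0, "d", "A4B1C1", -60), (700, "d", "A4B1C1", -62)])
        assert len(build_episodes(rows, gap_threshold_s=600)) == 0

    def test_single_detection_device_forms_no_episode(self):
        rows = _records([(0, "d", "A4B1C1", -60)])
        assert len(build_episodes(rows)) == 0


def brute_force_episodes(records, gap_threshold_s):
    """Independent oracle: sort, group by id, split on gaps, keep runs of >=2."""
    out = []
    for device_id in sorted(set(records["device_id"])):
        rows = sorted(
            records[records["device_id"] == device_id].itertuples(),
            key=lambda r: r.timestamp,
        )
        run = [rows[0]]
        runs = []
        for r in rows[1:]:
            if (r.timestamp - run[-1].timestamp).total_seconds() <= gap_threshold_s:
                run.append(r)
            else:
                runs.append(run)
                run = [r]
        runs.append(run)
        for chunk in runs:
            if len(chunk) >= 2:
                out.append(
                    (
                        device_id,
                        chunk[0].timestamp,
                        chunk[-1].timestamp,
                        len(chunk),
                        np.mean([r.rssi for r in chunk]),
                    )
                )
    return sorted(out, key=lambda e: (e[1], e[0]))


def _random_log(rng):
    n = rng.integers(2, 25)
    ids = [f"d{rng.integers(0, 5)}" for _ in range(n)]
    secs = rng.integers(0, 4000, size=n)
    order = np.argsort(secs, kind="stable")
    return _records(
        [(int(secs[i]), ids[i], "A4B1C1", int(rng.integers(-90, -40))) for i in order]
    )


def test_build_episodes_matches_brute_force_on_random_logs():
    rng = np.random.default_rng(2023)
    for _ in range(1000):
        gap = float(rng.choice([60, 300, 600]))
        log = _random_log(rng)
        got = build_episodes(log, gap)
        expected = brute_force_episodes(log, gap)
        assert len(got) == len(expected)
        for row, exp in zip(got.itertuples(), expected):
            assert row.device_id == exp[0]
            assert pd.Timestamp(row.start) == pd.Timestamp(exp[1])
            assert pd.Timestamp(row.end) == pd.Timestamp(exp[2])
            assert row.n_detections == exp[3]
            assert row.mean_rssi == pytest.approx(exp[4])


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    st.lists(
        st.tuples(
            st.integers(min_value=0, max_value=5000),
            st.sampled_from(["a", "b", "c"]),
        ),
        min_size=1,
        max_size=30,
    ),
    st.sampled_from([120.0, 600.0]),
)
def test_episode_partition_property(events, gap):
    """Episodes are per-device, time-disjoint, and cover only multi-detection runs."""
    events = sorted(events)
    log = _records([(s, d, "A4B1C1", -60) for s, d in events])
    eps = build_episodes(log, gap)
    assert (eps["n_detections"] >= 2).all()
    assert (eps["dwell_min"] >= 0).all()
    total = int(eps["n_detections"].sum()) if len(eps) else 0
    assert total <= len(log)
    for _, grp in eps.groupby("device_id"):
        starts = list(grp["start"])
        ends = list(grp["end"])
        for e_prev, s_next in zip(ends, starts[1:]):
            assert s_next > e_prev


class TestDwellScreen:
    def test_inclusive_boundary(self):
        eps = pd.DataFrame({"dwell_min": [6.0, 6.01], "device_id": ["a", "b"]})
        kept = apply_dwell_screen(eps, 6.0)
        assert list(kept["device_id"]) == ["a"]

    def test_empty_input(self):
        assert len(apply_dwell_screen(pd.DataFrame(columns=["dwell_min"]))) == 0

    def test_roughly_half_of_median_length_stays_survive(self):
        # smoker stays log-normal with median 6 min; dwell is slightly shorter
        # than the stay (first/last burst clipping), so retention sits a bit
        # above one half
        cfg = ScenarioConfig(
            smoker_rate_per_hour=flat_rates(40.0),
            passerby_rate_per_hour=ZERO,
            smoker_carriage_p=1.0,
            fixed_devices=(),
        )
        log, _ = generate_scenario(cfg, seed=9)
        eps = build_episodes(log)
        frac = len(apply_dwell_screen(eps, 6.0)) / len(eps)
        assert 0.4 < frac < 0.8


class TestFunnel:
    def test_published_style_stage_percentages(self):
        # an event-day funnel: 128,313 detections shrinking to 659 episodes
        funnel = compute_funnel(128_313, 115_950, 11_068, 1_817, 659)
        pct = funnel.percentages()
        assert pct["in_business_hours"] == 90.4
        assert pct["multi_detection_ids"] == 8.6
        assert pct["dwell_computable_ids"] == 1.4
        assert pct["eligible_episodes"] == 0.5

    def test_percentages_round_half_up(self):
        assert compute_funnel(1000, 905, 0, 0, 0).percentages()["in_business_hours"] == 90.5
        assert compute_funnel(200, 1, 0, 0, 0).percentages()["in_business_hours"] == 0.5

    def test_zero_total_yields_zero_percentages(self):
        assert all(v == 0.0 for v in compute_funnel(0, 0, 0, 0, 0).percentages().values())

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            compute_funnel(10, -1, 0, 0, 0)

    def test_funnel_monotone_on_simulated_day(self, sim_day, small_scenario):
        log, _ = sim_day
        _, _, funnel, _ = run_preprocess(log, small_scenario.business_hours)
        assert funnel.total_detections >= funnel.in_business_hours
        assert funnel.multi_detection_ids >= funnel.dwell_computable_ids
        assert funnel.dwell_computable_ids <= funnel.in_business_hours
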