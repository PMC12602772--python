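"""Generator properties: landscape realism knobs, survey layout, ground truth."""

import numpy as np
import pandas as pd
import pytest

from owlbaci import synthetic as syn
from owlbaci.covariates import _cells_within
from owlbaci.synthetic import HEX_SPACING


class TestLandscape:
    def test_zero_severity_request_yields_empty_burn(self):
        fire = syn.FireSpec(2020, (4000.0, 4000.0), 2000.0, 0.0)
        land = syn.simulate_landscape((8000, 8000), 20.0, [fire], seed=1)
        assert land.fires[0][1].sum() == 0

    def test_realized_severity_fraction_within_tolerance(self, tiny_landscape):
        for spec, mask in tiny_landscape.fires:
            foot = _cells_within(mask.shape, tiny_landscape.cell_size, (0, 0),
                                 spec.center, spec.radius)
            assert mask[foot].mean() == pytest.approx(spec.severity_frac, abs=0.05)
            assert set(np.unique(mask)) <= {0, 1}

    def test_footprint_outside_extent_is_an_error(self):
        fire = syn.FireSpec(2020, (9000.0, 1000.0), 500.0, 0.5)
        with pytest.raises(ValueError, match="outside extent"):
            syn.simulate_landscape((8000, 8000), 20.0, [fire], seed=1)

    def test_seeded_runs_are_bit_identical(self):
        fire = syn.FireSpec(2020, (4000.0, 4000.0), 2000.0, 0.5)
        a = syn.simulate_landscape((8000, 8000), 40.0, [fire], seed=9)
        b = syn.simulate_landscape((8000, 8000), 40.0, [fire], seed=9)
        assert np.array_equal(a.elevation, b.elevation)
        assert np.array_equal(a.seral, b.seral)
        assert np.array_equal(a.fires[0][1], b.fires[0][1])


class TestSurvey:
    def test_single_hexagon_has_two_separated_arus(self, tiny_landscape):
        d = syn.simulate_survey(tiny_landscape, n_hex=1, seed=3)
        assert len(d.arus) == 2
        a, b = d.arus.iloc[0], d.arus.iloc[1]
        assert np.hypot(a.x - b.x, a.y - b.y) >= 500.0

    def test_two_arus_per_hexagon_at_least_500m_apart(self, tiny_survey):
        for _, grp in tiny_survey.arus.groupby("hexagon"):
            assert len(grp) == 2
            (x1, y1), (x2, y2) = grp[["x", "y"]].to_numpy()
            assert np.hypot(x1 - x2, y1 - y2) >= 500.0

    def test_sampled_hexagons_share_no_edges(self, tiny_survey):
        xy = tiny_survey.hexagons[["x", "y"]].to_numpy()
        d2 = ((xy[:, None] - xy[None, :]) ** 2).sum(-1)
        np.fill_diagonal(d2, np.inf)
        assert np.sqrt(d2.min()) > 1.05 * HEX_SPACING

    def test_continuous_plan_is_one_35_day_interval(self, tiny_landscape):
        d = syn.simulate_survey(tiny_landscape, n_hex=2, seasons=(2022,),
                                deployment_plan={2022: "continuous"}, seed=4)
        for _, grp in d.deployments.groupby("aru_id"):
            assert len(grp) == 1
            iv = grp.iloc[0]
            assert (iv.end - iv.start) == pd.Timedelta(days=35)

    def test_pulsed_plan_is_three_weeks_with_14_day_gaps(self, tiny_landscape):
        d = syn.simulate_survey(tiny_landscape, n_hex=2, seasons=(2018,),
                                deployment_plan={2018: "pulsed"}, seed=4)
        for _, grp in d.deployments.groupby("aru_id"):
            grp = grp.sort_values("start")
            assert len(grp) == 3
            assert ((grp.end - grp.start) == pd.Timedelta(days=7)).all()
            gaps = grp.start.values[1:] - grp.end.values[:-1]
            assert (gaps >= np.timedelta64(14, "D")).all()

    def test_overfull_request_errors(self, tiny_landscape):
        with pytest.raises(ValueError, match="non-contiguous"):
            syn.simulate_survey(tiny_landscape, n_hex=500, seed=4)


class TestDetections:
    def test_unknown_model_is_an_error(self, tiny_survey, tiny_landscape, tiny_truth):
        with pytest.raises(ValueError, match="model_id"):
            syn.simulate_detections(tiny_survey, tiny_landscape, tiny_truth, "nope")

    def test_seeded_runs_are_identical(self, tiny_survey, tiny_landscape, tiny_truth):
        d1, _ = syn.simulate_detections(tiny_survey, tiny_landscape, tiny_truth,
                                        "bo_tc", seed=21)
        d2, _ = syn.simulate_detections(tiny_survey, tiny_landscape, tiny_truth,
                                        "bo_tc", seed=21)
        pd.testing.assert_frame_equal(d1, d2)

    def test_events_fall_inside_deployments_and_at_night(self, tiny_detections,
                                                         tiny_survey):
        det, _ = tiny_detections
        dep = tiny_survey.deployments
        for ev in det.itertuples():
            ts = pd.Timestamp(ev.timestamp)
            assert ts.hour >= 20 or ts.hour < 8
            mine = dep[(dep.aru_id == ev.aru_id) & (dep.season == ts.year)]
            assert ((mine.start <= ts) & (ts < mine.end)).any()

    def test_zero_detection_probability_yields_no_events(self, tiny_survey,
                                                         tiny_landscape):
        truth = syn.TruthParams(seed=31, det_intercept=-40.0, det_date=0.0,
                                det_ruggedness=0.0, det_hours=0.0, det_invader=0.0,
                                det_year={})
        truth.n_removals = 3
        det, info = syn.simulate_detections(tiny_survey, tiny_landscape, truth,
                                            "bo_tc", species="flammulated", seed=31)
        assert (det.species == "flammulated").sum() == 0
        assert info["z"].sum() > 0  # occupied sites existed, detection failed

    def test_null_model_occupancy_near_half(self, tiny_landscape):
        # logit(psi) = 0 with no random effects: occupancy frequency ~ 0.5
        design = syn.simulate_survey(tiny_landscape, n_hex=8, seed=5)
        truth = syn.TruthParams(seed=41, sigma_year=0.0, sigma_site=0.0)
        truth.occupancy_beta["fire_tc"] = np.array([0.0, 0.0, 0.0])
        truth.n_removals = 2
        zs = []
        for rep in range(16):  # 16 x 64 rows ~ 1000 site-years
            _, _, info = syn.simulate_encounter_data(
                design, tiny_landscape, truth, "fire_tc", seed=100 + rep)
            zs.append(info["z"])
        z = np.concatenate(zs)
        se = np.sqrt(0.25 / z.size)
        assert z.mean() == pytest.approx(0.5, abs=3 * se)

    def test_occupancy_frequencies_match_generating_probabilities(
            self, tiny_landscape):
        # fire model with sigma=0: empirical z frequencies track invlogit
        # values in burned and unburned strata (closed-form check)
        design = syn.simulate_survey(tiny_landscape, n_hex=8, seed=6)
        truth = syn.TruthParams(seed=43, sigma_year=0.0, sigma_site=0.0)
        truth.n_removals = 2
        zs, psis = [], []
        for rep in range(16):
            _, covs, info = syn.simulate_encounter_data(
                design, tiny_landscape, truth, "fire_tc", seed=200 + rep)
            zs.append(info["z"])
            psis.append(info["psi"])
        z, psi = np.concatenate(zs), np.concatenate(psis)
        burned = np.tile(covs["burn"].to_numpy() > 0, 16)
        for stratum in (burned, ~burned):
            n = stratum.sum()
            expected = psi[stratum].mean()
            se = np.sqrt(expected * (1 - expected) / n)
            assert z[stratum].mean() == pytest.approx(expected, abs=3 * se + 1e-9)


class TestScores:
    def test_labels_consistent_with_planted_true_calls(self):
        streams = syn.simulate_scores(syn.SpeciesScoreProfile(true_rate=2.0),
                                      n_hours=200, seed=8)
        assert np.mean([s.label for s in streams]) > 0.7
        for s in streams:
            assert s.scores.size == 0 or (0 <= s.scores).all() and (s.scores <= 1).all()

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            syn.simulate_scores(syn.SpeciesScoreProfile(true_rate=-1.0), 10, 0)

    def test_fp_week_simulation_matches_analytic_rate(self):
        profile = syn.SpeciesScoreProfile()
        tau = 0.8
        got = syn.simulate_fp_weeks(profile, tau, n_weeks=4000, seed=9)
        want = -np.expm1(-84 * profile.fp_rate * profile.fp_tail(tau))
        se = np.sqrt(want * (1 - want) / 4000)
        assert got == pytest.approx(want, abs=4 * se)
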