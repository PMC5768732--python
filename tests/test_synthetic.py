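"""Synthetic split-beam survey generator: determinism, Poisson placement,
truth bookkeeping and file round-trips."""

import dataclasses

import numpy as np
import pytest
from scipy import stats as sps

from acoustica import (
    SchoolEvent,
    SiteScenario,
    length_to_weight,
    read_survey,
    simulate_sed_from_fish,
    simulate_survey,
    simulate_transect,
    ts_to_length,
    write_survey,
)
from acoustica.synthetic import SurveyParseError, beam_diameter_m


class TestSimulateSed:
    def test_zero_noise_ts_matches_regression(self, rng):
        sed = simulate_sed_from_fish(10.0, 200.0, 0.0, rng)
        assert sed.ts_dB == pytest.approx(-44.97, abs=0.005)
        sed1 = simulate_sed_from_fish(1.0, 200.0, 0.0, rng)
        assert sed1.ts_dB == pytest.approx(-64.07, abs=0.005)

    def test_seeded_determinism(self):
        a = simulate_sed_from_fish(15.0, 200.0, 3.0, np.random.default_rng(5))
        b = simulate_sed_from_fish(15.0, 200.0, 3.0, np.random.default_rng(5))
        assert a == b

    def test_shape_fields_pass_default_filters(self, rng):
        for _ in range(50):
            sed = simulate_sed_from_fish(8.0, 200.0, 3.0, rng)
            assert 0.8 <= sed.echo_length_rel <= 1.2
            assert 0.0 <= sed.angle_sd_deg <= 0.8

    @pytest.mark.parametrize("length,freq", [(-1.0, 200.0), (0.0, 200.0), (5.0, 0.0)])
    def test_rejects_nonpositive_inputs(self, length, freq, rng):
        with pytest.raises(ValueError):
            simulate_sed_from_fish(length, freq, 1.0, rng)


class TestSimulateTransect:
    def test_zero_density_gives_empty_transect(self, shallow_scenario, rng):
        sc = dataclasses.replace(shallow_scenario, true_areal_density=0.0)
        pings, seds, truth = simulate_transect(sc, 300.0, rng=rng)
        assert seds == []
        assert truth.density_fish_ha == 0.0
        assert all(np.all(p.sv_profile == 0) for p in pings)

    def test_school_event_inflates_density(self, shallow_scenario):
        with_school = dataclasses.replace(
            shallow_scenario, school_event=SchoolEvent(25.0, 9.0, 20.0)
        )
        _, _, t_off = simulate_transect(
            shallow_scenario, 500.0, rng=np.random.default_rng(3)
        )
        _, _, t_on = simulate_transect(with_school, 500.0, rng=np.random.default_rng(3))
        assert t_on.density_fish_ha > t_off.density_fish_ha

    def test_realized_density_converges_to_intensity(self, shallow_scenario):
        densities = [
            simulate_transect(
                shallow_scenario, 200.0, rng=np.random.default_rng(1000 + i)
            )[2].density_fish_ha
            for i in range(200)
        ]
        assert np.mean(densities) == pytest.approx(500.0, rel=0.05)

    def test_fish_counts_are_poisson(self):
        """Chi-square goodness of fit of realized counts against Poisson at
        intensity × footprint, over 500 seeds (alpha = 0.01)."""
        sc = SiteScenario("P", "mixed", 500.0, np.log(12.0), 0.3, (25.0, 25.000001), 1)
        counts = np.array(
            [
                simulate_transect(sc, 200.0, rng=np.random.default_rng(i))[2].n_fish
                for i in range(500)
            ]
        )
        lam = 500.0 * (200.0 * beam_diameter_m(25.0 / 2.0)) / 1e4
        edges = np.arange(counts.min(), counts.max() + 2)
        obs = np.array([(counts == e).sum() for e in edges[:-1]], dtype=float)
        exp = sps.poisson.pmf(edges[:-1], lam) * counts.size
        # pool sparse tails so expected counts are >= 5
        keep = exp >= 5
        obs_p = np.concatenate([[obs[~keep].sum()], obs[keep]])
        exp_p = np.concatenate([[exp[~keep].sum()], exp[keep]])
        exp_p *= obs_p.sum() / exp_p.sum()
        stat, p = sps.chisquare(obs_p, exp_p)
        assert p > 0.01

    def test_truth_biomass_is_exact_weight_sum(self, shallow_scenario):
        _, seds, truth = simulate_transect(
            shallow_scenario, 400.0, rng=np.random.default_rng(9), ts_noise_sd_dB=0.0
        )
        lengths = ts_to_length(np.array([s.ts_dB for s in seds]))
        expected = length_to_weight(lengths).sum() * 1e-6 / (truth.footprint_m2 / 1e4)
        assert truth.biomass_t_ha == pytest.approx(expected, rel=1e-9)

    def test_degenerate_geometry_raises(self, shallow_scenario):
        with pytest.raises(ValueError):
            simulate_transect(shallow_scenario, 0.0)


class TestSurveyIO:
    def test_round_trip_identity(self, shallow_scenario, tmp_path):
        pings, seds, truths = simulate_survey([shallow_scenario], 7, 200.0)
        write_survey(pings, seds, truths, tmp_path)
        p2, s2, t2 = read_survey(tmp_path)
        assert len(p2) == len(pings) and len(s2) == len(seds)
        for a, b in zip(pings, p2):
            assert a.transect_id == b.transect_id
            np.testing.assert_allclose(a.sv_profile, b.sv_profile)
        assert s2 == seds
        assert t2 == truths

    def test_empty_survey_round_trips(self, tmp_path):
        write_survey([], [], [], tmp_path)
        pings, seds, truths = read_survey(tmp_path)
        assert pings == [] and seds == [] and truths == []

    def test_negative_range_is_a_parse_error(self, shallow_scenario, tmp_path):
        pings, seds, truths = simulate_survey([shallow_scenario], 7, 200.0)
        write_survey(pings, seds, truths, tmp_path)
        f = tmp_path / "survey_seds.csv"
        lines = f.read_text().splitlines()
        parts = lines[1].split(",")
        parts[2] = "-5.0"  # range_m
        lines[1] = ",".join(parts)
        f.write_text("\n".join(lines))
        with pytest.raises(SurveyParseError, match="line 2"):
            read_survey(tmp_path)

    def test_same_master_seed_reproduces_survey(self, shallow_scenario):
        _, s1, t1 = simulate_survey([shallow_scenario], 42, 200.0)
        _, s2, t2 = simulate_survey([shallow_scenario], 42, 200.0)
        assert s1 == s2 and t1 == t2
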