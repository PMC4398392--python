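"""Population thinning, ping synthesis physics, and the target-level fast path."""

import numpy as np
import pytest
from scipy.stats import norm

from echosurvey.beam import max_offaxis_angle_deg, two_way_gain_db
from echosurvey.detection import DetectionParams, detect_all
from echosurvey.simulate import (
    SimConfig,
    build_population,
    demo_config,
    simulate_pings,
    simulate_target_level,
    spectrum_counts,
)
from echosurvey.sizeclass import DEFAULT_SCHEME


class TestPopulation:
    def test_zero_rate_no_thinning(self):
        cfg = demo_config(3).replace(
            class_initial_counts={4: 500, 16: 200},
            per_class_loss_rate_per_day={4: 0.0, 16: 0.0},
        )
        assert build_population(cfg, 30).class_counts() == {4: 500, 16: 200}

    def test_thinned_count_within_binomial_interval(self):
        # N0=1673, rate -0.067, day 32: expectation ~196, 99% interval [162, 230]
        cfg = demo_config(11).replace(
            class_initial_counts={4: 1673}, per_class_loss_rate_per_day={4: -0.067}
        )
        n = build_population(cfg, 32).class_counts()[4]
        p = np.exp(-0.067 * 32)
        lo = 1673 * p - 3.29 * np.sqrt(1673 * p * (1 - p))
        hi = 1673 * p + 3.29 * np.sqrt(1673 * p * (1 - p))
        assert lo <= n <= hi

    def test_geometric_spectrum_construction(self):
        assert spectrum_counts(1, 3.0) == {4: 81, 8: 27, 16: 9, 32: 3, 64: 1}

    def test_nested_thinning_monotone_in_day(self):
        cfg = demo_config(5).replace(
            class_initial_counts={8: 800}, per_class_loss_rate_per_day={8: -0.05}
        )
        counts = [build_population(cfg, d).class_counts().get(8, 0) for d in (0, 10, 20, 30)]
        assert counts[0] == 800
        assert all(b <= a for a, b in zip(counts, counts[1:]))

    def test_lengths_and_ts_consistent_with_classes(self):
        pop = build_population(demo_config(1), 0)
        for lab, lo, hi in zip(
            DEFAULT_SCHEME.labels, DEFAULT_SCHEME.bounds_cm[:-1], DEFAULT_SCHEME.bounds_cm[1:]
        ):
            sel = pop.class_label == lab
            assert np.all((pop.length_cm[sel] >= lo) & (pop.length_cm[sel] < hi))

    def test_thinning_conservation_over_subpopulations(self):
        """Realized counts of two disjoint subpopulations sum, in
        distribution, to the whole-population realization (mean and
        variance over 200 seeds)."""
        day, rate, n_a, n_b = 20, -0.05, 300, 500
        sums, wholes = [], []
        for seed in range(200):
            ca = demo_config(seed).replace(
                class_initial_counts={8: n_a}, per_class_loss_rate_per_day={8: rate}
            )
            cb = demo_config(seed + 10_000).replace(
                class_initial_counts={8: n_b}, per_class_loss_rate_per_day={8: rate}
            )
            cw = demo_config(seed + 20_000).replace(
                class_initial_counts={8: n_a + n_b}, per_class_loss_rate_per_day={8: rate}
            )
            sums.append(
                build_population(ca, day).class_counts().get(8, 0)
                + build_population(cb, day).class_counts().get(8, 0)
            )
            wholes.append(build_population(cw, day).class_counts().get(8, 0))
        p = np.exp(rate * day)
        mean_se = np.sqrt((n_a + n_b) * p * (1 - p) / 200)
        assert abs(np.mean(sums) - (n_a + n_b) * p) < 4 * mean_se
        assert abs(np.mean(wholes) - (n_a + n_b) * p) < 4 * mean_se
        true_var = (n_a + n_b) * p * (1 - p)
        assert 0.65 < np.var(sums, ddof=1) / true_var < 1.5
        assert 0.65 < np.var(wholes, ddof=1) / true_var < 1.5


class TestPingSynthesis:
    def test_empty_population_is_noise(self, tiny_config):
        from echosurvey.simulate import FishPopulation

        z = np.empty(0)
        pop = FishPopulation(0, z, z, z, z, z, np.empty(0, dtype=int))
        pings = simulate_pings(pop, tiny_config, seed=2)
        for p in pings[:10]:
            water = p.range_grid_m < p.bottom_range_m_true - 0.5
            assert np.all(np.abs(p.ts_uncomp_db[water] - tiny_config.noise_floor_db) < 3 * 2.0 + 4)

    def test_on_axis_peak_reproduces_base_ts(self, tiny_config):
        from echosurvey.simulate import FishPopulation

        cfg = tiny_config.replace(mean_depth_m=20.0, noise_floor_db=-200.0, angle_noise_sd_deg=0.0)
        pop = FishPopulation(
            day=0,
            length_cm=np.array([20.0]),
            base_ts_db=np.array([-40.0]),
            depth_m=np.array([10.45]),
            x_m=np.array([2.5]),
            y_m=np.array([10.5 * cfg.ping_spacing_m]),  # directly under a ping
            class_label=np.array([16]),
        )
        pings = simulate_pings(pop, cfg, seed=1)

        def water_peak(p):  # exclude the bottom echo from the search
            sel = p.range_grid_m < 15.0
            return float(p.ts_uncomp_db[sel].max())

        peak = max(water_peak(p) for p in pings)
        # closest-approach ping: on-axis, so the peak sample ~= base TS
        assert peak == pytest.approx(-40.0, abs=0.15)
        best = max(pings, key=water_peak)
        sel = best.range_grid_m < 15.0
        level = water_peak(best) - 6.0
        above = best.range_grid_m[sel][best.ts_uncomp_db[sel] >= level]
        width = above.max() - above.min()
        assert width == pytest.approx(cfg.pulse_length_m, abs=3 * cfg.sample_interval_m)

    def test_config_error_when_max_range_above_bottom(self, tiny_config):
        from echosurvey.simulate import FishPopulation

        z = np.empty(0)
        pop = FishPopulation(0, z, z, z, z, z, np.empty(0, dtype=int))
        with pytest.raises(ValueError):
            simulate_pings(pop, tiny_config, seed=1, max_range_m=5.0)

    def test_detector_consistency_without_noise(self, tiny_config):
        """With noise and angle jitter disabled, every fish inside the
        compensation-limited beam is detected exactly once per insonifying
        ping (geometric oracle equivalence)."""
        from echosurvey.simulate import FishPopulation

        cfg = tiny_config.replace(noise_floor_db=-200.0, angle_noise_sd_deg=0.0)
        rng = np.random.default_rng(42)
        nf = 6
        pop = FishPopulation(
            day=0,
            length_cm=np.full(nf, 20.0),
            base_ts_db=rng.uniform(-48.0, -35.0, nf),
            depth_m=np.array([3.0, 4.3, 5.6, 6.9, 8.0, 8.8]),  # >1.5 m apart in range
            x_m=rng.uniform(2.0, 3.0, nf),
            y_m=rng.uniform(1.0, 9.0, nf),
            class_label=np.full(nf, 16),
        )
        pings = simulate_pings(pop, cfg, seed=3)
        params = DetectionParams()
        targets = detect_all(pings, params)
        # geometric oracle: expected (ping, fish) detections
        expected = 0
        for p in pings:
            x_t = 2.5 if p.transect_id == 0 else 7.5
            y_p = (p.ping_index % (len(pings) // 2) + 0.5) * cfg.ping_spacing_m
            for j in range(nf):
                dz = pop.depth_m[j] - cfg.transducer_draft_m
                tmi = np.degrees(np.arctan2(pop.y_m[j] - y_p, dz))
                tma = np.degrees(np.arctan2(pop.x_m[j] - x_t, dz))
                if max(abs(tmi), abs(tma)) >= cfg.half_power_beamwidth_deg:
                    continue
                comp = -two_way_gain_db(tmi, tma, cfg.half_power_beamwidth_deg)
                if comp <= params.max_beam_comp_db and pop.base_ts_db[j] >= params.ts_threshold_db:
                    expected += 1
        assert len(targets) == expected
        for t in targets:  # each detection matches a fish TS after compensation
            assert np.min(np.abs(pop.base_ts_db - t.ts_comp_db)) < 0.2

    def test_in_beam_count_matches_analytic_density(self):
        """Mean fish-in-beam per ping agrees with density x beam-cone volume."""
        cfg = SimConfig(
            seed=0,
            basin_area_km2=0.0004,  # 20 m x 20 m
            mean_depth_m=12.0,
            transect_spacing_m=10.0,
            class_initial_counts={16: 1200},
            per_class_loss_rate_per_day={16: 0.0},
            noise_floor_db=-200.0,
            angle_noise_sd_deg=0.0,
        )
        pop = build_population(cfg, 0)
        theta = max_offaxis_angle_deg(15.0, cfg.half_power_beamwidth_deg)
        pings = simulate_pings(pop, cfg, seed=9)
        # count in-beam fish geometrically per ping (the oracle)
        observed = []
        tx = cfg.transect_x_positions(0)
        per = int(np.floor(cfg.side_m / cfg.ping_spacing_m))
        for p in pings:
            x_t = tx[p.transect_id]
            y_p = (p.ping_index % per + 0.5) * cfg.ping_spacing_m
            dz = pop.depth_m - cfg.transducer_draft_m
            tmi = np.degrees(np.arctan2(pop.y_m - y_p, dz))
            tma = np.degrees(np.arctan2(pop.x_m - x_t, dz))
            inb = (np.abs(tmi) < theta) & (np.abs(tma) < theta)
            observed.append(int(inb.sum()))
        # analytic: fish uniform in [2, 12] m depth over the plot area
        density = 1200 / (cfg.side_m**2 * 10.0)
        t = np.tan(np.radians(theta))
        z1, z2 = 2.0 - 0.45, 12.0 - 0.45
        vol = (2 * t) ** 2 * (z2**3 - z1**3) / 3.0  # square-footprint pyramid slice
        expect = density * vol
        assert np.mean(observed) == pytest.approx(expect, rel=0.2)


class TestTargetLevel:
    def test_determinism(self):
        cfg = demo_config(2)
        pop = build_population(cfg, 7)
        a = simulate_target_level(pop, cfg, 7, seed=99)
        b = simulate_target_level(pop, cfg, 7, seed=99)
        assert [(t.ping_index, t.range_m, t.ts_comp_db) for t in a] == [
            (t.ping_index, t.range_m, t.ts_comp_db) for t in b
        ]

    def test_single_class_closure(self):
        from echosurvey.sizeclass import assign_size_class

        cfg = demo_config(4).replace(
            class_initial_counts={16: 3000},
            per_class_loss_rate_per_day={16: -0.03},
            ts_sd_db=0.2,  # keep TS scatter inside the 6 dB class band
            ts_measurement_sd_db=0.1,
        )
        pop = build_population(cfg, 0)
        targets = simulate_target_level(pop, cfg, 0, seed=5)
        labels = {assign_size_class(t.ts_comp_db) for t in targets}
        assert len(targets) > 50
        assert labels <= {8, 16, 32}
        inner = [t for t in targets if -40.0 < t.ts_comp_db < -36.5]
        assert all(assign_size_class(t.ts_comp_db) == 16 for t in inner)

    def test_counts_match_sampled_volume_expectation(self):
        """Mean emitted count over 100 seeds agrees with the brute-force
        per-fish detection probability (integrating the along-track angle
        over the ping cycle) within Monte-Carlo error."""
        cfg = demo_config(6).replace(
            basin_area_km2=0.01,  # 100 m x 100 m
            transect_spacing_m=10.0,
            class_initial_counts={16: 400},
            per_class_loss_rate_per_day={16: 0.0},
        )
        pop = build_population(cfg, 0)
        tx = cfg.transect_x_positions(0)
        dz = pop.depth_m - cfg.transducer_draft_m
        dx = np.abs(pop.x_m[:, None] - tx[None, :]).min(axis=1)
        tma = np.degrees(np.arctan2(dx, dz))
        p_ts = norm.sf(-52.6, loc=pop.base_ts_db, scale=cfg.ts_measurement_sd_db)
        dys = np.linspace(-cfg.ping_spacing_m / 2, cfg.ping_spacing_m / 2, 41)
        p_geom = np.zeros(len(pop))
        for j in range(len(pop)):
            tmi = np.degrees(np.arctan2(dys, dz[j]))
            ok = (np.abs(tmi) < cfg.half_power_beamwidth_deg) & (
                tma[j] < cfg.half_power_beamwidth_deg
            )
            comp = np.full(len(dys), np.inf)
            comp[ok] = -two_way_gain_db(tmi[ok], tma[j], cfg.half_power_beamwidth_deg)
            p_geom[j] = np.mean(comp <= 15.0)
        expect = float(np.sum(p_geom * p_ts))
        counts = [
            len(simulate_target_level(pop, cfg, 0, seed=s)) for s in range(100)
        ]
        se = np.sqrt(expect / 100) + np.std(counts) / np.sqrt(100)
        assert np.mean(counts) == pytest.approx(expect, abs=max(4 * se, 2.0))
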