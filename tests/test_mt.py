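"""Plus-end dynamic instability, nucleation, and the tubulin pool."""

import numpy as np
import pytest

from conftest import straight_mt
from myonuc.mt import (GROWING, SHRINKING, NucleationSite, TubulinPool,
                       catastrophe_rate, growth_speed, step_plus_end,
                       try_nucleate)

KIN = dict(v_grow0=0.2, v_shrink=0.4, fg=1.5, cat_time_free=600.0,
           cat_time_stalled=30.0)


class TestGrowthSpeed:
    def test_unloaded_full_pool(self):
        assert growth_speed(0.2, 0.0, 1.5, TubulinPool(100.0)) == \
            pytest.approx(0.2)

    def test_force_at_sensitivity_scale(self):
        v = growth_speed(0.2, 1.5, 1.5, TubulinPool(100.0))
        assert v == pytest.approx(0.2 / np.e)

    def test_exhausted_pool(self):
        pool = TubulinPool(100.0, L_polymerized=100.0)
        assert growth_speed(0.2, 0.0, 1.5, pool) == 0.0

    def test_negative_force_clamped(self):
        # assisting force does not speed growth beyond v0
        assert growth_speed(0.2, -3.0, 1.5, TubulinPool(100.0)) == \
            pytest.approx(0.2)


class TestCatastropheRate:
    def test_free_growth_limit(self):
        assert catastrophe_rate(0.2, 0.2, 600.0, 30.0) == \
            pytest.approx(1 / 600.0)

    def test_stalled_limit(self):
        assert catastrophe_rate(0.0, 0.2, 600.0, 30.0) == \
            pytest.approx(1 / 30.0)

    def test_linear_interpolation_at_half_speed(self):
        assert catastrophe_rate(0.1, 0.2, 600.0, 30.0) == \
            pytest.approx(1 / 315.0)

    def test_monotone_in_speed(self):
        rates = [catastrophe_rate(v, 0.2, 600.0, 30.0)
                 for v in np.linspace(0, 0.2, 20)]
        assert all(a >= b for a, b in zip(rates, rates[1:]))

    def test_bad_stalled_time(self):
        with pytest.raises(ValueError):
            catastrophe_rate(0.1, 0.2, 600.0, 0.0)


class TestStepPlusEnd:
    def test_growth_without_catastrophe(self):
        mt = straight_mt(5.0)
        pool = TubulinPool(1000.0, L_polymerized=5.0)
        rng = np.random.default_rng(0)
        out = step_plus_end(mt, pool, 0.01, rng,
                            v_grow0=0.2, v_shrink=0.4, fg=1.5,
                            cat_time_free=1e12, cat_time_stalled=1e12)
        assert out.plus_state == GROWING
        dL = 0.2 * (1 - 5.0 / 1000.0) * 0.01   # pool-attenuated growth
        assert out.length == pytest.approx(5.0 + dL)
        assert pool.L_polymerized == pytest.approx(5.0 + dL)

    def test_full_depolymerization_frees_site_and_pool(self):
        site = NucleationSite(host="nuc", position=(0.0, 0.0), occupied=True)
        mt = straight_mt(0.003)
        mt.anchor = site
        mt.plus_state = SHRINKING
        pool = TubulinPool(10.0, L_polymerized=0.003)
        out = step_plus_end(mt, pool, 0.01, np.random.default_rng(0), **KIN)
        assert out is None
        assert not site.occupied
        assert pool.L_polymerized == pytest.approx(0.0)

    def test_catastrophe_frequency_matches_closed_form(self):
        """Empirical catastrophe frequency over many one-step trials matches
        1 − exp(−rate·dt) within 3σ binomial."""
        rng = np.random.default_rng(42)
        dt, n = 0.5, 20000
        pool = TubulinPool(1e9)
        rate = catastrophe_rate(0.2, 0.2, 600.0, 30.0)
        hits = 0
        for _ in range(n):
            mt = straight_mt(5.0)
            step_plus_end(mt, pool, dt, rng, **KIN)
            hits += mt.plus_state == SHRINKING
        p = 1.0 - np.exp(-rate * dt)
        assert abs(hits / n - p) < 3 * np.sqrt(p * (1 - p) / n)

    def test_no_rescue_over_trajectory(self):
        """Once shrinking, an MT never grows again."""
        rng = np.random.default_rng(1)
        pool = TubulinPool(1e6)
        mt = straight_mt(8.0)
        pool.L_polymerized = mt.length
        seen_shrinking = False
        for _ in range(10000):
            out = step_plus_end(mt, pool, 0.1, rng, v_grow0=0.2,
                                v_shrink=0.05, fg=1.5, cat_time_free=50.0,
                                cat_time_stalled=50.0)
            if out is None:
                break
            if seen_shrinking:
                assert out.plus_state == SHRINKING
            seen_shrinking = seen_shrinking or out.plus_state == SHRINKING
        assert seen_shrinking

    def test_vertex_resampling_keeps_segments_near_target(self):
        rng = np.random.default_rng(2)
        pool = TubulinPool(1e12)   # effectively unlimited
        mt = straight_mt(1.0)
        for _ in range(3000):
            step_plus_end(mt, pool, 0.1, rng, v_grow0=0.2, v_shrink=0.4,
                          fg=1.5, cat_time_free=1e12, cat_time_stalled=1e12)
        assert mt.length == pytest.approx(1.0 + 3000 * 0.02)
        seglens = np.hypot(*np.diff(mt.vertices, axis=0).T)
        assert np.allclose(seglens[:-1], 2.0)
        assert 0 < mt.last_segment <= 2.0 + 1e-9


class TestTryNucleate:
    def test_occupied_site_blocks(self):
        site = NucleationSite("n", (0, 0), occupied=True)
        assert try_nucleate(site, 1e9, 1.0, np.random.default_rng(0),
                            TubulinPool(10.0), 0, 5, 2.0) is None

    def test_host_cap_blocks(self):
        site = NucleationSite("n", (0, 0))
        assert try_nucleate(site, 1e9, 1.0, np.random.default_rng(0),
                            TubulinPool(10.0), 5, 5, 2.0) is None

    def test_exhausted_pool_blocks(self):
        site = NucleationSite("n", (0, 0))
        pool = TubulinPool(1.0, L_polymerized=0.99)
        assert try_nucleate(site, 1e9, 1.0, np.random.default_rng(0),
                            pool, 0, 5, 2.0) is None

    def test_direction_is_unbiased_horizontal(self):
        rng = np.random.default_rng(7)
        plus_x = 0
        n = 4000
        for _ in range(n):
            site = NucleationSite("n", (0.0, 0.0))
            mt = try_nucleate(site, 1e9, 1.0, rng, TubulinPool(1e9), 0, 5, 2.0)
            assert mt is not None and mt.vertices[1, 1] == 0.0  # horizontal
            plus_x += mt.vertices[1, 0] > 0
        assert abs(plus_x / n - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_nucleation_probability(self):
        rng = np.random.default_rng(8)
        rate, dt, n = 0.7, 0.5, 20000
        hits = 0
        for _ in range(n):
            site = NucleationSite("n", (0.0, 0.0))
            hits += try_nucleate(site, rate, dt, rng, TubulinPool(1e9),
                                 0, 5, 2.0) is not None
        p = 1 - np.exp(-rate * dt)
        assert abs(hits / n - p) < 3 * np.sqrt(p * (1 - p) / n)


class TestSteadyStateLengths:
    def test_population_matches_event_driven_oracle(self):
        """Length distribution of an unloaded, constant-rate population
        matches an exact event-driven simulation of the two-state model."""
        v, vs, rate, T = 1.0, 2.0, 0.1, 60.0
        n = 1000

        # oracle: exact exponential catastrophe clocks, no time stepping
        rng = np.random.default_rng(11)
        oracle = []
        for _ in range(n):
            t, length, growing = 0.0, 0.0, True
            while t < T:
                if growing:
                    tau = rng.exponential(1.0 / rate)
                    if t + tau >= T:
                        length += v * (T - t)
                        t = T
                    else:
                        length += v * tau
                        t += tau
                        growing = False
                else:
                    tau = length / vs
                    if t + tau >= T:
                        length -= vs * (T - t)
                        t = T
                    else:
                        t += tau
                        length, growing = 0.0, True  # instant renucleation
            oracle.append(length)
        oracle = np.asarray(oracle)

        # stepped model via step_plus_end with instant renucleation
        rng2 = np.random.default_rng(12)
        pool = TubulinPool(1e12)
        lengths = []
        dt = 0.05
        for _ in range(n):
            mt = straight_mt(1e-6)
            for _ in range(int(T / dt)):
                out = step_plus_end(mt, pool, dt, rng2, v_grow0=v,
                                    v_shrink=vs, fg=1.5,
                                    cat_time_free=1 / rate,
                                    cat_time_stalled=1 / rate)
                if out is None:
                    mt = straight_mt(1e-6)
            lengths.append(mt.length)
        lengths = np.asarray(lengths)

        sem = np.sqrt(oracle.var() / n + lengths.var() / n)
        assert abs(oracle.mean() - lengths.mean()) < 3 * sem


class TestPoolInvariants:
    def test_bounds_enforced(self):
        pool = TubulinPool(10.0)
        pool.polymerize(9.5)
        with pytest.raises(ValueError):
            pool.polymerize(1.0)
        pool.depolymerize(100.0)
        assert pool.L_polymerized == 0.0
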