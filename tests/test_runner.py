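"""State assembly, event loop contracts, and seeded ensembles."""

import dataclasses

import numpy as np
import pytest

from myonuc.config import SimulationParams, make_condition
from myonuc.runner import (initialize, run, run_ensemble, simulate)

FAST = SimulationParams(nucleus_count=5, duration=20.0)


class TestInitialize:
    def test_control_wiring(self):
        st = initialize("control", FAST, seed=1)
        assert st.n_nuclei == 5
        assert st.body_pos.shape == (5, 2)          # no centrosomes
        assert st.site_active.all()                 # NE sites active
        assert st.mt_alive.sum() == 0               # no MTs at t=0

    def test_relocated_nucleation_wiring(self):
        st = initialize("no_ne_nucleation", FAST, seed=1)
        assert st.body_pos.shape == (10, 2)         # 5 nuclei + 5 centrosomes
        ne_sites = st.site_body < 5
        assert not st.site_active[ne_sites].any()   # NE sites inactive
        assert st.site_active[~ne_sites].all()      # centrosome sites active
        # NE kinesin retained, dynein retained
        assert (st.con_sp == 1).sum() == 5 * FAST.kif5b_per_nucleus
        assert (st.con_sp == 0).sum() == 5 * FAST.dynein_per_nucleus

    def test_third_condition_drops_ne_kinesin_keeps_dynein(self):
        st = initialize("no_ne_nucleation_no_kif5b", FAST, seed=1)
        assert (st.con_sp == 1).sum() == 0
        assert (st.con_sp == 0).sum() == 5 * FAST.dynein_per_nucleus

    def test_nuclei_start_clustered_at_center(self):
        st = initialize("control", FAST, seed=2)
        x = st.body_pos[:5, 0]
        span = x.max() - x.min()
        assert span < 5 * (2 * FAST.nucleus_radius + 1)  # contact cluster
        assert abs(x.mean()) < 5.0

    def test_no_initial_overlaps_and_inside_domain(self):
        st = initialize("no_ne_nucleation", FAST, seed=3)
        pos, rad = st.body_pos, st.body_rad
        for i in range(len(pos)):
            for j in range(i + 1, len(pos)):
                d = np.hypot(*(pos[i] - pos[j]))
                assert d >= rad[i] + rad[j] - 1e-6
            a = st.domain.half_length_a - rad[i]
            b = st.domain.half_width_b - rad[i]
            assert (pos[i, 0] / a) ** 2 + (pos[i, 1] / b) ** 2 <= 1 + 1e-9

    def test_same_seed_identical_state(self):
        s1 = initialize("no_ne_nucleation", FAST, seed=7)
        s2 = initialize("no_ne_nucleation", FAST, seed=7)
        assert np.array_equal(s1.body_pos, s2.body_pos)
        assert np.array_equal(s1.site_angle, s2.site_angle)
        assert np.array_equal(s1.con_anchor_angle, s2.con_anchor_angle)
        assert np.array_equal(s1.con_pos, s2.con_pos)


class TestRun:
    def test_zero_duration_gives_initial_frame_only(self):
        res = run(initialize("control", FAST, seed=1), duration=0.0)
        assert res.times.shape == (1,)
        assert res.times[0] == 0.0

    def test_null_dynamics_is_static(self):
        """kT=0, no motors, no nucleation: nuclei do not move."""
        p = dataclasses.replace(FAST, temperature_kT=0.0, nucleation_rate=0.0,
                                dynein_per_nucleus=0, kif5b_per_nucleus=0,
                                map4_per_myotube=0, map7kif5b_per_myotube=0)
        res = run(initialize("control", p, seed=1), duration=10.0,
                  frame_stride=100)
        for frame in res.body_traj:
            assert np.array_equal(frame, res.body_traj[0])
        assert res.events["nucleations"] == 0

    def test_full_run_is_pure_function_of_seed(self):
        r1 = simulate("control", FAST, seed=11, duration=20.0)
        r2 = simulate("control", FAST, seed=11, duration=20.0)
        assert np.array_equal(r1.final_x_um, r2.final_x_um)
        assert r1.events == r2.events
        r3 = simulate("control", FAST, seed=12, duration=20.0)
        assert not np.array_equal(r1.final_x_um, r3.final_x_um)

    def test_state_cannot_be_rerun(self):
        st = initialize("control", FAST, seed=1)
        run(st, duration=1.0)
        with pytest.raises(RuntimeError):
            run(st, duration=1.0)

    def test_matched_seeds_diverge_only_after_first_nucleation(self):
        """With nucleation as the only difference-maker, nuclear
        trajectories of the two nucleation conditions coincide frame by
        frame until an MT exists in either run."""
        p = dataclasses.replace(FAST, nucleation_rate=0.002)
        r1 = run(initialize("control", p, seed=5), duration=30.0,
                 frame_stride=25)
        r2 = run(initialize("no_ne_nucleation", p, seed=5), duration=30.0,
                 frame_stride=25)
        first = min(s for s in (r1.events["first_nucleation_step"],
                                r2.events["first_nucleation_step"]) if s >= 0)
        steps = np.concatenate([[0], np.arange(1, r1.times.size) * 25])
        diverged = False
        for fi, step in enumerate(steps):
            same = np.allclose(r1.body_traj[fi, :5], r2.body_traj[fi, :5])
            if step <= first:
                assert same, f"premature divergence at step {step}"
            diverged = diverged or not same
        assert diverged  # nucleation eventually separates the trajectories

    def test_tubulin_conservation_every_frame(self):
        res = run(initialize("control", FAST, seed=3), duration=30.0,
                  frame_stride=10)
        assert np.max(np.abs(res.poly_um - res.sum_mt_len_um)) < 1e-6
        assert res.poly_um.max() <= FAST.tubulin_pool_Lmax + 1e-9

    def test_confinement_soft_bound(self):
        res = run(initialize("control", FAST, seed=4), duration=30.0,
                  frame_stride=10)
        # soft-potential equilibrium penetration stays far below 1 μm at
        # the default stiffness
        assert res.max_penetration_um.max() < 1.0


class TestEnsemble:
    def test_bookkeeping(self):
        ens = run_ensemble(conditions=("control", "no_ne_nucleation"),
                           n_replicates=3, nucleus_counts=(5,),
                           seed_base=50, duration=5.0)
        df = ens.positions
        assert len(df) == 2 * 3 * 5            # conditions × reps × nuclei
        assert set(df["condition"]) == {"control", "no_ne_nucleation"}
        assert ens.seeds["control"] == [50, 51, 52]

    def test_replicates_match_individual_runs(self):
        """Ensemble replicates are independent: replicate i equals a
        standalone run with the same seed and nucleus count."""
        ens = run_ensemble(conditions=("control",), n_replicates=2,
                           nucleus_counts=(5, 6), seed_base=9, duration=10.0)
        p = dataclasses.replace(SimulationParams(), nucleus_count=6, seed=10)
        solo = simulate("control", p, seed=10, duration=10.0)
        rep1 = ens.positions[ens.positions["replicate"] == 1]
        assert np.allclose(np.sort(rep1["x_um"]), np.sort(solo.final_x_um))

    def test_rerun_reproduces_sf_vector(self):
        kw = dict(conditions=("control",), n_replicates=2,
                  nucleus_counts=(5,), seed_base=77, duration=10.0)
        a = run_ensemble(**kw).positions
        b = run_ensemble(**kw).positions
        assert np.array_equal(a["x_um"].to_numpy(), b["x_um"].to_numpy())

    def test_bad_replicate_count(self):
        with pytest.raises(ValueError):
            run_ensemble(n_replicates=0)


class TestNumericalInvariants:
    def test_no_spurious_drift_at_equilibrium(self):
        """Two passive nuclei at elevated temperature diffuse without a
        systematic drift and stay inside the accessible region."""
        p = SimulationParams(nucleus_count=2, temperature_kT=2.0,
                             nucleation_rate=0.0, dynein_per_nucleus=0,
                             kif5b_per_nucleus=0, map4_per_myotube=0,
                             map7kif5b_per_myotube=0)
        disp = []
        for seed in range(8):
            res = run(initialize("control", p, seed=seed), duration=60.0,
                      frame_stride=100)
            disp.append(res.body_traj[-1] - res.body_traj[0])
            a = res.params.nucleus_radius
            assert res.max_penetration_um.max() < 0.5
        disp = np.concatenate(disp)       # (16, 2) independent displacements
        t, gamma = 60.0, 6 * np.pi * 1.0 * 4.0
        sigma = np.sqrt(2 * 2.0 * t / gamma)
        sem = sigma / np.sqrt(len(disp))
        assert abs(disp[:, 0].mean()) < 4 * sem
        assert abs(disp[:, 1].mean()) < 4 * sem

    def test_time_step_halving_converges(self):
        """Halving dt changes the small-ensemble mean SF by less than the
        ensemble scatter."""
        means = {}
        for dt in (0.02, 0.01):
            p = SimulationParams(nucleus_count=5, dt=dt)
            sfs = [simulate("control", p, seed=s, duration=240.0).sf_series[-1]
                   for s in range(4)]
            means[dt] = (np.mean(sfs), np.std(sfs, ddof=1) / np.sqrt(len(sfs)))
        sem = np.hypot(means[0.02][1], means[0.01][1])
        assert abs(means[0.02][0] - means[0.01][0]) <= max(2 * sem, 0.05)
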