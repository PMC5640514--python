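"""Assemble simulation state, run the event loop, and run seeded ensembles.

A replicate is a pure function of (condition, params, seed): initialization
uses a seeded generator and the engine draws all in-run randomness from a
counter-based stream keyed by the same seed.  ``run_ensemble`` sweeps
replicates across the three conditions with nucleus counts cycling 5–9 and
returns a long table of final nuclear axial positions ready for the
spreading-factor analysis.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import engine as eng
from .config import (ConditionSpec, MyotubeDomain, SimulationParams,
                     make_condition, make_domain)
from .spreading import MyotubeNuclei, spreading_factor

log = logging.getLogger(__name__)

DEFAULT_NUCLEUS_COUNTS = (5, 6, 7, 8, 9)


@dataclass
class SimulationState:
    """Flat-array state consumed by the engine kernel (single use per run)."""

    condition: ConditionSpec
    params: SimulationParams
    domain: MyotubeDomain
    seed: int
    # bodies
    body_pos: np.ndarray
    body_rad: np.ndarray
    body_drag: np.ndarray
    body_mobile: np.ndarray
    n_nuclei: int
    # nucleation sites (one potential MT slot per site)
    site_body: np.ndarray
    site_angle: np.ndarray
    site_active: np.ndarray
    site_mt: np.ndarray
    # microtubules
    mt_alive: np.ndarray
    mt_growing: np.ndarray
    mt_nv: np.ndarray
    mt_last: np.ndarray
    mt_body: np.ndarray
    verts: np.ndarray
    # connectors
    con_sp: np.ndarray
    con_anchor_body: np.ndarray
    con_anchor_angle: np.ndarray
    con_pos: np.ndarray
    con_state: np.ndarray
    con_mt: np.ndarray
    con_abs: np.ndarray
    # species tables
    sp_v0: np.ndarray
    sp_dir: np.ndarray
    sp_fstall: np.ndarray
    sp_kon: np.ndarray
    sp_koff: np.ndarray
    sp_capr: np.ndarray
    sp_springk: np.ndarray
    sp_fdetach: np.ndarray
    head_kind: np.ndarray
    # scalars
    P: np.ndarray
    pool: np.ndarray
    time: float = 0.0
    consumed: bool = False


@dataclass
class SimulationResult:
    """Trajectory and diagnostics of one replicate."""

    condition: str
    seed: int
    nucleus_count: int
    myotube_length_um: float
    times: np.ndarray
    body_traj: np.ndarray          # (n_frames, n_bodies, 2), nuclei first
    n_nuclei: int
    final_x_um: np.ndarray         # axial nuclear positions in [0, L]
    poly_um: np.ndarray            # tubulin polymer per frame
    sum_mt_len_um: np.ndarray      # independent per-frame sum of MT lengths
    n_mts: np.ndarray
    max_penetration_um: np.ndarray
    events: dict
    params: SimulationParams = field(repr=False, default=None)

    @property
    def sf_series(self) -> np.ndarray:
        """Spreading factor of the nuclei at every recorded frame."""
        L = self.myotube_length_um
        a = L / 2.0
        out = np.empty(self.times.size)
        for i in range(self.times.size):
            x = np.clip(self.body_traj[i, :self.n_nuclei, 0] + a, 0.0, L)
            out[i] = spreading_factor(MyotubeNuclei("traj", L, x))
        return out


def _relax_overlaps(pos, rad, domain, max_iter=500):
    """Push overlapping bodies apart and keep centers inside the reduced
    ellipse; raises if overlaps persist."""
    n = pos.shape[0]
    for _ in range(max_iter):
        moved = False
        for i in range(n):
            for j in range(i + 1, n):
                d = pos[i] - pos[j]
                dist = float(np.hypot(*d))
                rsum = rad[i] + rad[j]
                if dist < rsum - 1e-9:
                    u = d / dist if dist > 1e-9 else np.array([1.0, 0.0])
                    shift = 0.5 * (rsum - dist) + 1e-6
                    pos[i] += u * shift
                    pos[j] -= u * shift
                    moved = True
        for i in range(n):
            ra = domain.half_length_a - rad[i]
            rb = domain.half_width_b - rad[i]
            if (pos[i, 0] / ra) ** 2 + (pos[i, 1] / rb) ** 2 > 1.0:
                qx, qy = eng.nearest_on_ellipse(ra, rb, pos[i, 0], pos[i, 1])
                pos[i] = (qx, qy)
                moved = True
        if not moved:
            return
    raise RuntimeError("could not place bodies without overlap "
                       f"after {max_iter} relaxation sweeps")


def _uniform_in_ellipse(rng, a, b):
    for _ in range(100000):
        x = rng.uniform(-a, a)
        y = rng.uniform(-b, b)
        if (x / a) ** 2 + (y / b) ** 2 <= 1.0:
            return x, y
    raise RuntimeError("rejection sampling in ellipse failed")


def initialize(condition: ConditionSpec | str, params: SimulationParams,
               seed: int | None = None) -> SimulationState:
    """Build the t=0 state: nuclei clustered at the domain center (so that
    spreading is the observable), centrosome-like bodies (when NE nucleation
    is off) placed uniformly at random, no MTs yet, all connectors unbound.
    """
    if isinstance(condition, str):
        condition = make_condition(condition)
    if seed is None:
        seed = params.seed
    rng = np.random.default_rng(seed)
    domain = make_domain(params.nucleus_count)
    n = params.nucleus_count
    R = params.nucleus_radius

    # nuclear arrangement at t=0 (overlap-free after steric relaxation)
    if params.initial_arrangement == "clustered":
        # contact cluster around the domain center
        spacing = 2.0 * R + 0.4
        xs = (np.arange(n) - (n - 1) / 2.0) * spacing
        ys = rng.uniform(-0.5, 0.5, size=n)
    elif params.initial_arrangement == "dispersed":
        xs = np.linspace(-(domain.half_length_a - R - 1),
                         domain.half_length_a - R - 1, n)
        xs = xs + rng.uniform(-1.0, 1.0, size=n)
        ys = rng.uniform(-0.5, 0.5, size=n)
    else:  # uniform random axial positions with a contact-free minimum gap
        lo = -(domain.half_length_a - R - 0.5)
        min_gap = 2.0 * R + 0.4
        for _ in range(20000):
            xs = np.sort(rng.uniform(lo, -lo, size=n))
            if np.all(np.diff(xs) >= min_gap):
                break
        else:
            raise RuntimeError("could not draw a contact-free uniform "
                               "arrangement")
        ys = rng.uniform(-0.5, 0.5, size=n)
    nuc_pos = np.column_stack([xs, ys])

    k_cen = condition.cytoplasmic_centrosomes_per_nucleus * n
    cen_pos = np.zeros((k_cen, 2))
    rc = params.centrosome_radius
    placed = 0
    tries = 0
    while placed < k_cen:
        tries += 1
        if tries > 100000:
            raise RuntimeError("could not place centrosomes without overlap")
        x, y = _uniform_in_ellipse(rng, domain.half_length_a - rc,
                                   domain.half_width_b - rc)
        ok = all(np.hypot(x - p[0], y - p[1]) > R + rc for p in nuc_pos)
        ok = ok and all(np.hypot(x - p[0], y - p[1]) > 2 * rc
                        for p in cen_pos[:placed])
        if ok:
            cen_pos[placed] = (x, y)
            placed += 1

    pos = np.vstack([nuc_pos, cen_pos])
    rad = np.concatenate([np.full(n, R), np.full(k_cen, rc)])
    _relax_overlaps(pos, rad, domain)
    drag = 6.0 * np.pi * params.viscosity * rad
    mobile = np.ones(n + k_cen, dtype=np.uint8)
    if not params.centrosomes_mobile:
        mobile[n:] = 0

    # nucleation sites: every nucleus and centrosome carries a full set of
    # slots; NE slots are simply inactive when nucleation is relocated
    cap = params.max_mts_per_nucleus
    nb = n + k_cen
    site_body = np.repeat(np.arange(nb, dtype=np.int32), cap)
    site_angle = rng.uniform(0.0, 2.0 * np.pi, size=nb * cap)
    active_per_body = np.concatenate([
        np.full(n, condition.ne_nucleation),
        np.full(k_cen, True)]).astype(np.uint8)
    site_active = np.repeat(active_per_body, cap)
    ns = site_body.size
    site_mt = np.full(ns, -1, dtype=np.int32)

    VMAX = int(np.ceil(domain.length / params.segment_length)) + 4
    mt_alive = np.zeros(ns, dtype=np.uint8)
    mt_growing = np.zeros(ns, dtype=np.uint8)
    mt_nv = np.zeros(ns, dtype=np.int32)
    mt_last = np.zeros(ns)
    mt_body = np.zeros(ns, dtype=np.int32)
    verts = np.zeros((ns, VMAX, 2))

    # connectors: NE dynein/Kif5b anchored on nucleus surfaces (uniform
    # angles = even density), cytoplasmic MAP4 and MAP7-Kif5b complexes
    sp_list, anchor_body, anchor_angle, con_xy = [], [], [], []
    n_dyn = params.dynein_per_nucleus if params.ne_dynein_retained else 0
    n_kif = params.kif5b_per_nucleus if condition.ne_kif5b else 0
    for i in range(n):
        for _ in range(n_dyn):
            sp_list.append(eng.SP_DYNEIN)
            anchor_body.append(i)
            anchor_angle.append(rng.uniform(0.0, 2.0 * np.pi))
            con_xy.append((0.0, 0.0))
        for _ in range(n_kif):
            sp_list.append(eng.SP_KIF5B)
            anchor_body.append(i)
            anchor_angle.append(rng.uniform(0.0, 2.0 * np.pi))
            con_xy.append((0.0, 0.0))
    for sp, count in ((eng.SP_MAP4, params.map4_per_myotube),
                      (eng.SP_MAP7KIF5B, params.map7kif5b_per_myotube)):
        for _ in range(count):
            sp_list.append(sp)
            anchor_body.append(-1)
            anchor_angle.append(0.0)
            con_xy.append(_uniform_in_ellipse(rng, domain.half_length_a,
                                              domain.half_width_b))
    C = len(sp_list)
    con_sp = np.asarray(sp_list, dtype=np.int8)
    con_anchor_body = np.asarray(anchor_body, dtype=np.int32)
    con_anchor_angle = np.asarray(anchor_angle)
    con_pos = np.asarray(con_xy) if C else np.zeros((0, 2))
    con_state = np.zeros((C, 2), dtype=np.uint8)
    con_mt = np.full((C, 2), -1, dtype=np.int32)
    con_abs = np.zeros((C, 2))

    # species tables: dynein, kif5b, map4, map7-kif5b
    mp = [params.dynein, params.kif5b, params.map4, params.map7kif5b]
    sp_v0 = np.array([m.v0 for m in mp])
    sp_dir = np.array([float(m.directionality) for m in mp])
    sp_fstall = np.array([max(m.f_stall, 1.0) for m in mp])
    sp_kon = np.array([m.k_on for m in mp])
    sp_koff = np.array([m.k_off for m in mp])
    sp_capr = np.array([m.capture_radius for m in mp])
    sp_springk = np.array([m.spring_k for m in mp])
    sp_fdetach = np.array([m.detach_force for m in mp])
    head_kind = np.array([
        [eng.HEAD_ANCHOR, eng.HEAD_MOTOR],    # NE dynein
        [eng.HEAD_ANCHOR, eng.HEAD_MOTOR],    # NE kif5b
        [eng.HEAD_PASSIVE, eng.HEAD_PASSIVE],  # MAP4 crosslinker
        [eng.HEAD_PASSIVE, eng.HEAD_MOTOR],   # MAP7-Kif5b complex
    ], dtype=np.int8)

    P = np.zeros(eng.NPAR)
    P[eng.DT] = params.dt
    P[eng.KT] = params.temperature_kT
    P[eng.VISC] = params.viscosity
    P[eng.CONF_K] = params.confinement_k
    P[eng.STERIC_K] = params.steric_k
    P[eng.SEG_L0] = params.segment_length
    P[eng.RIGID] = params.mt_rigidity
    P[eng.VGROW0] = params.v_grow0
    P[eng.VSHRINK] = params.v_shrink
    P[eng.FG] = params.force_sensitivity_fg
    P[eng.LMAX] = params.tubulin_pool_Lmax
    P[eng.CAT_TF] = params.cat_time_free
    P[eng.CAT_TS] = params.cat_time_stalled
    P[eng.NUC_RATE] = params.nucleation_rate
    P[eng.ELL_A] = domain.half_length_a
    P[eng.ELL_B] = domain.half_width_b
    P[eng.CONN_D] = params.connector_diffusion
    P[eng.EPS_NUC] = 0.05

    return SimulationState(
        condition=condition, params=params, domain=domain, seed=int(seed),
        body_pos=pos, body_rad=rad, body_drag=drag, body_mobile=mobile,
        n_nuclei=n,
        site_body=site_body, site_angle=site_angle, site_active=site_active,
        site_mt=site_mt,
        mt_alive=mt_alive, mt_growing=mt_growing, mt_nv=mt_nv,
        mt_last=mt_last, mt_body=mt_body, verts=verts,
        con_sp=con_sp, con_anchor_body=con_anchor_body,
        con_anchor_angle=con_anchor_angle, con_pos=con_pos,
        con_state=con_state, con_mt=con_mt, con_abs=con_abs,
        sp_v0=sp_v0, sp_dir=sp_dir, sp_fstall=sp_fstall, sp_kon=sp_kon,
        sp_koff=sp_koff, sp_capr=sp_capr, sp_springk=sp_springk,
        sp_fdetach=sp_fdetach, head_kind=head_kind, P=P, pool=np.zeros(1),
    )


def run(state: SimulationState, duration: float | None = None,
        frame_stride: int = 500) -> SimulationResult:
    """Run the event loop for ``duration`` seconds (default: params.duration).

    Per step: force accumulation → overdamped Langevin move → MT dynamic
    instability → connector kinetics → nucleation.  Frames are recorded
    every ``frame_stride`` steps.  The state is consumed: running it twice
    would replay the same random stream, so a fresh state is required per
    run.
    """
    if state.consumed:
        raise RuntimeError("state already run; build a fresh one with initialize()")
    state.consumed = True
    if duration is None:
        duration = state.params.duration
    if duration < 0:
        raise ValueError("duration must be >= 0")
    dt = state.params.dt
    n_steps = int(round(duration / dt))
    nb = state.body_pos.shape[0]
    n_frames = n_steps // frame_stride + 2
    fr_body = np.zeros((n_frames, nb, 2))
    fr_poly = np.zeros(n_frames)
    fr_sumlen = np.zeros(n_frames)
    fr_nmts = np.zeros(n_frames, dtype=np.int32)
    fr_maxpen = np.zeros(n_frames)
    ev = np.zeros(eng.NEV, dtype=np.int64)
    ev[eng.EV_FIRST_NUC_STEP] = -1

    used = eng.run_kernel(
        state.body_pos, state.body_rad, state.body_drag, state.body_mobile,
        state.site_body, state.site_angle, state.site_active, state.site_mt,
        state.mt_alive, state.mt_growing, state.mt_nv, state.mt_last,
        state.mt_body, state.verts,
        state.con_sp, state.con_anchor_body, state.con_anchor_angle,
        state.con_pos, state.con_state, state.con_mt, state.con_abs,
        state.sp_v0, state.sp_dir, state.sp_fstall, state.sp_kon,
        state.sp_koff, state.sp_capr, state.sp_springk, state.sp_fdetach,
        state.head_kind,
        state.P, state.pool, n_steps, frame_stride, state.seed,
        fr_body, fr_poly, fr_sumlen, fr_nmts, fr_maxpen, ev)

    fr_body = fr_body[:used]
    if not np.isfinite(fr_body).all():
        raise RuntimeError(
            "numerical blow-up: non-finite positions; reduce dt "
            f"(currently {dt} s) or stiffnesses")
    step_of_frame = np.concatenate([[0], np.arange(1, used) * frame_stride])
    step_of_frame[-1] = n_steps
    times = step_of_frame * dt
    L = state.domain.length
    a = state.domain.half_length_a
    final_x = np.clip(state.body_pos[:state.n_nuclei, 0] + a, 0.0, L)
    events = {
        "nucleations": int(ev[eng.EV_NUCLEATION]),
        "catastrophes": int(ev[eng.EV_CATASTROPHE]),
        "removals": int(ev[eng.EV_REMOVAL]),
        "attachments": int(ev[eng.EV_ATTACH]),
        "detachments": int(ev[eng.EV_DETACH]),
        "first_nucleation_step": int(ev[eng.EV_FIRST_NUC_STEP]),
    }
    return SimulationResult(
        condition=state.condition.name, seed=state.seed,
        nucleus_count=state.n_nuclei, myotube_length_um=L, times=times,
        body_traj=fr_body, n_nuclei=state.n_nuclei, final_x_um=final_x,
        poly_um=fr_poly[:used], sum_mt_len_um=fr_sumlen[:used],
        n_mts=fr_nmts[:used], max_penetration_um=fr_maxpen[:used],
        events=events, params=state.params)


def simulate(condition: str | ConditionSpec, params: SimulationParams,
             seed: int, duration: float | None = None,
             frame_stride: int = 500) -> SimulationResult:
    """Initialize and run one replicate (pure function of its arguments)."""
    return run(initialize(condition, params, seed), duration, frame_stride)


@dataclass
class EnsembleResult:
    """Final nuclear positions across conditions and replicates."""

    positions: pd.DataFrame       # one row per nucleus
    seeds: dict
    results: list = field(repr=False, default_factory=list)

    def sf_table(self) -> pd.DataFrame:
        from .spreading import sf_table
        df = self.positions.rename(columns={"replicate_id": "myotube_id"})
        return sf_table(df, group="condition")


def run_ensemble(conditions=("control", "no_ne_nucleation",
                             "no_ne_nucleation_no_kif5b"),
                 n_replicates: int = 20,
                 nucleus_counts=DEFAULT_NUCLEUS_COUNTS,
                 seed_base: int = 0,
                 params: SimulationParams | None = None,
                 duration: float | None = None,
                 keep_results: bool = False,
                 progress: bool = False) -> EnsembleResult:
    """Seeded ensemble across conditions.

    Replicate ``i`` of every condition simulates a myotube with
    ``nucleus_counts[i % len(nucleus_counts)]`` nuclei and seed
    ``seed_base + i``, so conditions are compared on matched seeds and
    domain sizes.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    base = params or SimulationParams()
    rows = []
    seeds = {}
    results = []
    for cond in conditions:
        cond_seeds = []
        for i in range(n_replicates):
            n = int(nucleus_counts[i % len(nucleus_counts)])
            seed = int(seed_base) + i
            cond_seeds.append(seed)
            p = dataclasses.replace(base, nucleus_count=n, seed=seed)
            res = simulate(cond, p, seed, duration=duration)
            if progress:
                log.info("%s rep %d (n=%d, seed=%d): SF=%.3f", cond, i, n,
                         seed, res.sf_series[-1])
            if keep_results:
                results.append(res)
            rid = f"{cond}_rep{i:03d}"
            for k, x in enumerate(res.final_x_um):
                rows.append({"replicate_id": rid, "condition": cond,
                             "replicate": i, "seed": seed,
                             "nucleus_count": n,
                             "length_um": res.myotube_length_um,
                             "nucleus_index": k, "x_um": float(x)})
        seeds[cond] = cond_seeds
    return EnsembleResult(positions=pd.DataFrame(rows), seeds=seeds,
                          results=results)
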