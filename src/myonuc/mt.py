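"""Microtubule entities, nucleation, and plus-end dynamic instability.

MTs are polarized fibers: the minus end stays anchored at its nucleation
site (a point on a nucleus or centrosome surface), the plus end switches
stochastically from growth to shrinkage (catastrophe) and never back (no
rescue).  Growth is slowed by antagonistic force with sensitivity
``fg = 1.5 pN`` and by depletion of a fixed tubulin pool; the catastrophe
rate rises as growth slows, interpolating between the free-growth and
stalled mean catastrophe times.

The batched equivalents of these operations run inside the compiled
engine; this module is the single-fiber reference surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .engine import (catastrophe_rate_formula, growth_speed_formula,
                     motor_speed_formula)  # noqa: F401  (re-exported)

GROWING = "growing"
SHRINKING = "shrinking"


@dataclass
class TubulinPool:
    """Fixed tubulin pool, tracked as polymer-length equivalent (μm)."""

    L_max: float
    L_polymerized: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.L_polymerized <= self.L_max:
            raise ValueError("need 0 <= L_polymerized <= L_max")

    @property
    def free_fraction(self) -> float:
        return max(0.0, 1.0 - self.L_polymerized / self.L_max)

    def polymerize(self, dL: float) -> None:
        if self.L_polymerized + dL > self.L_max + 1e-9:
            raise ValueError("tubulin pool exhausted")
        self.L_polymerized += dL

    def depolymerize(self, dL: float) -> None:
        self.L_polymerized = max(0.0, self.L_polymerized - dL)


@dataclass
class NucleationSite:
    """A nucleation slot on a host surface; holds at most one MT minus end."""

    host: object
    position: np.ndarray
    occupied: bool = False

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)


@dataclass
class Microtubule:
    """Vertex-chain fiber; minus end first, plus end last.

    All segments have the target length except the terminal one, whose
    length is ``last_segment``; total length = (nv−2)·l0 + last_segment.
    """

    vertices: np.ndarray
    segment_length_target: float
    last_segment: float
    plus_state: str = GROWING
    anchor: Optional[NucleationSite] = None
    id: int = field(default=0)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 2)
        if self.vertices.shape[0] < 2:
            raise ValueError("a microtubule needs at least two vertices")
        if self.plus_state not in (GROWING, SHRINKING):
            raise ValueError(f"bad plus_state {self.plus_state!r}")

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def length(self) -> float:
        return (self.n_vertices - 2) * self.segment_length_target + self.last_segment

    @property
    def tip_tangent(self) -> np.ndarray:
        d = self.vertices[-1] - self.vertices[-2]
        n = np.hypot(*d)
        return d / n if n > 1e-12 else np.array([1.0, 0.0])

    def point_at(self, s: float) -> np.ndarray:
        """Position at abscissa s from the minus end."""
        l0 = self.segment_length_target
        nseg = self.n_vertices - 1
        i = min(int(s / l0), nseg - 1)
        seglen = l0 if i < nseg - 1 else self.last_segment
        t = np.clip((s - i * l0) / seglen if seglen > 0 else 0.0, 0.0, 1.0)
        return (1 - t) * self.vertices[i] + t * self.vertices[i + 1]


def growth_speed(v0: float, f_antagonistic: float, fg: float,
                 pool: TubulinPool) -> float:
    """Loaded, pool-limited growth speed.

    v = v0 · (1 − L_polymerized/L_max) · exp(−f/fg), with the antagonistic
    force clamped at zero from below; v ∈ [0, v0].
    """
    if fg <= 0:
        raise ValueError("force sensitivity fg must be > 0")
    return float(growth_speed_formula(v0, f_antagonistic, fg,
                                      pool.L_polymerized, pool.L_max))


def catastrophe_rate(v: float, v0: float, t_free: float, t_stalled: float) -> float:
    """Growth-rate-dependent catastrophe rate (1/s).

    The mean catastrophe time interpolates linearly in normalized speed
    between the stalled value (v=0) and the free-growth value (v=v0), so
    the rate is monotonically non-increasing in v.
    """
    if t_stalled <= 0:
        raise ValueError("t_stalled must be > 0")
    if t_free < t_stalled:
        raise ValueError("t_free must be >= t_stalled")
    return float(catastrophe_rate_formula(v, v0, t_free, t_stalled))


def step_plus_end(mt: Microtubule, pool: TubulinPool, dt: float,
                  rng: np.random.Generator, *, v_grow0: float,
                  v_shrink: float, fg: float, cat_time_free: float,
                  cat_time_stalled: float,
                  f_antagonistic: float = 0.0) -> Optional[Microtubule]:
    """Advance one plus end by dt.

    A growing MT elongates along its tip tangent by v·dt (resampling
    vertices to keep segments near the target length) and catastrophes
    with probability 1 − exp(−rate·dt); a shrinking MT shortens by
    v_shrink·dt.  Returns the MT, or None when it depolymerizes completely
    (pool credited, nucleation site freed).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    l0 = mt.segment_length_target
    if mt.plus_state == GROWING:
        v = growth_speed(v_grow0, f_antagonistic, fg, pool)
        dL = v * dt
        if dL > 0:
            u = mt.tip_tangent
            mt.vertices[-1] = mt.vertices[-1] + u * dL
            mt.last_segment += dL
            pool.polymerize(dL)
            if mt.last_segment > l0:
                excess = mt.last_segment - l0
                tip = mt.vertices[-1].copy()
                mt.vertices[-1] = tip - u * excess
                mt.vertices = np.vstack([mt.vertices, tip])
                mt.last_segment = excess
        rate = catastrophe_rate(v, v_grow0, cat_time_free, cat_time_stalled)
        if rng.random() < 1.0 - np.exp(-rate * dt):
            mt.plus_state = SHRINKING
        return mt
    # shrinking
    dL = v_shrink * dt
    if dL >= mt.length:
        pool.depolymerize(mt.length)
        if mt.anchor is not None:
            mt.anchor.occupied = False
        return None
    pool.depolymerize(dL)
    rem = dL
    while rem > 0:
        if mt.last_segment > rem:
            mt.vertices[-1] = mt.vertices[-1] - mt.tip_tangent * rem
            mt.last_segment -= rem
            rem = 0.0
        else:
            rem -= mt.last_segment
            mt.vertices = mt.vertices[:-1]
            mt.last_segment = l0
    return mt


def try_nucleate(site: NucleationSite, rate: float, dt: float,
                 rng: np.random.Generator, pool: TubulinPool,
                 host_mt_count: int, max_mts_per_host: int,
                 segment_length: float, seed_length: float = 0.05
                 ) -> Optional[Microtubule]:
    """First-order nucleation attempt at a free site.

    With probability 1 − exp(−rate·dt), creates a short growing MT whose
    initial direction is +x or −x with equal probability (horizontal
    nucleation), minus end anchored at the site.  Gated by site occupancy,
    the per-host MT cap, and pool availability.
    """
    if site.occupied or host_mt_count >= max_mts_per_host:
        return None
    if pool.L_polymerized + seed_length > pool.L_max:
        return None
    if rng.random() >= 1.0 - np.exp(-rate * dt):
        return None
    direction = np.array([1.0, 0.0]) if rng.random() < 0.5 else np.array([-1.0, 0.0])
    v0 = site.position.astype(float)
    mt = Microtubule(
        vertices=np.vstack([v0, v0 + direction * seed_length]),
        segment_length_target=segment_length,
        last_segment=seed_length,
        plus_state=GROWING,
        anchor=site)
    site.occupied = True
    pool.polymerize(seed_length)
    return mt
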