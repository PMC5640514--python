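"""Motors and crosslinkers linking MTs to nuclei and to each other.

Four species: NE-anchored dynein (minus-end-directed) and Kif5b (plus-end-
directed) whose first head is a permanent anchor on a nucleus surface;
cytoplasmic MAP4 (passive–passive crosslinker) and the MAP7–Kif5b complex
(passive MT binder + plus-end motor), which organizes and slides
antiparallel MT pairs.  Heads bind MTs as first-order events within a
capture radius, unbind force-independently, exert zero-rest-length Hookean
spring forces, and motor heads move along the fiber with a linear
force–velocity relation (stall force f_s, no walking backward).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .config import MotorParams

HEAD_KINDS = ("anchor", "passive", "motor")


@dataclass(frozen=True)
class ConnectorSpecies:
    """A two-headed connector type; head kinds per the module docstring."""

    name: str
    head_kinds: tuple[str, str]
    params: MotorParams

    def __post_init__(self) -> None:
        for k in self.head_kinds:
            if k not in HEAD_KINDS:
                raise ValueError(f"bad head kind {k!r}")
        if "motor" in self.head_kinds:
            if self.params.v0 <= 0 or self.params.f_stall <= 0:
                raise ValueError("motor heads need v0 > 0 and f_stall > 0")
        elif self.params.v0 != 0:
            raise ValueError("passive connectors must have v0 = 0")


def attach_probability(k_on: float, dt: float) -> float:
    """First-order binding probability over one step: 1 − exp(−k_on·dt)."""
    return 1.0 - np.exp(-k_on * dt)


def detach_probability(k_off: float, dt: float) -> float:
    return 1.0 - np.exp(-k_off * dt)


def attach(head_point, candidates: Sequence[tuple[int, np.ndarray, float]],
           k_on: float, capture_radius: float, dt: float,
           rng: np.random.Generator) -> Optional[tuple[int, float]]:
    """Attempt to bind a free head to a nearby MT point.

    ``candidates`` is a sequence of (mt_id, point, abscissa).  With
    probability 1 − exp(−k_on·dt) the head binds the nearest candidate
    within the capture radius; ties resolve to the smallest distance then
    the lowest mt_id.  Returns (mt_id, abscissa) or None.
    """
    head_point = np.asarray(head_point, dtype=float)
    eligible = []
    for mt_id, point, abscissa in candidates:
        d = float(np.hypot(*(np.asarray(point, dtype=float) - head_point)))
        if d <= capture_radius:
            eligible.append((d, mt_id, abscissa))
    if not eligible:
        return None
    if rng.random() >= attach_probability(k_on, dt):
        return None
    d, mt_id, abscissa = min(eligible)
    return mt_id, abscissa


def detach(dt: float, k_off: float, rng: np.random.Generator) -> bool:
    """Force-independent first-order unbinding of a bound head."""
    return rng.random() < detach_probability(k_off, dt)


def motor_velocity(f_parallel: float, v0: float, f_stall: float) -> float:
    """Linear force–velocity law.

    ``f_parallel`` is the load component along the direction of motion
    (negative = opposing).  v = v0·(1 − f_opposing/f_stall), clamped to
    [0, v0]: the motor stalls rather than walks backward, and assisting
    load does not push it beyond v0.
    """
    if f_stall <= 0:
        raise ValueError("f_stall must be > 0")
    f_opposing = max(0.0, -f_parallel)
    return float(np.clip(v0 * (1.0 - f_opposing / f_stall), 0.0, v0))


def connector_forces(point_a, point_b, k: float
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Zero-rest-length Hookean spring force pair between two head points."""
    point_a = np.asarray(point_a, dtype=float)
    point_b = np.asarray(point_b, dtype=float)
    f_on_a = k * (point_b - point_a)
    return f_on_a, -f_on_a


def walk(abscissa: float, f_parallel: float, dt: float, species: MotorParams,
         mt_length: float) -> float:
    """Advance a bound motor head along its MT by v·dt.

    Plus-end-directed heads (directionality +1) move toward larger
    abscissa, minus-end-directed (−1) toward zero; passive heads (v0 = 0)
    stay put.  Heads dwell at the fiber ends until they unbind.
    """
    if species.v0 == 0.0 or species.directionality == 0:
        return float(np.clip(abscissa, 0.0, mt_length))
    v = motor_velocity(f_parallel, species.v0, species.f_stall)
    s = abscissa + species.directionality * v * dt
    return float(np.clip(s, 0.0, mt_length))
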