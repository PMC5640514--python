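"""Overdamped Langevin mechanics: bodies, confinement, soft excluded volume.

Nuclei and centrosome-like structures are rigid disks that translate (no
rotation) through a homogeneous viscous cytoplasm with Stokes drag
γ = 6πηR.  Each degree of freedom moves by (F/γ)·dt plus Brownian noise
√(2·kT·dt/γ)·ξ.  The elliptical myotube boundary confines everything via a
soft penalty toward the nearest boundary point; bodies use the ellipse
reduced by their radius.  Excluded volume between bodies (and between MT
vertices and bodies) is a soft linear repulsion; MT–MT pairs are exempt —
fibers interact with each other only through connectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import MyotubeDomain
from .engine import nearest_on_ellipse


@dataclass
class Body:
    """Rigid disk (nucleus or centrosome-like structure)."""

    kind: str
    position: np.ndarray
    radius: float
    drag: float

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.radius <= 0 or self.drag <= 0:
            raise ValueError("radius and drag must be > 0")


def stokes_drag(viscosity: float, radius: float) -> float:
    """Translational drag γ = 6πηR (pN·s/μm)."""
    return 6.0 * np.pi * viscosity * radius


def nearest_boundary_point(domain: MyotubeDomain, point) -> np.ndarray:
    """Closest point on the ellipse boundary for a point on or outside it."""
    qx, qy = nearest_on_ellipse(domain.half_length_a, domain.half_width_b,
                                float(point[0]), float(point[1]))
    return np.array([qx, qy])


def confinement_force(point, domain: MyotubeDomain, k: float,
                      body_radius: float = 0.0) -> np.ndarray:
    """Soft confinement penalty on a point (or body center).

    Zero inside the ellipse (reduced by ``body_radius`` for finite-size
    bodies); an outward excursion produces a restoring force of magnitude
    k × penetration depth, directed toward the nearest boundary point.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    a = domain.half_length_a - body_radius
    b = domain.half_width_b - body_radius
    if a <= 0 or b <= 0:
        raise ValueError("body too large for the domain")
    x, y = float(point[0]), float(point[1])
    if (x / a) ** 2 + (y / b) ** 2 <= 1.0:
        return np.zeros(2)
    qx, qy = nearest_on_ellipse(a, b, x, y)
    return k * np.array([qx - x, qy - y])


def steric_force(body_a: Body, body_b: Body, k: float
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Soft excluded-volume pair force between two bodies.

    Zero at center distance ≥ rA+rB, otherwise equal-and-opposite linear
    repulsion k × overlap along the center line.  Coincident centers fall
    back to the +x axis.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    d = body_a.position - body_b.position
    dist = float(np.hypot(*d))
    overlap = body_a.radius + body_b.radius - dist
    if overlap <= 0:
        return np.zeros(2), np.zeros(2)
    u = d / dist if dist > 1e-9 else np.array([1.0, 0.0])
    f = k * overlap * u
    return f, -f


def point_body_steric(point, body: Body, k: float
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Soft repulsion between a zero-radius point (an MT vertex) and a body."""
    probe = Body("point", np.asarray(point, dtype=float), 1e-12, 1.0)
    f_point, f_body = steric_force(probe, body, k)
    return f_point, f_body


def langevin_step(positions, forces, drags, kT: float, dt: float,
                  rng: np.random.Generator) -> np.ndarray:
    """One overdamped Euler–Maruyama step for a set of point DOFs.

    positions, forces: (n, 2); drags: (n,).  Raises on non-finite force,
    naming the offending entry.
    """
    positions = np.asarray(positions, dtype=float)
    forces = np.asarray(forces, dtype=float)
    drags = np.asarray(drags, dtype=float).reshape(-1, 1)
    if dt <= 0:
        raise ValueError("dt must be > 0")
    bad = ~np.isfinite(forces).all(axis=1)
    if bad.any():
        raise FloatingPointError(
            f"non-finite force on degree(s) of freedom {np.where(bad)[0].tolist()}")
    noise = rng.standard_normal(positions.shape) if kT > 0 else 0.0
    return positions + forces / drags * dt + np.sqrt(2.0 * kT * dt / drags) * noise
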