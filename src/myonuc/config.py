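"""Parameter registry, condition definitions, and myotube domain construction.

The simulated myotube is a 2D ellipse whose long axis lies along +x. Its
size follows the per-nucleus sizing rule used throughout: a myotube carrying
``n`` nuclei is ``19·n`` μm long and 14 μm wide, which for n = 5..9 gives the
five canonical geometries 95, 114, 133, 152 and 171 μm × 14 μm.

All tunable physics lives in :class:`SimulationParams`.  Defaults form a
documented ledger (see ``docs/methods.md``); every value can be overridden
from a YAML config and the fully resolved set can be echoed with provenance.
"""

from __future__ import annotations

import dataclasses
import io
import logging
from dataclasses import dataclass, field

import numpy as np
import yaml

log = logging.getLogger(__name__)

#: full myotube width in μm (the ellipse minor axis, 2b)
MYOTUBE_WIDTH_UM = 14.0
#: myotube length per nucleus in μm (the ellipse major axis is 19·n)
LENGTH_PER_NUCLEUS_UM = 19.0

CONDITION_NAMES = ("control", "no_ne_nucleation", "no_ne_nucleation_no_kif5b")


@dataclass(frozen=True)
class MyotubeDomain:
    """Elliptical 2D confinement region, centered at the origin.

    ``half_length_a`` is along +x (the myotube long axis), ``half_width_b``
    along y.  Lengths in μm.
    """

    half_length_a: float
    half_width_b: float

    def __post_init__(self) -> None:
        if not (self.half_length_a > self.half_width_b > 0):
            raise ValueError(
                f"ellipse requires a > b > 0, got a={self.half_length_a}, "
                f"b={self.half_width_b}"
            )

    @property
    def length(self) -> float:
        """Full myotube length 2a in μm."""
        return 2.0 * self.half_length_a

    @property
    def width(self) -> float:
        """Full myotube width 2b in μm."""
        return 2.0 * self.half_width_b

    def contains(self, point, margin: float = 0.0) -> bool:
        """True if ``point`` lies inside the ellipse shrunk by ``margin``."""
        a = self.half_length_a - margin
        b = self.half_width_b - margin
        if a <= 0 or b <= 0:
            return False
        x, y = float(point[0]), float(point[1])
        return (x / a) ** 2 + (y / b) ** 2 <= 1.0


def make_domain(nucleus_count: int) -> MyotubeDomain:
    """Myotube ellipse for a given nucleus count.

    Full length is 19 μm per nucleus (95 μm for five nuclei up to 171 μm for
    nine); full width is always 14 μm.  Counts outside 5..9 use the same
    per-nucleus rule, flagged in the log as extrapolated.
    """
    if int(nucleus_count) != nucleus_count or nucleus_count < 2:
        raise ValueError(f"nucleus_count must be an integer >= 2, got {nucleus_count}")
    n = int(nucleus_count)
    if not 5 <= n <= 9:
        log.info("nucleus_count %d outside 5..9: domain length extrapolated as 19*n", n)
    return MyotubeDomain(
        half_length_a=LENGTH_PER_NUCLEUS_UM * n / 2.0,
        half_width_b=MYOTUBE_WIDTH_UM / 2.0,
    )


@dataclass(frozen=True)
class ConditionSpec:
    """One of the three simulated perturbations.

    ``ne_nucleation``: nuclei nucleate MTs from their envelope.
    ``ne_kif5b``: plus-end motors (Kif5b) anchored at the NE.
    ``cytoplasmic_centrosomes``: number of mobile centrosome-like bodies that
    take over nucleation when the NE is inactive (one per nucleus).
    NE dynein is retained in all three conditions (toggle in params).
    """

    name: str
    ne_nucleation: bool
    ne_kif5b: bool
    cytoplasmic_centrosomes_per_nucleus: int


def make_condition(name: str) -> ConditionSpec:
    """Build one of the three canonical conditions by name.

    ``control``: MTs nucleated from the NE, Kif5b at the NE.
    ``no_ne_nucleation``: nucleation moved to randomly placed cytoplasmic
    centrosome-like structures (one per nucleus); NE Kif5b retained.
    ``no_ne_nucleation_no_kif5b``: additionally removes Kif5b from the NE.
    """
    if name == "control":
        return ConditionSpec(name, ne_nucleation=True, ne_kif5b=True,
                             cytoplasmic_centrosomes_per_nucleus=0)
    if name == "no_ne_nucleation":
        return ConditionSpec(name, ne_nucleation=False, ne_kif5b=True,
                             cytoplasmic_centrosomes_per_nucleus=1)
    if name == "no_ne_nucleation_no_kif5b":
        return ConditionSpec(name, ne_nucleation=False, ne_kif5b=False,
                             cytoplasmic_centrosomes_per_nucleus=1)
    raise ValueError(f"unknown condition {name!r}; expected one of {CONDITION_NAMES}")


@dataclass(frozen=True)
class MotorParams:
    """Per-species connector parameters.

    ``v0`` is the unloaded speed in μm/s; ``directionality`` is +1 for
    plus-end-directed heads (kinesin) and −1 for minus-end-directed (dynein);
    passive binders have v0 = 0.  Binding is first-order at ``k_on`` within
    ``capture_radius``; unbinding is first-order at ``k_off``, amplified
    under load by the Kramers factor exp(F/detach_force) (set
    ``detach_force = inf`` for strictly force-independent unbinding).  The
    link is a zero-rest-length Hookean spring of stiffness ``spring_k``.
    """

    v0: float
    directionality: int
    f_stall: float
    k_on: float
    k_off: float
    capture_radius: float
    spring_k: float
    detach_force: float = 3.0

    def __post_init__(self) -> None:
        if self.v0 < 0 or self.k_on < 0 or self.k_off < 0:
            raise ValueError("rates and speeds must be >= 0")
        if self.v0 > 0 and self.f_stall <= 0:
            raise ValueError("motor heads require f_stall > 0")
        if self.capture_radius <= 0 or self.spring_k < 0:
            raise ValueError("capture_radius > 0 and spring_k >= 0 required")
        if self.detach_force <= 0:
            raise ValueError("detach_force must be > 0 (inf disables)")


@dataclass
class SimulationParams:
    """Full physical parameter set with documented defaults.

    Units: μm, s, pN (so kT in pN·μm, viscosity in pN·s/μm²).
    """

    # integration
    dt: float = 0.02                     # s
    duration: float = 1800.0             # s
    temperature_kT: float = 0.0042       # pN·μm (≈ 37 °C)
    viscosity: float = 1.0               # pN·s/μm², homogeneous cytoplasm

    # bodies
    nucleus_radius: float = 4.0          # μm
    nucleus_count: int = 5
    centrosome_radius: float = 1.0       # μm
    centrosomes_mobile: bool = False     # anchored in the cytoplasmic matrix
    initial_arrangement: str = "clustered"  # nuclei at t=0: clustered | uniform | dispersed

    # microtubules
    mt_rigidity: float = 20.0            # pN·μm² bending rigidity
    segment_length: float = 4.0          # μm, fiber discretization
    v_grow0: float = 0.2                 # μm/s unloaded growth at full pool
    v_shrink: float = 0.4                # μm/s
    force_sensitivity_fg: float = 1.5    # pN, growth-force sensitivity
    tubulin_pool_per_nucleus: float = 500.0  # μm polymer-equivalent per nucleus
    cat_time_free: float = 600.0         # s, mean catastrophe time, free growth
    cat_time_stalled: float = 60.0       # s, mean catastrophe time, stalled
    nucleation_rate: float = 0.1         # 1/s per free site
    max_mts_per_nucleus: int = 5         # nucleation-site cap per body

    # connectors
    dynein_per_nucleus: int = 2
    kif5b_per_nucleus: int = 50
    map4_per_myotube: int = 50
    map7kif5b_per_myotube: int = 100
    ne_dynein_retained: bool = True      # dynein stays at the NE in all conditions
    connector_diffusion: float = 1.0     # μm²/s for unbound cytoplasmic complexes
    dynein: MotorParams = field(default_factory=lambda: MotorParams(
        v0=1.0, directionality=-1, f_stall=5.0, k_on=1.0, k_off=1.0,
        capture_radius=0.3, spring_k=100.0))
    kif5b: MotorParams = field(default_factory=lambda: MotorParams(
        v0=0.8, directionality=+1, f_stall=5.0, k_on=5.0, k_off=0.5,
        capture_radius=0.3, spring_k=100.0))
    map4: MotorParams = field(default_factory=lambda: MotorParams(
        v0=0.0, directionality=0, f_stall=0.0, k_on=5.0, k_off=0.5,
        capture_radius=0.3, spring_k=100.0))
    map7kif5b: MotorParams = field(default_factory=lambda: MotorParams(
        v0=0.8, directionality=+1, f_stall=5.0, k_on=5.0, k_off=0.5,
        capture_radius=0.3, spring_k=100.0))

    # interaction stiffnesses
    confinement_k: float = 100.0         # pN/μm
    steric_k: float = 100.0              # pN/μm

    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        positive = ("dt", "nucleus_radius", "centrosome_radius", "segment_length",
                    "force_sensitivity_fg", "cat_time_stalled", "cat_time_free",
                    "viscosity")
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        nonneg = ("duration", "temperature_kT", "v_grow0", "v_shrink",
                  "tubulin_pool_per_nucleus", "nucleation_rate", "confinement_k",
                  "steric_k", "connector_diffusion")
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.cat_time_free < self.cat_time_stalled:
            raise ValueError("cat_time_free must be >= cat_time_stalled")
        if self.max_mts_per_nucleus < 1:
            raise ValueError("max_mts_per_nucleus must be >= 1")
        for count in ("nucleus_count", "dynein_per_nucleus", "kif5b_per_nucleus",
                      "map4_per_myotube", "map7kif5b_per_myotube"):
            if getattr(self, count) < 0 or int(getattr(self, count)) != getattr(self, count):
                raise ValueError(f"{count} must be a non-negative integer")
        if self.nucleus_count < 2:
            raise ValueError("nucleus_count must be >= 2")
        if self.initial_arrangement not in ("uniform", "clustered", "dispersed"):
            raise ValueError("initial_arrangement must be uniform, clustered "
                             "or dispersed")

    @property
    def tubulin_pool_Lmax(self) -> float:
        """Total polymer-equivalent tubulin pool for this myotube (μm)."""
        return self.tubulin_pool_per_nucleus * self.nucleus_count


_MOTOR_FIELDS = {"dynein", "kif5b", "map4", "map7kif5b"}


def dump_params(params: SimulationParams) -> str:
    """Serialize a parameter set to YAML (round-trips via :func:`load_params`)."""
    d = {}
    for f in dataclasses.fields(params):
        v = getattr(params, f.name)
        d[f.name] = dataclasses.asdict(v) if f.name in _MOTOR_FIELDS else v
    buf = io.StringIO()
    yaml.safe_dump(d, buf, sort_keys=False)
    return buf.getvalue()


def load_params(config_text: str | None = None) -> SimulationParams:
    """Resolve a YAML config against the default ledger.

    Absent keys take their defaults; unknown keys and invalid values raise a
    :class:`ValueError` naming the key.  The resolved set is echoed to the
    log with per-key provenance (default vs user).
    """
    data = yaml.safe_load(config_text) if config_text else None
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError("config must be a mapping of parameter names to values")
    known = {f.name for f in dataclasses.fields(SimulationParams)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        if key in _MOTOR_FIELDS:
            if not isinstance(value, dict):
                raise ValueError(f"{key} must be a mapping of motor parameters")
            base = dataclasses.asdict(getattr(SimulationParams(), key))
            bad = set(value) - set(base)
            if bad:
                raise ValueError(f"unknown {key} keys: {sorted(bad)}")
            base.update(value)
            try:
                kwargs[key] = MotorParams(**base)
            except ValueError as e:
                raise ValueError(f"invalid value under {key!r}: {e}") from e
        else:
            kwargs[key] = value
    try:
        params = SimulationParams(**kwargs)
    except (TypeError, ValueError) as e:
        raise ValueError(f"invalid config: {e}") from e
    for f in dataclasses.fields(params):
        origin = "user" if f.name in data else "default"
        log.debug("param %-26s = %-12r (%s)", f.name, getattr(params, f.name), origin)
    return params
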