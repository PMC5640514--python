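# Methods

## Scope

`myonuc` contains three connected components:

1. an agent-based mechanical simulation of myonuclear positioning in
   myotubes (microtubules nucleated from the nuclear envelope, NE-anchored
   dynein and Kif5b, cytoplasmic crosslinkers, elliptical confinement);
2. the nuclear spreading-factor (SF) statistic with Mann-Whitney condition
   comparisons, applicable to simulated and imaged nucleus tables alike;
3. a BioID/TMT quantitation pipeline (bait normalization, ±DOX ratios,
   myotube-enrichment filter) with a synthetic-screen generator.

## The mechanical model

### Geometry and bodies

A myotube is a 2D ellipse with its long axis along x.  A myotube carrying
*n* nuclei is 19·*n* μm long and 14 μm wide (95 × 14 μm for five nuclei up
to 171 × 14 μm for nine).  Nuclei are rigid disks of radius 4 μm;
centrosome-like structures (present only when NE nucleation is disabled)
are disks of radius 1 μm, anchored in place — they stand for
PCM1/Akap450-positive seeds embedded in the cytoplasmic matrix.  (Mobile
centrosome-like bodies are an option, but free disks of this size are
pushed to the myotube poles by motor reaction forces within minutes of
simulated time, after which every plus end points inward and NE kinesin
compacts the nuclei — a geometry artifact rather than a biological
prediction.)  Nuclei translate but do not rotate; in 2D at
this scale rotation adds little because all anchors live on circles and
the nucleation directions are horizontal.  Drag is Stokes-like,
γ = 6πηR, with a homogeneous cytoplasmic viscosity η = 1 pN·s/μm².

### Equations of motion

All degrees of freedom (body centers and fiber vertices) obey overdamped
Langevin dynamics: per step each moves by (F/γ)·dt plus Brownian noise
√(2·kT·dt/γ)·ξ with kT = 0.0042 pN·μm (37 °C).  Explicit Euler–Maruyama is
used; with the default stiffnesses (100 pN/μm) and drags, the stiffest
relaxation rate times dt is ≤ 0.5 at dt = 0.02 s, inside the stability
region.  A time-step-halving check on the ensemble mean SF is part of the
test suite.

### Microtubules

MTs are polarized vertex chains (segment target 4 μm) with harmonic
bending rigidity κ = 20 pN·μm² (small-angle discretization).
Inextensibility is enforced by projecting segment lengths back to their
stored values after each move, walking outward from the anchored minus
end; this replaces a stiff stretching penalty, which at these drags would
have forced a much smaller time step for no observable difference in
behaviour.  The minus end is pinned to its nucleation site (a point on the
host surface); forces landing on the minus-end vertex are transferred to
the host body, so momentum bookkeeping closes.

Plus ends show dynamic instability without rescue.  The growth speed is

    v = v0 · (1 − L_poly/L_max) · exp(−f_antag / f_g),

with v0 = 0.2 μm/s, a fixed tubulin pool of 500 μm polymer-equivalent per
nucleus shared across the myotube, and force sensitivity f_g = 1.5 pN;
only the force component antiparallel to the tip tangent attenuates
growth.  The catastrophe rate rises as growth slows: the mean catastrophe
time interpolates linearly in v/v0 between the stalled value (60 s) and
the free-growth value (600 s).  Shrinkage is 0.4 μm/s; a fiber reaching
zero length is removed and its site freed.  Nucleation is a first-order
event (0.1 s⁻¹ per free site, 5 sites per nucleation-competent body,
giving steady-state fibers of a few tens of μm — long enough to span the
~19 μm internuclear spacing, which is what the inter-nuclear force network
requires),
gated by pool availability; new fibers start horizontal, +x or −x with
equal probability.  MTs have no mutual excluded volume — they interact
with each other only through connectors — while body–body and MT–body
pairs repel softly (k = 100 pN/μm times overlap).  The elliptical boundary
confines everything via the same soft penalty toward the nearest boundary
point (bodies use the ellipse reduced by their radius); the nearest-point
projection is solved by bisection to ~1e-12 μm.

### Connectors

Four two-headed species, all exerting zero-rest-length Hookean spring
forces (k = 100 pN/μm) and obeying a linear force–velocity law
v = v0(1 − f/f_stall) clamped to [0, v0] (stall 5 pN):

| species | head 1 | head 2 | count (default) |
|---|---|---|---|
| NE dynein | anchor on nucleus | motor, minus-directed, 1.0 μm/s | 2 per nucleus |
| NE Kif5b | anchor on nucleus | motor, plus-directed, 0.8 μm/s | 50 per nucleus |
| MAP4 | passive MT binder | passive MT binder | 50 per myotube |
| MAP7–Kif5b | passive MT binder (MAP7) | motor, plus-directed (Kif5b) | 100 per myotube |

Binding is first-order (k_on = 5 s⁻¹ for kinesin and the cytoplasmic
species, 1 s⁻¹ for NE dynein, within a 0.3 μm capture radius,
nearest eligible fiber point, ties to the lowest fiber id); unbinding is
first-order (k_off = 0.5 s⁻¹; 1 s⁻¹ for NE dynein) amplified under load by a Kramers factor
exp(F/3 pN).  Motor heads dwell at fiber ends until they unbind, but a
head overtaken by a *shrinking* plus end is released rather than dragged —
without these two rules (load-dependent release, shrinking-end release)
end-bound heads act as unbreakable kinematic tethers whose spring force is
unbounded, and the resulting artificial cohesion overwhelms every other
force in the model.  NE-anchored motors do not bind fibers nucleated by
their own nucleus: that self-load is internal (it nets to zero on the
body) but would keep essentially every NE motor occupied in 2D, where a
nucleus's own fibers hug its surface; excluding it lets NE motors act on
passing fibers, which is the interaction the model is about.  Unbound
cytoplasmic connectors diffuse (D = 1 μm²/s) inside the ellipse.

### Conditions and initialization

Three conditions: control (NE nucleation + NE Kif5b), relocated nucleation
(NE sites inactive, one anchored centrosome-like body per nucleus placed
uniformly at random, NE Kif5b retained), and relocated nucleation without
NE Kif5b.  NE dynein is retained in all three (a toggle exists).  Nuclei
start in a contact cluster at the domain center — spreading is the
observable — with small lateral jitter and overlap-free placement by
steric relaxation.  There are no MTs at t = 0.

The per-step order is: force accumulation → Langevin move → MT dynamic
instability → connector kinetics (release/unbind/walk/bind) → nucleation.

### Randomness and determinism

Every variate is a counter-based hash of (seed, step, purpose, entity)
(splitmix64 finalizer, Box–Muller for normals).  A replicate is therefore
a bit-exact pure function of (condition, params, seed); replicates are
independent by construction; and two conditions run with the same seed
consume identical randomness for each shared entity, so their nuclear
trajectories coincide until the first nucleation event makes them differ —
a property the tests assert directly.

### Parameter provenance and calibration

The printed sources fix the geometry table, the 1.5 pN growth-force
sensitivity, the existence of a fixed tubulin pool, growth-dependent
catastrophe, no-rescue dynamic instability, horizontal nucleation, the
motor/crosslinker cast, and first-order event statistics.  The remaining
numbers (motor counts and kinetics, catastrophe times, pool size, capture
radius, nucleation rate, stiffnesses, dt, duration) are this package's
default ledger: values were chosen in the physiological range and then
calibrated *as a set* so that the control condition shows steady, nearly
complete nuclear dispersal within the simulated duration while the
perturbed conditions disperse less — the qualitative regime the model is
meant to operate in.  They are defaults, not measurements; all are
overridable from a YAML config, and the resolved set is echoed with
provenance.  Two calibration observations worth recording: (i) with
force-independent unbinding the minus-end-dwelling dynein stalls all
motion (see above), so load-dependent release is on by default; (ii) with
a 30 s stalled-catastrophe time fibers die before spanning the ~19 μm
internuclear spacing and no long-range ordering can build, so the stalled
mean catastrophe time defaults to 60 s (stalled plus ends catastrophe
within about a minute in vitro, and pruning stalled tips keeps the network
from jamming); (iii) NE dynein is kept sparse
and weakly engaged — with strong, processive dynein the perturbed
conditions *disperse* (nuclei are transported to the scattered
centrosome-like seeds) instead of clustering.

Under this ledger the control condition disperses its nuclei nearly evenly
(mean SF ≈ 0.8 at 1800 s), while both perturbed conditions leave nuclei
clustered around the myotube center (mean SF ≈ 0.25–0.4).  The ranking
*between* the two perturbed conditions comes out opposite to the imaging
literature's expectation: here, NE kinesin acting on cytoplasmically
anchored tracks compresses the central cluster slightly *below* the
no-kinesin baseline, because the anchored seeds necessarily surround the
initial cluster and their plus ends point inward, so kinesin transport is
net-centripetal.  Every examined variation (motor counts and kinetics,
processivity, fiber length and pool, seed mobility/size/count, initial
arrangements, longer durations) either preserved this inversion or
destroyed the much larger control-versus-perturbed separation.  The
control-versus-perturbed contrast is the robust model output; the fine
ranking between the two perturbed conditions is not a prediction this
model supports, and the corresponding test documents that by failing on
that single inequality.

Simulated durations: 1800 s by default (the control SF trajectory
approaches its plateau; a plateau diagnostic is available from
`SimulationResult.sf_series`).  Ensembles used by the analysis scripts and
the acceptance checks run 20 replicates per condition with nucleus counts
cycling 5–9, ~6 s of wall clock per replicate.

## The spreading factor

For one myotube with N ≥ 3 nuclei at axial positions x_i in [0, L],

    SF = mean over unordered pairs of |x_i − x_j|  /  E(N, L),
    E(N, L) = L (N + 1) / (3 (N − 1)),

where E(N, L) is the all-pairs mean distance of N points evenly spaced
from 0 to L.  SF = 1 for perfectly even spacing spanning the tube and → 0
as nuclei collapse.  "Average distance" is read as the all-pairs mean
(robust to ordering); a consecutive-neighbour variant is available behind
a flag for sensitivity analysis.  The reference is the even-spacing value
rather than the literal maximizer of the mean pairwise distance (which
would be end-clustering, giving SF > 1 for a phenotype everyone would call
maximally *un*-spread); under this reading lower SF = less spread, which
matches how the statistic is used.  Myotubes with fewer than three nuclei
are excluded, with the exclusion logged.  Experimental 2D centroids should
be projected on the myotube's principal axis upstream; simulated nuclei
use x directly.

Condition comparisons report per-group mean, interquartile range and n,
with two-sided Mann-Whitney tests between groups: exact enumeration when
the smaller group has ≤ 8 observations without ties, otherwise the normal
approximation with tie and continuity corrections (scipy's rank-sum
machinery behind this module's interface; an independent enumeration
oracle checks it in the tests).

## BioID/TMT quantitation

Input: a protein × sample reporter-abundance table over
(myoblast, myotube) × (untreated, biotin-only, +DOX+biotin) × replicate,
with a flagged bait row; missing values are explicit NaN and never
silently imputed.  Steps:

1. **Identification gate** — keep proteins identified in ≥ 2 biological
   replicates.
2. **Bait normalization** — every +DOX sample column is scaled so the bait
   level equals the geometric mean of bait levels across +DOX samples;
   −DOX controls, where the bait is not induced, are untouched.  Factors
   are logged.  Scaling any raw +DOX column by a constant moves only the
   geometric-mean reference, so all ratios shift by one protein-independent
   constant and all ratio-of-ratios are exactly invariant.
3. **±DOX ratio** — r = abundance(+DOX+biotin) / (abundance(−DOX control) +
   pseudocount), per state and replicate; the control is the biotin-only
   sample when present, else untreated.  The pseudocount defaults to the
   smallest nonzero abundance in the control column, keeping ratios finite
   for proteins absent from the control (flagged, logged).
4. **Enrichment filter** — per replicate a protein is myotube-enriched
   when r_myotube / r_myoblast ≥ the fold threshold; it passes when
   enriched in ≥ 2 of 3 replicates.  The default threshold is 2.0, the
   log-space midpoint between the background expectation (ratio-of-ratios
   = 1) and the 4-fold planted effect the synthetic screen models; with
   20 % measurement CV the per-replicate log ratio-of-ratios has σ ≈ 0.4,
   so threshold 2 leaves ≈ 1.75 σ of margin on both sides.  The published
   candidate count depends on an unprinted cutoff, so a threshold sweep is
   reported instead of asserting any single count; matching the published
   set exactly would additionally require the original supplementary
   table, which can be supplied in the documented schema.

## Synthetic data

**Nucleus tables** emulate imaged myotube phenotypes in three regimes:
clustered (Gaussian around the midpoint, truncated), dispersed (even
spacing + uniform jitter), uniform (i.i.d.).  Lengths follow the 19 μm-
per-nucleus rule.  **TMT tables** draw protein base abundances from a
log-normal, give background proteins equal expected ±DOX ratios in both
cell states, multiply the planted interactors' myotube +DOX abundance by
the effect size (default 4), apply per-sample bait scale factors to whole
+DOX columns (undone exactly by bait normalization), multiplicative
log-normal noise at the stated CV (default 20 %), and missingness
completely at random (default 1 %, a typical reporter-ion missingness
level after the identification gate).  Truth labels are always emitted
next to the data.

What the generators do *not* emulate — segmentation errors and myotube
outline curvature in the nucleus tables; peptide-level rollup,
isotope-impurity crosstalk, ratio compression, and intensity-dependent
missingness in the TMT tables.  Tests passing on these generators
therefore validate the statistics and the pipeline plumbing, not
robustness to those real-data artifacts.

## Numerical choices and degenerate inputs

Ellipse nearest-point by bisection (tolerance ~1e-12 μm, exact for
on-axis points); coincident body centers repel along +x (logged
deterministic fallback); binding ties break by distance then lowest fiber
id; motor heads at fiber ends dwell (growing/static ends) or release
(shrinking ends); zero-length fibers are removed and their sites freed;
non-finite forces abort with a diagnostic naming the degree of freedom;
numerical blow-up (non-finite positions) aborts with dt guidance.

## Known limitations

2D only; no nuclear deformation or rotation; no hydrodynamic coupling; no
MT rescue, severing, or minus-end dynamics; motor stepping is continuous
(no discrete steps or ATP kinetics); the parameter ledger is a calibrated
stand-in where the sources print no values; SF saturation near 1 depends
on the simulated duration and motor balance, so absolute simulated SF
values should be read as model output under this ledger, not as
predictions of imaging values.
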