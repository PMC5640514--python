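# myonuc — myonuclear positioning: simulation, spreading statistics, and BioID quantitation

In differentiated skeletal muscle cells (myotubes), the centrosomal
proteins that normally nucleate microtubules relocate to the nuclear
envelope (NE), turning each nucleus into a microtubule-organizing center.
This NE nucleation activity — recruited through the muscle-specific LINC
component Nesprin-1α and the scaffold Akap450 — matters because myotube
nuclei must spread out evenly along the fiber, and mispositioned nuclei
are a hallmark of several muscular dystrophies.  `myonuc` is a desk-scale
toolkit for studying this system computationally:

* **Simulation** — an agent-based mechanical model of nuclei in a 2D
  elliptical myotube (19 μm of length per nucleus × 14 μm wide).  Nuclei
  nucleate microtubules from their envelope; fibers undergo dynamic
  instability without rescue, with growth slowed by force (sensitivity
  1.5 pN) and by depletion of a fixed tubulin pool, and catastrophe
  accelerating as growth slows.  NE-anchored dynein and Kif5b plus
  cytoplasmic MAP4 and MAP7–Kif5b crosslinkers couple fibers to nuclei and
  to each other with Hookean springs and a linear force–velocity law; all
  motion follows overdamped Langevin dynamics.  Three conditions mirror
  the biology: control; nucleation relocated from the NE to anchored
  cytoplasmic centrosome-like seeds (NE Kif5b retained); and additionally
  removing NE Kif5b.
* **Spreading factor (SF)** — the dispersion statistic for nuclei along a
  myotube: the mean pairwise axial distance between nuclei divided by the
  even-spacing reference E(N, L) = L(N+1)/(3(N−1)); SF = 1 for evenly
  spread nuclei, → 0 for a clump.  Myotubes need ≥ 3 nuclei to be scored.
  Conditions/genotypes are compared with two-sided Mann-Whitney tests
  (exact for small groups without ties).
* **BioID/TMT quantitation** — bait-normalized reporter abundances,
  +DOX/−DOX labeling ratios, and the ≥2-of-3-replicates myotube-enrichment
  filter that defines candidate NE interactors, plus a threshold-sweep
  report.
* **Synthetic data** — generators for nucleus-centroid tables (clustered /
  dispersed / uniform regimes) and TMT screens with planted interactors
  and ground-truth labels, so every pipeline stage is testable without
  downloads.

See `docs/methods.md` for the full model description, the parameter
ledger, and known limitations.

## Worked example

Spreading factor of one myotube and a tiny simulation:

```python
>>> import numpy as np
>>> from myonuc import MyotubeNuclei, spreading_factor
>>> spreading_factor(MyotubeNuclei("m1", length=100.0, x=[0.0, 10.0, 20.0]))
0.2
```

Three nuclei packed into one end of a 100 μm myotube have a mean pairwise
distance of 40/3 μm against an even-spacing reference of 200/3 μm —
SF = 0.2, a strongly clustered myotube.  A full simulated replicate:

```python
>>> from myonuc import SimulationParams, simulate
>>> res = simulate("control", SimulationParams(nucleus_count=5), seed=1)
>>> round(float(res.sf_series[0]), 2), round(float(res.sf_series[-1]), 2)
(0.35, 0.64)
```

Five nuclei that start as a contact cluster (SF 0.35) disperse along the
95 μm myotube over 30 simulated minutes (SF 0.64 for this replicate; the
20-replicate ensemble below averages 0.78).

The analysis scripts reproduce the condition comparison end to end:

```bash
python analysis/01_simulate_conditions.py   # 20 replicates x 3 conditions
python analysis/02_spreading_analysis.py    # SF summary + Mann-Whitney + figure
python analysis/03_bioid_enrichment.py      # synthetic BioID screen + recovery
```

`02` prints, for 20 replicates per condition (nucleus counts cycling 5–9,
seed base 0):

```
Spreading-factor summary (per-myotube SF):
                condition  n  mean_sf     q1  median     q3
                  control 20   0.7833 0.7559    0.78 0.8144
         no_ne_nucleation 20    0.254  0.195  0.2348 0.2979
no_ne_nucleation_no_kif5b 20   0.3859 0.3588  0.3918 0.4054

Pairwise two-sided Mann-Whitney tests:
         group_a                   group_b   U  p_two_sided
         control          no_ne_nucleation 400    6.796e-08
         control no_ne_nucleation_no_kif5b 400    6.796e-08
no_ne_nucleation no_ne_nucleation_no_kif5b  27    3.069e-06
```

Control myotubes disperse their nuclei nearly evenly (mean SF 0.78),
while both perturbed conditions leave nuclei clustered around the myotube
center (mean SF 0.25 and 0.39) — relocating nucleation away from the NE
abolishes spreading (p ≈ 7×10⁻⁸).  The two perturbed conditions rank in
the opposite order to the published figure; `docs/methods.md` discusses
why their small difference is not a robust output of this model.

`03` prints the synthetic BioID screen result (1000 proteins, 50 planted
4-fold interactors, 20 % CV): 52 candidates pass the ≥2-of-3 enrichment
rule, recovering 98 % of planted interactors at a 0.32 % background
false-positive rate, plus the candidate count across a fold-threshold
sweep (488 at 1.0× down to 1 at 8×).

A `myonuc` command-line tool wraps the same functionality
(`myonuc simulate`, `ensemble`, `sf`, `compare`, `bioid`, `gen nuclei`,
`gen tmt`); run `myonuc --help`.

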