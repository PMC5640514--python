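"""Synthetic inputs with the statistical structure the analyses assume.

Two generators:

* :func:`gen_nuclei` emulates nucleus-centroid tables from imaged myotubes
  in clustered, dispersed, or uniform-random regimes (the phenotypes seen
  when NE microtubule nucleation is intact vs disrupted).
* :func:`gen_tmt` emulates a BioID/TMT protein-quantification table with
  sample-to-sample bait-level variation, background binders, and a planted
  set of myotube-enriched interactors.

Both are pure functions of their spec (seed included) and emit ground-truth
labels next to the data so downstream recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bioid import CELL_STATES, COLUMN_NAMES, QuantTable
from .config import LENGTH_PER_NUCLEUS_UM

REGIMES = ("clustered", "dispersed", "uniform")


@dataclass(frozen=True)
class NucleiGeneratorSpec:
    """Spec for synthetic nucleus-centroid tables.

    ``regime``: clustered (Gaussian around the myotube midpoint, width
    ``cluster_sigma`` μm, truncated to the tube), dispersed (even spacing
    plus uniform jitter of half-amplitude ``jitter`` μm), or uniform
    (i.i.d. Uniform(0, L)).  Myotube length follows the 19 μm-per-nucleus
    sizing rule.
    """

    regime: str = "clustered"
    n_myotubes: int = 20
    nuclei_range: tuple[int, int] = (5, 9)
    length_per_nucleus: float = LENGTH_PER_NUCLEUS_UM
    cluster_sigma: float = 5.0
    jitter: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"regime must be one of {REGIMES}")
        if self.regime == "clustered" and self.cluster_sigma <= 0:
            raise ValueError("cluster_sigma must be > 0 in the clustered regime")
        lo, hi = self.nuclei_range
        if lo < 3 or hi < lo:
            raise ValueError("nuclei_range must satisfy 3 <= lo <= hi")


def gen_nuclei(spec: NucleiGeneratorSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a long nucleus table plus per-myotube truth labels.

    Returns ``(table, truth)``: the table has one row per nucleus with
    columns (myotube_id, length_um, x_um); truth records the regime and
    generating parameters per myotube.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.nuclei_range
    rows, truth_rows = [], []
    for m in range(spec.n_myotubes):
        n = int(rng.integers(lo, hi + 1))
        length = spec.length_per_nucleus * n
        if spec.regime == "clustered":
            x = rng.normal(length / 2.0, spec.cluster_sigma, size=n)
            # truncate to the myotube by resampling out-of-range draws
            for _ in range(1000):
                bad = (x < 0) | (x > length)
                if not bad.any():
                    break
                x[bad] = rng.normal(length / 2.0, spec.cluster_sigma, size=int(bad.sum()))
            x = np.clip(x, 0.0, length)
        elif spec.regime == "dispersed":
            base = np.linspace(0.0, length, n)
            x = base + rng.uniform(-spec.jitter, spec.jitter, size=n)
            x = np.clip(x, 0.0, length)
        else:
            x = rng.uniform(0.0, length, size=n)
        mid = f"mt{m:03d}"
        rows += [{"myotube_id": mid, "length_um": length, "x_um": xi} for xi in x]
        truth_rows.append({"myotube_id": mid, "regime": spec.regime,
                           "n_nuclei": n, "length_um": length})
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


@dataclass(frozen=True)
class TMTGeneratorSpec:
    """Spec for synthetic BioID/TMT quantification tables.

    Background proteins have the same expected +DOX/−DOX labeling ratio in
    myoblasts and myotubes; the ``n_planted`` interactors have their
    myotube +DOX abundance multiplied by ``effect_size``.  Per-sample bait
    scale factors (log-normal, sd ``bait_scale_sigma`` in log space)
    multiply whole +DOX columns, emulating varying bait expression.
    Multiplicative log-normal measurement noise has coefficient of
    variation ``cv``; entries go missing completely at random at
    ``missing_rate``.
    """

    n_proteins: int = 1000
    n_planted: int = 50
    effect_size: float = 4.0
    abundance_mu: float = np.log(1000.0)   # log-space mean of base abundance
    abundance_sigma: float = 1.0
    background_ratio: float = 10.0         # expected +DOX/−DOX for background
    bait_abundance: float = 5e4
    bait_scale_sigma: float = 0.5
    cv: float = 0.2
    missing_rate: float = 0.01
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.effect_size <= 0:
            raise ValueError("effect_size must be > 0")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.n_planted > self.n_proteins:
            raise ValueError("n_planted cannot exceed n_proteins")


BAIT_ID = "BAIT_BirA"


def gen_tmt(spec: TMTGeneratorSpec) -> tuple[QuantTable, pd.DataFrame]:
    """Generate a quantification table plus per-protein truth labels.

    Returns ``(table, truth)``; truth flags the planted myotube-enriched
    interactors.  The bait row is present in every sample (tiny leaky
    level in −DOX controls) and carries the per-sample scale factor in
    +DOX columns, so bait normalization can undo it exactly.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_proteins
    proteins = [f"P{i:04d}" for i in range(n)]
    planted = rng.choice(n, size=spec.n_planted, replace=False)
    is_planted = np.zeros(n, dtype=bool)
    is_planted[planted] = True

    base = np.exp(rng.normal(spec.abundance_mu, spec.abundance_sigma, size=n))
    noise_sigma = np.sqrt(np.log1p(spec.cv ** 2))  # log-normal sd for given CV

    columns, data = [], []
    for state in CELL_STATES:
        for rep in range(1, spec.n_replicates + 1):
            bait_scale = float(np.exp(rng.normal(0.0, spec.bait_scale_sigma)))
            for treatment in ("noDOX_biotin", "DOX_biotin"):
                if treatment == "DOX_biotin":
                    expected = base * spec.background_ratio
                    if state == "myotube":
                        expected = np.where(is_planted,
                                            expected * spec.effect_size, expected)
                    expected = expected * bait_scale
                    bait_val = spec.bait_abundance * bait_scale
                else:
                    expected = base.copy()
                    bait_val = spec.bait_abundance * 1e-4  # leaky background
                noise = np.exp(rng.normal(0.0, noise_sigma, size=n)) \
                    if spec.cv > 0 else np.ones(n)
                col = expected * noise
                if spec.missing_rate > 0:
                    col = np.where(rng.random(n) < spec.missing_rate, np.nan, col)
                columns.append((state, treatment, rep))
                data.append(np.append(col, bait_val))
    df = pd.DataFrame(
        np.column_stack(data),
        index=proteins + [BAIT_ID],
        columns=pd.MultiIndex.from_tuples(columns, names=COLUMN_NAMES),
    )
    truth = pd.DataFrame({"protein": proteins, "planted": is_planted})
    return QuantTable(df, BAIT_ID), truth


def recovery_stats(records: pd.DataFrame, truth: pd.DataFrame) -> dict:
    """Recovery and false-positive rate of the enrichment filter vs truth."""
    truth = truth.set_index("protein")
    passed = records.loc[records.index.intersection(truth.index), "pass"]
    planted = truth["planted"]
    aligned = passed.reindex(planted.index, fill_value=False).astype(bool)
    tp = int((aligned & planted).sum())
    fp = int((aligned & ~planted).sum())
    return {
        "recovery": tp / max(int(planted.sum()), 1),
        "fpr": fp / max(int((~planted).sum()), 1),
        "n_pass": int(aligned.sum()),
    }
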