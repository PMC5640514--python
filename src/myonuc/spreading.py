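"""Nuclear spreading-factor statistic and condition comparisons.

The spreading factor (SF) of a myotube quantifies how dispersed its nuclei
are along the long axis: it is the ratio of the observed mean pairwise
distance between nuclear centroids (projected on the axis) to the reference
mean pairwise distance of the same number of nuclei spaced evenly from 0 to
the myotube length.  SF = 1 for perfectly even spacing spanning the tube,
SF → 0 as nuclei collapse onto one point.  Only myotubes with at least
three nuclei enter the analysis.

For N points evenly spaced on [0, L] the mean over all unordered pairs of
|x_i − x_j| is E(N, L) = L·(N+1) / (3·(N−1)), which is the normalization
used here.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

MIN_NUCLEI = 3  # inclusion rule: myotubes with >= 3 nuclei


@dataclass(frozen=True)
class MyotubeNuclei:
    """Axial nuclear positions of one myotube.

    ``length`` in μm; ``x`` holds axial centroid positions in [0, length].
    """

    myotube_id: str
    length: float
    x: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        if self.length <= 0:
            raise ValueError(f"myotube {self.myotube_id}: length must be > 0")
        if self.x.ndim != 1:
            raise ValueError("x must be a 1D array of axial positions")

    @property
    def n(self) -> int:
        return self.x.size


def even_spacing_reference(n: int, length: float) -> float:
    """Mean pairwise distance of n points evenly spaced from 0 to ``length``."""
    if n < 2:
        raise ValueError("reference needs n >= 2")
    return length * (n + 1) / (3.0 * (n - 1))


def mean_pairwise_distance(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    n = x.size
    diffs = np.abs(x[:, None] - x[None, :])
    return float(diffs[np.triu_indices(n, k=1)].mean())


def consecutive_distance(x: np.ndarray) -> float:
    """Mean distance between axially consecutive nuclei (sensitivity variant)."""
    xs = np.sort(np.asarray(x, dtype=float))
    return float(np.diff(xs).mean())


def spreading_factor(nuclei: MyotubeNuclei, pairwise: bool = True) -> float:
    """Spreading factor of one myotube.

    Observed mean pairwise distance between nuclei divided by the
    even-spacing reference E(N, L) = L(N+1)/(3(N−1)).  With
    ``pairwise=False`` the observed statistic is the mean consecutive
    neighbour distance and the reference is the even spacing L/(N−1).
    Requires N >= 3 nuclei and L > 0.
    """
    if nuclei.length <= 0:
        raise ValueError("myotube length must be > 0")
    if nuclei.n < MIN_NUCLEI:
        raise ValueError(
            f"myotube {nuclei.myotube_id} has {nuclei.n} nuclei; "
            f"the inclusion rule requires >= {MIN_NUCLEI}"
        )
    if pairwise:
        obs = mean_pairwise_distance(nuclei.x)
        ref = even_spacing_reference(nuclei.n, nuclei.length)
    else:
        obs = consecutive_distance(nuclei.x)
        ref = nuclei.length / (nuclei.n - 1)
    return obs / ref


def sf_table(df: pd.DataFrame, group: str | None = None,
             pairwise: bool = True) -> pd.DataFrame:
    """Per-myotube SF from a long table.

    Expects columns ``myotube_id``, ``length_um``, ``x_um`` (one row per
    nucleus) and optionally a group/condition column.  Myotubes with fewer
    than three nuclei are excluded with a logged reason.
    """
    rows = []
    keys = ["myotube_id"] + ([group] if group else [])
    for key, sub in df.groupby(keys, sort=False):
        if not isinstance(key, tuple):
            key = (key,)
        length = float(sub["length_um"].iloc[0])
        x = sub["x_um"].to_numpy(dtype=float)
        if x.size < MIN_NUCLEI:
            log.info("excluding myotube %s: only %d nuclei (< %d)",
                     key[0], x.size, MIN_NUCLEI)
            continue
        nuc = MyotubeNuclei(str(key[0]), length, x)
        row = {"myotube_id": key[0], "n_nuclei": x.size, "length_um": length,
               "sf": spreading_factor(nuc, pairwise=pairwise)}
        if group:
            row[group] = key[1]
        rows.append(row)
    return pd.DataFrame(rows)


def mann_whitney(group_a, group_b, alternative: str = "two-sided"
                 ) -> tuple[float, float]:
    """Mann-Whitney rank-sum test (two-sided by default).

    Returns (U, p) where U counts pairs in which a ``group_a`` value
    exceeds a ``group_b`` value (ties as 1/2).  The p-value is exact (full
    enumeration of rank assignments) when the smaller group has at most 8
    observations and there are no ties; otherwise the normal approximation
    with tie and continuity corrections is used.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (min(a.size, b.size) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def compare_conditions(sf: pd.DataFrame, group: str = "condition") -> dict:
    """Summary report across condition groups of per-myotube SF values.

    Returns a dict with a per-group summary table (mean, interquartile
    range, n — the descriptors drawn on the SF figures) and a pairwise
    Mann-Whitney table.  Requires at least two groups.
    """
    groups = {name: sub["sf"].to_numpy(dtype=float)
              for name, sub in sf.groupby(group, sort=False)}
    if len(groups) < 2:
        raise ValueError("need at least two condition groups to compare")
    summary = pd.DataFrame(
        [{group: name, "n": v.size, "mean_sf": v.mean(),
          "q1": np.percentile(v, 25), "median": np.median(v),
          "q3": np.percentile(v, 75)}
         for name, v in groups.items()])
    pair_rows = []
    for (na, va), (nb, vb) in itertools.combinations(groups.items(), 2):
        u, p = mann_whitney(va, vb)
        pair_rows.append({"group_a": na, "group_b": nb, "U": u, "p_two_sided": p})
    return {"summary": summary, "pairwise": pd.DataFrame(pair_rows)}


def format_report(report: dict, group: str = "condition") -> str:
    """Human-readable rendering of :func:`compare_conditions` output."""
    lines = ["Spreading-factor summary (per-myotube SF):",
             report["summary"].to_string(index=False, float_format="%.4g"),
             "", "Pairwise two-sided Mann-Whitney tests:",
             report["pairwise"].to_string(index=False, float_format="%.4g")]
    return "\n".join(lines)
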