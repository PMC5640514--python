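"""BioID/TMT quantitation: bait normalization, ±DOX ratios, enrichment filter.

The input is a protein × sample table of TMT reporter abundances from a
proximity-labeling experiment in which the bait (a BirA*-tagged nuclear
envelope protein) is expressed under doxycycline control in myoblasts and
myotubes, with three biological replicates and per-state controls
(untreated, and biotin-only).  Analysis steps:

1. ``identification_gate`` — keep proteins identified in ≥2 replicates.
2. ``bait_normalize``   — scale every +DOX sample so the bait level is
   equal across +DOX samples (reference: geometric mean), correcting for
   sample-to-sample variation in bait expression/labeling.
3. ``dox_ratio``        — per replicate and cell state, the +DOX/−DOX
   abundance ratio, the unit of "bait-dependent labeling".
4. ``enrichment_filter``— a protein is myotube-enriched in a replicate when
   its myotube ratio exceeds its myoblast ratio by a fold threshold, and
   passes overall when enriched in at least two of three replicates.

Tables are pandas DataFrames indexed by protein id, with a three-level
column MultiIndex (cell_state, treatment, replicate); missing values are
NaN and are never silently imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

CELL_STATES = ("myoblast", "myotube")
TREATMENTS = ("noDOX_noBiotin", "noDOX_biotin", "DOX_biotin")
COLUMN_NAMES = ("cell_state", "treatment", "replicate")
DOX = "DOX_biotin"

#: default fold threshold for "preferentially associated in myotubes";
#: the ratio-of-ratios r_mt/r_mb must reach this value in a replicate.
DEFAULT_FOLD_THRESHOLD = 2.0


@dataclass
class QuantTable:
    """Protein × sample reporter-abundance matrix with a flagged bait row."""

    data: pd.DataFrame
    bait_id: str
    normalization: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not isinstance(self.data.columns, pd.MultiIndex) or \
                self.data.columns.nlevels != 3:
            raise ValueError("columns must be a (cell_state, treatment, replicate) "
                             "MultiIndex")
        self.data.columns = self.data.columns.set_names(list(COLUMN_NAMES))
        if self.bait_id not in self.data.index:
            raise ValueError(f"bait {self.bait_id!r} not present in the table")
        with np.errstate(invalid="ignore"):
            if (self.data.to_numpy(dtype=float) < 0).any():
                raise ValueError("abundances must be >= 0")

    @property
    def proteins(self) -> pd.Index:
        return self.data.index

    def dox_columns(self) -> list[tuple]:
        return [c for c in self.data.columns if c[1] == DOX]

    def replicates(self, cell_state: str) -> list:
        return sorted({c[2] for c in self.data.columns if c[0] == cell_state})


def identification_gate(identified: pd.DataFrame, min_replicates: int = 2) -> pd.Index:
    """Proteins identified in at least ``min_replicates`` biological replicates.

    ``identified`` is a boolean protein × replicate frame (any column
    scheme); the gate runs upstream of enrichment.
    """
    counts = identified.astype(bool).sum(axis=1)
    return identified.index[counts >= min_replicates]


def bait_normalize(table: QuantTable) -> QuantTable:
    """Equalize bait abundance across +DOX samples.

    Each +DOX sample column is multiplied by (geometric-mean bait)/(bait in
    that sample), so that after scaling the bait level is identical in all
    +DOX samples.  −DOX control columns, where the bait is not induced, are
    left untouched.  Factors are recorded in ``normalization`` and logged.
    Raises if the bait is missing or zero in any +DOX sample.
    """
    cols = table.dox_columns()
    bait = table.data.loc[table.bait_id, cols].astype(float)
    bad = [c for c, v in bait.items() if not np.isfinite(v) or v <= 0]
    if bad:
        raise ValueError(f"bait {table.bait_id!r} missing or zero in +DOX "
                         f"sample(s): {bad}")
    reference = float(np.exp(np.mean(np.log(bait.to_numpy(dtype=float)))))
    factors = reference / bait
    out = table.data.copy()
    for c in cols:
        out[c] = out[c] * factors[c]
        log.debug("bait normalization factor %s = %.6g", c, factors[c])
    return QuantTable(out, table.bait_id,
                      normalization={"reference": reference,
                                     "factors": {c: float(factors[c]) for c in cols}})


def _control_column(table: QuantTable, cell_state: str, replicate) -> tuple:
    """The −DOX control for a sample: biotin-only when present, else untreated."""
    for treatment in ("noDOX_biotin", "noDOX_noBiotin"):
        col = (cell_state, treatment, replicate)
        if col in table.data.columns:
            return col
    raise KeyError(f"no −DOX control column for {cell_state} replicate {replicate}")


def column_pseudocount(table: QuantTable, column: tuple) -> float:
    """Smallest nonzero abundance in a column (default missing-value offset)."""
    col = table.data[column].to_numpy(dtype=float)
    nonzero = col[np.isfinite(col) & (col > 0)]
    return float(nonzero.min()) if nonzero.size else 0.0


def dox_ratio(table: QuantTable, protein, cell_state: str, replicate,
              pseudocount: float | None = None) -> float:
    """+DOX/−DOX abundance ratio for one protein, state and replicate.

    r = abundance(+DOX +biotin) / (abundance(−DOX control) + pseudocount).
    The control is the biotin-only sample when present, else untreated.
    ``pseudocount`` defaults to the smallest nonzero abundance in the
    control column, keeping ratios finite when a protein is absent from
    the control.  Returns NaN (a missing-value record) when the protein or
    its +DOX abundance is absent.
    """
    if protein not in table.data.index:
        return float("nan")
    num_col = (cell_state, DOX, replicate)
    den_col = _control_column(table, cell_state, replicate)
    num = float(table.data.at[protein, num_col])
    den = float(table.data.at[protein, den_col])
    if not np.isfinite(num):
        return float("nan")
    if pseudocount is None:
        pseudocount = column_pseudocount(table, den_col)
    if not np.isfinite(den):
        den = 0.0
        log.debug("protein %s absent in %s; pseudocount %.4g applied",
                  protein, den_col, pseudocount)
    denom = den + pseudocount
    return num / denom if denom > 0 else float("nan")


def ratio_table(table: QuantTable, pseudocount: float | None = None) -> pd.DataFrame:
    """Per-protein, per-replicate ±DOX ratios for both cell states.

    Vectorized over the whole table; returns a frame with a
    (cell_state, replicate) column MultiIndex of ratios.
    """
    blocks = {}
    for state in CELL_STATES:
        reps = sorted({c[2] for c in table.data.columns
                       if c[0] == state and c[1] == DOX})
        for rep in reps:
            num = table.data[(state, DOX, rep)].astype(float)
            den_col = _control_column(table, state, rep)
            den = table.data[den_col].astype(float)
            pc = (column_pseudocount(table, den_col)
                  if pseudocount is None else pseudocount)
            denom = den.fillna(0.0) + pc
            r = num / denom.where(denom > 0)
            blocks[(state, rep)] = r.where(np.isfinite(num))
    out = pd.DataFrame(blocks)
    out.columns = pd.MultiIndex.from_tuples(out.columns,
                                            names=["cell_state", "replicate"])
    return out


def enrichment_filter(ratios: pd.DataFrame,
                      fold_threshold: float = DEFAULT_FOLD_THRESHOLD,
                      bait_id: str | None = None) -> pd.DataFrame:
    """Myotube-enrichment records and the candidate pass set.

    ``ratios`` comes from :func:`ratio_table`.  Per replicate, a protein is
    enriched when r_myotube / r_myoblast >= ``fold_threshold``; it passes
    when enriched in at least two of three replicates (proteins with fewer
    evaluable replicates are still scored but flagged ``incomplete``).
    Returns one row per protein, candidates first, ordered by median
    ratio-of-ratios descending.
    """
    if fold_threshold <= 0:
        raise ValueError("fold_threshold must be > 0")
    mt = ratios["myotube"]
    mb = ratios["myoblast"]
    reps = [r for r in mt.columns if r in mb.columns]
    ror = pd.DataFrame({r: mt[r] / mb[r] for r in reps})
    evaluable = ror.notna().sum(axis=1)
    enriched = (ror >= fold_threshold).sum(axis=1)
    out = pd.DataFrame({
        "median_ror": ror.median(axis=1),
        "n_evaluable": evaluable,
        "n_enriched": enriched,
        "incomplete": evaluable < len(reps),
        "pass": enriched >= 2,
    })
    for r in reps:
        out[f"ror_rep{r}"] = ror[r]
    if bait_id is not None and bait_id in out.index:
        out.loc[bait_id, "pass"] = False  # the bait itself is not a candidate
    return out.sort_values(["pass", "median_ror"], ascending=[False, False])


def candidate_set(records: pd.DataFrame) -> pd.Index:
    """Protein ids passing the ≥2-of-3 myotube-enrichment rule."""
    return records.index[records["pass"]]


def threshold_sweep(ratios: pd.DataFrame, thresholds) -> pd.DataFrame:
    """Candidate-set size as a function of the fold threshold.

    The published candidate count depends on an unprinted cutoff, so the
    sweep reports the whole curve instead of asserting one value.
    """
    rows = [{"fold_threshold": t,
             "n_candidates": int(enrichment_filter(ratios, t)["pass"].sum())}
            for t in thresholds]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------- I/O ----

def read_quant_table(path, bait_id: str) -> QuantTable:
    """Read a delimited abundance table.

    Expected: a ``protein`` column then one column per sample named
    ``cellstate.treatment.replicate`` (e.g. ``myotube.DOX_biotin.1``).
    """
    df = pd.read_csv(path, sep=None, engine="python").set_index("protein")
    cols = []
    for c in df.columns:
        state, treatment, rep = c.split(".")
        cols.append((state, treatment, int(rep)))
    df.columns = pd.MultiIndex.from_tuples(cols, names=COLUMN_NAMES)
    return QuantTable(df, bait_id)


def write_quant_table(table: QuantTable, path) -> None:
    df = table.data.copy()
    df.columns = [f"{s}.{t}.{r}" for s, t, r in df.columns]
    df.index.name = "protein"
    df.to_csv(path)
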