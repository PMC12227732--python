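"""QC-filtered RPKM abundance tables and ecological summaries.

The abundance unit is RPKM: reads mapped to a vOTU representative, per
kilobase of contig, per million reads mapped in the sample.  Before the
transform, counts supported by less than 75% breadth of coverage are
zeroed (spurious-alignment guard), and vOTU rows failing QC (short
contigs, host-gene excess, plasmids) are dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .io_formats import VotuAnnotation

__all__ = [
    "CountMatrix",
    "AbundanceMatrix",
    "breadth_filter",
    "to_rpkm",
    "qc_filter_votus",
    "richness",
    "shannon",
    "relative_abundance",
    "bray_curtis_similarity",
]


@dataclass
class CountMatrix:
    """Read counts with per-sample mapping totals and per-cell breadth.

    ``counts`` and ``breadth`` are vOTU x sample frames on identical axes;
    ``mapped_total`` is reads mapped per sample (the RPKM denominator),
    computed from the mapping itself, before any breadth zeroing.
    """

    counts: pd.DataFrame
    mapped_total: pd.Series
    breadth: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.breadth.index) or not self.counts.columns.equals(
            self.breadth.columns
        ):
            raise ValueError("counts and breadth must share axes")
        missing = set(self.counts.columns) - set(self.mapped_total.index)
        if missing:
            raise ValueError(f"mapped_total missing samples {sorted(missing)}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        b = self.breadth.to_numpy()
        if ((b < 0) | (b > 1)).any():
            raise ValueError("breadth outside [0,1]")
        if ((self.counts.to_numpy() > 0) & (b == 0)).any():
            raise ValueError("nonzero count with zero breadth")


@dataclass
class AbundanceMatrix:
    """vOTU x sample RPKM matrix with per-sample metadata attached.

    ``sample_meta`` is indexed by sample_id and carries at least ``study``
    and ``role`` columns; optional per-sample covariates (e.g. external
    contamination estimates) may be added by downstream stages.
    """

    rpkm: pd.DataFrame
    sample_meta: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = set(self.rpkm.columns) - set(self.sample_meta.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")
        values = self.rpkm.to_numpy()
        if np.isnan(values).any():
            raise ValueError("NaN in RPKM matrix")
        if (values < 0).any():
            raise ValueError("negative RPKM")

    def copy(self) -> "AbundanceMatrix":
        return AbundanceMatrix(self.rpkm.copy(), self.sample_meta.copy())

    @property
    def biological_samples(self) -> list[str]:
        meta = self.sample_meta.loc[list(self.rpkm.columns)]
        return [s for s in self.rpkm.columns if meta.at[s, "role"] == "sample"]

    @property
    def nc_samples(self) -> list[str]:
        meta = self.sample_meta.loc[list(self.rpkm.columns)]
        return [s for s in self.rpkm.columns if meta.at[s, "role"] == "nc"]


def breadth_filter(matrix: CountMatrix, min_breadth: float = 0.75) -> CountMatrix:
    """Zero counts whose breadth of coverage is strictly below the cut-off.

    A count at exactly ``min_breadth`` breadth is retained (the rule is
    "less than").  Idempotent; never increases any count.
    """
    counts = matrix.counts.where(matrix.breadth >= min_breadth, 0)
    return CountMatrix(counts, matrix.mapped_total.copy(), matrix.breadth.copy())


def to_rpkm(matrix: CountMatrix, annotations: list[VotuAnnotation],
            sample_meta: pd.DataFrame) -> AbundanceMatrix:
    """RPKM transform: count / (length/1e3) / (mapped_total/1e6)."""
    lengths = {a.votu_id: a.length_bp for a in annotations}
    missing = set(matrix.counts.index) - set(lengths)
    if missing:
        raise ValueError(f"vOTUs without annotation: {sorted(missing)}")
    totals = matrix.mapped_total.loc[matrix.counts.columns]
    zero_total = totals[totals <= 0]
    if len(zero_total):
        nonzero = matrix.counts[zero_total.index].to_numpy().sum()
        if nonzero:
            raise ValueError(
                f"mapped_total is 0 for {list(zero_total.index)} with nonzero counts"
            )
        totals = totals.replace(0, 1)  # all-zero sample: RPKM column stays 0
    kb = pd.Series(lengths).loc[matrix.counts.index] / 1e3
    rpkm = matrix.counts.div(kb, axis=0).div(totals / 1e6, axis=1)
    return AbundanceMatrix(rpkm, sample_meta)


def qc_filter_votus(
    matrix: AbundanceMatrix,
    annotations: list[VotuAnnotation],
    min_length: int = 1000,
) -> AbundanceMatrix:
    """Drop vOTU rows that fail representative-level QC.

    Removed when shorter than ``min_length`` bp, when the representative
    has fewer viral than host genes (ties retained: "fewer" is strict),
    or when flagged as a plasmid.  Surviving rows are value-identical.
    """
    by_id = {a.votu_id: a for a in annotations}
    missing = set(matrix.rpkm.index) - set(by_id)
    if missing:
        raise ValueError(f"vOTUs without annotation: {sorted(missing)}")
    keep = [
        v
        for v in matrix.rpkm.index
        if by_id[v].length_bp >= min_length
        and by_id[v].viral_gene_count >= by_id[v].host_gene_count
        and not by_id[v].plasmid_flag
    ]
    return AbundanceMatrix(matrix.rpkm.loc[keep], matrix.sample_meta)


def richness(matrix: AbundanceMatrix) -> pd.Series:
    """Number of vOTUs with nonzero abundance per sample."""
    return (matrix.rpkm > 0).sum(axis=0).astype(int)


def shannon(matrix: AbundanceMatrix) -> pd.Series:
    """Shannon diversity H = -sum p ln p per sample (natural log).

    Samples with zero total abundance yield NaN (undefined).
    """
    totals = matrix.rpkm.sum(axis=0)
    out = pd.Series(np.nan, index=matrix.rpkm.columns, dtype=float)
    for s in matrix.rpkm.columns:
        if totals[s] > 0:
            p = matrix.rpkm[s].to_numpy() / totals[s]
            p = p[p > 0]
            out[s] = float(-(p * np.log(p)).sum())
    return out


def relative_abundance(matrix: AbundanceMatrix) -> pd.DataFrame:
    """Per-sample relative RPKM shares (columns sum to 1; all-zero -> 0)."""
    totals = matrix.rpkm.sum(axis=0)
    return matrix.rpkm.div(totals.replace(0, np.nan), axis=1).fillna(0.0)


def bray_curtis_similarity(matrix: AbundanceMatrix) -> pd.DataFrame:
    """Pairwise compositional similarity, 1 - Bray-Curtis dissimilarity.

    Pairs where both samples are entirely zero are undefined (NaN, with a
    warning); the diagonal is 1 for nonzero samples.
    """
    data = matrix.rpkm.to_numpy().T
    nonzero = data.sum(axis=1) > 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sim = 1.0 - squareform(pdist(data, metric="braycurtis"))
    np.fill_diagonal(sim, 1.0)
    if (~nonzero).any():
        warnings.warn("all-zero sample(s); their similarities are undefined (NaN)")
        sim[~nonzero, :] = np.nan
        sim[:, ~nonzero] = np.nan
    return pd.DataFrame(sim, index=matrix.rpkm.columns, columns=matrix.rpkm.columns)
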