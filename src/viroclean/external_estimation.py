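"""Contamination estimation against an external negativeome catalog.

For studies without internal NCs, contamination is estimated from a
catalog of NC-detected vOTUs built elsewhere, in a leave-own-study-out
fashion (a sample is only compared against NC vOTUs from other studies).
Two metrics are supported:

* vOTU sharing — the percentage of a sample's detected vOTUs that belong
  to the external catalog (presence/absence based, the better-performing
  estimator);
* read mapping — the percentage of a sample's reads mapped to catalog
  contigs covered to more than 50% (or 75%) breadth (the weaker
  estimator; kept with a flag in the output).

Concordance between estimators (or against internal strain-sharing) is
quantified with study-wise Spearman correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .abundance import AbundanceMatrix
from .decontam import NegativeomeCatalog
from .stats import spearman
from .votu_cluster import map_to_catalog

__all__ = [
    "EstimationResult",
    "estimate_by_votu_sharing",
    "estimate_by_read_mapping",
    "concordance",
    "attach_estimates",
]


@dataclass
class EstimationResult:
    """Per-sample external-contamination estimates plus concordance."""

    per_sample: pd.DataFrame = field(repr=False)
    per_study_rho: pd.DataFrame | None = None
    weaker_estimator: str = "pct_reads_mapped_qualified"


def estimate_by_votu_sharing(
    matrix: AbundanceMatrix,
    catalog: NegativeomeCatalog,
    contig_map: dict[str, str | None] | None = None,
) -> pd.Series:
    """% of a sample's vOTUs assigned to other studies' NC catalog entries.

    When the sample table and the catalog use different sequence universes,
    supply ``contig_map`` (sample vOTU id -> catalog id or None) produced
    by :func:`viroclean.votu_cluster.map_to_catalog`; membership is then
    evaluated on the mapped ids.  Samples with zero richness yield NaN.
    """
    meta = matrix.sample_meta
    out = pd.Series(np.nan, index=pd.Index(matrix.biological_samples, name="sample_id"))
    for s in out.index:
        external = catalog.votus_excluding_study(meta.at[s, "study"])
        present = list(matrix.rpkm.index[matrix.rpkm[s] > 0])
        if not present:
            continue
        if contig_map is not None:
            shared = sum(1 for v in present if contig_map.get(v) in external)
        else:
            shared = sum(1 for v in present if v in external)
        out[s] = 100.0 * shared / len(present)
    return out


def estimate_with_sequences(
    matrix: AbundanceMatrix,
    catalog: NegativeomeCatalog,
    query_seqs: dict[str, str],
    ani_min: float = 95.0,
    af_min: float = 85.0,
) -> pd.Series:
    """Sequence-route variant: map contigs onto the catalog first."""
    if not catalog.sequences:
        raise ValueError("catalog carries no sequences; use the table route")
    contig_map = map_to_catalog(query_seqs, catalog.sequences, ani_min, af_min)
    return estimate_by_votu_sharing(matrix, catalog, contig_map=contig_map)


def estimate_by_read_mapping(
    read_assignments: pd.DataFrame,
    breadth: pd.DataFrame,
    total_reads: pd.Series,
    breadth_min: float = 0.75,
) -> pd.Series:
    """% of reads mapped to catalog contigs covered beyond ``breadth_min``.

    Only contigs with breadth strictly greater than the threshold qualify
    ("more than" 50% or 75% coverage); reads on borderline contigs do not
    count.  ``total_reads`` of 0 is an error.
    """
    if not read_assignments.index.equals(breadth.index) or not read_assignments.columns.equals(
        breadth.columns
    ):
        raise ValueError("read_assignments and breadth must share axes")
    totals = total_reads.loc[read_assignments.columns]
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"total_reads must be positive; offending samples {bad}")
    qualified = read_assignments.where(breadth > breadth_min, 0)
    return 100.0 * qualified.sum(axis=0) / totals


def concordance(
    metric_a: pd.Series,
    metric_b: pd.Series,
    study_by_sample: pd.Series,
    min_n: int = 3,
) -> pd.DataFrame:
    """Study-wise + pooled Spearman correlation between two sample metrics.

    Groups with fewer than ``min_n`` complete pairs, or with zero variance
    in either metric, yield a null rho.
    """
    df = pd.DataFrame({"a": metric_a, "b": metric_b}).dropna()
    df["study"] = study_by_sample.loc[df.index]
    rows = []
    groups = [(study, grp) for study, grp in df.groupby("study")]
    groups.append(("pooled", df))
    for study, grp in groups:
        rho = spearman(grp["a"], grp["b"]) if len(grp) >= min_n else None
        rows.append({"study": study, "n": len(grp),
                     "spearman_rho": np.nan if rho is None else rho})
    return pd.DataFrame(rows).set_index("study")


def attach_estimates(
    matrix: AbundanceMatrix, estimates: pd.Series, name: str = "pct_votus_shared_external"
) -> AbundanceMatrix:
    """Attach per-sample estimates as a metadata covariate.

    Downstream models can then use the estimate as a correction factor;
    the correction itself is out of scope here.
    """
    meta = matrix.sample_meta.copy()
    meta[name] = estimates.reindex(meta.index)
    return AbundanceMatrix(matrix.rpkm, meta)
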