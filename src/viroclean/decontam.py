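"""Negativeome construction, sharing metrics, and decontamination.

The negativeome is the per-study set of vOTUs detected (nonzero RPKM) in
at least one negative control.  Biological samples are then screened at
two levels:

* vOTU (species) level — the sample detects a vOTU present in NCs;
* strain level — additionally, the sample's strain is identical to an NC
  strain (popANI >= 99.999% over the compared regions).

Species-level decontamination zeroes every own-study NC-shared vOTU;
strain-level decontamination zeroes only cells backed by a strain-identity
call, preserving resident strains of NC-shared species.  By default the
strain call waives the 75% comparable-fraction requirement (shallow NC
coverage should not rescue a contaminant).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .abundance import AbundanceMatrix, relative_abundance, richness
from .stats import median_iqr
from .strains import StrainComparison, is_shared_strain

__all__ = [
    "NegativeomeEntry",
    "NegativeomeCatalog",
    "SharingRecord",
    "DecontaminationReport",
    "DecontaminationOutcome",
    "build_negativeome",
    "votu_sharing",
    "strain_sharing",
    "strain_decontaminate",
    "species_decontaminate",
    "decontaminate",
    "decontamination_summary",
]

logger = logging.getLogger(__name__)

_METRIC_COLUMNS = [
    "richness_before",
    "richness_after_strain",
    "richness_after_species",
    "pct_richness_shared_votu",
    "pct_richness_shared_strain",
    "pct_abundance_shared_votu",
    "pct_abundance_shared_strain",
]


@dataclass(frozen=True)
class NegativeomeEntry:
    votu_id: str
    study: str
    source_nc_ids: tuple[str, ...]


@dataclass
class NegativeomeCatalog:
    """Study-annotated set of NC-detected vOTUs (the negativeome)."""

    entries: list[NegativeomeEntry]
    sequences: dict[str, str] | None = None

    def votus_for_study(self, study: str) -> set[str]:
        return {e.votu_id for e in self.entries if e.study == study}

    def votus_excluding_study(self, study: str) -> set[str]:
        return {e.votu_id for e in self.entries if e.study != study}

    def ncs_for(self, votu_id: str, study: str) -> tuple[str, ...]:
        for e in self.entries:
            if e.votu_id == votu_id and e.study == study:
                return e.source_nc_ids
        return ()

    def studies(self) -> set[str]:
        return {e.study for e in self.entries}

    def overlap_histogram(self) -> dict[int, int]:
        """How many vOTUs occur in NCs of exactly k studies, for each k."""
        per_votu: dict[str, set[str]] = {}
        for e in self.entries:
            per_votu.setdefault(e.votu_id, set()).add(e.study)
        hist: dict[int, int] = {}
        for studies in per_votu.values():
            hist[len(studies)] = hist.get(len(studies), 0) + 1
        return dict(sorted(hist.items()))

    @property
    def votu_ids(self) -> set[str]:
        return {e.votu_id for e in self.entries}


@dataclass(frozen=True)
class SharingRecord:
    """One sample x vOTU sharing event against one or more NCs."""

    sample_id: str
    votu_id: str
    level: str  # votu | strain
    nc_ids: tuple[str, ...]
    scope: str  # own_study | external

    def __post_init__(self) -> None:
        if self.level not in {"votu", "strain"}:
            raise ValueError(f"unknown level {self.level!r}")
        if self.scope not in {"own_study", "external"}:
            raise ValueError(f"unknown scope {self.scope!r}")
        if not self.nc_ids:
            raise ValueError("nc_ids must be non-empty")


@dataclass
class DecontaminationReport:
    """Per-sample removal lists and richness/abundance sharing metrics."""

    per_sample: pd.DataFrame = field(repr=False)
    removed_strain: dict[str, list[str]] = field(default_factory=dict)
    removed_species: dict[str, list[str]] = field(default_factory=dict)


@dataclass
class DecontaminationOutcome:
    """Everything one decontamination run produces."""

    catalog: NegativeomeCatalog
    votu_records: list[SharingRecord]
    strain_records: list[SharingRecord]
    strain_matrix: AbundanceMatrix
    species_matrix: AbundanceMatrix
    report: DecontaminationReport


def build_negativeome(matrix: AbundanceMatrix) -> NegativeomeCatalog:
    """Collect, per study, the vOTUs with nonzero abundance in >= 1 NC."""
    meta = matrix.sample_meta
    ncs = [s for s in matrix.rpkm.columns if meta.at[s, "role"] == "nc"]
    if not ncs:
        raise ValueError("no negative controls in metadata")
    entries: list[NegativeomeEntry] = []
    for study in sorted({meta.at[s, "study"] for s in ncs}):
        study_ncs = [s for s in ncs if meta.at[s, "study"] == study]
        sub = matrix.rpkm[study_ncs]
        for votu in sub.index[(sub > 0).any(axis=1)]:
            sources = tuple(s for s in study_ncs if sub.at[votu, s] > 0)
            entries.append(NegativeomeEntry(votu, study, sources))
    return NegativeomeCatalog(entries=sorted(entries, key=lambda e: (e.study, e.votu_id)))


def votu_sharing(
    matrix: AbundanceMatrix,
    catalog: NegativeomeCatalog,
    scope: str = "own_study",
) -> tuple[list[SharingRecord], pd.DataFrame]:
    """vOTU-level sharing of biological samples with the negativeome.

    Per sample: n_shared, pct_richness_shared (of detected vOTUs) and
    pct_abundance_shared (summed relative RPKM of shared vOTUs).  Samples
    with zero richness get null metrics.
    """
    if scope not in {"own_study", "external"}:
        raise ValueError(f"unknown scope {scope!r}")
    rel = relative_abundance(matrix)
    meta = matrix.sample_meta
    records: list[SharingRecord] = []
    rows = []
    for s in matrix.biological_samples:
        study = meta.at[s, "study"]
        if scope == "own_study":
            target = catalog.votus_for_study(study)
            source_studies = [study]
        else:
            target = catalog.votus_excluding_study(study)
            source_studies = sorted(catalog.studies() - {study})
        present = set(matrix.rpkm.index[matrix.rpkm[s] > 0])
        shared = sorted(present & target)
        for votu in shared:
            nc_ids = tuple(
                nc
                for st in source_studies
                for nc in catalog.ncs_for(votu, st)
            )
            records.append(SharingRecord(s, votu, "votu", nc_ids, scope))
        n = len(present)
        rows.append(
            {
                "sample_id": s,
                "study": study,
                "richness": n,
                "n_shared": len(shared),
                "pct_richness_shared": 100.0 * len(shared) / n if n else np.nan,
                "pct_abundance_shared": (
                    100.0 * float(rel.loc[shared, s].sum()) if n else np.nan
                ),
            }
        )
    metrics = pd.DataFrame(
        rows,
        columns=["sample_id", "study", "richness", "n_shared",
                 "pct_richness_shared", "pct_abundance_shared"],
    ).set_index("sample_id")
    return records, metrics


def _index_comparisons(
    comparisons: list[StrainComparison],
) -> dict[tuple[str, str, str], StrainComparison]:
    index: dict[tuple[str, str, str], StrainComparison] = {}
    for c in comparisons:
        index[(c.votu_id, c.sample_a, c.sample_b)] = c
        index[(c.votu_id, c.sample_b, c.sample_a)] = c
    return index


def strain_sharing(
    votu_records: list[SharingRecord],
    comparisons: list[StrainComparison],
    mode: str = "decontamination",
    popani_min: float = 99.999,
    min_fraction: float = 0.75,
) -> list[SharingRecord]:
    """Promote vOTU-level sharing records to strain level.

    A record is promoted iff the sample's strain is identical (per
    :func:`is_shared_strain`) to the strain of >= 1 of its NCs.  Missing
    comparisons degrade to "not promoted" with a logged warning — the
    sample/NC pair could not be profiled, so no strain claim is made.
    """
    index = _index_comparisons(comparisons)
    promoted: list[SharingRecord] = []
    for rec in votu_records:
        matching_ncs = []
        for nc in rec.nc_ids:
            comp = index.get((rec.votu_id, rec.sample_id, nc))
            if comp is None:
                logger.warning(
                    "no strain comparison for vOTU %s between %s and NC %s; "
                    "record not promoted via this NC",
                    rec.votu_id, rec.sample_id, nc,
                )
                continue
            if comp.compared_positions == 0:
                continue
            if is_shared_strain(comp, popani_min, min_fraction, mode):
                matching_ncs.append(nc)
        if matching_ncs:
            promoted.append(
                SharingRecord(
                    rec.sample_id, rec.votu_id, "strain",
                    tuple(matching_ncs), rec.scope,
                )
            )
    return promoted


def _zero_cells(
    matrix: AbundanceMatrix, removals: dict[str, list[str]]
) -> AbundanceMatrix:
    clean = matrix.copy()
    for sample, votus in removals.items():
        clean.rpkm.loc[votus, sample] = 0.0
    return clean


def _base_report_frame(matrix: AbundanceMatrix) -> pd.DataFrame:
    samples = matrix.biological_samples
    df = pd.DataFrame(index=pd.Index(samples, name="sample_id"),
                      columns=_METRIC_COLUMNS, dtype=float)
    df["richness_before"] = richness(matrix).loc[samples].astype(float)
    return df


def strain_decontaminate(
    matrix: AbundanceMatrix, strain_records: list[SharingRecord]
) -> tuple[AbundanceMatrix, DecontaminationReport]:
    """Zero the RPKM of every strain-identical (vOTU, sample) cell."""
    removed: dict[str, list[str]] = {}
    for rec in strain_records:
        if rec.level != "strain":
            raise ValueError("strain_decontaminate expects strain-level records")
        removed.setdefault(rec.sample_id, []).append(rec.votu_id)
    removed = {s: sorted(set(v)) for s, v in removed.items()}
    clean = _zero_cells(matrix, removed)
    per_sample = _base_report_frame(matrix)
    per_sample["richness_after_strain"] = (
        richness(clean).loc[per_sample.index].astype(float)
    )
    rel = relative_abundance(matrix)
    for s in per_sample.index:
        n = per_sample.at[s, "richness_before"]
        votus = removed.get(s, [])
        per_sample.at[s, "pct_richness_shared_strain"] = (
            100.0 * len(votus) / n if n else np.nan
        )
        per_sample.at[s, "pct_abundance_shared_strain"] = (
            100.0 * float(rel.loc[votus, s].sum()) if n else np.nan
        )
    return clean, DecontaminationReport(per_sample=per_sample, removed_strain=removed)


def species_decontaminate(
    matrix: AbundanceMatrix, catalog: NegativeomeCatalog
) -> tuple[AbundanceMatrix, DecontaminationReport]:
    """Zero every vOTU detected in the sample's own-study NCs."""
    meta = matrix.sample_meta
    removed: dict[str, list[str]] = {}
    for s in matrix.biological_samples:
        target = catalog.votus_for_study(meta.at[s, "study"])
        present = set(matrix.rpkm.index[matrix.rpkm[s] > 0])
        votus = sorted(present & target)
        if votus:
            removed[s] = votus
    clean = _zero_cells(matrix, removed)
    per_sample = _base_report_frame(matrix)
    per_sample["richness_after_species"] = (
        richness(clean).loc[per_sample.index].astype(float)
    )
    rel = relative_abundance(matrix)
    for s in per_sample.index:
        n = per_sample.at[s, "richness_before"]
        votus = removed.get(s, [])
        per_sample.at[s, "pct_richness_shared_votu"] = (
            100.0 * len(votus) / n if n else np.nan
        )
        per_sample.at[s, "pct_abundance_shared_votu"] = (
            100.0 * float(rel.loc[votus, s].sum()) if n else np.nan
        )
    return clean, DecontaminationReport(per_sample=per_sample, removed_species=removed)


def decontaminate(
    matrix: AbundanceMatrix,
    comparisons: list[StrainComparison],
    popani_min: float = 99.999,
    min_fraction: float = 0.75,
    strain_mode: str = "decontamination",
) -> DecontaminationOutcome:
    """Full own-study decontamination at strain and species level.

    Builds the negativeome, computes vOTU- and strain-level sharing, zeroes
    the corresponding cells, and returns both cleaned matrices with one
    combined report.  Asserts the structural invariant that strain-level
    removals are a subset of species-level removals per sample.
    """
    catalog = build_negativeome(matrix)
    votu_records, votu_metrics = votu_sharing(matrix, catalog, scope="own_study")
    strain_records = strain_sharing(
        votu_records, comparisons, strain_mode, popani_min, min_fraction
    )
    strain_matrix, strain_report = strain_decontaminate(matrix, strain_records)
    species_matrix, species_report = species_decontaminate(matrix, catalog)

    for s, votus in strain_report.removed_strain.items():
        if not set(votus) <= set(species_report.removed_species.get(s, [])):
            raise AssertionError(
                f"strain-level removals for {s!r} not a subset of species-level"
            )

    per_sample = _base_report_frame(matrix)
    per_sample["richness_after_strain"] = strain_report.per_sample["richness_after_strain"]
    per_sample["richness_after_species"] = species_report.per_sample["richness_after_species"]
    per_sample["pct_richness_shared_votu"] = species_report.per_sample["pct_richness_shared_votu"]
    per_sample["pct_abundance_shared_votu"] = species_report.per_sample["pct_abundance_shared_votu"]
    per_sample["pct_richness_shared_strain"] = strain_report.per_sample["pct_richness_shared_strain"]
    per_sample["pct_abundance_shared_strain"] = strain_report.per_sample["pct_abundance_shared_strain"]
    report = DecontaminationReport(
        per_sample=per_sample,
        removed_strain=strain_report.removed_strain,
        removed_species=species_report.removed_species,
    )
    return DecontaminationOutcome(
        catalog=catalog,
        votu_records=votu_records,
        strain_records=strain_records,
        strain_matrix=strain_matrix,
        species_matrix=species_matrix,
        report=report,
    )


def decontamination_summary(
    report: DecontaminationReport,
    sample_meta: pd.DataFrame,
    contaminated_only: bool = True,
) -> pd.DataFrame:
    """Study-level median/IQR of richness drops and shared fractions.

    By default summarizes only samples that shared >= 1 vOTU with NCs
    (richness drops are reported "per contaminated sample").
    """
    df = report.per_sample.copy()
    df["study"] = sample_meta.loc[df.index, "study"]
    before = df["richness_before"]
    with np.errstate(invalid="ignore", divide="ignore"):
        df["pct_richness_drop_strain"] = 100.0 * (
            before - df["richness_after_strain"]
        ) / before
        df["pct_richness_drop_species"] = 100.0 * (
            before - df["richness_after_species"]
        ) / before
    if contaminated_only:
        df = df[df["pct_richness_shared_votu"] > 0]
    rows = []
    metrics = [
        "pct_richness_drop_strain",
        "pct_richness_drop_species",
        "pct_richness_shared_votu",
        "pct_richness_shared_strain",
        "pct_abundance_shared_votu",
        "pct_abundance_shared_strain",
    ]
    for study, grp in df.groupby("study"):
        row: dict[str, float | str] = {"study": study, "n_samples": len(grp)}
        for m in metrics:
            vals = grp[m].dropna()
            if len(vals):
                med, q1, q3 = median_iqr(vals)
            else:
                med = q1 = q3 = np.nan
            row[f"{m}_median"] = med
            row[f"{m}_q1"] = q1
            row[f"{m}_q3"] = q3
        rows.append(row)
    return pd.DataFrame(rows).set_index("study")
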