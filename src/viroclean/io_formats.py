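"""Readers and writers for the toolkit's external formats.

All tabular formats are tab-separated with fixed headers; coordinates are
1-based inclusive throughout.  Missing optional metadata is encoded as the
empty string (never an "NA" literal).  Every reader validates its input and
raises :class:`FormatError` naming the offending record or row.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .votu_cluster import AlignmentRecord

__all__ = [
    "FormatError",
    "SampleMetadata",
    "VotuAnnotation",
    "read_fasta",
    "write_fasta",
    "read_metadata",
    "write_metadata",
    "metadata_frame",
    "read_annotations",
    "write_annotations",
    "read_pileup",
    "write_pileup",
    "read_alignments",
    "write_alignments",
    "read_matrix",
    "write_matrix",
    "write_newick",
    "write_report",
]

ROLES = {"sample", "nc"}
GROUPS = {"infant", "mother", "nc"}
NUCLEIC_ACIDS = {"DNA", "RNA"}

METADATA_COLUMNS = [
    "sample_id", "study", "role", "subject_id", "group", "age_months", "nucleic_acid",
]
ANNOTATION_COLUMNS = [
    "votu_id", "length_bp", "viral_gene_count", "host_gene_count",
    "plasmid_flag", "completeness_pct",
]
PILEUP_COLUMNS = ["sample_id", "votu_id", "pos", "A", "C", "G", "T"]


class FormatError(ValueError):
    """Raised when an external file violates the documented dialect."""


@dataclass(frozen=True)
class SampleMetadata:
    """Study/role/subject covariates for one sequencing library."""

    sample_id: str
    study: str
    role: str  # sample | nc
    subject_id: str | None = None
    group: str = "nc"  # infant | mother | nc
    age_months: float | None = None
    nucleic_acid: str | None = None  # DNA | RNA

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise FormatError(f"sample {self.sample_id!r}: unknown role {self.role!r}")
        if self.group not in GROUPS:
            raise FormatError(f"sample {self.sample_id!r}: unknown group {self.group!r}")
        if self.role == "nc" and self.group != "nc":
            raise FormatError(f"sample {self.sample_id!r}: role=nc requires group=nc")
        if self.age_months is not None and self.age_months < 0:
            raise FormatError(f"sample {self.sample_id!r}: negative age_months")
        if self.nucleic_acid is not None and self.nucleic_acid not in NUCLEIC_ACIDS:
            raise FormatError(
                f"sample {self.sample_id!r}: unknown nucleic_acid {self.nucleic_acid!r}"
            )


@dataclass(frozen=True)
class VotuAnnotation:
    """Per-vOTU QC annotations used by the abundance-table filters."""

    votu_id: str
    length_bp: int
    viral_gene_count: int = 0
    host_gene_count: int = 0
    plasmid_flag: bool = False
    completeness_pct: float | None = None

    def __post_init__(self) -> None:
        if self.length_bp < 1:
            raise FormatError(f"vOTU {self.votu_id!r}: length_bp must be >= 1")
        if self.viral_gene_count < 0 or self.host_gene_count < 0:
            raise FormatError(f"vOTU {self.votu_id!r}: negative gene count")
        if self.completeness_pct is not None and not 0 <= self.completeness_pct <= 100:
            raise FormatError(f"vOTU {self.votu_id!r}: completeness outside [0,100]")


# ---------------------------------------------------------------------------
# FASTA

_IUPAC = set("ACGTN")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an ordered id -> uppercase-sequence map."""
    seqs: dict[str, str] = {}
    current: str | None = None
    chunks: list[str] = []

    def _flush() -> None:
        if current is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FormatError(f"FASTA record {current!r}: empty sequence")
        bad = set(seq) - _IUPAC
        if bad:
            raise FormatError(
                f"FASTA record {current!r}: non-IUPAC character(s) {sorted(bad)}"
            )
        seqs[current] = seq

    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                current = line[1:].split()[0]
                if not current:
                    raise FormatError("FASTA record with empty id")
                if current in seqs:
                    raise FormatError(f"duplicate FASTA id {current!r}")
                chunks = []
            else:
                if current is None:
                    raise FormatError("FASTA: sequence before first header")
                chunks.append(line.upper())
    _flush()
    if not seqs:
        raise FormatError(f"{path}: no FASTA records")
    return seqs


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as handle:
        for name, seq in seqs.items():
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# tabular helpers


def _read_tsv(path: str | Path, columns: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns) != columns:
        raise FormatError(
            f"{path}: expected columns {columns}, found {list(df.columns)}"
        )
    return df


def _opt_float(value: str, where: str) -> float | None:
    if value == "":
        return None
    try:
        return float(value)
    except ValueError as exc:
        raise FormatError(f"{where}: not a number: {value!r}") from exc


# ---------------------------------------------------------------------------
# metadata


def read_metadata(path: str | Path) -> list[SampleMetadata]:
    df = _read_tsv(path, METADATA_COLUMNS)
    out: list[SampleMetadata] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        where = f"{path} line {i} (sample {row.sample_id!r})"
        if row.sample_id in seen:
            raise FormatError(f"{where}: duplicate sample_id")
        seen.add(row.sample_id)
        out.append(
            SampleMetadata(
                sample_id=row.sample_id,
                study=row.study,
                role=row.role,
                subject_id=row.subject_id or None,
                group=row.group,
                age_months=_opt_float(row.age_months, where),
                nucleic_acid=row.nucleic_acid or None,
            )
        )
    return out


def write_metadata(records: list[SampleMetadata], path: str | Path) -> None:
    rows = []
    for m in records:
        rows.append(
            {
                "sample_id": m.sample_id,
                "study": m.study,
                "role": m.role,
                "subject_id": m.subject_id or "",
                "group": m.group,
                "age_months": "" if m.age_months is None else repr(float(m.age_months)),
                "nucleic_acid": m.nucleic_acid or "",
            }
        )
    pd.DataFrame(rows, columns=METADATA_COLUMNS).to_csv(path, sep="\t", index=False)


def metadata_frame(records: list[SampleMetadata]) -> pd.DataFrame:
    """Metadata as a DataFrame indexed by sample_id (for matrix joins)."""
    df = pd.DataFrame([dataclasses.asdict(m) for m in records])
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise FormatError(f"duplicate sample_id {dup!r}")
    return df.set_index("sample_id")


# ---------------------------------------------------------------------------
# annotations


def read_annotations(path: str | Path) -> list[VotuAnnotation]:
    df = _read_tsv(path, ANNOTATION_COLUMNS)
    out: list[VotuAnnotation] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        where = f"{path} line {i} (vOTU {row.votu_id!r})"
        if row.votu_id in seen:
            raise FormatError(f"{where}: duplicate votu_id")
        seen.add(row.votu_id)
        if row.plasmid_flag not in {"true", "false"}:
            raise FormatError(f"{where}: plasmid_flag must be 'true' or 'false'")
        try:
            length = int(row.length_bp)
            viral = int(row.viral_gene_count)
            host = int(row.host_gene_count)
        except ValueError as exc:
            raise FormatError(f"{where}: non-integer count") from exc
        out.append(
            VotuAnnotation(
                votu_id=row.votu_id,
                length_bp=length,
                viral_gene_count=viral,
                host_gene_count=host,
                plasmid_flag=row.plasmid_flag == "true",
                completeness_pct=_opt_float(row.completeness_pct, where),
            )
        )
    return out


def write_annotations(records: list[VotuAnnotation], path: str | Path) -> None:
    rows = []
    for a in records:
        rows.append(
            {
                "votu_id": a.votu_id,
                "length_bp": a.length_bp,
                "viral_gene_count": a.viral_gene_count,
                "host_gene_count": a.host_gene_count,
                "plasmid_flag": "true" if a.plasmid_flag else "false",
                "completeness_pct": (
                    "" if a.completeness_pct is None else repr(float(a.completeness_pct))
                ),
            }
        )
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# pileups


def validate_pileup(df: pd.DataFrame, annotations: list[VotuAnnotation]) -> pd.DataFrame:
    """Validate a per-position depth table against vOTU lengths."""
    lengths = {a.votu_id: a.length_bp for a in annotations}
    if list(df.columns) != PILEUP_COLUMNS:
        raise FormatError(f"pileup: expected columns {PILEUP_COLUMNS}")
    depths = df[["A", "C", "G", "T"]].to_numpy()
    if (depths < 0).any():
        bad = int(np.argwhere((depths < 0).any(axis=1))[0][0])
        raise FormatError(f"pileup row {bad}: negative depth")
    total = depths.sum(axis=1)
    if (total == 0).any():
        bad = int(np.argmax(total == 0))
        raise FormatError(f"pileup row {bad}: all-zero depth row forbidden")
    unknown = set(df["votu_id"]) - set(lengths)
    if unknown:
        raise FormatError(f"pileup: unannotated vOTU(s) {sorted(unknown)}")
    limits = df["votu_id"].map(lengths).to_numpy()
    pos = df["pos"].to_numpy()
    out_of_range = (pos < 1) | (pos > limits)
    if out_of_range.any():
        bad = int(np.argmax(out_of_range))
        raise FormatError(
            f"pileup row {bad}: pos {pos[bad]} outside [1, {limits[bad]}] "
            f"for vOTU {df['votu_id'].iloc[bad]!r}"
        )
    if df.duplicated(subset=["sample_id", "votu_id", "pos"]).any():
        dup = df[df.duplicated(subset=["sample_id", "votu_id", "pos"])].iloc[0]
        raise FormatError(
            f"pileup: duplicate position ({dup.sample_id}, {dup.votu_id}, {dup.pos})"
        )
    return df


def read_pileup(path: str | Path, annotations: list[VotuAnnotation]) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"sample_id": str, "votu_id": str, "pos": np.int64,
               "A": np.int64, "C": np.int64, "G": np.int64, "T": np.int64},
    )
    if list(df.columns) != PILEUP_COLUMNS:
        raise FormatError(f"{path}: expected columns {PILEUP_COLUMNS}")
    return validate_pileup(df, annotations)


def write_pileup(df: pd.DataFrame, path: str | Path) -> None:
    df[PILEUP_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# alignments (12-column tabular dialect; minus-strand hits have tstart > tend)


def read_alignments(path: str | Path) -> list[AlignmentRecord]:
    out: list[AlignmentRecord] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise FormatError(f"{path} line {lineno}: expected 12 columns")
            try:
                ts, te = int(fields[8]), int(fields[9])
                strand = "+" if ts <= te else "-"
                if strand == "-":
                    ts, te = te, ts
                out.append(
                    AlignmentRecord(
                        query_id=fields[0],
                        target_id=fields[1],
                        pct_identity=float(fields[2]),
                        aln_length=int(fields[3]),
                        mismatches=int(fields[4]),
                        gapopens=int(fields[5]),
                        qstart=int(fields[6]),
                        qend=int(fields[7]),
                        tstart=ts,
                        tend=te,
                        evalue=float(fields[10]),
                        bitscore=float(fields[11]),
                        strand=strand,
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path} line {lineno}: {exc}") from exc
    return out


def write_alignments(records: list[AlignmentRecord], path: str | Path) -> None:
    with open(path, "w") as handle:
        for r in records:
            ts, te = (r.tend, r.tstart) if r.strand == "-" else (r.tstart, r.tend)
            handle.write(
                "\t".join(
                    str(x)
                    for x in (
                        r.query_id, r.target_id, f"{r.pct_identity:.3f}",
                        r.aln_length, r.mismatches, r.gapopens,
                        r.qstart, r.qend, ts, te, f"{r.evalue:g}", f"{r.bitscore:g}",
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# matrices, trees, reports


def read_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.name != "votu_id":
        raise FormatError(f"{path}: first column must be 'votu_id'")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric matrix value") from exc
    if df.isna().any().any():
        col = df.columns[df.isna().any()][0]
        raise FormatError(f"{path}: NaN in matrix (column {col!r})")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    if matrix.isna().any().any():
        raise FormatError("refusing to write matrix containing NaN")
    matrix.to_csv(path, sep="\t", index_label="votu_id")


def write_newick(newick: str, path: str | Path) -> None:
    if not newick.rstrip().endswith(";"):
        raise FormatError("newick string must end with ';'")
    Path(path).write_text(newick.rstrip() + "\n")


class _ReportEncoder(json.JSONEncoder):
    def default(self, o):  # noqa: D102
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            v = float(o)
            return None if math.isnan(v) else v
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        if isinstance(o, pd.DataFrame):
            return json.loads(o.to_json(orient="index"))
        if isinstance(o, pd.Series):
            return json.loads(o.to_json())
        return super().default(o)


def write_report(report, path: str | Path) -> None:
    """Serialize a report object (dataclass / dict / DataFrame) to JSON."""
    with open(path, "w") as handle:
        json.dump(report, handle, cls=_ReportEncoder, indent=2, sort_keys=True)
        handle.write("\n")
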