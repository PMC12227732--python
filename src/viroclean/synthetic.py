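"""Synthetic multi-study virome fixtures with planted contamination.

The generator emulates the structure that NC-based decontamination
assumes: several studies, each with biological samples (infants with low
richness, mothers with higher richness) and a few negative controls;
a per-study contaminant pool drawn from a common cross-study pool (so an
external catalog has something to detect); contaminated samples carry NC
strains *identical* to the NC consensus, while resident vOTUs that happen
to coincide with NC species carry strains diverged by a configurable
number of SNPs — exercising the strain-vs-species distinction.

Everything is deterministic given the config seed, and every generated
table passes the io_formats validators.  Pileups are error-free by
default so popANI boundary arithmetic is exact; an optional per-position
error rate adds spurious alleles for robustness tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .abundance import (
    AbundanceMatrix,
    CountMatrix,
    breadth_filter,
    qc_filter_votus,
    to_rpkm,
)
from .io_formats import SampleMetadata, VotuAnnotation, metadata_frame
from .strains import AlleleProfile, StrainComparison, compare_strains

__all__ = [
    "SimConfig",
    "TruthRecord",
    "TruthLabels",
    "SyntheticDataset",
    "EvalMetrics",
    "simulate_genomes",
    "mutate_strain",
    "simulate_dataset",
    "simulate_study",
    "simulate_pileups",
    "strain_comparisons",
    "evaluate_against_truth",
]

_BASES = "ACGT"
_BITS = np.array([1, 2, 4, 8], dtype=np.uint8)


@dataclass(frozen=True)
class SimConfig:
    """Study-design and noise parameters for the simulator.

    Defaults describe a deliberately small design: 3 studies of 8 infant
    + 4 maternal samples with 2 NCs each, 50 vOTUs of 8-12 kb, resident
    strains diverged from NC strains by 50-200 SNPs, 60% of samples
    contaminated, and long-tailed (log-normal) contaminant abundance
    shares with a median around 1.5%.  Full coverage and error-free
    pileups by default.
    """

    seed: int
    n_studies: int = 3
    n_infants: int = 8
    n_mothers: int = 4
    n_ncs: int = 2
    n_votus: int = 50
    genome_length_range: tuple[int, int] = (8000, 12000)
    strain_snp_range: tuple[int, int] = (50, 200)
    contamination_fraction: float = 0.6
    contaminant_abundance_mu: float = math.log(0.015)
    contaminant_abundance_sigma: float = 1.5
    mean_contaminants: float = 2.0
    richness_infant: tuple[float, float] = (8.0, 0.7)  # (median, log-sigma)
    richness_mother: tuple[float, float] = (16.0, 0.4)
    shared_pool_size: int = 12
    nc_pool_size: int = 8
    nc_detection_prob: float = 0.85
    mean_coverage: float = 10.0
    gap_fraction: float = 0.0
    error_rate: float = 0.0
    total_reads: int = 200_000

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("n_studies", "n_infants", "n_ncs", "n_votus", "total_reads"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_mothers < 0:
            raise ValueError("n_mothers must be >= 0")
        for name in ("contamination_fraction", "gap_fraction", "error_rate",
                     "nc_detection_prob"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not (1 <= self.nc_pool_size <= self.shared_pool_size <= self.n_votus):
            raise ValueError("need 1 <= nc_pool_size <= shared_pool_size <= n_votus")
        lo, hi = self.genome_length_range
        if not 1 <= lo <= hi:
            raise ValueError("bad genome_length_range")
        if self.strain_snp_range[0] < 1 or self.strain_snp_range[0] > self.strain_snp_range[1]:
            raise ValueError("bad strain_snp_range")

    @property
    def n_samples(self) -> int:
        return self.n_infants + self.n_mothers


@dataclass(frozen=True)
class TruthRecord:
    sample_id: str
    votu_id: str
    is_contaminant: bool
    strain_id: str
    snp_positions: tuple[int, ...] = ()


@dataclass
class TruthLabels:
    """Ground truth for every (sample, vOTU) occurrence."""

    records: list[TruthRecord]

    def contaminant_pairs(self) -> set[tuple[str, str]]:
        return {(r.sample_id, r.votu_id) for r in self.records if r.is_contaminant}

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "sample_id": r.sample_id,
                    "votu_id": r.votu_id,
                    "is_contaminant": r.is_contaminant,
                    "strain_id": r.strain_id,
                    "n_snps": len(r.snp_positions),
                }
                for r in self.records
            ]
        )

    def per_sample_contamination(self) -> pd.DataFrame:
        """Truth contamination per sample: contaminant richness fraction."""
        df = self.frame()
        grouped = df.groupby("sample_id")["is_contaminant"]
        out = pd.DataFrame(
            {"n_votus": grouped.size(), "n_contaminants": grouped.sum().astype(int)}
        )
        out["contaminant_fraction"] = out["n_contaminants"] / out["n_votus"]
        return out


@dataclass
class SyntheticDataset:
    """One simulated multi-study dataset plus its ground truth."""

    config: SimConfig
    genomes: dict[str, str] = field(repr=False)
    annotations: list[VotuAnnotation] = field(repr=False)
    metadata: list[SampleMetadata] = field(repr=False)
    counts: CountMatrix = field(repr=False)
    matrix: AbundanceMatrix = field(repr=False)  # breadth-filtered, QC'd RPKM
    truth: TruthLabels = field(repr=False)
    profiles: dict[tuple[str, str], AlleleProfile] = field(repr=False)
    coverage_masks: dict[tuple[str, str], np.ndarray] = field(repr=False)
    strain_codes: dict[tuple[str, str], np.ndarray] = field(repr=False)


def _codes_to_seq(codes: np.ndarray) -> str:
    return "".join(np.array(list(_BASES))[codes])


def simulate_genomes(config: SimConfig, rng: np.random.Generator | None = None
                     ) -> dict[str, str]:
    """Uniform-random A/C/G/T ancestral genomes, deterministic per seed."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    lo, hi = config.genome_length_range
    genomes = {}
    for i in range(config.n_votus):
        length = int(rng.integers(lo, hi + 1))
        genomes[f"v{i:03d}"] = _codes_to_seq(rng.integers(0, 4, length))
    return genomes


def mutate_strain(genome: str, n_snps: int, seed: int | np.random.Generator
                  ) -> tuple[str, tuple[int, ...]]:
    """Plant exactly ``n_snps`` substitutions; returns (sequence, 1-based positions)."""
    if n_snps > len(genome):
        raise ValueError("n_snps exceeds genome length")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    codes = np.frombuffer(genome.encode(), dtype=np.uint8).copy()
    lookup = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate(_BASES):
        lookup[ord(b)] = i
    base_codes = lookup[codes]
    if (base_codes < 0).any():
        raise ValueError("genome must be A/C/G/T only")
    positions = np.sort(rng.choice(len(genome), size=n_snps, replace=False))
    shift = rng.integers(1, 4, size=n_snps)
    base_codes[positions] = (base_codes[positions] + shift) % 4
    return _codes_to_seq(base_codes), tuple(int(p) + 1 for p in positions)


def _draw_richness(rng, median: float, sigma: float, n_votus: int) -> int:
    r = int(round(rng.lognormal(math.log(median), sigma)))
    return max(1, min(n_votus, r))


def _mutated_codes(ancestral: np.ndarray, n_snps: int, rng) -> tuple[np.ndarray, tuple[int, ...]]:
    codes = ancestral.copy()
    positions = np.sort(rng.choice(len(codes), size=n_snps, replace=False))
    shift = rng.integers(1, 4, size=n_snps)
    codes[positions] = (codes[positions] + shift) % 4
    return codes, tuple(int(p) + 1 for p in positions)


def simulate_dataset(config: SimConfig) -> SyntheticDataset:
    """Generate genomes, metadata, counts, RPKM, profiles and truth labels."""
    rng = np.random.default_rng(config.seed)
    lo, hi = config.genome_length_range
    votu_ids = [f"v{i:03d}" for i in range(config.n_votus)]
    lengths = {v: int(rng.integers(lo, hi + 1)) for v in votu_ids}
    ancestral = {v: rng.integers(0, 4, lengths[v]).astype(np.int8) for v in votu_ids}
    genomes = {v: _codes_to_seq(ancestral[v]) for v in votu_ids}

    annotations = []
    for v in votu_ids:
        viral = int(rng.integers(2, 10))
        annotations.append(
            VotuAnnotation(
                votu_id=v,
                length_bp=lengths[v],
                viral_gene_count=viral,
                host_gene_count=int(rng.integers(0, viral + 1)),
                plasmid_flag=False,
                completeness_pct=float(np.round(rng.uniform(50, 100), 1)),
            )
        )

    shared_pool = sorted(rng.choice(votu_ids, config.shared_pool_size, replace=False))

    metadata: list[SampleMetadata] = []
    truth_records: list[TruthRecord] = []
    strain_codes: dict[tuple[str, str], np.ndarray] = {}
    shares: dict[str, dict[str, float]] = {}  # sample -> votu -> abundance share

    snp_lo, snp_hi = config.strain_snp_range
    for si in range(1, config.n_studies + 1):
        study = f"Study{si}"
        nc_pool = sorted(rng.choice(shared_pool, config.nc_pool_size, replace=False))

        nc_ids = [f"{study}_NC{j + 1}" for j in range(config.n_ncs)]
        negativeome: set[str] = set()
        for nc in nc_ids:
            detected = [v for v in nc_pool if rng.random() < config.nc_detection_prob]
            if not detected:
                detected = [nc_pool[int(rng.integers(len(nc_pool)))]]
            negativeome.update(detected)
            weights = rng.lognormal(0.0, 1.0, len(detected))
            weights /= weights.sum()
            shares[nc] = dict(zip(detected, weights))
            metadata.append(SampleMetadata(nc, study, "nc", None, "nc", None, "DNA"))
            for v in detected:
                strain_codes[(v, nc)] = ancestral[v]

        negativeome_sorted = sorted(negativeome)
        for j in range(config.n_samples):
            is_infant = j < config.n_infants
            sample = f"{study}_S{j + 1:02d}"
            group = "infant" if is_infant else "mother"
            median, sigma = (
                config.richness_infant if is_infant else config.richness_mother
            )
            r = _draw_richness(rng, median, sigma, config.n_votus)
            contaminated = rng.random() < config.contamination_fraction
            contams: list[str] = []
            if contaminated:
                n_c = 1 + int(rng.poisson(max(config.mean_contaminants - 1, 0)))
                n_c = min(n_c, len(negativeome_sorted), r)
                contams = sorted(
                    rng.choice(negativeome_sorted, n_c, replace=False)
                )
            others = [v for v in votu_ids if v not in contams]
            residents = sorted(rng.choice(others, r - len(contams), replace=False))

            c_shares = np.clip(
                rng.lognormal(
                    config.contaminant_abundance_mu,
                    config.contaminant_abundance_sigma,
                    len(contams),
                ),
                1e-4,
                0.99,
            )
            if c_shares.sum() > 0.95 or not residents:
                c_shares = c_shares / c_shares.sum() * (0.95 if residents else 1.0)
            r_weights = rng.lognormal(0.0, 1.0, len(residents))
            if len(residents):
                r_weights = r_weights / r_weights.sum() * (1.0 - c_shares.sum())
            sample_shares = dict(zip(contams, c_shares))
            sample_shares.update(zip(residents, r_weights))
            shares[sample] = sample_shares

            for v in contams:
                strain_codes[(v, sample)] = ancestral[v]
                truth_records.append(
                    TruthRecord(sample, v, True, f"{v}::nc", ())
                )
            for v in residents:
                n_snps = int(rng.integers(snp_lo, min(snp_hi, lengths[v]) + 1))
                codes, positions = _mutated_codes(ancestral[v], n_snps, rng)
                strain_codes[(v, sample)] = codes
                truth_records.append(
                    TruthRecord(sample, v, False, f"{v}::{sample}", positions)
                )

            age = float(np.round(rng.uniform(0, 12), 1)) if is_infant else None
            metadata.append(
                SampleMetadata(
                    sample, study, "sample", f"subj_{sample}", group, age, "DNA"
                )
            )

    # counts, breadth, coverage masks
    sample_ids = [m.sample_id for m in metadata]
    counts = pd.DataFrame(0, index=votu_ids, columns=sample_ids, dtype=np.int64)
    breadth = pd.DataFrame(0.0, index=votu_ids, columns=sample_ids)
    coverage_masks: dict[tuple[str, str], np.ndarray] = {}
    for s in sample_ids:
        for v, share in shares[s].items():
            counts.at[v, s] = max(1, int(round(share * config.total_reads)))
            mask = np.ones(lengths[v], dtype=bool)
            if config.gap_fraction > 0:
                gap_len = int(round(config.gap_fraction * lengths[v]))
                if gap_len:
                    start = int(rng.integers(0, lengths[v] - gap_len + 1))
                    mask[start : start + gap_len] = False
            coverage_masks[(v, s)] = mask
            breadth.at[v, s] = float(mask.mean())
    mapped_total = counts.sum(axis=0)
    count_matrix = CountMatrix(counts, mapped_total, breadth)

    meta_frame = metadata_frame(metadata)
    filtered = breadth_filter(count_matrix, min_breadth=0.75)
    matrix = qc_filter_votus(to_rpkm(filtered, annotations, meta_frame), annotations)

    # allele profiles from strain codes + coverage masks
    profiles: dict[tuple[str, str], AlleleProfile] = {}
    for (v, s), codes in strain_codes.items():
        mask = coverage_masks[(v, s)]
        allele = np.where(mask, _BITS[codes], 0).astype(np.uint8)
        consensus = np.where(mask, codes, -1).astype(np.int8)
        if config.error_rate > 0:
            err = rng.random(lengths[v]) < config.error_rate
            err &= mask
            if err.any():
                wrong = (codes[err] + rng.integers(1, 4, int(err.sum()))) % 4
                allele[err] |= _BITS[wrong]
        profiles[(v, s)] = AlleleProfile(v, s, lengths[v], allele, consensus)

    return SyntheticDataset(
        config=config,
        genomes=genomes,
        annotations=annotations,
        metadata=metadata,
        counts=count_matrix,
        matrix=matrix,
        truth=TruthLabels(truth_records),
        profiles=profiles,
        coverage_masks=coverage_masks,
        strain_codes=strain_codes,
    )


# the dataset covers all configured studies; kept as the operation alias
simulate_study = simulate_dataset


def simulate_pileups(dataset: SyntheticDataset, seed: int | None = None) -> pd.DataFrame:
    """Per-position depth rows for every (sample, vOTU) occurrence.

    Depth at each covered position is 1 + Poisson(mean_coverage - 1), all
    placed on the strain base (with ``error_rate``, a binomial share of
    reads moves to a random other base, never silencing the true base).
    """
    cfg = dataset.config
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    chunks = []
    for (v, s) in sorted(dataset.strain_codes):
        codes = dataset.strain_codes[(v, s)]
        mask = dataset.coverage_masks[(v, s)]
        pos = np.flatnonzero(mask) + 1
        if not len(pos):
            continue
        depth = 1 + rng.poisson(max(cfg.mean_coverage - 1, 0), len(pos))
        table = np.zeros((len(pos), 4), dtype=np.int64)
        table[np.arange(len(pos)), codes[mask]] = depth
        if cfg.error_rate > 0:
            moved = rng.binomial(np.maximum(depth - 1, 0), cfg.error_rate)
            has = moved > 0
            if has.any():
                wrong = (codes[mask][has] + rng.integers(1, 4, int(has.sum()))) % 4
                rows = np.flatnonzero(has)
                table[rows, codes[mask][has]] -= moved[has]
                table[rows, wrong] += moved[has]
        chunk = pd.DataFrame(table, columns=list(_BASES))
        chunk.insert(0, "pos", pos)
        chunk.insert(0, "votu_id", v)
        chunk.insert(0, "sample_id", s)
        chunks.append(chunk)
    return pd.concat(chunks, ignore_index=True)


def strain_comparisons(
    dataset: SyntheticDataset, scope: str = "own_study"
) -> list[StrainComparison]:
    """popANI comparisons between biological samples and NCs.

    ``scope`` picks the NC set per sample: its own study's NCs
    (decontamination) or all other studies' NCs (external estimation).
    Only vOTUs present in both members of a pair are compared.
    """
    meta = metadata_frame(dataset.metadata)
    samples = [m.sample_id for m in dataset.metadata if m.role == "sample"]
    ncs = [m.sample_id for m in dataset.metadata if m.role == "nc"]
    by_member: dict[str, set[str]] = {}
    for (v, s) in dataset.profiles:
        by_member.setdefault(s, set()).add(v)
    out = []
    for s in samples:
        study = meta.at[s, "study"]
        if scope == "own_study":
            targets = [nc for nc in ncs if meta.at[nc, "study"] == study]
        elif scope == "external":
            targets = [nc for nc in ncs if meta.at[nc, "study"] != study]
        else:
            raise ValueError(f"unknown scope {scope!r}")
        for nc in targets:
            for v in sorted(by_member.get(s, set()) & by_member.get(nc, set())):
                out.append(
                    compare_strains(dataset.profiles[(v, s)], dataset.profiles[(v, nc)])
                )
    return out


@dataclass(frozen=True)
class EvalMetrics:
    """Confusion-matrix summary of a decontamination run against truth.

    false_removal_rate is the fraction of removed cells that were not
    true contaminants (0 when nothing was removed).
    """

    sensitivity: float | None
    specificity: float | None
    false_removal_rate: float
    tp: int
    fp: int
    fn: int
    tn: int


def evaluate_against_truth(
    removed: dict[str, list[str]],
    truth: TruthLabels,
    matrix: AbundanceMatrix,
) -> EvalMetrics:
    """Score removals over all nonzero (sample, vOTU) cells."""
    universe = {
        (s, v)
        for s in matrix.biological_samples
        for v in matrix.rpkm.index[matrix.rpkm[s] > 0]
    }
    positives = truth.contaminant_pairs() & universe
    predicted = {
        (s, v) for s, votus in removed.items() for v in votus
    } & universe
    tp = len(predicted & positives)
    fp = len(predicted - positives)
    fn = len(positives - predicted)
    tn = len(universe) - tp - fp - fn
    return EvalMetrics(
        sensitivity=tp / (tp + fn) if (tp + fn) else None,
        specificity=tn / (tn + fp) if (tn + fp) else None,
        false_removal_rate=fp / (tp + fp) if (tp + fp) else 0.0,
        tp=tp, fp=fp, fn=fn, tn=tn,
    )
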