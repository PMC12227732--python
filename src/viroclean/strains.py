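"""Strain reconstruction and population-ANI comparison within vOTUs.

A sample's strain of a vOTU is represented as an allele profile: at every
position covered by at least ``min_cov`` reads, the set of observed bases
(depth >= 1 each) plus the modal consensus base.  Two strains are compared
over the positions covered in both samples:

* popANI counts a position as different only when the two allele sets are
  disjoint (no shared allele);
* conANI counts a position as different whenever the consensus bases
  differ; hence popANI >= conANI always.

Strains are considered shared at >= 99.999% popANI (inclusive), with at
least 75% of the genome mutually covered in analysis mode; decontamination
mode waives the coverage-fraction requirement to tolerate shallow NCs.
Boundary decisions use exact integer/rational arithmetic, never
pre-rounded percentages.  Dissimilarity trees use d = 1 - popANI/100 with
hierarchical clustering and ultrametric (half-distance) node heights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "BASES",
    "AlleleProfile",
    "StrainComparison",
    "StrainTree",
    "build_allele_profile",
    "consensus_sequence",
    "compare_strains",
    "is_shared_strain",
    "build_strain_tree",
    "comparison_table",
]

BASES = "ACGT"
_BITS = np.array([1, 2, 4, 8], dtype=np.uint8)  # A, C, G, T


@dataclass
class AlleleProfile:
    """Observed alleles and consensus for one vOTU in one sample.

    ``allele_mask`` is a genome-length uint8 array of ACGT bit flags
    (0 = position uncovered); ``consensus_code`` holds 0..3 base codes
    with -1 at uncovered positions.
    """

    votu_id: str
    sample_id: str
    genome_length: int
    allele_mask: np.ndarray = field(repr=False)
    consensus_code: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.genome_length < 1:
            raise ValueError("genome_length must be positive")
        if len(self.allele_mask) != self.genome_length:
            raise ValueError("allele_mask length != genome_length")
        if len(self.consensus_code) != self.genome_length:
            raise ValueError("consensus_code length != genome_length")
        covered = self.allele_mask > 0
        if (self.consensus_code[covered] < 0).any():
            raise ValueError("covered position without consensus")
        if (self.consensus_code[~covered] != -1).any():
            raise ValueError("consensus at uncovered position")
        # consensus base must be one of the observed alleles
        codes = self.consensus_code[covered]
        if not (self.allele_mask[covered] & _BITS[codes]).all():
            raise ValueError("consensus base not among observed alleles")

    @property
    def covered_positions(self) -> np.ndarray:
        """1-based positions with coverage >= min_cov."""
        return np.flatnonzero(self.allele_mask > 0) + 1

    def alleles_at(self, pos: int) -> set[str]:
        mask = int(self.allele_mask[pos - 1])
        return {BASES[i] for i in range(4) if mask & (1 << i)}


@dataclass(frozen=True)
class StrainComparison:
    """Pairwise popANI/conANI record for one vOTU between two samples."""

    votu_id: str
    sample_a: str
    sample_b: str
    genome_length: int
    compared_positions: int
    popani_diff_count: int
    conani_diff_count: int

    def __post_init__(self) -> None:
        if self.popani_diff_count > self.conani_diff_count:
            raise ValueError("popANI differences cannot exceed conANI differences")

    @property
    def popani(self) -> float | None:
        if self.compared_positions == 0:
            return None
        # single correctly-rounded division keeps printed boundaries exact
        return 100.0 * (self.compared_positions - self.popani_diff_count) / (
            self.compared_positions
        )

    @property
    def conani(self) -> float | None:
        if self.compared_positions == 0:
            return None
        return 100.0 * (self.compared_positions - self.conani_diff_count) / (
            self.compared_positions
        )

    @property
    def fraction_compared(self) -> float:
        return self.compared_positions / self.genome_length


def build_allele_profile(
    pileup_rows: pd.DataFrame,
    votu_id: str,
    sample_id: str,
    genome_length: int,
    min_cov: int = 1,
) -> AlleleProfile:
    """Profile one (sample, vOTU) from per-position depth rows.

    A position is covered iff its total depth is >= ``min_cov``; every base
    with depth >= 1 at a covered position is an allele; the consensus is
    the modal base (depth ties broken lexicographically, A<C<G<T).
    """
    if genome_length < 1:
        raise ValueError("genome_length must be positive")
    rows = pileup_rows
    if "sample_id" in rows.columns:
        rows = rows[(rows["sample_id"] == sample_id) & (rows["votu_id"] == votu_id)]
    allele_mask = np.zeros(genome_length, dtype=np.uint8)
    consensus = np.full(genome_length, -1, dtype=np.int8)
    if len(rows):
        pos = rows["pos"].to_numpy(dtype=np.int64)
        if (pos < 1).any() or (pos > genome_length).any():
            raise ValueError(f"pileup position outside [1, {genome_length}]")
        depths = rows[list(BASES)].to_numpy(dtype=np.int64)
        keep = depths.sum(axis=1) >= min_cov
        pos, depths = pos[keep], depths[keep]
        allele_mask[pos - 1] = ((depths > 0) * _BITS).sum(axis=1).astype(np.uint8)
        # np.argmax returns the first maximum: lexicographic tie-break for free
        consensus[pos - 1] = np.argmax(depths, axis=1).astype(np.int8)
    return AlleleProfile(votu_id, sample_id, genome_length, allele_mask, consensus)


def consensus_sequence(profile: AlleleProfile) -> str:
    """Consensus base string, 'N' at uncovered positions."""
    lookup = np.array(list("ACGTN"))
    codes = profile.consensus_code.copy()
    codes[codes < 0] = 4
    return "".join(lookup[codes])


def compare_strains(a: AlleleProfile, b: AlleleProfile) -> StrainComparison:
    """popANI/conANI over the mutually covered positions of two profiles."""
    if a.votu_id != b.votu_id:
        raise ValueError(f"vOTU mismatch: {a.votu_id!r} vs {b.votu_id!r}")
    if a.genome_length != b.genome_length:
        raise ValueError("genome_length mismatch")
    both = (a.allele_mask > 0) & (b.allele_mask > 0)
    compared = int(both.sum())
    pop_diff = int(((a.allele_mask & b.allele_mask) == 0)[both].sum())
    con_diff = int((a.consensus_code != b.consensus_code)[both].sum())
    return StrainComparison(
        votu_id=a.votu_id,
        sample_a=a.sample_id,
        sample_b=b.sample_id,
        genome_length=a.genome_length,
        compared_positions=compared,
        popani_diff_count=pop_diff,
        conani_diff_count=con_diff,
    )


def _frac(x: float) -> Fraction:
    # float thresholds like 99.999 are decimal literals; str() recovers them
    return Fraction(str(x))


def is_shared_strain(
    comparison: StrainComparison,
    popani_min: float = 99.999,
    min_fraction: float = 0.75,
    mode: str = "analysis",
) -> bool:
    """Decide strain identity from a comparison, with exact boundary math.

    analysis mode requires popANI >= popani_min AND fraction_compared >=
    min_fraction; decontamination mode waives the fraction requirement
    (shallow NCs should still trigger removal).
    """
    if comparison.compared_positions == 0:
        raise ValueError("null comparison: no mutually covered positions")
    if mode not in {"analysis", "decontamination"}:
        raise ValueError(f"unknown mode {mode!r}")
    diff_rate = Fraction(comparison.popani_diff_count, comparison.compared_positions)
    popani_ok = diff_rate <= (Fraction(100) - _frac(popani_min)) / 100
    if mode == "decontamination":
        return popani_ok
    fraction = Fraction(comparison.compared_positions, comparison.genome_length)
    return popani_ok and fraction >= _frac(min_fraction)


@dataclass
class StrainTree:
    """Ultrametric dendrogram of strains from 1 - popANI distances."""

    votu_id: str
    leaves: list[str]
    linkage: np.ndarray = field(repr=False)
    method: str = "complete"

    def node_heights(self) -> np.ndarray:
        """Ultrametric merge heights (half the merge distance)."""
        return self.linkage[:, 2] / 2.0

    def to_newick(self) -> str:
        n = len(self.leaves)
        heights = self.node_heights()

        def height(node: int) -> float:
            return 0.0 if node < n else float(heights[node - n])

        def render(node: int, parent_h: float) -> str:
            bl = parent_h - height(node)
            if node < n:
                return f"{self.leaves[node]}:{bl:.10g}"
            left, right = int(self.linkage[node - n, 0]), int(self.linkage[node - n, 1])
            h = height(node)
            return f"({render(left, h)},{render(right, h)}):{bl:.10g}"

        root = n + len(heights) - 1
        h = height(root)
        left, right = int(self.linkage[-1, 0]), int(self.linkage[-1, 1])
        return f"({render(left, h)},{render(right, h)});"


def build_strain_tree(
    comparisons: list[StrainComparison],
    min_fraction: float = 0.75,
    linkage_method: str = "complete",
) -> StrainTree:
    """Hierarchically cluster samples by 1 - popANI for one vOTU.

    Pairs with fraction_compared below ``min_fraction`` (or no compared
    positions) are excluded; the retained leaf set must then be completely
    comparable — missing pairs are an error (no distance imputation).
    """
    if not comparisons:
        raise ValueError("no comparisons supplied")
    votu = comparisons[0].votu_id
    if any(c.votu_id != votu for c in comparisons):
        raise ValueError("comparisons mix vOTUs")
    retained = {}
    for c in comparisons:
        if c.compared_positions == 0:
            continue
        if Fraction(c.compared_positions, c.genome_length) < _frac(min_fraction):
            continue
        retained[frozenset((c.sample_a, c.sample_b))] = 1.0 - c.popani / 100.0
    leaves = sorted({s for pair in retained for s in pair})
    if len(leaves) < 2:
        raise ValueError("fewer than 2 leaves remain after the fraction filter")
    missing = [
        (a, b)
        for i, a in enumerate(leaves)
        for b in leaves[i + 1 :]
        if frozenset((a, b)) not in retained
    ]
    if missing:
        raise ValueError(
            f"incomplete distance matrix for vOTU {votu!r}; missing pairs: {missing}"
        )
    n = len(leaves)
    dmat = np.zeros((n, n))
    for i, a in enumerate(leaves):
        for j in range(i + 1, n):
            d = retained[frozenset((a, leaves[j]))]
            dmat[i, j] = dmat[j, i] = d
    linkage = hierarchy.linkage(squareform(dmat, checks=False), method=linkage_method)
    return StrainTree(votu_id=votu, leaves=leaves, linkage=linkage, method=linkage_method)


def comparison_table(comparisons: list[StrainComparison]) -> pd.DataFrame:
    """Tidy frame of comparisons (one row per vOTU/sample pair)."""
    rows = [
        {
            "votu_id": c.votu_id,
            "sample_a": c.sample_a,
            "sample_b": c.sample_b,
            "compared_positions": c.compared_positions,
            "popani": c.popani,
            "conani": c.conani,
            "fraction_compared": c.fraction_compared,
        }
        for c in comparisons
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "votu_id", "sample_a", "sample_b", "compared_positions",
            "popani", "conani", "fraction_compared",
        ],
    )
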