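"""Species-level dereplication of viral contigs into vOTUs.

Contigs are clustered at the MIUViG species rank: 95% average nucleotide
identity (ANI) over 85% alignment fraction of the shorter sequence (AF),
both thresholds inclusive.  Pairwise evidence comes either from an external
all-vs-all search (12-column tabular records) or from the built-in pairwise
aligner, which runs exhaustive Smith-Waterman for short sequences and a
k-mer-seeded X-drop extension otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from Bio import Align

__all__ = [
    "AlignmentRecord",
    "AniPair",
    "VotuClustering",
    "align_pair",
    "compute_ani",
    "greedy_cluster",
    "map_to_catalog",
    "pairwise_ani",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AlignmentRecord:
    """One local alignment (HSP) between a query and a target sequence.

    Coordinates are 1-based inclusive and stored ascending on both
    sequences; ``strand`` records whether the target was reverse
    complemented.  Fields mirror the common 12-column tabular dialect.
    """

    query_id: str
    target_id: str
    pct_identity: float
    aln_length: int
    mismatches: int
    gapopens: int
    qstart: int
    qend: int
    tstart: int
    tend: int
    evalue: float = 0.0
    bitscore: float = 0.0
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.qstart > self.qend or self.tstart > self.tend:
            raise ValueError(
                f"alignment {self.query_id}/{self.target_id}: coordinates "
                "must be ascending (minus strand is flagged, not swapped)"
            )
        if self.aln_length <= 0:
            raise ValueError("aln_length must be positive")


@dataclass(frozen=True)
class AniPair:
    """ANI and alignment fraction (of the shorter sequence) for one pair."""

    a_id: str
    b_id: str
    ani: float
    af_shorter: float


@dataclass
class VotuClustering:
    """Partition of contigs into vOTUs; representatives are longest members."""

    clusters: dict[str, list[str]]
    membership: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.membership:
            self.membership = {
                m: rep for rep, members in self.clusters.items() for m in members
            }

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)


# ---------------------------------------------------------------------------
# pairwise alignment


def _exhaustive_records(
    a: str, b: str, a_id: str, b_id: str, strand: str
) -> list[AlignmentRecord]:
    aligner = Align.PairwiseAligner(
        mode="local",
        match_score=1,
        mismatch_score=-1,
        open_gap_score=-3,
        extend_gap_score=-1,
    )
    score = aligner.score(a, b)
    if score <= 0:
        return []
    aln = aligner.align(a, b)[0]
    counts = aln.counts()
    ident, mism = counts.identities, counts.mismatches
    length = aln.length
    blocks_q, blocks_t = aln.aligned
    qstart, qend = int(blocks_q[0][0]) + 1, int(blocks_q[-1][1])
    ts, te = int(blocks_t[0][0]) + 1, int(blocks_t[-1][1])
    gapopens = max(0, len(blocks_q) - 1)
    if strand == "-":
        ts, te = len(b) - te + 1, len(b) - ts + 1
    return [
        AlignmentRecord(
            query_id=a_id,
            target_id=b_id,
            pct_identity=100.0 * ident / length,
            aln_length=int(length),
            mismatches=int(mism),
            gapopens=gapopens,
            qstart=qstart,
            qend=qend,
            tstart=ts,
            tend=te,
            bitscore=float(score),
            strand=strand,
        )
    ]


def _xdrop_extend(a: str, b: str, qpos: int, tpos: int, xdrop: int = 12):
    """Ungapped extension around an exact seed on one diagonal.

    Returns 0-based half-open (qs, qe) on ``a`` plus match/mismatch counts.
    """
    best, score = 0, 0
    left = 0
    i, j = qpos - 1, tpos - 1
    while i >= 0 and j >= 0:
        score += 1 if a[i] == b[j] else -1
        if score > best:
            best, left = score, qpos - i
        if best - score > xdrop:
            break
        i, j = i - 1, j - 1
    best_r, score = 0, 0
    right = 0
    i, j = qpos, tpos
    while i < len(a) and j < len(b):
        score += 1 if a[i] == b[j] else -1
        if score > best_r:
            best_r, right = score, i - qpos + 1
        if best_r - score > xdrop:
            break
        i, j = i + 1, j + 1
    qs, qe = qpos - left, qpos + right
    matches = sum(1 for k in range(qs, qe) if a[k] == b[k - qpos + tpos])
    return qs, qe, matches, (qe - qs) - matches


def _seeded_records(
    a: str,
    b: str,
    a_id: str,
    b_id: str,
    strand: str,
    k: int = 11,
    min_len: int = 50,
    min_identity: float = 70.0,
) -> list[AlignmentRecord]:
    index: dict[str, list[int]] = {}
    for j in range(len(b) - k + 1):
        index.setdefault(b[j : j + k], []).append(j)
    diagonals: dict[int, list[int]] = {}
    for i in range(len(a) - k + 1):
        for j in index.get(a[i : i + k], ()):
            diagonals.setdefault(i - j, []).append(i)

    raw = []
    for diag, qpos_list in diagonals.items():
        covered_to = -1
        for qpos in qpos_list:
            if qpos <= covered_to:
                continue
            qs, qe, matches, mism = _xdrop_extend(a, b, qpos, qpos - diag)
            covered_to = qe
            length = qe - qs
            if length < min_len:
                continue
            identity = 100.0 * matches / length
            if identity < min_identity:
                continue
            raw.append((matches - mism, qs, qe, matches, mism, diag))

    raw.sort(key=lambda r: (-r[0], r[1]))
    kept: list[tuple] = []
    for cand in raw:
        _, qs, qe, *_ = cand
        overlap = any(
            min(qe, kqe) - max(qs, kqs) > 0.5 * (qe - qs)
            for _, kqs, kqe, *_ in kept
        )
        if not overlap:
            kept.append(cand)

    records = []
    for score, qs, qe, matches, mism, diag in kept:
        ts, te = qs - diag + 1, qe - diag
        if strand == "-":
            ts, te = len(b) - te + 1, len(b) - (qs - diag + 1) + 1
        records.append(
            AlignmentRecord(
                query_id=a_id,
                target_id=b_id,
                pct_identity=100.0 * matches / (qe - qs),
                aln_length=qe - qs,
                mismatches=mism,
                gapopens=0,
                qstart=qs + 1,
                qend=qe,
                tstart=ts,
                tend=te,
                bitscore=float(score),
                strand=strand,
            )
        )
    return records


def align_pair(
    seq_a: str,
    seq_b: str,
    a_id: str = "query",
    b_id: str = "target",
    mode: str = "auto",
) -> list[AlignmentRecord]:
    """Locally align two sequences on both strands.

    ``mode`` is "exhaustive" (optimal Smith-Waterman via Biopython),
    "seeded" (k-mer-seeded ungapped X-drop extension), or "auto"
    (exhaustive when both sequences are <= 2 kb).  Output is deterministic
    for fixed inputs.
    """
    if not seq_a or not seq_b:
        raise ValueError("align_pair: empty sequence")
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    if mode == "auto":
        mode = "exhaustive" if max(len(seq_a), len(seq_b)) <= 2000 else "seeded"
    engine = _exhaustive_records if mode == "exhaustive" else _seeded_records

    plus = engine(seq_a, seq_b, a_id, b_id, "+")
    minus = engine(seq_a, reverse_complement(seq_b), a_id, b_id, "-")
    if mode == "exhaustive":
        # a single optimal HSP per pair: keep the better strand (tie -> plus)
        best_plus = plus[0].bitscore if plus else float("-inf")
        best_minus = minus[0].bitscore if minus else float("-inf")
        return plus if best_plus >= best_minus else minus
    return sorted(plus + minus, key=lambda r: (-r.bitscore, r.qstart, r.strand))


# ---------------------------------------------------------------------------
# ANI / AF


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def compute_ani(
    records: list[AlignmentRecord], len_a: int, len_b: int
) -> AniPair:
    """Aggregate HSPs between one pair into (ANI, AF of the shorter sequence).

    ANI is the alignment-length-weighted mean identity over all HSPs; AF is
    the merged union of aligned intervals projected onto the shorter
    sequence, as a percentage of its length.  No records yields the
    (0, 0) sentinel.
    """
    if not records:
        return AniPair("", "", 0.0, 0.0)
    a_id, b_id = records[0].query_id, records[0].target_id
    for r in records:
        if (r.query_id, r.target_id) != (a_id, b_id):
            raise ValueError("compute_ani: records mix sequence pairs")
    total = sum(r.aln_length for r in records)
    ani = sum(r.pct_identity * r.aln_length for r in records) / total
    if len_a <= len_b:
        shorter_len = len_a
        intervals = [(r.qstart, r.qend) for r in records]
    else:
        shorter_len = len_b
        intervals = [(r.tstart, r.tend) for r in records]
    intervals = [(s, min(e, shorter_len)) for s, e in intervals]
    union = sum(e - s + 1 for s, e in _merge_intervals(intervals))
    return AniPair(a_id, b_id, ani, 100.0 * union / shorter_len)


def pairwise_ani(
    seqs: dict[str, str], mode: str = "auto"
) -> list[AniPair]:
    """All-vs-all ANI/AF for a set of sequences (internal aligner)."""
    ids = sorted(seqs)
    pairs = []
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            records = align_pair(seqs[a], seqs[b], a, b, mode=mode)
            pair = compute_ani(records, len(seqs[a]), len(seqs[b]))
            pairs.append(replace(pair, a_id=a, b_id=b))
    return pairs


# ---------------------------------------------------------------------------
# clustering


def _pair_lookup(ani_pairs: list[AniPair]) -> dict[frozenset, tuple[float, float]]:
    lookup: dict[frozenset, tuple[float, float]] = {}
    for p in ani_pairs:
        key = frozenset((p.a_id, p.b_id))
        prev = lookup.get(key)
        if prev is None or (p.ani, p.af_shorter) > prev:
            lookup[key] = (p.ani, p.af_shorter)
    return lookup


def greedy_cluster(
    ani_pairs: list[AniPair],
    lengths: dict[str, int],
    ani_min: float = 95.0,
    af_min: float = 85.0,
) -> VotuClustering:
    """Greedy species-level dereplication at inclusive ANI/AF cut-offs.

    Contigs are scanned longest first (ties by id); each joins the first
    existing representative it matches at >= ani_min ANI and >= af_min AF,
    otherwise it seeds a new cluster.  Representatives are therefore the
    longest members of their clusters.
    """
    for p in ani_pairs:
        for cid in (p.a_id, p.b_id):
            if cid not in lengths:
                raise ValueError(f"contig {cid!r} in ani_pairs but not in lengths")
    lookup = _pair_lookup(ani_pairs)
    order = sorted(lengths, key=lambda c: (-lengths[c], c))
    reps: list[str] = []
    clusters: dict[str, list[str]] = {}
    for contig in order:
        for rep in reps:
            hit = lookup.get(frozenset((contig, rep)))
            if hit is not None and hit[0] >= ani_min and hit[1] >= af_min:
                clusters[rep].append(contig)
                break
        else:
            reps.append(contig)
            clusters[contig] = [contig]
    return VotuClustering(clusters=clusters)


def map_to_catalog(
    query_seqs: dict[str, str],
    catalog_seqs: dict[str, str],
    ani_min: float = 95.0,
    af_min: float = 85.0,
    mode: str = "auto",
) -> dict[str, str | None]:
    """Assign each query to its best catalog entry at the species cut-offs.

    Best = highest AF, then highest ANI, then lexicographically smallest
    catalog id; queries with no qualifying hit map to None.
    """
    if not catalog_seqs:
        raise ValueError("map_to_catalog: empty catalog")
    assignment: dict[str, str | None] = {}
    for qid in sorted(query_seqs):
        best: tuple[float, float, str] | None = None
        for cid in sorted(catalog_seqs):
            records = align_pair(query_seqs[qid], catalog_seqs[cid], qid, cid, mode)
            pair = compute_ani(records, len(query_seqs[qid]), len(catalog_seqs[cid]))
            if pair.ani >= ani_min and pair.af_shorter >= af_min:
                key = (-pair.af_shorter, -pair.ani, cid)
                if best is None or key < best:
                    best = key
        assignment[qid] = best[2] if best is not None else None
    return assignment
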