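"""Strain-unique region discovery and whole-genome identity.

The discovery step subtracts same-species background genomes from the target
assembly at the canonical k-mer level: every position of the target whose
k-mer occurs nowhere in the background starts a "unique" run, runs are merged
across short interruptions, and merged runs longer than a minimum span become
candidate regions.  Candidates are then screened by local alignment: a region
is kept only if it aligns poorly (< low_threshold) to every genome of a
non-target collection and strongly (>= high_threshold) to the target genome
itself.

The module also provides a fragment-based average nucleotide identity (ANI):
one genome is chopped into fixed-length fragments, each fragment is aligned
to the other genome, and fragments whose best alignment covers >= 70% of the
fragment at >= 30% identity contribute their identity to the mean (the ANIb
convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .align import AlignScoring, SubjectSeeds, best_local_alignment, max_score_vs_records
from .seqio import SequenceRecord

__all__ = [
    "KmerIndex",
    "CandidateRegion",
    "build_kmer_index",
    "find_unique_regions",
    "specificity_filter",
    "ani",
]

# byte-value -> 2-bit code lookup; 255 marks non-ACGT (N, gaps)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i

_DECODE = "ACGT"


def encode_sequence(seq: str) -> np.ndarray:
    """2-bit-code array of a DNA string (255 where the base is not ACGT)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def canonical_kmer_values(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical k-mer integer values for every window of ``seq``.

    Returns ``(values, valid)`` arrays of length ``len(seq) - k + 1``;
    windows containing non-ACGT bases are flagged invalid and their value is
    meaningless.  The canonical value is the minimum of the 2-bit encodings
    of the k-mer and its reverse complement, so indexing is strand-blind.
    """
    codes = encode_sequence(seq)
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    bad = codes == 255
    cum = np.concatenate(([0], np.cumsum(bad)))
    valid = (cum[k:] - cum[:-k]) == 0
    safe = np.where(bad, 0, codes).astype(np.uint64)
    windows = np.lib.stride_tricks.sliding_window_view(safe, k)
    powers = (np.uint64(4) ** np.arange(k - 1, -1, -1, dtype=np.uint64))
    fwd = windows @ powers
    rc = (np.uint64(3) - windows) @ powers[::-1]
    return np.minimum(fwd, rc), valid


def encode_kmer(kmer: str) -> int:
    """Canonical integer value of a single k-mer (no N allowed)."""
    values, valid = canonical_kmer_values(kmer, len(kmer))
    if not valid[0]:
        raise ValueError("k-mer contains non-ACGT characters")
    return int(values[0])


@dataclass
class KmerIndex:
    """Set of canonical k-mers drawn from a collection of genomes.

    ``members`` is a sorted array of canonical 2-bit k-mer encodings; use
    :meth:`contains` for string lookups.  This index plays the role a read
    aligner's genome index plays in subtraction pipelines.
    """

    k: int
    members: np.ndarray
    source_ids: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.members)

    def contains(self, kmer: str) -> bool:
        if len(kmer) != self.k:
            raise ValueError(f"expected a {self.k}-mer, got length {len(kmer)}")
        value = np.uint64(encode_kmer(kmer))
        pos = np.searchsorted(self.members, value)
        return bool(pos < len(self.members) and self.members[pos] == value)

    def contains_values(self, values: np.ndarray) -> np.ndarray:
        """Vectorised membership for an array of canonical values."""
        pos = np.searchsorted(self.members, values)
        pos_clipped = np.minimum(pos, len(self.members) - 1)
        if len(self.members) == 0:
            return np.zeros(len(values), dtype=bool)
        return self.members[pos_clipped] == values


def build_kmer_index(genomes: list[SequenceRecord], k: int = 21) -> KmerIndex:
    """Index every canonical k-mer (N-free windows only) of the genomes."""
    if k % 2 == 0 or not 15 <= k <= 31:
        raise ValueError("k must be odd and within [15, 31]")
    if not genomes:
        raise ValueError("at least one genome is required to build an index")
    chunks = []
    for rec in genomes:
        values, valid = canonical_kmer_values(rec.seq, k)
        chunks.append(values[valid])
    members = np.unique(np.concatenate(chunks)) if chunks else np.empty(0, np.uint64)
    return KmerIndex(k=k, members=members, source_ids=[g.id for g in genomes])


@dataclass
class CandidateRegion:
    """A target-unique genomic interval (0-based, half-open, forward strand)."""

    contig_id: str
    start: int
    end: int
    seq: str
    target_score: int | None = None
    max_nontarget_score: int | None = None

    @property
    def region_id(self) -> str:
        return f"{self.contig_id}:{self.start}-{self.end}"

    def __len__(self) -> int:
        return self.end - self.start


def find_unique_regions(
    target: list[SequenceRecord],
    background: KmerIndex,
    min_len: int = 1000,
    merge_gap: int = 100,
) -> list[CandidateRegion]:
    """Report target intervals whose k-mers are absent from the background.

    For each contig, start positions whose (N-free) k-mer is missing from
    ``background`` form runs; runs separated by at most ``merge_gap``
    background-covered positions are merged, and a merged run is reported
    when its base span (last absent start + k - start) reaches ``min_len``.
    Windows containing N count as covered, so assembly gaps never seed or
    extend a region.
    """
    if background.k > min_len:
        raise ValueError("min_len must be at least the index k")
    regions: list[CandidateRegion] = []
    k = background.k
    for rec in target:
        values, valid = canonical_kmer_values(rec.seq, k)
        if len(values) == 0:
            continue
        absent = valid & ~background.contains_values(values)
        if not absent.any():
            continue
        starts = np.flatnonzero(absent)
        # split where the gap between consecutive absent positions exceeds
        # merge_gap covered positions
        breaks = np.flatnonzero(np.diff(starts) - 1 > merge_gap)
        run_bounds = zip(
            np.concatenate(([0], breaks + 1)),
            np.concatenate((breaks, [len(starts) - 1])),
        )
        for lo, hi in run_bounds:
            start = int(starts[lo])
            end = int(starts[hi]) + k
            if end - start >= min_len:
                regions.append(
                    CandidateRegion(rec.id, start, end, rec.seq[start:end])
                )
    regions.sort(key=lambda r: (r.contig_id, r.start))
    return regions


def specificity_filter(
    regions: list[CandidateRegion],
    target_genome: list[SequenceRecord],
    nontarget_db: list[SequenceRecord],
    scoring: AlignScoring = AlignScoring(),
) -> list[CandidateRegion]:
    """Keep regions aligning poorly to non-targets and strongly to the target.

    A region survives iff its best local score against every non-target
    genome is below ``scoring.low_threshold`` and its best score against the
    target genome reaches ``scoring.high_threshold``.  Both scores are
    annotated on the surviving regions.
    """
    if not nontarget_db:
        warnings.warn(
            "empty non-target collection: cross-specificity test passes vacuously",
            stacklevel=2,
        )
    kept: list[CandidateRegion] = []
    nt_cache: dict[str, SubjectSeeds] = {}
    t_cache: dict[str, SubjectSeeds] = {}
    for region in regions:
        nt_score = max_score_vs_records(
            region.seq, nontarget_db, scoring, nt_cache, stop_at=scoring.low_threshold
        )
        if nt_score >= scoring.low_threshold:
            continue
        t_score = max_score_vs_records(
            region.seq, target_genome, scoring, t_cache, stop_at=scoring.high_threshold
        )
        if t_score < scoring.high_threshold:
            continue
        region.max_nontarget_score = nt_score
        region.target_score = t_score
        kept.append(region)
    return kept


# ANIb-convention fragment acceptance thresholds
_ANI_MIN_COVERAGE = 0.70
_ANI_MIN_IDENTITY = 0.30
_ANI_SEED_K = 13


def _fragments(genome: list[SequenceRecord], fragment_len: int) -> list[str]:
    frags = []
    for rec in genome:
        for i in range(0, len(rec.seq), fragment_len):
            piece = rec.seq[i : i + fragment_len]
            if len(piece) >= _ANI_SEED_K:
                frags.append(piece)
    return frags


def ani(
    genome_a: list[SequenceRecord],
    genome_b: list[SequenceRecord],
    fragment_len: int = 1020,
    scoring: AlignScoring = AlignScoring(),
) -> tuple[float, float]:
    """Fragment-based average nucleotide identity of A against B.

    Returns ``(ani_percent, coverage_percent)``: the mean percent identity of
    contributing fragments and the percentage of fragments that contribute.
    A fragment contributes when its best local alignment to B covers at least
    70% of the fragment at >= 30% identity.
    """
    total_a = sum(len(r.seq) for r in genome_a)
    total_b = sum(len(r.seq) for r in genome_b)
    if total_a < fragment_len or total_b < fragment_len:
        raise ValueError("both genomes must be at least one fragment long")
    seeds = [SubjectSeeds(rec.seq, _ANI_SEED_K) for rec in genome_b]
    identities: list[float] = []
    frags = _fragments(genome_a, fragment_len)
    for frag in frags:
        best = _best_fragment_alignment(frag, seeds, scoring)
        if best is None:
            continue
        qaligned, ident, columns = best
        if columns == 0:
            continue
        coverage = qaligned / len(frag)
        identity = ident / columns
        if coverage >= _ANI_MIN_COVERAGE and identity >= _ANI_MIN_IDENTITY:
            identities.append(100.0 * identity)
    if not identities:
        return 0.0, 0.0
    ani_percent = float(np.mean(identities))
    coverage_percent = 100.0 * len(identities) / len(frags)
    return ani_percent, coverage_percent


def _best_fragment_alignment(
    frag: str, subject_seeds: list[SubjectSeeds], scoring: AlignScoring
):
    """Best (by score) seeded local alignment of a fragment on either strand."""
    from .seqio import revcomp
    from .align import _cluster_windows

    best_score = 0
    best = None
    for query in (frag, revcomp(frag)):
        for seeds in subject_seeds:
            windows = _cluster_windows(
                seeds.hits(query), len(query), len(seeds.subject), seeds.k
            )
            # largest seed clusters first; a couple suffice for the optimum
            windows.sort(key=lambda w: (w[1] - w[0]), reverse=True)
            for qlo, qhi, slo, shi in windows[:3]:
                score, qaligned, ident, columns = best_local_alignment(
                    query, seeds.subject[slo:shi], scoring
                )
                if score > best_score:
                    best_score = score
                    best = (qaligned, ident, columns)
    return best
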