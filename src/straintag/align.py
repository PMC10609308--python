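"""Local alignment scoring with blastn-style parameters.

Scores are maximal Smith-Waterman local-alignment scores with affine gaps
under a blastn-like scheme (match +2, mismatch -3, gap existence -5, per-base
gap extension -2; a gap of length L costs 5 + 2L).  Both strands of the query
are always considered.

Small problems are solved exactly with a full dynamic-programming matrix
(Biopython's C Gotoh implementation).  Against large subjects a seed-and-
extend strategy is used: exact shared words seed diagonal clusters, and the
exact aligner runs only inside windows around each cluster.  The reported
score equals the exact score whenever the optimal alignment contains at
least one exact seed word, which holds for every alignment clearing the
screening thresholds used in this package.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from functools import lru_cache

from Bio import Align

from .seqio import SequenceRecord, revcomp

__all__ = ["AlignScoring", "SubjectSeeds", "local_align_score", "best_local_alignment"]

# full-matrix alignment is used below this many DP cells
_EXACT_CELLS = 4_000_000

_SEED_K = 11
_DIAG_BAND = 25
_WINDOW_MARGIN = 60


@dataclass(frozen=True)
class AlignScoring:
    """Scoring scheme and screening thresholds for local alignment.

    ``gap_open`` is a gap-existence cost and ``gap_extend`` a per-base cost,
    so a gap of length L costs ``|gap_open| + L*|gap_extend|`` (the blastn
    convention).  ``low_threshold``/``high_threshold`` are the screening
    cut-offs applied to candidate regions (reject when any non-target scores
    >= low_threshold is false: regions must score < low_threshold on every
    non-target and >= high_threshold on the target), and ``min_region_len``
    the minimum reportable unique-region span.
    """

    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2
    low_threshold: int = 40
    high_threshold: int = 200
    min_region_len: int = 1000

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match score must be positive")
        if self.mismatch >= 0 or self.gap_open >= 0 or self.gap_extend >= 0:
            raise ValueError("mismatch and gap penalties must be negative")
        if self.low_threshold <= 0 or self.high_threshold <= 0:
            raise ValueError("screening thresholds must be positive")


@lru_cache(maxsize=8)
def _aligner(scoring: AlignScoring) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    # PairwiseAligner charges open_gap_score for the first gapped base,
    # so existence+per-base semantics need open = gap_open + gap_extend.
    aligner.open_gap_score = scoring.gap_open + scoring.gap_extend
    aligner.extend_gap_score = scoring.gap_extend
    return aligner


class SubjectSeeds:
    """Exact-word index of a subject sequence for seeded alignment.

    Built once per subject and reused across many queries (e.g. when several
    candidate regions are screened against the same non-target genome).
    """

    def __init__(self, subject: str, k: int = _SEED_K):
        self.subject = subject
        self.k = k
        index: dict[str, list[int]] = defaultdict(list)
        for i in range(len(subject) - k + 1):
            word = subject[i : i + k]
            if "N" not in word:
                index[word].append(i)
        self.index = dict(index)

    def hits(self, query: str) -> list[tuple[int, int]]:
        """(query_pos, subject_pos) for every shared exact word."""
        k = self.k
        out: list[tuple[int, int]] = []
        index = self.index
        for q in range(len(query) - k + 1):
            positions = index.get(query[q : q + k])
            if positions:
                out.extend((q, s) for s in positions)
        return out


def _cluster_windows(
    hits: list[tuple[int, int]], qlen: int, slen: int, k: int
) -> list[tuple[int, int, int, int]]:
    """Group seed hits into diagonal clusters and return alignment windows."""
    if not hits:
        return []
    hits = sorted(hits, key=lambda h: (h[0] - h[1], h[0]))
    windows = []
    cur = [hits[0]]
    for h in hits[1:]:
        if (h[0] - h[1]) - (cur[-1][0] - cur[-1][1]) <= _DIAG_BAND:
            cur.append(h)
        else:
            windows.append(cur)
            cur = [h]
    windows.append(cur)
    out = []
    for cluster in windows:
        qlo = min(q for q, _ in cluster)
        qhi = max(q for q, _ in cluster) + k
        slo = min(s for _, s in cluster)
        shi = max(s for _, s in cluster) + k
        # margin lets the local alignment extend past the outermost seeds
        m = _WINDOW_MARGIN + _DIAG_BAND
        out.append(
            (max(0, qlo - m), min(qlen, qhi + m), max(0, slo - m), min(slen, shi + m))
        )
    return out


def _seeded_score(
    query: str, seeds: SubjectSeeds, scoring: AlignScoring
) -> float:
    aligner = _aligner(scoring)
    best = 0.0
    for qlo, qhi, slo, shi in _cluster_windows(
        seeds.hits(query), len(query), len(seeds.subject), seeds.k
    ):
        score = aligner.score(query[qlo:qhi], seeds.subject[slo:shi])
        if score > best:
            best = score
    return best


def local_align_score(
    query: str,
    subject: str | SubjectSeeds,
    scoring: AlignScoring = AlignScoring(),
) -> int:
    """Best local alignment score of query (either strand) vs subject.

    ``subject`` may be a prebuilt :class:`SubjectSeeds` to amortise indexing
    across queries; a plain string is aligned exactly when small enough and
    seeded otherwise.
    """
    if isinstance(subject, SubjectSeeds):
        subj_str = subject.subject
    else:
        subj_str = subject
    if not query or not subj_str:
        raise ValueError("query and subject must be non-empty")
    exact = (
        not isinstance(subject, SubjectSeeds)
        and len(query) * len(subj_str) <= _EXACT_CELLS
    )
    best = 0.0
    if exact:
        aligner = _aligner(scoring)
        for q in (query, revcomp(query)):
            score = aligner.score(q, subj_str)
            if score > best:
                best = score
    else:
        seeds = subject if isinstance(subject, SubjectSeeds) else SubjectSeeds(subj_str)
        for q in (query, revcomp(query)):
            score = _seeded_score(q, seeds, scoring)
            if score > best:
                best = score
    return int(max(0.0, best))


def max_score_vs_records(
    query: str,
    records: list[SequenceRecord],
    scoring: AlignScoring = AlignScoring(),
    seed_cache: dict[str, SubjectSeeds] | None = None,
    stop_at: int | None = None,
) -> int:
    """Max local score of query against a set of sequences.

    ``seed_cache`` (keyed by record id) amortises subject indexing;
    ``stop_at`` short-circuits once the running max reaches that value.
    """
    best = 0
    for rec in records:
        if len(query) * len(rec.seq) <= _EXACT_CELLS:
            subject: str | SubjectSeeds = rec.seq
        elif seed_cache is not None:
            subject = seed_cache.setdefault(rec.id, SubjectSeeds(rec.seq))
        else:
            subject = SubjectSeeds(rec.seq)
        best = max(best, local_align_score(query, subject, scoring))
        if stop_at is not None and best >= stop_at:
            break
    return best


def best_local_alignment(
    query: str, subject: str, scoring: AlignScoring = AlignScoring()
):
    """One optimal local alignment of query vs subject (forward strands).

    Returns ``(score, aligned_query_bases, identities, alignment_columns)``;
    all zeros when no positive-scoring alignment exists.
    """
    aligner = _aligner(scoring)
    alignments = aligner.align(query, subject)
    try:
        aln = alignments[0]
    except IndexError:
        return 0, 0, 0, 0
    counts = aln.counts()
    qblocks = aln.aligned[0]
    qaligned = int(sum(e - s for s, e in qblocks))
    columns = counts.identities + counts.mismatches + counts.gaps
    return int(aln.score), qaligned, int(counts.identities), int(columns)
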