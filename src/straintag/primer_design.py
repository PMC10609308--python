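"""Primer pair enumeration, binding-site scanning and in-silico PCR.

Candidate primer pairs are enumerated inside strain-unique regions under
hard constraints (primer size 20-25 with optimum 22, GC 45-55%, pair Tm
difference <= 1 deg C, product size window, self/cross dimer dG floor) and
returned deterministically ranked.  Specificity is assessed without a
thermodynamic mispriming model, by mismatch counting: a genome site can
misprime a primer only when it has fewer than 6 total mismatches AND fewer
than 5 mismatches within the primer's five 3'-terminal bases; sites with 9
or more total mismatches are ignored outright.  In-silico PCR combines
mispriming-capable sites of the two primers on opposite strands, 3' ends
facing, within a product-size ceiling.
"""

from __future__ import annotations

import bisect
import warnings
from dataclasses import dataclass, field

import numpy as np

from .seqio import SequenceRecord, revcomp
from .thermo import ThermoConditions, dimer_dg, tm_nn
from .uniqueness import CandidateRegion, encode_sequence

__all__ = [
    "DesignConstraints",
    "SpecificityRules",
    "PrimerPair",
    "BindingSite",
    "Amplicon",
    "SpecificityVerdict",
    "enumerate_candidates",
    "find_binding_sites",
    "is_unintended_binder",
    "insilico_pcr",
    "specificity_verdict",
]


@dataclass(frozen=True)
class DesignConstraints:
    size_min: int = 20
    size_opt: int = 22
    size_max: int = 25
    gc_min: float = 45.0
    gc_max: float = 55.0
    max_tm_diff: float = 1.0
    product_min: int = 100
    product_max: int = 500
    # worst acceptable self/cross dimer stability; -9 kcal/mol is the common
    # screening cutoff for overall dimer dG (note that several published,
    # experimentally clean primer sets sit between -5 and -7.5)
    dimer_dg_floor: float = -9.0

    def __post_init__(self) -> None:
        if not self.size_min <= self.size_opt <= self.size_max:
            raise ValueError("need size_min <= size_opt <= size_max")
        if self.gc_min >= self.gc_max:
            raise ValueError("need gc_min < gc_max")
        if self.product_min >= self.product_max:
            raise ValueError("need product_min < product_max")


@dataclass(frozen=True)
class SpecificityRules:
    """Mismatch-counting mispriming stringency.

    A site can misprime iff total mismatches < ``min_total_mismatch`` and
    3'-terminal (last 5 bases) mismatches < ``min_3prime_mismatch``; sites
    with >= ``ignore_above`` total mismatches are never reported.
    """

    min_total_mismatch: int = 6
    min_3prime_mismatch: int = 5
    ignore_above: int = 9
    max_amplicon: int = 4000

    def __post_init__(self) -> None:
        if self.min_3prime_mismatch > 5:
            raise ValueError("min_3prime_mismatch counts within the last 5 bases")
        if self.ignore_above <= self.min_total_mismatch:
            raise ValueError("ignore_above must exceed min_total_mismatch")


@dataclass
class PrimerPair:
    """A forward/reverse oligo pair on a template region.

    ``rev`` is given 5'->3' on the opposite strand; ``fwd_start``/``rev_end``
    are 0-based template coordinates of the amplified interval, so
    ``product_len == rev_end - fwd_start`` (outer-edge-inclusive).
    """

    fwd: str
    rev: str
    region_id: str
    fwd_start: int
    rev_end: int
    product_len: int
    tm_fwd: float
    tm_rev: float
    gc_fwd: float
    gc_rev: float
    name: str = ""


@dataclass(frozen=True)
class BindingSite:
    contig_id: str
    start: int  # 0-based forward-strand start of the primer-length window
    strand: str  # '+' or '-'
    total_mismatches: int
    last5_mismatches: int


@dataclass(frozen=True)
class Amplicon:
    contig_id: str
    start: int
    end: int
    length: int
    fwd_site: BindingSite
    rev_site: BindingSite


@dataclass
class SpecificityVerdict:
    passed: bool
    target_amplicons: list[Amplicon] = field(default_factory=list)
    offtarget_amplicons: list[tuple[str, Amplicon]] = field(default_factory=list)


def _gc_fraction_ok(window: str, constraints: DesignConstraints) -> float | None:
    gc = window.count("G") + window.count("C")
    pct = 100.0 * gc / len(window)
    if constraints.gc_min <= pct <= constraints.gc_max:
        return int(pct * 100 + 0.5) / 100.0
    return None


def _windows(
    region_seq: str, constraints: DesignConstraints, cond: ThermoConditions
):
    """All constraint-satisfying primer windows of the region.

    Returns (forward, reverse) lists; each entry is
    (coord, size, primer_seq, tm, gc, self_dg) where coord is fwd_start for
    forward windows and rev_end for reverse windows.
    """
    fwd, rev = [], []
    n = len(region_seq)
    tm_cache: dict[str, float] = {}
    for size in range(constraints.size_min, constraints.size_max + 1):
        for start in range(0, n - size + 1):
            window = region_seq[start : start + size]
            if "N" in window:
                continue
            gc = _gc_fraction_ok(window, constraints)
            if gc is None:
                continue
            tm = tm_cache.get(window)
            if tm is None:
                tm = tm_nn(window, cond)
                tm_cache[window] = tm
            self_f = dimer_dg(window, window, cond=cond)
            if self_f >= constraints.dimer_dg_floor:
                fwd.append((start, size, window, tm, gc, self_f))
            rprimer = revcomp(window)
            self_r = dimer_dg(rprimer, rprimer, cond=cond)
            if self_r >= constraints.dimer_dg_floor:
                # Tm and GC are duplex properties, identical for revcomp
                rev.append((start + size, size, rprimer, tm, gc, self_r))
    fwd.sort(key=lambda w: (w[0], w[1]))
    rev.sort(key=lambda w: (w[0], w[1]))
    return fwd, rev


def enumerate_candidates(
    region: CandidateRegion,
    constraints: DesignConstraints = DesignConstraints(),
    cond: ThermoConditions = ThermoConditions(),
    max_candidates: int | None = None,
) -> list[PrimerPair]:
    """Deterministically ranked primer pairs satisfying every constraint.

    Ranking: closeness of both primer sizes to ``size_opt``, then pair Tm
    difference, then leftmost forward start, then shortest product.  With
    ``max_candidates`` set, the top of the ranked list is returned (cross-
    dimer screening is evaluated lazily in rank order).
    """
    if len(region.seq) < constraints.product_min:
        warnings.warn(
            f"region {region.region_id} shorter than product_min; no candidates",
            stacklevel=2,
        )
        return []
    fwd_windows, rev_windows = _windows(region.seq, constraints, cond)
    rev_coords = [w[0] for w in rev_windows]
    provisional = []
    for fstart, fsize, fseq, ftm, fgc, _ in fwd_windows:
        lo = bisect.bisect_left(rev_coords, fstart + constraints.product_min)
        hi = bisect.bisect_right(rev_coords, fstart + constraints.product_max)
        for rend, rsize, rseq, rtm, rgc, _ in rev_windows[lo:hi]:
            if rend - rsize < fstart + fsize:  # primers must not overlap
                continue
            tm_diff = abs(ftm - rtm)
            if tm_diff > constraints.max_tm_diff:
                continue
            product = rend - fstart
            rank = (
                abs(fsize - constraints.size_opt) + abs(rsize - constraints.size_opt),
                tm_diff,
                fstart,
                product,
                rend,
            )
            provisional.append(
                (rank, fstart, rend, fseq, rseq, ftm, rtm, fgc, rgc, product)
            )
    provisional.sort(key=lambda p: p[0])
    pairs: list[PrimerPair] = []
    for _, fstart, rend, fseq, rseq, ftm, rtm, fgc, rgc, product in provisional:
        if dimer_dg(fseq, rseq, cond=cond) < constraints.dimer_dg_floor:
            continue
        pairs.append(
            PrimerPair(
                fwd=fseq,
                rev=rseq,
                region_id=region.region_id,
                fwd_start=fstart,
                rev_end=rend,
                product_len=product,
                tm_fwd=ftm,
                tm_rev=rtm,
                gc_fwd=fgc,
                gc_rev=rgc,
            )
        )
        if max_candidates is not None and len(pairs) >= max_candidates:
            break
    return pairs


def _mismatch_profile(genome_codes: np.ndarray, primer_codes: np.ndarray):
    """Per-window mismatch counts: (total, first 5 positions, last 5)."""
    m = len(primer_codes)
    n = len(genome_codes) - m + 1
    if n <= 0:
        return None
    windows = np.lib.stride_tricks.sliding_window_view(genome_codes, m)
    neq = windows != primer_codes
    total = neq.sum(axis=1)
    first5 = neq[:, :5].sum(axis=1)
    last5 = neq[:, m - 5 :].sum(axis=1)
    return total, first5, last5


def find_binding_sites(
    primer: str,
    genomes: list[SequenceRecord],
    rules: SpecificityRules = SpecificityRules(),
) -> list[BindingSite]:
    """All candidate binding sites of a primer on either strand.

    On '+', the primer anneals to the minus strand and extends rightward
    from ``start``; its 3' end sits at ``start + len - 1``.  On '-', the
    primer anneals to the plus strand, extends leftward, and its 3' end sits
    at ``start``.  Sites with >= ``ignore_above`` total mismatches are not
    reported.  Bases outside {A,C,G,T} mismatch everything.
    """
    sites: list[BindingSite] = []
    p_plus = encode_sequence(primer)
    p_minus = encode_sequence(revcomp(primer))
    for rec in genomes:
        g = encode_sequence(rec.seq)
        prof = _mismatch_profile(g, p_plus)
        if prof is not None:
            total, _, last5 = prof
            for pos in np.flatnonzero(total < rules.ignore_above):
                sites.append(
                    BindingSite(rec.id, int(pos), "+", int(total[pos]), int(last5[pos]))
                )
        prof = _mismatch_profile(g, p_minus)
        if prof is not None:
            # minus strand: the primer's 3'-terminal bases map to the first
            # 5 genome positions of the window
            total, first5, _ = prof
            for pos in np.flatnonzero(total < rules.ignore_above):
                sites.append(
                    BindingSite(rec.id, int(pos), "-", int(total[pos]), int(first5[pos]))
                )
    sites.sort(key=lambda s: (s.contig_id, s.start, s.strand))
    return sites


def is_unintended_binder(site: BindingSite, rules: SpecificityRules = SpecificityRules()) -> bool:
    """True when the site can actually prime (i.e. would misprime if off-target)."""
    return (
        site.total_mismatches < rules.min_total_mismatch
        and site.last5_mismatches < rules.min_3prime_mismatch
    )


def insilico_pcr(
    pair: PrimerPair,
    genomes: list[SequenceRecord],
    rules: SpecificityRules = SpecificityRules(),
) -> list[Amplicon]:
    """Predicted amplicons of a primer pair on a genome.

    Considers both orientations (fwd on '+' with rev on '-', and vice
    versa); both sites must be priming-capable, on the same contig, 3' ends
    facing inward, and the outer-edge product length must not exceed
    ``rules.max_amplicon``.
    """
    lengths = {pair.fwd: len(pair.fwd), pair.rev: len(pair.rev)}
    sites = {
        primer: [
            s
            for s in find_binding_sites(primer, genomes, rules)
            if is_unintended_binder(s, rules)
        ]
        for primer in (pair.fwd, pair.rev)
    }
    amplicons: list[Amplicon] = []
    for left_primer, right_primer in (
        (pair.fwd, pair.rev),
        (pair.rev, pair.fwd),
    ):
        plus = [s for s in sites[left_primer] if s.strand == "+"]
        minus = [s for s in sites[right_primer] if s.strand == "-"]
        for ps in plus:
            for ms in minus:
                if ps.contig_id != ms.contig_id:
                    continue
                start = ps.start
                end = ms.start + lengths[right_primer]
                length = end - start
                # 3' ends must face inward and leave a positive product
                if ms.start < ps.start + lengths[left_primer]:
                    continue
                if length > rules.max_amplicon:
                    continue
                amplicons.append(
                    Amplicon(ps.contig_id, start, end, length, ps, ms)
                )
    amplicons.sort(key=lambda a: (a.contig_id, a.start, a.end))
    return amplicons


def specificity_verdict(
    pair: PrimerPair,
    target: list[SequenceRecord],
    nontargets: list[SequenceRecord],
    rules: SpecificityRules = SpecificityRules(),
) -> SpecificityVerdict:
    """PASS iff the pair makes exactly its intended product on the target
    and no product on any non-target genome."""
    on_target = insilico_pcr(pair, target, rules)
    off = []
    for rec in nontargets:
        for amp in insilico_pcr(pair, [rec], rules):
            off.append((rec.id, amp))
    ok = (
        len(on_target) == 1
        and on_target[0].length == pair.product_len
        and not off
    )
    return SpecificityVerdict(ok, on_target, off)
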