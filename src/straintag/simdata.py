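"""Synthetic genomes with known ground truth for every pipeline stage.

The generator emulates the data regime the method is built for: a clonal
"backbone" chromosome shared by a family of same-species sibling strains at
~99.9% identity (i.i.d. substitutions, no indels), a target strain that
additionally carries a small number of strain-unique islands (random
sequence guaranteed to share no canonical k-mer with any background
genome), independent non-target genomes standing in for co-habiting
species/starter cultures, and mixed "community" lanes for end-to-end
detection tests.  Every genome also carries one conserved control cassette
(a 16S-rDNA stand-in) so a universal control primer pair amplifies in every
lane.

All outputs are byte-reproducible from the scenario seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .primer_design import PrimerPair
from .seqio import SequenceRecord, revcomp, write_fasta
from .thermo import dimer_dg, tm_nn
from .uniqueness import KmerIndex, build_kmer_index, canonical_kmer_values

__all__ = [
    "SimScenario",
    "GroundTruth",
    "ScenarioBundle",
    "simulate_backbone",
    "mutate_genome",
    "implant_islands",
    "make_scenario",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimScenario:
    """Parameters of one synthetic study. The defaults describe the regime
    the pipeline targets: a ~100 kb backbone (a bacterial chromosome scaled
    to desk size), three siblings at 0.1% divergence (ANI ~= 99.9%), two
    1.5 kb unique islands and two non-target genomes."""

    seed: int = 0
    backbone_len: int = 100_000
    gc: float = 0.45
    n_siblings: int = 3
    sibling_mut_rate: float = 0.001
    islands: tuple[tuple[int, int], ...] = ((1500, 2),)
    n_nontargets: int = 2
    nontarget_len: int = 100_000
    k: int = 21
    cassette_len: int = 800

    def island_lengths(self) -> list[int]:
        out = []
        for length, count in self.islands:
            out.extend([length] * count)
        return out


@dataclass
class GroundTruth:
    """What the generator knows and the pipeline must recover."""

    islands: list[tuple[str, int, int]] = field(default_factory=list)
    lanes: dict[str, bool] = field(default_factory=dict)  # lane -> contains target
    control_product_len: int | None = None
    sibling_mut_rate: float = 0.0


@dataclass
class ScenarioBundle:
    scenario: SimScenario
    target: list[SequenceRecord]
    siblings: list[SequenceRecord]
    nontargets: list[SequenceRecord]
    communities: dict[str, list[SequenceRecord]]
    control: PrimerPair
    truth: GroundTruth

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.target, outdir / "target.fasta")
        for rec in self.siblings:
            write_fasta([rec], outdir / f"{rec.id}.fasta")
        for rec in self.nontargets:
            write_fasta([rec], outdir / f"{rec.id}.fasta")
        for lane, records in self.communities.items():
            write_fasta(records, outdir / f"community.{lane}.fasta")
        truth = {
            "islands": [list(i) for i in self.truth.islands],
            "lanes": self.truth.lanes,
            "control_product_len": self.truth.control_product_len,
            "sibling_mut_rate": self.truth.sibling_mut_rate,
            "control": {"fwd": self.control.fwd, "rev": self.control.rev},
        }
        (outdir / "ground_truth.json").write_text(json.dumps(truth, indent=2))
        with open(outdir / "lanes.tsv", "w") as fh:
            fh.write("lane\tcontains_target\tn_genomes\n")
            for lane, records in self.communities.items():
                fh.write(f"{lane}\t{self.truth.lanes[lane]}\t{len(records)}\n")


def _random_dna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    codes = rng.choice(4, size=length, p=probs)
    return _BASES[codes].tobytes().decode("ascii")


def simulate_backbone(length: int, gc: float, seed) -> SequenceRecord:
    """An i.i.d. random chromosome with the requested GC fraction."""
    if length < 10_000:
        raise ValueError("backbone length must be >= 10 kb")
    if not 0.2 <= gc <= 0.8:
        raise ValueError("gc must be within [0.2, 0.8]")
    rng = np.random.default_rng(seed)
    return SequenceRecord("backbone", _random_dna(rng, length, gc))


def mutate_genome(genome: SequenceRecord, rate: float, seed) -> SequenceRecord:
    """i.i.d. substitutions (to a uniformly random different base), no indels."""
    if not 0 <= rate <= 0.05:
        raise ValueError("substitution rate must be within [0, 0.05]")
    rng = np.random.default_rng(seed)
    codes = np.frombuffer(genome.seq.encode("ascii"), dtype=np.uint8).copy()
    is_base = np.isin(codes, _BASES)
    hit = (rng.random(len(codes)) < rate) & is_base
    idx = np.flatnonzero(hit)
    if len(idx):
        lookup = np.full(256, 0, dtype=np.uint8)
        for i, b in enumerate(_BASES):
            lookup[b] = i
        old = lookup[codes[idx]]
        new = (old + rng.integers(1, 4, size=len(idx))) % 4
        codes[idx] = _BASES[new]
    return SequenceRecord(genome.id, codes.tobytes().decode("ascii"), genome.description)


def _kmer_set(seq: str, k: int) -> np.ndarray:
    values, valid = canonical_kmer_values(seq, k)
    return np.unique(values[valid])


def _disjoint(values: np.ndarray, pool: np.ndarray) -> bool:
    if len(pool) == 0:
        return True
    pos = np.searchsorted(pool, values)
    pos = np.minimum(pos, len(pool) - 1)
    return not np.any(pool[pos] == values)


def implant_islands(
    genome: SequenceRecord,
    spec: list[tuple[int, int]],
    background: KmerIndex,
    seed,
    max_tries: int = 50,
    exclude: list[tuple[int, int]] | None = None,
) -> tuple[SequenceRecord, GroundTruth]:
    """Insert random islands sharing no canonical k-mer with the background.

    Each island is rejection-sampled until its k-mers are absent from the
    background index, from the host genome, and from islands already
    accepted.  Islands are inserted at random points separated by at least
    2k bases and outside any ``exclude`` interval (host coordinates);
    ground-truth coordinates refer to the returned genome.
    """
    k = background.k
    rng = np.random.default_rng(seed)
    lengths = []
    for length, count in spec:
        lengths.extend([length] * count)
    host_kmers = _kmer_set(genome.seq, k)
    accepted_kmers = np.empty(0, dtype=np.uint64)
    islands: list[str] = []
    for length in lengths:
        for attempt in range(max_tries):
            seq = _random_dna(rng, length)
            values = _kmer_set(seq, k)
            if (
                _disjoint(values, background.members)
                and _disjoint(values, host_kmers)
                and _disjoint(values, accepted_kmers)
            ):
                islands.append(seq)
                accepted_kmers = np.union1d(accepted_kmers, values)
                break
        else:
            raise RuntimeError(
                "island rejection sampling exhausted: use a longer backbone "
                "or smaller/fewer islands"
            )
    # insertion points, pairwise separated by >= 2k and outside exclusions
    n = len(genome.seq)
    forbidden = exclude or []
    for attempt in range(100):
        points = np.sort(rng.integers(k, n - k, size=len(islands)))
        if len(points) >= 2 and not np.all(np.diff(points) >= 2 * k):
            continue
        if any(lo - k < p < hi + k for p in points.tolist() for lo, hi in forbidden):
            continue
        break
    else:
        raise RuntimeError("could not place islands with the required separation")
    pieces = []
    truth = GroundTruth()
    prev = 0
    offset = 0
    for point, island in zip(points.tolist(), islands):
        pieces.append(genome.seq[prev:point])
        start = point + offset
        truth.islands.append((genome.id, start, start + len(island)))
        pieces.append(island)
        offset += len(island)
        prev = point
    pieces.append(genome.seq[prev:])
    return SequenceRecord(genome.id, "".join(pieces), genome.description), truth


def _insert(seq: str, cassette: str, pos: int) -> str:
    return seq[:pos] + cassette + seq[pos:]


def _pick_control_pair(cassette: str, rng: np.random.Generator) -> PrimerPair:
    """A well-behaved universal primer pair on the conserved cassette.

    Scans candidate 22-mer windows near the cassette ends for a pair with
    moderate GC and no self/cross dimer below -5 kcal/mol; the product spans
    most of the cassette (well above typical strain-band sizes, so the
    control band never co-migrates with a fingerprint band).
    """
    size = 22
    n = len(cassette)
    for fstart in range(0, 60):
        fwd = cassette[fstart : fstart + size]
        if not 40 <= 100 * (fwd.count("G") + fwd.count("C")) / size <= 60:
            continue
        if dimer_dg(fwd, fwd) < -5.0:
            continue
        for rend in range(n, n - 60, -1):
            rev = revcomp(cassette[rend - size : rend])
            if not 40 <= 100 * (rev.count("G") + rev.count("C")) / size <= 60:
                continue
            if dimer_dg(rev, rev) < -5.0 or dimer_dg(fwd, rev) < -5.0:
                continue
            return PrimerPair(
                fwd=fwd,
                rev=rev,
                region_id="control_cassette",
                fwd_start=fstart,
                rev_end=rend,
                product_len=rend - fstart,
                tm_fwd=tm_nn(fwd),
                tm_rev=tm_nn(rev),
                gc_fwd=round(100 * (fwd.count("G") + fwd.count("C")) / size, 2),
                gc_rev=round(100 * (rev.count("G") + rev.count("C")) / size, 2),
                name="P1/P2",
            )
    raise RuntimeError("no acceptable control pair found on the cassette")


def make_scenario(scenario: SimScenario = SimScenario()) -> ScenarioBundle:
    """Generate a full study: target, siblings, non-targets, communities.

    The target genome is the shared backbone plus the control cassette plus
    the unique islands; siblings are the cassette-bearing backbone mutated
    at ``sibling_mut_rate`` (no islands); non-targets are independent random
    genomes with the cassette.  Community lanes mix genomes the way a
    fermented-food sample would (target or a sibling, plus the non-targets
    as starter-culture stand-ins).
    """
    root = np.random.SeedSequence(scenario.seed)
    (
        s_backbone,
        s_cassette,
        s_islands,
        s_siblings,
        s_nontargets,
    ) = root.spawn(5)
    backbone = simulate_backbone(scenario.backbone_len, scenario.gc, s_backbone)
    cassette_rng = np.random.default_rng(s_cassette)
    cassette = _random_dna(cassette_rng, scenario.cassette_len)
    control = _pick_control_pair(cassette, cassette_rng)

    cassette_pos = len(backbone.seq) // 3
    host = SequenceRecord("target", _insert(backbone.seq, cassette, cassette_pos))
    siblings = []
    for i, child in enumerate(s_siblings.spawn(scenario.n_siblings), start=1):
        mutated = mutate_genome(host, scenario.sibling_mut_rate, child)
        siblings.append(SequenceRecord(f"sibling_{i}", mutated.seq))
    nontargets = []
    for i, child in enumerate(s_nontargets.spawn(scenario.n_nontargets), start=1):
        rng = np.random.default_rng(child)
        seq = _random_dna(rng, scenario.nontarget_len, scenario.gc)
        seq = _insert(seq, cassette, len(seq) // 4)
        nontargets.append(SequenceRecord(f"nontarget_{i}", seq))

    rejection_pool = siblings + nontargets + [host]
    index = build_kmer_index(rejection_pool, scenario.k)
    target, truth = implant_islands(
        host,
        list(scenario.islands),
        index,
        s_islands,
        exclude=[(cassette_pos, cassette_pos + len(cassette))],
    )

    communities = {
        "target_mono": [target],
        "sibling_mono": [siblings[0]] if siblings else [],
        "yogurt_target": [target] + nontargets,
        "yogurt_no_target": ([siblings[0]] if siblings else []) + nontargets,
        "starters_only": list(nontargets),
    }
    communities = {k: v for k, v in communities.items() if v}
    truth.lanes = {lane: any(r.id == "target" for r in recs) for lane, recs in communities.items()}
    truth.control_product_len = control.product_len
    truth.sibling_mut_rate = scenario.sibling_mut_rate
    return ScenarioBundle(
        scenario=scenario,
        target=[target],
        siblings=siblings,
        nontargets=nontargets,
        communities=communities,
        control=control,
        truth=truth,
    )
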