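"""Multiplex panel assembly and electrophoretic fingerprint prediction.

A panel combines several strain-specific primer pairs (one per unique
region) with a universal control pair (e.g. 16S rDNA) in a single reaction.
The panel's expected band sizes must be mutually separable on a gel (both
an absolute and a relative size-difference rule) and every primer in the
reaction must be free of stable cross-dimers with every other primer.

Fingerprints list the band sizes the strain-specific pairs produce on a
genome, in gel order (largest first); the control band is tracked as a
separate reaction-validity flag, not as a fingerprint band.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from enum import Enum

from .primer_design import PrimerPair, SpecificityRules, insilico_pcr
from .seqio import SequenceRecord
from .thermo import ThermoConditions, dimer_dg

__all__ = [
    "SeparabilityRule",
    "PanelDesign",
    "GelFingerprint",
    "MatchVerdict",
    "PanelInfeasibleError",
    "band_separable",
    "select_panel",
    "predict_fingerprint",
    "fingerprint_match",
]


@dataclass(frozen=True)
class SeparabilityRule:
    """Minimum band-size spacing resolvable on a standard agarose gel."""

    min_abs_diff: int = 30
    min_rel_diff: float = 0.10

    def __post_init__(self) -> None:
        if self.min_abs_diff <= 0 or not 0 < self.min_rel_diff < 1:
            raise ValueError("invalid separability rule")


@dataclass
class PanelDesign:
    strain_id: str
    pairs: list[PrimerPair]
    control: PrimerPair
    expected_bands: list[int]  # descending, gel order
    control_band: int | None = None

    def all_primers(self) -> list[str]:
        primers = []
        for p in self.pairs + [self.control]:
            primers.extend([p.fwd, p.rev])
        return primers

    def to_json(self) -> str:
        payload = {
            "strain_id": self.strain_id,
            "expected_bands": self.expected_bands,
            "control_band": self.control_band,
            "control": {"fwd": self.control.fwd, "rev": self.control.rev},
            "pairs": [
                {
                    "name": p.name,
                    "region_id": p.region_id,
                    "fwd": p.fwd,
                    "rev": p.rev,
                    "product_len": p.product_len,
                    "tm_fwd": p.tm_fwd,
                    "tm_rev": p.tm_rev,
                    "gc_fwd": p.gc_fwd,
                    "gc_rev": p.gc_rev,
                }
                for p in self.pairs
            ],
        }
        return json.dumps(payload, indent=2)


@dataclass
class GelFingerprint:
    genome_id: str
    bands: list[int]  # descending
    has_control: bool


class MatchVerdict(str, Enum):
    DETECTED = "DETECTED"
    NOT_DETECTED = "NOT_DETECTED"
    INVALID_RUN = "INVALID_RUN"


class PanelInfeasibleError(RuntimeError):
    pass


def band_separable(sizes: list[int], rule: SeparabilityRule = SeparabilityRule()) -> bool:
    """True iff every band pair differs by >= min_abs_diff bases and by
    >= min_rel_diff of the larger band."""
    if not sizes:
        raise ValueError("at least one band size is required")
    ordered = sorted(sizes)
    for a, b in itertools.combinations(ordered, 2):
        if b - a < rule.min_abs_diff or (b - a) / b < rule.min_rel_diff:
            return False
    return True


def _cross_dimer_ok(
    primers: list[str], dg_floor: float, cond: ThermoConditions
) -> tuple[bool, float]:
    worst = 0.0
    for a, b in itertools.combinations(primers, 2):
        dg = dimer_dg(a, b, cond=cond)
        worst = min(worst, dg)
        if dg < dg_floor:
            return False, worst
    return True, worst


def select_panel(
    candidates: dict[str, list[PrimerPair]],
    n_sets: int = 3,
    control: PrimerPair | None = None,
    rule: SeparabilityRule = SeparabilityRule(),
    dg_floor: float = -9.0,
    cond: ThermoConditions = ThermoConditions(),
    strain_id: str = "target",
    control_band: int | None = None,
) -> PanelDesign:
    """First feasible combination of one pair per region, plus the control.

    Regions are visited in sorted-id order and pairs in their given (ranked)
    order, so identical inputs always produce the identical panel.  The
    control band participates in the separability test only when its product
    size is known (``control_band``); the control primers always participate
    in the cross-dimer audit.  Raises :class:`PanelInfeasibleError`, naming
    the most restrictive constraint, when nothing works.
    """
    region_ids = sorted(rid for rid, plist in candidates.items() if plist)
    if len(region_ids) < n_sets:
        raise PanelInfeasibleError(
            f"need candidate pairs from >= {n_sets} distinct regions, "
            f"have {len(region_ids)}"
        )
    if control is None:
        raise ValueError("a universal control pair is required")
    rejected = {"band separability": 0, "cross-primer dimer": 0}
    for combo_ids in itertools.combinations(region_ids, n_sets):
        for combo in itertools.product(*(candidates[r] for r in combo_ids)):
            bands = [p.product_len for p in combo]
            audit_bands = bands + ([control_band] if control_band else [])
            if not band_separable(audit_bands, rule):
                rejected["band separability"] += 1
                continue
            primers = [s for p in combo for s in (p.fwd, p.rev)]
            primers += [control.fwd, control.rev]
            ok, _ = _cross_dimer_ok(primers, dg_floor, cond)
            if not ok:
                rejected["cross-primer dimer"] += 1
                continue
            return PanelDesign(
                strain_id=strain_id,
                pairs=list(combo),
                control=control,
                expected_bands=sorted(bands, reverse=True),
                control_band=control_band,
            )
    worst = max(rejected, key=lambda k: rejected[k])
    raise PanelInfeasibleError(
        "no feasible panel: "
        + ", ".join(f"{k} rejected {v} combinations" for k, v in rejected.items())
        + f"; most restrictive: {worst}"
    )


def predict_fingerprint(
    panel: PanelDesign,
    genome: list[SequenceRecord],
    rules: SpecificityRules = SpecificityRules(),
) -> GelFingerprint:
    """Predicted banding pattern of the panel on a genome.

    Bands are the distinct product sizes of the strain-specific pairs
    (co-migrating equal sizes collapse to one band), largest first;
    ``has_control`` records whether the universal control amplifies.
    """
    bands: set[int] = set()
    for pair in panel.pairs:
        for amp in insilico_pcr(pair, genome, rules):
            bands.add(amp.length)
    control_amps = insilico_pcr(panel.control, genome, rules)
    genome_id = genome[0].id if genome else ""
    return GelFingerprint(
        genome_id=genome_id,
        bands=sorted(bands, reverse=True),
        has_control=len(control_amps) > 0,
    )


def fingerprint_match(
    observed: GelFingerprint,
    panel: PanelDesign,
    tolerance: SeparabilityRule = SeparabilityRule(),
) -> MatchVerdict:
    """Call a lane: target DETECTED, NOT_DETECTED, or INVALID_RUN.

    A lane without the control band is an invalid reaction.  The target is
    detected when every expected band is observed within ``min_abs_diff``
    bases and no unexplained extra band appears.
    """
    if not observed.has_control:
        return MatchVerdict.INVALID_RUN
    remaining = list(observed.bands)
    for expected in panel.expected_bands:
        hit = next(
            (b for b in remaining if abs(b - expected) < tolerance.min_abs_diff),
            None,
        )
        if hit is None:
            return MatchVerdict.NOT_DETECTED
        remaining.remove(hit)
    if remaining:
        return MatchVerdict.NOT_DETECTED  # unexplained extra bands
    return MatchVerdict.DETECTED
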