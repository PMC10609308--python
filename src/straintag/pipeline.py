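"""End-to-end orchestration of the marker-discovery / panel-design stages.

These helpers wire the stage modules together the way the command-line
interface and the examples use them: subtract backgrounds to get candidate
regions, screen them for cross-specificity, enumerate primer pairs per
region, assemble a multiplex panel, and call detection verdicts on lanes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .align import AlignScoring
from .multiplex import (
    GelFingerprint,
    MatchVerdict,
    PanelDesign,
    SeparabilityRule,
    fingerprint_match,
    predict_fingerprint,
    select_panel,
)
from .primer_design import (
    DesignConstraints,
    PrimerPair,
    SpecificityRules,
    enumerate_candidates,
)
from .seqio import SequenceRecord
from .simdata import ScenarioBundle
from .thermo import ThermoConditions
from .uniqueness import (
    CandidateRegion,
    KmerIndex,
    build_kmer_index,
    find_unique_regions,
    specificity_filter,
)

__all__ = ["discover_regions", "design_primers", "run_scenario", "ScenarioResult"]


def discover_regions(
    target: list[SequenceRecord],
    backgrounds: list[SequenceRecord],
    nontargets: list[SequenceRecord],
    k: int = 21,
    min_len: int = 1000,
    merge_gap: int = 100,
    scoring: AlignScoring = AlignScoring(),
) -> list[CandidateRegion]:
    """Unique-region discovery plus cross-specificity screening."""
    if backgrounds:
        index = build_kmer_index(backgrounds, k)
    else:
        warnings.warn(
            "no background genomes: every position is trivially unique",
            stacklevel=2,
        )
        index = KmerIndex(k=k, members=np.empty(0, dtype=np.uint64))
    regions = find_unique_regions(target, index, min_len=min_len, merge_gap=merge_gap)
    return specificity_filter(regions, target, nontargets, scoring)


def design_primers(
    regions: list[CandidateRegion],
    constraints: DesignConstraints = DesignConstraints(),
    cond: ThermoConditions = ThermoConditions(),
    max_candidates: int | None = 25,
) -> dict[str, list[PrimerPair]]:
    """Ranked candidate pairs per region, keyed by region id."""
    out = {}
    for region in regions:
        pairs = enumerate_candidates(region, constraints, cond, max_candidates)
        for i, pair in enumerate(pairs, start=1):
            pair.name = f"{region.region_id}#{i}"
        if pairs:
            out[region.region_id] = pairs
    return out


@dataclass
class ScenarioResult:
    """Pipeline outcome on one synthetic study.

    ``raw_regions`` are the subtraction-stage unique regions (where island
    recovery is guaranteed by construction); ``regions`` are the subset
    surviving the cross-specificity screen, which may legitimately retire a
    marker that shows chance homology to a non-target genome.
    """

    raw_regions: list[CandidateRegion]
    regions: list[CandidateRegion]
    panel: PanelDesign
    fingerprints: dict[str, GelFingerprint] = field(default_factory=dict)
    verdicts: dict[str, MatchVerdict] = field(default_factory=dict)


def run_scenario(
    bundle: ScenarioBundle,
    n_sets: int | None = None,
    constraints: DesignConstraints = DesignConstraints(),
    rules: SpecificityRules = SpecificityRules(),
    rule: SeparabilityRule = SeparabilityRule(),
    scoring: AlignScoring = AlignScoring(),
    cond: ThermoConditions = ThermoConditions(),
    max_candidates: int | None = 25,
) -> ScenarioResult:
    """Full pipeline on a synthetic scenario, with lane verdicts.

    ``n_sets`` defaults to the number of regions that survive screening,
    capped at 3 (the tetraplex layout: three strain-specific pairs plus the
    control); a real design would likewise use however many clean markers
    the genome offers.
    """
    index = build_kmer_index(bundle.siblings, bundle.scenario.k)
    raw_regions = find_unique_regions(bundle.target, index)
    regions = specificity_filter(raw_regions, bundle.target, bundle.nontargets, scoring)
    candidates = design_primers(regions, constraints, cond, max_candidates)
    if n_sets is None:
        n_sets = min(3, len(candidates))
    panel = select_panel(
        candidates,
        n_sets=n_sets,
        control=bundle.control,
        rule=rule,
        dg_floor=constraints.dimer_dg_floor,
        cond=cond,
        strain_id=bundle.target[0].id,
        control_band=bundle.control.product_len,
    )
    result = ScenarioResult(raw_regions=raw_regions, regions=regions, panel=panel)
    for lane, records in bundle.communities.items():
        fp = predict_fingerprint(panel, records, rules)
        fp.genome_id = lane
        result.fingerprints[lane] = fp
        result.verdicts[lane] = fingerprint_match(fp, panel, rule)
    return result
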