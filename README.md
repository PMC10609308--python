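# straintag

Whole-genome design of strain-specific multiplex PCR fingerprint assays.

Closely related bacterial strains — e.g. probiotic *Lactiplantibacillus*
isolates inside a fermented-food matrix — can share >99.9% average
nucleotide identity, so species-level markers (16S, housekeeping genes)
cannot tell them apart. `straintag` implements the genome-subtraction route
to strain-level detection:

1. **Unique-region discovery.** The target assembly is compared against
   same-species background genomes at the canonical *k*-mer level
   (default *k* = 21): positions whose *k*-mer never occurs in any
   background genome form runs, runs are merged across short interruptions,
   and merged runs spanning ≥ 1000 bp become candidate regions.
2. **Cross-specificity screening.** Each candidate is scored by
   Smith–Waterman local alignment under blastn-style scoring
   (+2/−3, gap −5 −2·L). Regions are kept only if every non-target genome
   scores < 40 and the target itself scores ≥ 200.
3. **Primer design.** Inside surviving regions, primer pairs are enumerated
   under hard constraints (size 20–25, optimum 22; GC 45–55%; pair
   ΔTm ≤ 1 °C; product 100–500 bp; self/cross-dimer ΔG above a floor).
   Melting temperatures use the unified nearest-neighbor parameter set with
   Tm = ΔH/(ΔS + R·ln(C/4)) − 273.15, salt-corrected entropy
   (0.368·(N−1)·ln[mono]) and divalent-to-monovalent conversion
   (mono + 120·√(Mg−dNTP)); primer–primer dimers are scored by exhaustive
   ungapped register scanning of nearest-neighbor ΔG at 37 °C.
4. **Panel assembly & in-silico PCR.** One pair per region plus a universal
   16S-style control are combined so that all product sizes are
   gel-separable (≥ 30 bp and ≥ 10% apart) and every primer is cross-dimer
   clean. Fingerprints of arbitrary genomes are predicted by mismatch-rule
   in-silico PCR (a site can prime only with < 6 total mismatches and < 5
   mismatches in the five 3′-terminal bases) and called
   DETECTED / NOT_DETECTED / INVALID_RUN per lane.

A synthetic-data module generates seeded study bundles — shared backbone,
siblings at a chosen divergence, implanted k-mer-disjoint unique islands,
non-target "starter culture" genomes, mixed community lanes — with full
ground truth, so the whole pipeline is testable without downloads.

## Worked example

```bash
python examples/03_design_panel.py
```

```
panel for 'target':
  target:18440-19979#1
    fwd CGGACTGGTCAAAGTTAGCAGA  Tm 60.29 C  GC 50.00%
    rev CGGAGGATAGTTGGGGTTTGTT  Tm 60.29 C  GC 50.00%
    product 442 bp
  target:52162-53700#1
    fwd TGAGCGACTCACAGACCACAGA  Tm 63.29 C  GC 54.55%
    rev GCGACAAACGATGCTGTTTGCA  Tm 63.29 C  GC 50.00%
    product 257 bp
  control product: 779 bp
  expected fingerprint (gel order): [442, 257]
```

Two unique islands were implanted in the synthetic target; the pipeline
recovered both as regions (`target:18440-19979`, `target:52162-53700`),
designed one constraint-clean pair inside each, and combined them with the
universal control into a panel whose bands (442, 257 and control 779 bp)
are mutually resolvable on a 2% agarose gel. Running
`examples/04_gel_fingerprints.py` then predicts lanes: the target and the
target-containing "yogurt" community show bands 442+257+control
(DETECTED), while the 99.9%-identical sibling and starter-only lanes show
the control band alone (NOT_DETECTED).

The other examples cover the primer thermodynamics report
(`01_primer_thermodynamics.py`, the two published panels' length/GC/Tm/
self-dimer table) and region discovery step by step
(`02_unique_regions.py`).

## Command line

The same stages are available as a thin CLI for shell pipelines:

```bash
straintag simulate scenario.yaml -o sim/
straintag find-unique sim/target.fasta --background sim/sibling_1.fasta \
    --nontarget sim/nontarget_1.fasta -o uniq/
straintag design uniq/regions.fasta -o primers.tsv
straintag panel primers.tsv --control-fwd ... --control-rev ... \
    --control-template sim/target.fasta -o panel.json
straintag ispcr panel.json sim/community.yogurt_target.fasta -o lanes.tsv
```

Every stage writes a JSON manifest (input hashes, full configuration with
default/config/flag provenance) sufficient to reproduce its outputs.
Exit codes: 0 success, 2 valid-but-infeasible (no regions / no panel),
1 error.

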