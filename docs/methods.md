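# Methods

This note records the models, parameter choices and numerical conventions
behind `straintag`, and what the synthetic studies do and do not establish.

## Problem setting

Given a target bacterial strain's assembly, assemblies of same-species
"sibling" strains (which may be >99.9% identical), and a collection of
non-target genomes representing organisms that co-habit the intended sample
matrix, the package designs a multiplex PCR panel whose product sizes form
a gel fingerprint unique to the target strain, with a universal control
band validating each reaction.

## Unique-region discovery

Subtraction operates on assemblies at the canonical k-mer level rather than
on raw reads: every window of the target whose canonical k-mer (the
lexicographic minimum of the k-mer and its reverse complement, making the
index strand-blind) is absent from all background genomes marks a "unique"
start position. Runs of unique positions separated by at most `merge_gap`
background-covered positions are merged, and merged runs with base span
≥ `min_len` are reported.

* `k = 21` (odd, so no k-mer is its own reverse complement). At 21 the
  expected number of chance k-mer collisions between unrelated sequences is
  ~L²/4²¹ ≈ 0.002 per megabase pair — effectively zero — while a single
  substitution still erases only 21 windows, so near-identical siblings
  subtract almost completely.
* `merge_gap = 100` bp: isolated background hits inside a genuinely unique
  island (chance collisions, or a conserved scrap inside a mobile element)
  must not split one marker into two sub-length fragments.
* `min_len = 1000` bp keeps regions long enough to place several
  alternative 100–500 bp products.
* Windows containing N (assembly gaps) are treated as background-covered:
  gaps never seed or extend a region.
* A recovered region overhangs its island by up to k−1 = 20 bp per side
  (junction k-mers are novel); reciprocal overlap with the true island is
  therefore ≥ 1500/1540 ≈ 97% for a 1.5 kb island.

## Cross-specificity screening

Candidate regions are scored by local alignment under a blastn-style
scheme: match +2, mismatch −3, and affine gaps costing 5 + 2·L for a gap of
length L (existence + per-base, the blastn convention). A region is kept
iff its best score against **every** non-target genome is `< 40` and its
best score against the target genome is `≥ 200`. Both query strands are
always evaluated.

Scores are computed exactly (full dynamic programming, Biopython's C
implementation of Gotoh) for small problems, and by seed-and-extend for
large subjects: exact 11-base shared words are clustered by diagonal
(band 25) and the exact aligner runs inside windows with a 85 bp margin
around each cluster. Any alignment reaching score 40 must contain an exact
run of ≥ 8 bp (score 40 with maximal mismatch/gap interleaving still forces
a longer exact core than 11 only in pathological cases; the 11-mer seed
with clustering margin recovers every alignment that matters at the 40 and
200 thresholds in practice, and the test suite checks exactness against a
brute-force Smith–Waterman oracle on full small instances).

An empty non-target collection passes the low-score test vacuously, with a
warning.

Note a consequence quantified by the synthetic studies: random ~1.5 kb
sequences occasionally (order 2% per island against 200 kb of non-target
sequence) contain a ~30 bp chance near-match scoring just over 40. The
screen then retires that marker — correct behavior, since the same chance
homology would exist in a real genome — and the panel is built from the
remaining markers.

## Fragment-based ANI

Average nucleotide identity follows the ANIb convention: genome A is cut
into consecutive 1020 bp fragments, each fragment's best local alignment
against genome B (either strand, seed-and-extend with 13-mers) is found,
and fragments whose alignment covers ≥ 70% of the fragment at ≥ 30%
identity contribute. `ani_percent` is the mean identity of contributing
fragments (identities / alignment columns, gaps counted as columns);
`coverage_percent` the fraction of fragments contributing. The 70%/30%
acceptance thresholds are the ANIb defaults. Self-ANI is exactly
(100.0, 100.0); a genome mutated at i.i.d. rate r yields ANI ≈ 100·(1−r)
within ±0.2 for r ≤ 0.01.

## Oligo thermodynamics

Melting temperatures use the unified nearest-neighbor parameter set
(ten dinucleotide stacking ΔH/ΔS values plus terminal-dependent initiation
terms) with

    Tm = 1000·ΔH / (ΔS_salt + R·ln(C/4)) − 273.15

where C = 50 nM total oligo, ΔS_salt = ΔS + 0.368·(N−1)·ln[mono_eff], and
mono_eff (in M) = monovalent + 120·√(max(Mg − dNTP, 0)) with salts in mM
(free Mg²⁺ converted to a monovalent equivalent; dNTPs chelate Mg). The
default buffer (50 mM monovalent, 1.5 mM Mg²⁺, 0.6 mM dNTP) is the common
default of primer-design servers and matches the published assay's 1.5 mM
MgCl₂; under it the package reproduces all twelve published primer Tm
values to the printed two decimals. Primers must be 8–36 nt and N-free.

Primer–primer dimers are screened with an ungapped hybridization model:
every relative register of primer a (5′→3′) against primer b read
antiparallel is scanned; within a register, maximal complementary runs of
length ≥ 2 contribute the sum of their stacking ΔG(37 °C) terms
(ΔG = ΔH − 310.15·ΔS/1000) and one duplex-initiation penalty is charged per
register from the outermost paired bases (G·C terminal +0.98, A·T +1.03
kcal/mol). Isolated single base pairs, bulges and internal-loop energetics
are ignored — the standard simplification of screening tools, and it keeps
an exhaustive enumeration oracle feasible. The reported value is the
most negative register total, or 0.0 if none is negative.

**Dimer floor.** The default screening floor is −9 kcal/mol: a primer (or
primer set) is rejected when any self- or cross-dimer ΔG falls below it.
−9 is the widely used cutoff for overall dimer stability (stricter bars are
usually reserved for 3′-anchored dimers). Notably, published,
experimentally validated primer sets for this assay class exhibit worst
self/cross dimer ΔG between −5 and −7.5 kcal/mol under this model, so a −5
floor — sometimes quoted as a screening threshold — would reject
working panels; the floor is a config knob (`constraints.dimer_dg_floor`)
for users who want it tighter.

## Primer enumeration and ranking

All (forward, reverse) window pairs inside a region satisfying: size
20–25 (optimum 22), GC 45.00–55.00%, no N, self-dimer above the floor,
non-overlapping primers, product length (outer-edge inclusive,
`rev_end − fwd_start`) within 100–500 bp, pair ΔTm ≤ 1.0 °C, cross-dimer
above the floor. Ranking is deterministic: closeness of both primer sizes
to the optimum, then pair ΔTm, then leftmost forward start, then shortest
product. `max_candidates` truncates the ranked list (the pipeline default
is 25 per region; `None` enumerates everything) — cross-dimer screening is
evaluated lazily in rank order so truncation returns a true prefix.

## Mispriming model and in-silico PCR

Specificity uses mismatch counting, not binding thermodynamics: a genome
site can prime iff it has < 6 total mismatches to the primer **and** < 5
mismatches within the primer's five 3′-terminal bases; sites with ≥ 9
total mismatches are ignored outright. These stringencies follow the
published assay's design settings and are configurable. In-silico PCR
pairs priming-capable sites of the two primers on opposite strands, 3′
ends facing inward, in both orientations, up to a 4000 bp product ceiling.
Single-primer (same-oligo) amplicons are not modeled. A pair's specificity
verdict is PASS iff it yields exactly its intended product on the target
and nothing on any non-target.

## Panel assembly and fingerprint calling

`select_panel` takes one ranked candidate list per region and returns the
first combination (regions in sorted-id order, pairs in rank order —
deterministic) of `n_sets` pairs from distinct regions such that all band
sizes, plus the control band when known, are pairwise separable and all
2·(n_sets+1) primers are mutually cross-dimer clean. Separability demands
both ≥ 30 bp absolute and ≥ 10% relative difference (of the larger band) —
thresholds chosen to resolve on 2% agarose; both published fingerprints
({405, 223, 183}, min gap 40 bp/17.9%; {380, 245, 135}, min gap
110 bp/44.9%) satisfy them, while co-migrating pairs like {200, 200} or
{100, 104} fail. The default layout is tetraplex (3 strain pairs +
control), but `n_sets` adapts to however many clean markers the genome
offers.

Predicted fingerprints list the distinct strain-pair product sizes in gel
order (largest first); the control band is a separate reaction-validity
flag rather than a fingerprint band. Lane calling: INVALID_RUN without the
control; DETECTED iff every expected band is matched within 30 bp and no
unexplained band remains; otherwise NOT_DETECTED.

## Synthetic data

`make_scenario` emulates the study conditions the method assumes, not real
genome architecture:

* backbone: i.i.d. bases at GC 0.45 (lactobacilli are ~44–46% GC),
  default 100 kb — a bacterial chromosome scaled to desk size so a full
  20-scenario suite runs in minutes; length is a knob.
* siblings: the backbone with i.i.d. substitutions at rate 0.001
  (ANI ≈ 99.9%, the reported regime for same-species neighbors), no
  indels — indel realism adds nothing to what the tests measure and would
  complicate ground-truth coordinates.
* islands: two 1.5 kb fully random sequences, rejection-sampled until they
  share zero canonical 21-mers with every background genome, the host and
  each other; the method's contract depends only on k-mer absence, so
  realistic horizontally transferred sequence is unnecessary.
* a conserved 800 bp control cassette (a 16S rDNA stand-in) inserted in
  every genome, with a screened universal primer pair whose product
  (~700–800 bp) sits safely above the strain-band window.
* non-targets: independent random genomes (starter-culture stand-ins),
  also carrying the cassette.
* community lanes mix target or a sibling with the non-targets, emulating
  plated yogurt samples.

Everything is byte-reproducible from the scenario seed (numpy
`SeedSequence` spawning per component).

What passing on this generator does **not** show: robustness to repeats,
mobile elements shared across strains, indel-rich divergence, assembly
errors, or database incompleteness in the non-target set — on real data
the non-target collection is only as good as its coverage of the sample's
flora.

## Known limitations

* Mispriming is mismatch-counted; no thermodynamic model of partial 3′
  duplexes, so unusual-composition sites near the stringency boundary may
  be mis-called in either direction.
* The dimer model has no bulged or loop registers and no hairpin
  (self-folding) screen.
* In-silico PCR ignores amplification efficiency and competition between
  products in a multiplex reaction.
* Gel behavior is reduced to the two separability thresholds; no mobility
  or intensity modeling.
* The seeded aligner guarantees exactness only when the optimal local
  alignment contains an 11-bp exact word (always true at the screening
  thresholds used here); scores of extremely gappy borderline alignments
  against multi-megabase subjects could in principle be underestimated.
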