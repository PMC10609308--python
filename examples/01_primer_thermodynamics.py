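"""Thermodynamic report for a published strain-specific primer set.

Computes, for each primer of the two published tetraplex panels, its length,
GC content, nearest-neighbor melting temperature under PCR-buffer defaults
(50 nM oligo, 50 mM monovalent, 1.5 mM Mg2+, 0.6 mM dNTP) and its worst
self-dimer free energy at 37 degrees C.  Tm values should sit tightly
around the assay's 58 degree annealing step; strongly negative dimer dG
values flag oligos that waste primer in artifact duplexes.
"""

from straintag import dimer_dg, gc_percent, tm_nn

PANELS = {
    "L125": [
        ("6.2F", "CCCGATAGAGGTTCTTCAAGCC"),
        ("6.2R", "ACTCCAAGGATCCAAACAAGCC"),
        ("10.16F", "CGATTGCAGCAACGATAGATCC"),
        ("10.16R", "TAGACCCATTTTGCCAAGGTC"),
        ("12.1F", "AGGAGCAATGTGATTCTACCAC"),
        ("12.1R", "AGGCAATGCTATCGTCCATGA"),
    ],
    "L33": [
        ("2.2F", "CATATCGTCAACAATCCCACGG"),
        ("2.2R", "TAGCACTGTGGCTGAGTATTGG"),
        ("6.5F", "TACTTTCTGATCTGGTCGGGTC"),
        ("6.5R", "GCTTTACCGGACATCCTCAATG"),
        ("9.8F", "TGTTTTGGGTATAGCTGTGGC"),
        ("9.8R", "CGAACTCGGGCTAGAAATCATC"),
    ],
}

print(f"{'primer':8s} {'len':>3s} {'GC%':>6s} {'Tm(C)':>6s} {'self-dG':>8s}")
for strain, primers in PANELS.items():
    print(f"-- {strain} panel --")
    for name, seq in primers:
        print(
            f"{name:8s} {len(seq):3d} {gc_percent(seq):6.2f} "
            f"{tm_nn(seq):6.2f} {dimer_dg(seq, seq):8.2f}"
        )
print(
    "\nTm is the duplex melting temperature (deg C); self-dG the most stable\n"
    "self-hybridization register (kcal/mol at 37 C, more negative = stickier)."
)
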