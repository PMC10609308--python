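"""Nearest-neighbor oligonucleotide thermodynamics.

Melting temperatures use the unified nearest-neighbor parameter set
(dinucleotide stacking enthalpies/entropies plus initiation terms that
depend on the terminal base pair) under PCR-typical buffer conditions:
50 nM oligo, 50 mM monovalent cation, 1.5 mM Mg2+ and 0.6 mM dNTP.  Free
Mg2+ (Mg minus dNTP, which chelates it) is converted to a monovalent
equivalent via the 120*sqrt(mM) rule, and the duplex entropy receives the
0.368*(N-1)*ln[mono] salt correction.  With these conventions the Tm of a
non-self-complementary primer at total strand concentration C is

    Tm = 1000*dH / (dS_salt + R*ln(C/4)) - 273.15      [degrees C]

Primer-primer dimer stability is screened with an ungapped hybridization
model: every relative register of one primer against the reverse of the
other is scanned, complementary runs of length >= 2 contribute their
stacking free energies at 37 degrees C, one duplex-initiation penalty is
charged per register, and the most negative register total is reported
(0.0 when no register is stable).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .seqio import revcomp

__all__ = [
    "ThermoConditions",
    "NNParameterTable",
    "UNIFIED_NN",
    "tm_nn",
    "dimer_dg",
    "tm_difference",
]

R_GAS = 1.987  # cal / (mol K)


@dataclass(frozen=True)
class ThermoConditions:
    """Buffer and strand-concentration context for Tm and dG calculations.

    oligo_conc is molar; the salts and dNTP are mM.  ``temperature_for_dg``
    is the temperature (deg C) at which dimer free energies are evaluated.
    """

    oligo_conc: float = 50e-9
    monovalent: float = 50.0
    divalent: float = 1.5
    dntp: float = 0.6
    temperature_for_dg: float = 37.0

    def __post_init__(self) -> None:
        if min(self.oligo_conc, self.monovalent, self.divalent, self.dntp) < 0:
            raise ValueError("concentrations must be non-negative")

    @property
    def effective_monovalent(self) -> float:
        """Monovalent-equivalent salt (mM), with free-Mg conversion."""
        free_mg = max(self.divalent - self.dntp, 0.0)
        return self.monovalent + 120.0 * math.sqrt(free_mg)


def _symmetrize(pairs: dict[str, tuple[float, float]]) -> dict[str, tuple[float, float]]:
    full = {}
    for key, value in pairs.items():
        full[key] = value
        full[revcomp(key)] = value
    return full


# Unified NN set: stacking dH (kcal/mol) and dS (cal/mol K) per dinucleotide
# step read 5'->3' on one strand (reverse-complement steps are identical).
_STACKS = _symmetrize(
    {
        "AA": (-7.9, -22.2),
        "AT": (-7.2, -20.4),
        "TA": (-7.2, -21.3),
        "CA": (-8.5, -22.7),
        "GT": (-8.4, -22.4),
        "CT": (-7.8, -21.0),
        "GA": (-8.2, -22.2),
        "CG": (-10.6, -27.2),
        "GC": (-9.8, -24.4),
        "GG": (-8.0, -19.9),
    }
)


@dataclass(frozen=True)
class NNParameterTable:
    """Nearest-neighbor parameter set (stacking + initiation terms)."""

    stack_dh: dict = field(default_factory=lambda: {k: v[0] for k, v in _STACKS.items()})
    stack_ds: dict = field(default_factory=lambda: {k: v[1] for k, v in _STACKS.items()})
    init_gc_dh: float = 0.1
    init_gc_ds: float = -2.8
    init_at_dh: float = 2.3
    init_at_ds: float = 4.1

    def stack_dg(self, step: str, temp_c: float) -> float:
        t = temp_c + 273.15
        return self.stack_dh[step] - t * self.stack_ds[step] / 1000.0

    def init_dg(self, base: str, temp_c: float) -> float:
        t = temp_c + 273.15
        if base in "GC":
            return self.init_gc_dh - t * self.init_gc_ds / 1000.0
        return self.init_at_dh - t * self.init_at_ds / 1000.0


UNIFIED_NN = NNParameterTable()


def _validate_primer(primer: str, min_len: int = 8, max_len: int = 36) -> None:
    if not min_len <= len(primer) <= max_len:
        raise ValueError(
            f"primer length {len(primer)} outside [{min_len}, {max_len}]"
        )
    if set(primer) - set("ACGT"):
        raise ValueError("primer must be N-free and over {A,C,G,T}")


def tm_nn(
    primer: str,
    cond: ThermoConditions = ThermoConditions(),
    params: NNParameterTable = UNIFIED_NN,
) -> float:
    """Nearest-neighbor melting temperature in deg C, rounded to 2 decimals."""
    _validate_primer(primer)
    dh = 0.0
    ds = 0.0
    for terminal in (primer[0], primer[-1]):
        if terminal in "GC":
            dh += params.init_gc_dh
            ds += params.init_gc_ds
        else:
            dh += params.init_at_dh
            ds += params.init_at_ds
    for i in range(len(primer) - 1):
        step = primer[i : i + 2]
        dh += params.stack_dh[step]
        ds += params.stack_ds[step]
    ds += 0.368 * (len(primer) - 1) * math.log(cond.effective_monovalent / 1000.0)
    tm_kelvin = dh * 1000.0 / (ds + R_GAS * math.log(cond.oligo_conc / 4.0))
    return round(tm_kelvin - 273.15, 2)


def tm_difference(
    fwd: str, rev: str, cond: ThermoConditions = ThermoConditions()
) -> float:
    """|Tm(fwd) - Tm(rev)| in deg C."""
    return abs(tm_nn(fwd, cond) - tm_nn(rev, cond))


_PAIR = {"A": "T", "T": "A", "C": "G", "G": "C"}

_DG_CACHE: dict[tuple[int, float], tuple[dict, dict]] = {}


def _dg_tables(params: NNParameterTable, temp: float) -> tuple[dict, dict]:
    key = (id(params), temp)
    if key not in _DG_CACHE:
        stacks = {s: params.stack_dg(s, temp) for s in params.stack_dh}
        inits = {base: params.init_dg(base, temp) for base in "ACGT"}
        _DG_CACHE[key] = (stacks, inits)
    return _DG_CACHE[key]


def dimer_dg(
    a: str,
    b: str,
    params: NNParameterTable = UNIFIED_NN,
    cond: ThermoConditions = ThermoConditions(),
) -> float:
    """Most stable ungapped duplex free energy (kcal/mol) of two primers.

    All relative registers of ``a`` (5'->3') against ``b`` read antiparallel
    are scanned.  Within a register, maximal complementary runs of length
    >= 2 contribute the sum of their stacking dG terms; a single duplex
    initiation penalty (terminal-dependent, from the outermost paired bases)
    is charged per register.  Returns 0.0 when no register is stable
    (strictly negative).  Bulges and internal-loop energetics are ignored.
    """
    if len(a) < 8 or len(b) < 8:
        raise ValueError("primers must be at least 8 bases long")
    temp = cond.temperature_for_dg
    stacks, inits = _dg_tables(params, temp)
    b_rev = b[::-1]
    la, lb = len(a), len(b_rev)
    best = 0.0
    for offset in range(-(lb - 1), la):
        lo = max(0, offset)
        hi = min(la, offset + lb)
        # bonded at i means a[i] pairs with b_rev[i - offset]
        first_paired = None
        last_paired = None
        total = 0.0
        prev_bonded = False
        for i in range(lo, hi):
            bonded = _PAIR.get(a[i]) == b_rev[i - offset]
            if bonded and prev_bonded:
                total += stacks[a[i - 1 : i + 1]]
                if first_paired is None:
                    first_paired = i - 1
                last_paired = i
            prev_bonded = bonded
        if last_paired is None:
            continue
        total += inits[a[first_paired]] + inits[a[last_paired]]
        if total < best:
            best = total
    return best
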