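"""Independent brute-force oracles used to verify the fast implementations.

These are deliberately naive re-derivations: a full-matrix Gotoh local
aligner, an exhaustive dimer-register enumerator that recomputes free
energies from raw enthalpy/entropy, and a sliding-window mismatch counter.
They share no code with the package paths they check.
"""

from __future__ import annotations

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}


def random_dna(rng, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


def random_pair(rng, max_len: int) -> tuple[str, str]:
    """A random query/subject pair; half the time they share a planted
    (possibly mutated) segment so positive scores are exercised too."""
    q = random_dna(rng, rng.randint(10, max_len))
    s = random_dna(rng, rng.randint(10, max_len))
    if rng.random() < 0.5 and len(q) >= 16:
        lo = rng.randrange(0, len(q) - 12)
        seg = list(q[lo : lo + 12])
        if rng.random() < 0.5:
            seg[rng.randrange(len(seg))] = rng.choice("ACGT")
        pos = rng.randrange(0, max(1, len(s) - 12))
        s = s[:pos] + "".join(seg) + s[pos + 12 :]
    return q, s


def rc(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def sw_score_one_strand(
    q: str, s: str, match=2, mismatch=-3, gap_open=-5, gap_extend=-2
) -> int:
    """Full-matrix affine-gap Smith-Waterman; a gap of length L costs
    |gap_open| + L*|gap_extend|."""
    n, m = len(q), len(s)
    NEG = float("-inf")
    prev_h = [0.0] * (m + 1)
    prev_f = [NEG] * (m + 1)
    best = 0.0
    for i in range(1, n + 1):
        h = [0.0] * (m + 1)
        f = [NEG] * (m + 1)
        e = NEG
        for j in range(1, m + 1):
            e = max(h[j - 1] + gap_open + gap_extend, e + gap_extend)
            f[j] = max(prev_h[j] + gap_open + gap_extend, prev_f[j] + gap_extend)
            sub = match if q[i - 1] == s[j - 1] else mismatch
            h[j] = max(0.0, prev_h[j - 1] + sub, e, f[j])
            if h[j] > best:
                best = h[j]
        prev_h, prev_f = h, f
    return int(best)


def sw_score(q: str, s: str, **kw) -> int:
    """Both query strands."""
    return max(sw_score_one_strand(q, s, **kw), sw_score_one_strand(rc(q), s, **kw))


# raw unified NN enthalpies (kcal/mol) and entropies (cal/mol K), minimal set
_NN_RAW = {
    "AA": (-7.9, -22.2), "AT": (-7.2, -20.4), "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "GT": (-8.4, -22.4), "CT": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "CG": (-10.6, -27.2), "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9),
}


def _stack_dg37(step: str) -> float:
    if step not in _NN_RAW:
        step = rc(step)
    dh, ds = _NN_RAW[step]
    return dh - 310.15 * ds / 1000.0


def _init_dg37(base: str) -> float:
    dh, ds = (0.1, -2.8) if base in "GC" else (2.3, 4.1)
    return dh - 310.15 * ds / 1000.0


def dimer_dg_bruteforce(a: str, b: str) -> float:
    """Exhaustive enumeration of every hybridization register of a against
    antiparallel b; complementary runs >= 2 stack, one initiation charged
    per register from the outermost stacked bases."""
    best = 0.0
    la, lb = len(a), len(b)
    # shift: index of b (5'->3') paired with a[0] would be lb-1-shift ... we
    # simply slide reversed-b across a
    br = b[::-1]
    for shift in range(-(lb - 1), la):
        bonded = []
        for i in range(la):
            j = i - shift
            if 0 <= j < lb:
                bonded.append(_COMP[a[i]] == br[j])
            else:
                bonded.append(False)
        # collect maximal bonded runs
        runs = []
        i = 0
        while i < la:
            if bonded[i]:
                j = i
                while j + 1 < la and bonded[j + 1]:
                    j += 1
                if j > i:
                    runs.append((i, j))
                i = j + 1
            else:
                i += 1
        if not runs:
            continue
        total = 0.0
        for lo, hi in runs:
            for p in range(lo, hi):
                total += _stack_dg37(a[p : p + 2])
        total += _init_dg37(a[runs[0][0]]) + _init_dg37(a[runs[-1][1]])
        best = min(best, total)
    return best


def binding_sites_bruteforce(primer: str, genome: str, ignore_above: int = 9):
    """(start, strand, total, last5) via per-position counting on both strands."""
    out = []
    m = len(primer)
    primer_rc = rc(primer)
    for start in range(len(genome) - m + 1):
        window = genome[start : start + m]
        total = sum(1 for x, y in zip(primer, window) if x != y or x == "N")
        if total < ignore_above:
            last5 = sum(1 for x, y in zip(primer[-5:], window[-5:]) if x != y or x == "N")
            out.append((start, "+", total, last5))
        total = sum(1 for x, y in zip(primer_rc, window) if x != y or x == "N")
        if total < ignore_above:
            # primer 3' end maps to the window's first base on '-'
            last5 = sum(
                1 for x, y in zip(primer_rc[:5], window[:5]) if x != y or x == "N"
            )
            out.append((start, "-", total, last5))
    return out
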