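"""Oligonucleotide thermodynamics for primer screening.

Melting temperatures follow the two-state nearest-neighbor model with the
unified duplex parameter set (SantaLucia 1998): duplex enthalpy and entropy
are the sum of an initiation term per terminal base pair and one stacking
term per dinucleotide step.  Entropy is corrected for monovalent salt by
0.368·(N−1)·ln[Na+] cal/(mol·K), and

    Tm(K) = 1000·ΔH / (ΔS + R·ln(C_T/x)),

with R = 1.9872 cal/(mol·K), C_T the total oligo concentration and x = 4 for
non-self-complementary duplexes (1 for self-complementary ones).  Defaults of
1 μM primer and 50 mM Na+ match a standard qPCR mix.

Hairpin and primer-dimer screening is run-based, in the style of classical
primer-design heuristics: it looks for reverse-complementary runs rather than
folding a full free-energy model, which keeps the decisions deterministic and
checkable against exhaustive scans.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

R_GAS = 1.9872  # cal / (mol K)

# Unified nearest-neighbor parameters: (ΔH kcal/mol, ΔS cal/mol/K) per
# 5'->3' dinucleotide step on the top strand.
NN_UNIFIED: dict[str, tuple[float, float]] = {
    "AA": (-7.9, -22.2),
    "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7),
    "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4),
    "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0),
    "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2),
    "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9),
    "CC": (-8.0, -19.9),
}
#: terminal-base-pair initiation terms
INIT_AT = (2.3, 4.1)
INIT_GC = (0.1, -2.8)
#: self-complementary symmetry correction (entropy only)
SYM_DS = -1.4

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Oligo:
    """A 5'->3' primer sequence with its reaction conditions."""

    seq: str
    conc_molar: float = 1e-6
    salt_molar: float = 0.05

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError("empty oligo")
        if self.conc_molar <= 0 or self.salt_molar <= 0:
            raise ValueError("concentrations must be positive")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class ThermoResult:
    tm_c: float  #: melting temperature, °C
    dh: float  #: duplex enthalpy, kcal/mol
    ds: float  #: salt-corrected duplex entropy, cal/(mol·K)


def melt_temp(oligo: Oligo) -> ThermoResult:
    """Two-state nearest-neighbor melting temperature of a primer duplex."""
    seq = oligo.seq.upper()
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"ambiguous base {sorted(bad)[0]!r} in oligo {seq!r}")
    if len(seq) < 2:
        raise ValueError("oligo must have at least 2 bases")

    dh = ds = 0.0
    for terminal in (seq[0], seq[-1]):
        h, s = INIT_AT if terminal in "AT" else INIT_GC
        dh += h
        ds += s
    for i in range(len(seq) - 1):
        h, s = NN_UNIFIED[seq[i : i + 2]]
        dh += h
        ds += s

    selfcomp = seq == revcomp(seq)
    if selfcomp:
        ds += SYM_DS
    ds += 0.368 * (len(seq) - 1) * math.log(oligo.salt_molar)

    x = 1.0 if selfcomp else 4.0
    tm_k = dh * 1000.0 / (ds + R_GAS * math.log(oligo.conc_molar / x))
    return ThermoResult(tm_c=tm_k - 273.15, dh=dh, ds=ds)


@dataclass(frozen=True)
class HairpinResult:
    has_hairpin: bool
    best_stem: int  #: longest stem found (0 if none reaches min_stem)


def hairpin_check(oligo: Oligo, min_stem: int = 4, min_loop: int = 3) -> HairpinResult:
    """Flag intramolecular inverted repeats that could fold into a hairpin.

    A hairpin exists when two substrings of length >= ``min_stem`` that are
    reverse complements of each other are separated by a loop of at least
    ``min_loop`` bases.  Returns the longest such stem.
    """
    if min_stem < 3 or min_loop < 3:
        raise ValueError("min_stem and min_loop must each be >= 3")
    seq = oligo.seq.upper()
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    n = len(seq)
    best = 0
    # Every stem has an outermost base pair (i, j); extend inward from it.
    # A stem of length s from (i, j) pairs (i+t, j-t), t < s, and leaves a
    # loop of j - i - 2s + 1 unpaired bases, which must reach min_loop.
    for i in range(n):
        for j in range(i + min_loop + 1, n):
            if comp.get(seq[i]) != seq[j]:
                continue
            k = 1
            while i + k < j - k and comp.get(seq[i + k]) == seq[j - k]:
                k += 1
            usable = min(k, (j - i + 1 - min_loop) // 2)
            best = max(best, usable)
    return HairpinResult(best >= min_stem, best)


@dataclass(frozen=True)
class DimerResult:
    has_dimer: bool
    best_run: int  #: longest antiparallel complementary run
    best_3prime_run: int  #: longest run anchored at either oligo's 3' end


def dimer_check(a: Oligo, b: Oligo, min_run: int = 8, min_3prime_run: int = 4) -> DimerResult:
    """Flag antiparallel complementary runs between two primers.

    The overall flag is raised when the longest complementary run reaches
    ``min_run`` anywhere, or when a run anchored at the 3' end of either
    primer reaches ``min_3prime_run`` (a matched 3' end is what the
    polymerase extends, so shorter runs matter there).  Self-dimers are the
    ``a is b`` case.
    """
    if min_run < 4:
        raise ValueError("min_run must be >= 4")
    s1 = a.seq.upper()
    s2 = revcomp(b.seq.upper())  # common substrings of s1/s2 = complementary runs
    n, m = len(s1), len(s2)
    best = 0
    best3 = 0
    # O(nm) longest-common-substring DP; track runs touching 3' ends.
    prev = [0] * (m + 1)
    for i in range(1, n + 1):
        cur = [0] * (m + 1)
        for j in range(1, m + 1):
            if s1[i - 1] == s2[j - 1]:
                run = prev[j - 1] + 1
                cur[j] = run
                if run > best:
                    best = run
                # a's 3' end is s1[-1]; b's 3' end maps to s2[0], so a run
                # covering s2 position 0 ends b's 3' end: j - run == 0.
                if i == n or j - run == 0:
                    if run > best3:
                        best3 = run
        prev = cur
    flag = best >= min_run or best3 >= min_3prime_run
    return DimerResult(flag, best, best3)
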