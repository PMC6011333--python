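"""Conserved-region primer enumeration and six-criteria pair screening.

Candidate primers are consensus oligos read off windows of a nucleotide
alignment whose columns are sufficiently conserved and gap-free.  A candidate
pair is then judged against six criteria used when validating a
functional-gene qPCR marker:

  (i)   each primer's nearest-neighbor Tm within a window (default 60-67 °C);
  (ii)  no predicted hairpin, self-dimer or cross-dimer;
  (iii) Tm difference between the primers at most 1 °C;
  (iv)  amplification product at most 300 bp;
  (v)   database coverage: every target sequence matched with at most three
        mismatches per primer;
  (vi)  specificity: no in-silico amplicon from any non-target homolog.

In-silico PCR uses a mismatch-tolerant site scan with an exact 3'-terminal
trinucleotide requirement (polymerase extension needs a matched 3' end; the
anchor length is configurable and 0 disables it).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from funcmark.seqdb import Alignment, SequenceRecord, GAP
from funcmark.thermo import (
    Oligo,
    dimer_check,
    hairpin_check,
    melt_temp,
    revcomp,
)

_ENC = np.full(256, 4, dtype=np.int8)  # 4 = "never matches"
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i


def _encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class PrimerCandidate:
    """A consensus oligo anchored on the alignment.

    ``seq`` is always written 5'->3'.  For a reverse candidate it is the
    reverse complement of the plus-strand consensus whose first column is
    ``aln_start``.
    """

    seq: str
    aln_start: int
    strand: str  # "forward" | "reverse"

    def __post_init__(self) -> None:
        if self.strand not in ("forward", "reverse"):
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return len(self.seq)

    @property
    def plus_site(self) -> str:
        """The plus-strand sequence the primer footprint occupies."""
        return self.seq if self.strand == "forward" else revcomp(self.seq)


@dataclass(frozen=True)
class PrimerPair:
    fwd: PrimerCandidate
    rev: PrimerCandidate
    product_len_ref: int

    def __post_init__(self) -> None:
        if self.fwd.strand != "forward" or self.rev.strand != "reverse":
            raise ValueError("pair must be (forward, reverse)")
        if self.product_len_ref <= 0:
            raise ValueError("product_len_ref must be positive")


@dataclass(frozen=True)
class AmpliconHit:
    """One in-silico PCR product, 0-based half-open on the plus strand."""

    template_id: str
    start: int
    end: int
    fwd_mismatches: int
    rev_mismatches: int
    strand: str = "+"

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CriterionResult:
    name: str
    passed: bool
    value: object
    detail: str = ""


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds for the six pair-screening criteria."""

    tm_min: float = 60.0
    tm_max: float = 67.0
    dtm_max: float = 1.0
    max_product: int = 300
    max_mm: int = 3
    min_coverage: float = 1.0
    conc_molar: float = 1e-6
    salt_molar: float = 0.05
    hairpin_min_stem: int = 4
    hairpin_min_loop: int = 3
    dimer_min_run: int = 8
    dimer_min_3prime_run: int = 4
    end3_anchor: int = 3  # exact 3'-terminal bases required for binding


@dataclass(frozen=True)
class PrimerPairReport:
    pair: PrimerPair
    criteria: tuple[CriterionResult, ...]
    verdict: bool

    def criterion(self, name: str) -> CriterionResult:
        for c in self.criteria:
            if c.name == name:
                return c
        raise KeyError(name)

    def failed(self) -> list[str]:
        return [c.name for c in self.criteria if not c.passed]


# --------------------------------------------------------------------------
# Alignment profiling and candidate enumeration
# --------------------------------------------------------------------------

def conservation_profile(aln: Alignment) -> list[tuple[str, float, float]]:
    """Per-column (majority base, majority fraction, gap fraction).

    Fractions are over all rows; symbols other than A/C/G/T (e.g. ``N``)
    count toward neither base tallies nor gaps.  Ties break A < C < G < T.
    """
    if len(aln) < 2:
        raise ValueError("conservation profile needs at least 2 rows")
    n = len(aln)
    profile = []
    for col in range(aln.length):
        column = [r.seq[col].upper() for r in aln.records]
        counts = {b: 0 for b in "ACGT"}
        gaps = 0
        for sym in column:
            if sym in counts:
                counts[sym] += 1
            elif sym == GAP:
                gaps += 1
        major = max("ACGT", key=lambda b: (counts[b], -"ACGT".index(b)))
        profile.append((major, counts[major] / n, gaps / n))
    return profile


def enumerate_candidates(
    aln: Alignment,
    len_range: tuple[int, int] = (25, 30),
    min_conservation: float = 0.80,
    max_gap_fraction: float = 0.10,
) -> list[PrimerCandidate]:
    """All conserved consensus windows, as forward and reverse candidates.

    A window qualifies when every column has majority fraction >=
    ``min_conservation`` and gap fraction <= ``max_gap_fraction``.  Output is
    ordered by (start, length), forward before reverse.
    """
    profile = conservation_profile(aln)
    lo, hi = len_range
    ok = [
        frac >= min_conservation and gapfrac <= max_gap_fraction
        for _, frac, gapfrac in profile
    ]
    candidates: list[PrimerCandidate] = []
    for start in range(aln.length):
        for length in range(lo, hi + 1):
            end = start + length
            if end > aln.length or not all(ok[start:end]):
                continue
            consensus = "".join(profile[c][0] for c in range(start, end))
            candidates.append(PrimerCandidate(consensus, start, "forward"))
            candidates.append(PrimerCandidate(revcomp(consensus), start, "reverse"))
    return candidates


# --------------------------------------------------------------------------
# Mismatch scanning
# --------------------------------------------------------------------------

def count_mismatches(primer: str, site: str) -> int:
    """Hamming distance; any non-ACGT template symbol counts as a mismatch."""
    if len(primer) != len(site):
        raise ValueError(
            f"primer length {len(primer)} != site length {len(site)}"
        )
    p = _encode(primer)
    if (p == 4).any():
        raise ValueError("primer must be unambiguous A/C/G/T")
    return int((p != _encode(site)).sum())


def _site_mismatches(pattern: np.ndarray, template: np.ndarray) -> np.ndarray:
    """Mismatch count of ``pattern`` at every template offset (vectorized)."""
    if len(template) < len(pattern):
        return np.empty(0, dtype=np.int64)
    windows = sliding_window_view(template, len(pattern))
    return (windows != pattern).sum(axis=1)


def _binding_sites(
    primer_plus: str,
    anchor_plus: str,
    template: np.ndarray,
    template_str: str,
    max_mm: int,
    anchor_at_start: bool,
) -> list[tuple[int, int]]:
    """(offset, mismatches) of plus-strand sites where the primer binds.

    ``primer_plus`` is the plus-strand footprint pattern; ``anchor_plus`` the
    bases that must match exactly (the primer's 3'-terminal trinucleotide,
    expressed on the plus strand: at the site end for a forward primer, at
    the site start for a reverse primer).
    """
    mm = _site_mismatches(_encode(primer_plus), template)
    hits = []
    L = len(primer_plus)
    a = len(anchor_plus)
    for off in np.nonzero(mm <= max_mm)[0]:
        if a:
            site = template_str[off : off + L]
            anchored = site[:a] if anchor_at_start else site[L - a :]
            if anchored.upper() != anchor_plus:
                continue
        hits.append((int(off), int(mm[off])))
    return hits


def best_site(
    primer: PrimerCandidate, record: SequenceRecord
) -> tuple[int, int, str]:
    """Minimum-mismatch binding site over both template orientations.

    Returns ``(mismatches, offset, orientation)`` with orientation ``"+"``
    when the site lies on the template as given and ``"-"`` on its reverse
    complement; no 3'-anchor requirement is applied (coverage counts raw
    mismatches, as in the screening criterion).
    """
    pattern = _encode(primer.plus_site)
    best = (len(primer.seq) + 1, -1, "+")
    for orient, tmpl in (("+", record.seq), ("-", revcomp(record.seq))):
        mm = _site_mismatches(pattern, _encode(tmpl))
        if mm.size:
            off = int(mm.argmin())
            if int(mm[off]) < best[0]:
                best = (int(mm[off]), off, orient)
    return best


def coverage(
    primer: PrimerCandidate,
    db: Sequence[SequenceRecord],
    max_mm: int = 3,
) -> tuple[float, dict[str, tuple[int, int, str]]]:
    """Fraction of database sequences carrying a site with <= max_mm mismatches."""
    if not db:
        raise ValueError("empty database")
    sites = {rec.id: best_site(primer, rec) for rec in db}
    covered = sum(1 for mm, _, _ in sites.values() if mm <= max_mm)
    return covered / len(db), sites


# --------------------------------------------------------------------------
# In-silico PCR
# --------------------------------------------------------------------------

def _scan_orientation(
    pair: PrimerPair,
    tmpl_str: str,
    template_id: str,
    max_mm: int,
    max_product: int,
    end3: int,
    strand: str,
    total_len: int,
) -> list[AmpliconHit]:
    tmpl = _encode(tmpl_str)
    fseq = pair.fwd.seq.upper()
    rsite = revcomp(pair.rev.seq.upper())  # reverse primer's plus-strand footprint
    f_anchor = fseq[len(fseq) - end3 :] if end3 else ""
    r_anchor = rsite[:end3] if end3 else ""
    f_hits = _binding_sites(fseq, f_anchor, tmpl, tmpl_str, max_mm, anchor_at_start=False)
    r_hits = _binding_sites(rsite, r_anchor, tmpl, tmpl_str, max_mm, anchor_at_start=True)
    out = []
    for f_off, f_mm in f_hits:
        for r_off, r_mm in r_hits:
            start, end = f_off, r_off + len(rsite)
            product = end - start
            if r_off < f_off or product > max_product:
                continue
            if product < max(len(fseq), len(rsite)):
                continue  # primers must fit inside their own product
            if strand == "-":
                start, end = total_len - end, total_len - start
            out.append(
                AmpliconHit(template_id, start, end, f_mm, r_mm, strand)
            )
    return out


def insilico_pcr(
    pair: PrimerPair,
    template: SequenceRecord,
    max_mm: int = 3,
    max_product: int = 300,
    end3_anchor: int = 3,
) -> list[AmpliconHit]:
    """All PCR products the pair would form on a template.

    Both template orientations are scanned (the product of the pair on the
    minus strand is reported in plus-strand coordinates with strand ``-``).
    A primer binds a site when it has at most ``max_mm`` mismatches and its
    3'-terminal ``end3_anchor`` bases match exactly.  Products longer than
    ``max_product`` are ignored.  Hits are sorted by (start, end, strand).
    """
    n = len(template.seq)
    hits = _scan_orientation(
        pair, template.seq, template.id, max_mm, max_product, end3_anchor, "+", n
    )
    hits += _scan_orientation(
        pair, revcomp(template.seq), template.id, max_mm, max_product,
        end3_anchor, "-", n,
    )
    return sorted(hits, key=lambda h: (h.start, h.end, h.strand))


def specificity(
    pair: PrimerPair,
    nontargets: Sequence[SequenceRecord],
    max_mm: int = 3,
    max_product: int = 300,
    end3_anchor: int = 3,
) -> tuple[bool, list[AmpliconHit]]:
    """PASS iff no non-target template yields an in-silico amplicon."""
    if not nontargets:
        raise ValueError("empty non-target set")
    offending: list[AmpliconHit] = []
    for rec in nontargets:
        offending.extend(
            insilico_pcr(pair, rec, max_mm=max_mm, max_product=max_product,
                         end3_anchor=end3_anchor)
        )
    return not offending, offending


# --------------------------------------------------------------------------
# Six-criteria evaluation
# --------------------------------------------------------------------------

def evaluate_pair(
    pair: PrimerPair,
    db: Sequence[SequenceRecord],
    nontargets: Sequence[SequenceRecord],
    config: ScreenConfig = ScreenConfig(),
) -> PrimerPairReport:
    """Judge a primer pair against the six screening criteria.

    Every criterion records the measured value, not only the boolean, so a
    report doubles as a design ledger.  The verdict is the conjunction of
    all six.
    """
    fo = Oligo(pair.fwd.seq, config.conc_molar, config.salt_molar)
    ro = Oligo(pair.rev.seq, config.conc_molar, config.salt_molar)
    tm_f = melt_temp(fo).tm_c
    tm_r = melt_temp(ro).tm_c

    c1 = CriterionResult(
        "tm_window",
        config.tm_min <= tm_f <= config.tm_max
        and config.tm_min <= tm_r <= config.tm_max,
        (tm_f, tm_r),
        f"window [{config.tm_min}, {config.tm_max}] °C",
    )

    hp_f = hairpin_check(fo, config.hairpin_min_stem, config.hairpin_min_loop)
    hp_r = hairpin_check(ro, config.hairpin_min_stem, config.hairpin_min_loop)
    dim_ff = dimer_check(fo, fo, config.dimer_min_run, config.dimer_min_3prime_run)
    dim_rr = dimer_check(ro, ro, config.dimer_min_run, config.dimer_min_3prime_run)
    dim_fr = dimer_check(fo, ro, config.dimer_min_run, config.dimer_min_3prime_run)
    c2 = CriterionResult(
        "structure",
        not (
            hp_f.has_hairpin or hp_r.has_hairpin
            or dim_ff.has_dimer or dim_rr.has_dimer or dim_fr.has_dimer
        ),
        {
            "hairpin_fwd": hp_f.best_stem,
            "hairpin_rev": hp_r.best_stem,
            "self_dimer_fwd": dim_ff.best_run,
            "self_dimer_rev": dim_rr.best_run,
            "cross_dimer": dim_fr.best_run,
        },
        "no hairpin, self-dimer or cross-dimer",
    )

    dtm = abs(tm_f - tm_r)
    c3 = CriterionResult("delta_tm", dtm <= config.dtm_max, dtm,
                         f"|ΔTm| <= {config.dtm_max} °C")

    c4 = CriterionResult(
        "product_size",
        pair.product_len_ref <= config.max_product,
        pair.product_len_ref,
        f"product <= {config.max_product} bp",
    )

    cov_f, _ = coverage(pair.fwd, db, config.max_mm)
    cov_r, _ = coverage(pair.rev, db, config.max_mm)
    cov = min(cov_f, cov_r)
    c5 = CriterionResult(
        "coverage",
        cov >= config.min_coverage,
        {"fwd": cov_f, "rev": cov_r},
        f"fraction of DB with <= {config.max_mm} mismatches per primer",
    )

    spec_ok, offending = specificity(
        pair, nontargets, config.max_mm, config.max_product, config.end3_anchor
    )
    c6 = CriterionResult(
        "specificity", spec_ok, len(offending),
        "number of non-target in-silico amplicons",
    )

    criteria = (c1, c2, c3, c4, c5, c6)
    return PrimerPairReport(pair, criteria, all(c.passed for c in criteria))
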