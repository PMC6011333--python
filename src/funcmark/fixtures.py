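"""Deterministic synthetic data with known ground truth.

Three generators make every pipeline stage testable without any external
download:

* :func:`gen_family` — a gapless alignment of target-gene coding sequences
  plus paralog-like homologs.  Targets conserve every catalytic key residue
  of the policy and two primer-design windows delimiting a 133-nt amplicon;
  paralogs diverge faster and carry prescribed key-residue violations, the
  structure that separates a true functional marker from its near-homolog
  (e.g. ACC deaminase vs D-cysteine desulfhydrase).
* :func:`gen_reads` — amplicon reads drawn multinomially from core-region
  sequences with per-base substitution errors and optional length jitter.
* :func:`gen_ct` / :func:`gen_standards` — qPCR Ct values from known copy
  numbers under a chosen standard-curve slope/intercept and Gaussian Ct
  noise.

Substitutions in targets never touch key-residue codons, so the truth table
stays exact by construction.  All generators take an explicit seed and are
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from funcmark.community import Read
from funcmark.primer_screen import PrimerCandidate, PrimerPair
from funcmark.qpcr import AVOGADRO, BP_MOLAR_MASS, CurvePoint
from funcmark.seqdb import Alignment, ResiduePolicy, SequenceRecord, translate_cds
from funcmark.thermo import revcomp

DEFAULT_REQUIRED = ((51, "K"), (78, "S"), (295, "Y"), (296, "E"), (322, "L"))

#: fixed codon per amino acid used when forcing residues
_CODON_OF = {
    "K": "AAA", "S": "AGC", "Y": "TAC", "E": "GAA", "L": "CTG",
    "A": "GCT", "V": "GTT", "G": "GGT", "T": "ACC", "Q": "CAG",
}
_STOPS = {"TAA", "TAG", "TGA"}
_BASES = "ACGT"

#: canonical conserved primer-site windows written into every family
#: reference (stop-free in frame; the derived 25-mer pair sits in the
#: 60-67 °C Tm window with |ΔTm| < 0.2 °C and clean structure checks)
CANONICAL_WINDOWS = (
    "CTTCCTGTGGATGCTGTGTGCCCATCTGGCTGCACG",
    "TCCCTGCCGTTATCGGTCTGGGTGGCTTACGTAGAG",
)

_GENERA = (
    "Pseudomonas", "Burkholderia", "Azospirillum", "Ralstonia",
    "Variovorax", "Acidovorax", "Rhizobium", "Serratia",
    "Amycolatopsis", "Saccharopolyspora",
)
_OUT_GENERA = ("Escherichia", "Achromobacter", "Enterobacter")


@dataclass(frozen=True)
class FamilySpec:
    """Parameters of a synthetic target/paralog gene family.

    Defaults give a family of 30 targets and 8 paralog-like homologs of 330
    codons (enough to cover key residue 322), with 2% per-site divergence
    among targets and 30% in paralogs — the within-family spread of a
    conserved enzyme gene vs the divergence of a paralogous outgroup, whose
    primer regions must not cross-amplify.  ``conserved_windows`` (nt
    coordinates) receive canonical primer-site sequences and are untouched
    in targets, so a primer pair with a 133-nt product always exists.
    """

    n_target: int = 30
    n_paralog: int = 8
    length_codons: int = 330
    sub_rate: float = 0.02
    paralog_sub_rate: float = 0.30
    violation_positions: tuple[int, ...] = (78,)
    required: tuple[tuple[int, str], ...] = DEFAULT_REQUIRED
    conserved_windows: tuple[tuple[int, int], ...] = ((297, 333), (399, 435))
    seed: int = 0

    def __post_init__(self) -> None:
        for rate in (self.sub_rate, self.paralog_sub_rate):
            if not 0 <= rate <= 1:
                raise ValueError("substitution rates must be in [0, 1]")
        policy_positions = {p for p, _ in self.required}
        if not set(self.violation_positions) <= policy_positions:
            raise ValueError("violation_positions must be policy positions")
        if max(policy_positions) > self.length_codons:
            raise ValueError(
                f"policy position {max(policy_positions)} outside "
                f"{self.length_codons}-codon sequence"
            )


@dataclass
class Family:
    """A generated family with its ground truth."""

    nucleotide: Alignment
    protein: Alignment
    truth: dict[str, str]  #: id -> "target" | "paralog"
    policy: ResiduePolicy
    reference_id: str
    spec: FamilySpec


def _mutate_codonwise(
    seq: str,
    rate: float,
    rng: np.random.Generator,
    protected_nt: frozenset[int],
) -> str:
    """Per-site substitution avoiding protected positions and new stops."""
    out = list(seq)
    for c0 in range(0, len(seq), 3):
        codon = out[c0 : c0 + 3]
        original = out[c0 : c0 + 3]
        changed = False
        for k in range(3):
            pos = c0 + k
            if pos in protected_nt or rng.random() >= rate:
                continue
            current = codon[k]
            codon[k] = _BASES[(
                _BASES.index(current) + 1 + rng.integers(0, 3)
            ) % 4]
            changed = True
        if changed and "".join(codon) in _STOPS:
            codon = original  # never introduce an internal stop
        out[c0 : c0 + 3] = codon
    return "".join(out)


def gen_family(spec: FamilySpec) -> Family:
    """Generate the synthetic gene family described by ``spec``."""
    rng = np.random.default_rng(spec.seed)
    n_nt = spec.length_codons * 3

    # reference backbone: random non-stop codons, then forced key residues
    codons = []
    for _ in range(spec.length_codons):
        while True:
            codon = "".join(_BASES[i] for i in rng.integers(0, 4, size=3))
            if codon not in _STOPS:
                break
        codons.append(codon)
    for pos, aa in spec.required:
        codons[pos - 1] = _CODON_OF[aa]
    ref = "".join(codons)
    # canonical primer-site sequences at the conserved windows (codon-aligned
    # and stop-free so the reading frame stays clean)
    for (lo, hi), canon in zip(spec.conserved_windows, CANONICAL_WINDOWS):
        if hi - lo > len(canon):
            raise ValueError(
                f"conserved window ({lo}, {hi}) longer than canonical site"
            )
        ref = ref[:lo] + canon[: hi - lo] + ref[hi:]

    protected = set()
    for pos, _ in spec.required:
        protected.update(range((pos - 1) * 3, pos * 3))
    target_protected = set(protected)
    for lo, hi in spec.conserved_windows:
        if hi > n_nt:
            raise ValueError(f"conserved window ({lo}, {hi}) outside sequence")
        target_protected.update(range(lo, hi))
    target_protected = frozenset(target_protected)
    paralog_protected = frozenset(protected)

    records = [SequenceRecord("REF", f"{_GENERA[0]} reference", ref)]
    truth = {"REF": "target"}
    for i in range(spec.n_target):
        seq = _mutate_codonwise(ref, spec.sub_rate, rng, target_protected)
        genus = _GENERA[i % len(_GENERA)]
        rid = f"T{i + 1:04d}"
        records.append(SequenceRecord(rid, f"{genus} sp{i + 1}", seq))
        truth[rid] = "target"
    for i in range(spec.n_paralog):
        seq = _mutate_codonwise(ref, spec.paralog_sub_rate, rng, paralog_protected)
        codons = [seq[k : k + 3] for k in range(0, n_nt, 3)]
        expected = dict(spec.required)
        for pos in spec.violation_positions:
            wrong = "A" if expected[pos] != "A" else "V"
            codons[pos - 1] = _CODON_OF[wrong]
        seq = "".join(codons)
        genus = _OUT_GENERA[i % len(_OUT_GENERA)]
        rid = f"P{i + 1:04d}"
        records.append(SequenceRecord(rid, f"{genus} sp{i + 1}", seq))
        truth[rid] = "paralog"

    nucleotide = Alignment(tuple(records))
    protein = Alignment(tuple(translate_cds(r) for r in records))
    policy = ResiduePolicy("REF", spec.required)
    return Family(nucleotide, protein, truth, policy, "REF", spec)


def family_primer_pair(family: Family, primer_len: int = 25) -> PrimerPair:
    """The designed-in primer pair of a generated family (133-nt product).

    Forward primer starts at the first conserved window; the reverse primer
    footprint ends 133 nt downstream of that start.
    """
    ref = family.nucleotide.row(family.reference_id).seq
    start = family.spec.conserved_windows[0][0]
    end = start + 133
    fwd = PrimerCandidate(ref[start : start + primer_len], start, "forward")
    rev = PrimerCandidate(revcomp(ref[end - primer_len : end]), end - primer_len, "reverse")
    return PrimerPair(fwd, rev, 133)


# --------------------------------------------------------------------------
# Amplicon reads
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ReadSpec:
    """Parameters of a synthetic amplicon library.

    Defaults emulate a modest single-sample library: 500 reads over the
    provided core-region sequences, 0.5% per-base substitution error (a
    typical post-QC short-read error magnitude), no length jitter.
    """

    db: tuple[SequenceRecord, ...]
    abundances: tuple[float, ...]
    n_reads: int = 500
    error_rate: float = 0.005
    length_jitter: int = 0
    sample: str = "S1"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.db) != len(self.abundances):
            raise ValueError("db and abundances must have equal length")
        if any(w < 0 for w in self.abundances) or not any(self.abundances):
            raise ValueError("abundances must be >= 0 and not all zero")
        if not 0 <= self.error_rate <= 1:
            raise ValueError("error_rate must be in [0, 1]")


def gen_reads(spec: ReadSpec) -> tuple[list[Read], dict[str, tuple[str, str]]]:
    """Draw reads from the core database; returns (reads, truth).

    ``truth`` maps read id to (source record id, source genus).
    """
    rng = np.random.default_rng(spec.seed)
    weights = np.asarray(spec.abundances, dtype=float)
    weights = weights / weights.sum()
    sources = rng.choice(len(spec.db), size=spec.n_reads, p=weights)
    reads: list[Read] = []
    truth: dict[str, tuple[str, str]] = {}
    for k, src in enumerate(sources):
        rec = spec.db[int(src)]
        seq = list(rec.seq)
        for i in range(len(seq)):
            if rng.random() < spec.error_rate:
                seq[i] = _BASES[(_BASES.index(seq[i]) + 1 + rng.integers(0, 3)) % 4]
        if spec.length_jitter:
            delta = int(rng.integers(-spec.length_jitter, spec.length_jitter + 1))
            if delta < 0:
                seq = seq[:delta]
            elif delta > 0:
                seq += [_BASES[i] for i in rng.integers(0, 4, size=delta)]
        rid = f"{spec.sample}_R{k + 1:06d}"
        reads.append(Read(rid, "".join(seq), spec.sample))
        truth[rid] = (rec.id, rec.genus)
    return reads, truth


# --------------------------------------------------------------------------
# qPCR traces
# --------------------------------------------------------------------------

#: slope of a perfectly doubling reaction, −1/log10(2)
PERFECT_SLOPE = -3.321928094887362
#: default intercept placing the 5e-9..5e-15 g/μL dilution series at Ct 11-31
DEFAULT_INTERCEPT = -16.5


def copies_to_conc(copies: float, template_bp: int) -> float:
    """Template mass (g, per-μL convention) holding ``copies`` gene copies."""
    return copies * template_bp * BP_MOLAR_MASS / AVOGADRO


def gen_standards(
    slope: float = PERFECT_SLOPE,
    intercept: float = DEFAULT_INTERCEPT,
    concs: Sequence[float] = tuple(5.0 * 10.0 ** (-e) for e in range(9, 16)),
    replicates: int = 3,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[CurvePoint]:
    """Dilution-series standards with Gaussian Ct noise.

    The default series spans 5×10⁻⁹ … 5×10⁻¹⁵ g/μL in decade steps, the
    range of a genomic-DNA standard curve.
    """
    rng = np.random.default_rng(seed)
    points = []
    for conc in concs:
        for rep in range(replicates):
            ct = intercept + slope * np.log10(conc)
            if noise_sd:
                ct += rng.normal(0.0, noise_sd)
            points.append(CurvePoint(conc, float(ct), rep))
    return points


def gen_ct(
    copies: Mapping[str, float],
    template_bp: int = 133,
    slope: float = PERFECT_SLOPE,
    intercept: float = DEFAULT_INTERCEPT,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> dict[str, float]:
    """Ct value per sample from known copy numbers under the given curve."""
    rng = np.random.default_rng(seed)
    out = {}
    for sample, n_copies in copies.items():
        if n_copies <= 0:
            raise ValueError(f"sample {sample!r}: copies must be positive")
        conc = copies_to_conc(n_copies, template_bp)
        ct = intercept + slope * np.log10(conc)
        if noise_sd:
            ct += rng.normal(0.0, noise_sd)
        out[sample] = float(ct)
    return out
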