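"""Curation of the target-gene reference database.

A functional-gene marker is only as good as the database behind it: close
homologs with a different catalytic chemistry (here, D-cysteine
desulfhydrase-like paralogs of ACC deaminase) must be removed before primer
design, or the primers will co-amplify the wrong enzyme family.  The filter
implemented here anchors a set of required catalytic residues (e.g. Lys51,
Ser78, Tyr295, Glu296, Leu322) on a reference protein, maps those residue
positions through a multiple alignment, and discards every sequence whose
amino acid at any mapped column differs from the expectation.

The module also dereplicates entries that are both 100% identical at the
nucleotide level and carry the same species label, and extracts the amplicon
("core") region delimited by a primer pair so that short reads can later be
classified against sequences of matching length.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

GAP = "-"
#: IUPAC nucleotide one-letter codes (uppercase), gaps excluded.
IUPAC_NUC = frozenset("ACGTURYSWKMBDHVN")
STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class SequenceRecord:
    """A labeled sequence: accession-like ``id``, free-text ``taxon``, ``seq``.

    ``kind`` is ``"nucleotide"`` or ``"protein"``.  Nucleotide records may use
    any IUPAC ambiguity code; ``validate`` enforces this.
    """

    id: str
    taxon: str
    seq: str
    kind: str = "nucleotide"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SequenceRecord id must be non-empty")
        if not self.seq:
            raise ValueError(f"SequenceRecord {self.id!r}: empty sequence")
        if self.kind not in ("nucleotide", "protein"):
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.kind == "nucleotide":
            bad = set(self.seq.upper()) - IUPAC_NUC - {GAP}
            if bad:
                pos = next(
                    i for i, c in enumerate(self.seq.upper()) if c in bad
                )
                raise ValueError(
                    f"{self.id!r}: non-IUPAC symbol {self.seq[pos]!r} at position {pos}"
                )

    @property
    def genus(self) -> str:
        """First whitespace-delimited token of the taxon label."""
        return self.taxon.split()[0] if self.taxon.split() else ""


@dataclass(frozen=True)
class Alignment:
    """An ordered collection of equal-length gapped sequences."""

    records: tuple[SequenceRecord, ...]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("empty alignment")
        lengths = {len(r.seq) for r in self.records}
        if len(lengths) != 1:
            raise ValueError(f"ragged alignment: row lengths {sorted(lengths)}")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate ids in alignment")

    @property
    def length(self) -> int:
        return len(self.records[0].seq)

    def __len__(self) -> int:
        return len(self.records)

    def row(self, rec_id: str) -> SequenceRecord:
        for r in self.records:
            if r.id == rec_id:
                return r
        raise KeyError(rec_id)


@dataclass(frozen=True)
class ResiduePolicy:
    """Key-residue requirements anchored on a reference sequence.

    ``required`` holds ``(position, expected)`` pairs where ``position`` is the
    1-based residue index in the *ungapped* reference and ``expected`` a
    standard amino-acid letter.
    """

    reference_id: str
    required: tuple[tuple[int, str], ...]

    def __post_init__(self) -> None:
        positions = [p for p, _ in self.required]
        if positions != sorted(positions) or len(set(positions)) != len(positions):
            raise ValueError("required positions must be strictly increasing")
        for p, aa in self.required:
            if p < 1:
                raise ValueError(f"residue position {p} must be >= 1")
            if aa not in STANDARD_AA:
                raise ValueError(f"{aa!r} is not a standard amino acid")

    @classmethod
    def parse(cls, reference_id: str, spec: str) -> "ResiduePolicy":
        """Parse a compact ``K51,S78,Y295`` style specification."""
        required = []
        for token in spec.split(","):
            m = re.fullmatch(r"([A-Z])(\d+)", token.strip())
            if not m:
                raise ValueError(f"cannot parse residue token {token!r}")
            required.append((int(m.group(2)), m.group(1)))
        required.sort()
        return cls(reference_id, tuple(required))


@dataclass
class CurationReport:
    """Outcome of a curation step.

    ``kept`` and ``discarded`` partition the input ids; each discarded entry
    records the first failed residue position and the observed symbol (``-``
    marks a gap, i.e. a sequence not covering the position).
    ``dereplicated_away`` lists (removed id, retained id) pairs.
    """

    kept: list[str] = field(default_factory=list)
    discarded: list[tuple[str, int, str]] = field(default_factory=list)
    dereplicated_away: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        overlap = set(self.kept) & {d[0] for d in self.discarded}
        if overlap:
            raise ValueError(f"ids both kept and discarded: {sorted(overlap)}")

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("id\tstatus\tdetail\n")
            for i in self.kept:
                fh.write(f"{i}\tkept\t.\n")
            for i, pos, obs in self.discarded:
                status = "discarded_partial" if obs == GAP else "discarded_mismatch"
                fh.write(f"{i}\t{status}\tposition={pos};observed={obs}\n")
            for removed, retained in self.dereplicated_away:
                fh.write(f"{removed}\tdereplicated\tretained={retained}\n")


# --------------------------------------------------------------------------
# FASTA I/O: taxonomy rides in the description after the first whitespace.
# --------------------------------------------------------------------------

def read_fasta(path: str | Path, kind: str = "nucleotide") -> list[SequenceRecord]:
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        taxon = rec.description.split(None, 1)[1] if " " in rec.description else ""
        records.append(SequenceRecord(rec.id, taxon, str(rec.seq).upper(), kind))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    bio = [
        _BioSeqRecord(Seq(r.seq), id=r.id, description=r.taxon)
        for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")  # wraps at 60 columns


# --------------------------------------------------------------------------
# Operations
# --------------------------------------------------------------------------

def translate_cds(record: SequenceRecord, frame: int = 0) -> SequenceRecord:
    """Standard-genetic-code translation of a CDS record.

    The trailing partial codon is dropped; stop codons render as ``*`` and
    codons containing ``N`` as ``X``.  Frame 0 assumes an in-frame CDS, which
    holds for curated database entries; frames 1/2 shift the reading start.
    """
    if record.kind != "nucleotide":
        raise ValueError("translate_cds expects a nucleotide record")
    if frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0, 1 or 2, got {frame}")
    sub = record.seq.upper()[frame:]
    if len(sub) < 3:
        raise ValueError(f"{record.id!r}: fewer than 3 bases after frame offset")
    sub = sub[: len(sub) - len(sub) % 3]
    prot = str(Seq(sub).translate())
    return SequenceRecord(record.id, record.taxon, prot, kind="protein")


def map_reference_columns(aln: Alignment, policy: ResiduePolicy) -> list[int]:
    """Alignment columns (0-based) holding the reference's required residues."""
    ref = aln.row(policy.reference_id)
    wanted = {pos for pos, _ in policy.required}
    col_of: dict[int, int] = {}
    residue = 0
    for col, sym in enumerate(ref.seq):
        if sym != GAP:
            residue += 1
            if residue in wanted:
                col_of[residue] = col
    missing = sorted(wanted - col_of.keys())
    if missing:
        raise ValueError(
            f"reference {policy.reference_id!r} has only {residue} residues; "
            f"required position {missing[0]} not covered"
        )
    return [col_of[pos] for pos, _ in policy.required]


def filter_by_key_residues(aln: Alignment, policy: ResiduePolicy) -> CurationReport:
    """Keep sequences matching every required residue at the mapped columns.

    The reference is kept by construction.  A gap at a required column counts
    as a mismatch: a deleted catalytic residue cannot support activity, and a
    partial sequence not covering the position cannot be certified either (it
    is reported with observed symbol ``-`` so the two cases stay
    distinguishable in the report).
    """
    cols = map_reference_columns(aln, policy)
    report = CurationReport()
    for rec in aln.records:
        failure = None
        for (pos, expected), col in zip(policy.required, cols):
            observed = rec.seq[col].upper()
            if observed != expected:
                failure = (rec.id, pos, observed)
                break
        if failure is None:
            report.kept.append(rec.id)
        else:
            report.discarded.append(failure)
    return report


def dereplicate(records: Sequence[SequenceRecord]) -> CurationReport:
    """Collapse groups that are 100% identical AND share the species label.

    Identical sequences under *different* species labels are all retained:
    they are distinct observations of the marker in distinct taxa.  Within a
    group the lexicographically smallest id is kept (deterministic).
    """
    groups: dict[tuple[str, str], list[SequenceRecord]] = {}
    for rec in records:
        groups.setdefault((rec.seq.upper(), rec.taxon), []).append(rec)
    report = CurationReport()
    for members in groups.values():
        members = sorted(members, key=lambda r: r.id)
        report.kept.append(members[0].id)
        for extra in members[1:]:
            report.dereplicated_away.append((extra.id, members[0].id))
    # preserve input order in `kept` for reproducible output
    order = {r.id: i for i, r in enumerate(records)}
    report.kept.sort(key=order.__getitem__)
    return report


def extract_core_region(
    db: Sequence[SequenceRecord],
    pair,
    max_mismatch: int = 3,
    max_product: int = 300,
) -> tuple[list[SequenceRecord], list[tuple[str, str]]]:
    """Cut the primer-delimited amplicon out of each database sequence.

    Returns ``(core_records, log)`` where ``log`` lists (id, reason) for
    templates omitted because they carry no amplicon or an ambiguous
    (multiple-product) one.  Amplicons are primer-inclusive, 0-based
    half-open on the plus strand; a 25+83+25 construct yields a 133-nt core,
    the product-size convention of the qPCR assay.
    """
    from funcmark.primer_screen import insilico_pcr  # deferred: avoids cycle

    cores: list[SequenceRecord] = []
    log: list[tuple[str, str]] = []
    for rec in db:
        hits = insilico_pcr(pair, rec, max_mm=max_mismatch, max_product=max_product)
        if not hits:
            log.append((rec.id, "no_amplicon"))
        elif len(hits) > 1:
            log.append((rec.id, "ambiguous_multiple_amplicons"))
        else:
            h = hits[0]
            seq = rec.seq[h.start : h.end]
            if h.strand == "-":
                seq = str(Seq(seq).reverse_complement())
            cores.append(SequenceRecord(rec.id, rec.taxon, seq, "nucleotide"))
    return cores, log
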