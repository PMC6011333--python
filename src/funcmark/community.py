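"""Amplicon community profiling: QC, OTUs, classification, diversity.

Mirrors the treatment of functional-gene amplicon libraries: reads are
length- and ambiguity-filtered, dereplicated (optionally dropping singleton
unique sequences, as is common before diversity estimation), clustered into
OTUs at a 3% divergence radius by greedy abundance-ordered centroid
clustering, and classified by best global-alignment identity against a
curated core-region database.  Alpha diversity reports Shannon entropy
(nats), Simpson's index in its dominance form λ = Σ pᵢ² (smaller = more
diverse), and the Chao1 richness estimator; beta diversity is Bray-Curtis.

Subsampling (rarefaction to a common depth) draws reads without replacement,
i.e. multivariate hypergeometric per sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from funcmark.align import identity as _pairwise_identity
from funcmark.evocorr import DistanceMatrix
from funcmark.seqdb import SequenceRecord


@dataclass(frozen=True)
class Read:
    id: str
    seq: str
    sample: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"read {self.id!r}: empty sequence")


@dataclass
class UniqueSeq:
    """A dereplicated sequence with per-sample abundances."""

    seq: str
    abundance: int
    per_sample: dict[str, int]
    rep_id: str  #: lexicographically smallest contributing read id


@dataclass
class OtuTable:
    """Sample × OTU counts with centroid sequences and taxonomy."""

    counts: pd.DataFrame  # index = samples, columns = OTU ids, int
    centroids: dict[str, str]  # OTU id -> representative sequence
    taxonomy: dict[str, tuple[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        missing = set(self.counts.columns) - set(self.centroids)
        if missing:
            raise ValueError(f"OTUs without centroid: {sorted(missing)}")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otus(self) -> list[str]:
        return list(self.counts.columns)


@dataclass(frozen=True)
class DiversityRecord:
    shannon: float  #: H = −Σ pᵢ ln pᵢ, nats
    simpson: float  #: dominance λ = Σ pᵢ² (or 1−λ under the gini form)
    chao1: float
    s_obs: int


# --------------------------------------------------------------------------
# Read QC and dereplication
# --------------------------------------------------------------------------

def filter_reads(
    reads: Iterable[Read], min_len: int = 120, max_len: int = 160
) -> tuple[list[Read], list[tuple[str, str]]]:
    """Keep reads within [min_len, max_len] with no ambiguous base call."""
    kept: list[Read] = []
    rejected: list[tuple[str, str]] = []
    acgt = set("ACGT")
    for r in reads:
        if len(r.seq) < min_len:
            rejected.append((r.id, "too_short"))
        elif len(r.seq) > max_len:
            rejected.append((r.id, "too_long"))
        elif set(r.seq.upper()) - acgt:
            rejected.append((r.id, "ambiguous"))
        else:
            kept.append(r)
    return kept, rejected


def denoise(reads: Sequence[Read], drop_singletons: bool = False) -> list[UniqueSeq]:
    """Dereplicate identical reads; optionally drop singleton uniques.

    Without ``drop_singletons`` every input read stays represented (the
    dereplication is lossless); with it, unique sequences observed exactly
    once across all samples are removed, the usual precaution before
    rarefaction and diversity estimation.  Output is sorted by decreasing
    abundance, ties by representative read id.
    """
    by_seq: dict[str, UniqueSeq] = {}
    for r in reads:
        seq = r.seq.upper()
        u = by_seq.get(seq)
        if u is None:
            by_seq[seq] = UniqueSeq(seq, 1, {r.sample: 1}, r.id)
        else:
            u.abundance += 1
            u.per_sample[r.sample] = u.per_sample.get(r.sample, 0) + 1
            u.rep_id = min(u.rep_id, r.id)
    uniques = list(by_seq.values())
    if drop_singletons:
        uniques = [u for u in uniques if u.abundance > 1]
    return sorted(uniques, key=lambda u: (-u.abundance, u.rep_id))


# --------------------------------------------------------------------------
# OTU clustering and classification
# --------------------------------------------------------------------------

def cluster_otus(
    uniques: Sequence[UniqueSeq],
    radius: float = 0.03,
    identity_fn: Callable[[str, str], float] = _pairwise_identity,
) -> OtuTable:
    """Greedy abundance-ordered centroid clustering at ``1 - radius`` identity.

    Unique sequences are processed in decreasing abundance (ties by
    representative id); each joins the first existing centroid with pairwise
    identity >= 1 − radius, else founds a new OTU.  Deterministic and
    invariant to input order.
    """
    ordered = sorted(uniques, key=lambda u: (-u.abundance, u.rep_id))
    threshold = 1.0 - radius
    centroids: list[str] = []
    otu_ids: list[str] = []
    membership: dict[str, list[UniqueSeq]] = {}
    for u in ordered:
        assigned = None
        for otu_id, cent in zip(otu_ids, centroids):
            if identity_fn(u.seq, cent) >= threshold:
                assigned = otu_id
                break
        if assigned is None:
            assigned = f"OTU_{len(otu_ids) + 1}"
            otu_ids.append(assigned)
            centroids.append(u.seq)
            membership[assigned] = []
        membership[assigned].append(u)

    samples = sorted({s for u in uniques for s in u.per_sample})
    counts = pd.DataFrame(0, index=samples, columns=otu_ids, dtype=int)
    for otu_id, members in membership.items():
        for u in members:
            for sample, c in u.per_sample.items():
                counts.loc[sample, otu_id] += c
    return OtuTable(counts, dict(zip(otu_ids, centroids)))


def classify(
    centroid: str,
    core_db: Sequence[SequenceRecord],
    identity_fn: Callable[[str, str], float] = _pairwise_identity,
) -> tuple[str, float]:
    """Best-hit classification: (genus of best hit, identity).

    Ties in identity break by lexicographically smallest database id.
    """
    if not core_db:
        raise ValueError("empty core database")
    best_rec = None
    best_ident = -1.0
    for rec in sorted(core_db, key=lambda r: r.id):
        ident = identity_fn(centroid, rec.seq)
        if ident > best_ident:
            best_rec, best_ident = rec, ident
    return best_rec.genus, best_ident


def classify_table(table: OtuTable, core_db: Sequence[SequenceRecord]) -> OtuTable:
    """Fill the taxonomy of every OTU in place (and return the table)."""
    for otu_id, cent in table.centroids.items():
        table.taxonomy[otu_id] = classify(cent, core_db)
    return table


# --------------------------------------------------------------------------
# Subsampling and diversity
# --------------------------------------------------------------------------

def subsample(table: OtuTable, depth: int, seed: int | None = None) -> OtuTable:
    """Rarefy every sample to ``depth`` reads without replacement.

    Samples shallower than ``depth`` are excluded with a warning.  Drawing is
    multivariate hypergeometric, reproducible under ``seed``.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    rows = {}
    for sample in table.samples:
        row = table.counts.loc[sample].to_numpy()
        total = int(row.sum())
        if total < depth:
            warnings.warn(
                f"sample {sample!r} has {total} < depth {depth}; excluded",
                stacklevel=2,
            )
            continue
        rows[sample] = rng.multivariate_hypergeometric(row, depth)
    counts = pd.DataFrame.from_dict(
        rows, orient="index", columns=table.counts.columns, dtype=int
    )
    return OtuTable(counts, table.centroids, dict(table.taxonomy))


def alpha_diversity(counts: Sequence[int], simpson_form: str = "dominance") -> DiversityRecord:
    """Shannon (nats), Simpson, and Chao1 for one sample's OTU counts.

    Chao1 = S_obs + n₁²/(2 n₂) with singleton/doubleton counts n₁/n₂; when
    n₂ = 0 the bias-corrected S_obs + n₁(n₁−1)/(2(n₂+1)) is used.
    """
    c = np.asarray(counts, dtype=float)
    c = c[c > 0]
    if c.size == 0 or c.sum() <= 0:
        raise ValueError("empty sample")
    p = c / c.sum()
    shannon = float(-(p * np.log(p)).sum())
    lam = float((p**2).sum())
    if simpson_form == "dominance":
        simpson = lam
    elif simpson_form == "gini":
        simpson = 1.0 - lam
    else:
        raise ValueError(f"unknown simpson_form {simpson_form!r}")
    s_obs = int(c.size)
    n1 = int((c == 1).sum())
    n2 = int((c == 2).sum())
    if n2 > 0:
        chao1 = s_obs + n1 * n1 / (2.0 * n2)
    else:
        chao1 = s_obs + n1 * (n1 - 1) / 2.0
    return DiversityRecord(shannon, simpson, chao1, s_obs)


def rarefaction_curve(
    counts: Sequence[int],
    depths: Sequence[int],
    reps: int = 10,
    seed: int | None = None,
) -> dict[int, float]:
    """Mean observed OTU count at each subsampling depth."""
    c = np.asarray(counts, dtype=int)
    total = int(c.sum())
    rng = np.random.default_rng(seed)
    out: dict[int, float] = {}
    for depth in depths:
        if depth > total:
            raise ValueError(f"depth {depth} exceeds sample total {total}")
        richness = [
            int((rng.multivariate_hypergeometric(c, depth) > 0).sum())
            for _ in range(reps)
        ]
        out[int(depth)] = float(np.mean(richness))
    return out


def bray_curtis(table: OtuTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity between samples."""
    if len(table.samples) < 2:
        raise ValueError("need at least 2 samples")
    mat = table.counts.to_numpy(dtype=float)
    totals = mat.sum(axis=1)
    if (totals == 0).any():
        empty = [s for s, t in zip(table.samples, totals) if t == 0]
        raise ValueError(f"samples with zero total: {empty}")
    n = len(table.samples)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            num = np.abs(mat[i] - mat[j]).sum()
            den = (mat[i] + mat[j]).sum()
            d[i, j] = d[j, i] = num / den
    return DistanceMatrix(tuple(table.samples), d)
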