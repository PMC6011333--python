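"""Distance matrices and their correlation with host phylogeny.

The question asked here: does the evolutionary distance between host plants
predict how different their associated functional groups are?  Host-side
distances come from the Kimura two-parameter (K2P) model on aligned marker
sequences (or are supplied precomputed); community-side distances are
Euclidean differences of qPCR/qRT-PCR quantities or Bray-Curtis
dissimilarities.  The two distance sets are compared by Spearman rank
correlation over matched off-diagonal pairs — either plainly (the classical
usage, which treats the n(n−1)/2 pairwise distances as independent even
though they are not) or with a Mantel-style permutation test that respects
the matrix structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric labeled pairwise distances with a zero diagonal."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} != ({n}, {n})")
        if not np.isfinite(v).all():
            raise ValueError("non-finite distances")
        if not np.allclose(v, v.T):
            raise ValueError("matrix not symmetric")
        if not np.allclose(np.diag(v), 0):
            raise ValueError("diagonal not zero")
        if (v < 0).any():
            raise ValueError("negative distances")
        if len(set(self.labels)) != n:
            raise ValueError("duplicate labels")

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in row-major (label) order."""
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]

    def reordered(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(tuple(labels), self.values[np.ix_(idx, idx)])

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.labels, columns=self.labels).to_csv(
            path, sep="\t"
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(tuple(str(c) for c in df.columns), df.to_numpy(dtype=float))


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p: float
    n: int  #: number of pairwise distances compared
    method: str


# --------------------------------------------------------------------------
# Distances
# --------------------------------------------------------------------------

def k2p_distance(a: str, b: str) -> float:
    """Kimura two-parameter distance between two aligned sequences.

    K = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q) with P and Q the transition and
    transversion fractions over sites where neither sequence has a gap or N.
    Raises on saturation (log arguments ≤ 0) and when no comparable sites
    remain.
    """
    if len(a) != len(b):
        raise ValueError(f"aligned lengths differ: {len(a)} vs {len(b)}")
    valid = transitions = transversions = 0
    for x, y in zip(a.upper(), b.upper()):
        if x not in "ACGT" or y not in "ACGT":
            continue
        valid += 1
        if x == y:
            continue
        same_class = (x in PURINES) == (y in PURINES)
        if same_class:
            transitions += 1
        else:
            transversions += 1
    if valid == 0:
        raise ValueError("no comparable sites (all gapped or ambiguous)")
    P = transitions / valid
    Q = transversions / valid
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise ValueError(
            f"saturated divergence (P={P:.3f}, Q={Q:.3f}): K2P undefined"
        )
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def k2p_matrix(records: Sequence) -> DistanceMatrix:
    """Pairwise K2P distances among aligned records (``.id``/``.seq``)."""
    labels = tuple(r.id for r in records)
    n = len(records)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = k2p_distance(records[i].seq, records[j].seq)
    return DistanceMatrix(labels, d)


def euclidean_pairwise(
    values: Mapping[str, float], log_transform: bool = False
) -> DistanceMatrix:
    """|xᵢ − xⱼ| on raw or log10-transformed per-label quantities."""
    labels = tuple(values)
    if len(labels) < 2:
        raise ValueError("need at least 2 labels")
    x = np.array([values[l] for l in labels], dtype=float)
    if log_transform:
        if (x <= 0).any():
            bad = [l for l, v in zip(labels, x) if v <= 0]
            raise ValueError(f"non-positive values under log transform: {bad}")
        x = np.log10(x)
    d = np.abs(x[:, None] - x[None, :])
    return DistanceMatrix(labels, d)


# --------------------------------------------------------------------------
# Correlation
# --------------------------------------------------------------------------

def distance_correlation(
    dx: DistanceMatrix,
    dy: DistanceMatrix,
    method: str = "spearman",
    permutations: int = 999,
    seed: int | None = None,
) -> CorrelationResult:
    """Spearman correlation between two distance matrices.

    ``method="spearman"`` ranks the matched off-diagonal distances and uses
    the asymptotic two-sided p-value (average ranks on ties) — the classical
    treatment, which ignores the non-independence of pairwise distances.
    ``method="mantel_spearman"`` instead permutes the labels of one matrix,
    with p = (#{|rho_perm| >= |rho|} + 1)/(permutations + 1).
    """
    if set(dx.labels) != set(dy.labels):
        raise ValueError("label sets differ")
    dy = dy.reordered(dx.labels)
    x = dx.condensed()
    y = dy.condensed()
    n_pairs = len(x)
    if n_pairs < 3:
        raise ValueError("need at least 3 pairwise distances")

    rho, p_asym = stats.spearmanr(x, y)
    if method == "spearman":
        return CorrelationResult(float(rho), float(p_asym), n_pairs, method)
    if method != "mantel_spearman":
        raise ValueError(f"unknown method {method!r}")

    rng = np.random.default_rng(seed)
    n = len(dx.labels)
    count = 0
    for _ in range(permutations):
        perm = rng.permutation(n)
        y_perm = dy.values[np.ix_(perm, perm)][np.triu_indices(n, k=1)]
        rho_perm, _ = stats.spearmanr(x, y_perm)
        if abs(rho_perm) >= abs(rho):
            count += 1
    p = (count + 1) / (permutations + 1)
    return CorrelationResult(float(rho), float(p), n_pairs, method)
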