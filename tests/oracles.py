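"""Independent brute-force reference implementations used only by tests.

Each function here re-derives a quantity by the most direct method available
(naive loops, exhaustive enumeration, closed forms), deliberately sharing no
code with the package paths it checks.
"""

from __future__ import annotations

import math
from functools import lru_cache

COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


def rc(seq: str) -> str:
    return "".join(COMP[c] for c in reversed(seq))


# --------------------------------------------------------------------------
# Thermodynamics: direct table-lookup summation
# --------------------------------------------------------------------------

# Unified nearest-neighbor set, written per distinct duplex step; steps not
# listed are read via the reverse complement of the top-strand dinucleotide.
_NN = {
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


def brute_tm(seq: str, conc: float = 1e-6, salt: float = 0.05) -> float:
    """Nearest-neighbor Tm by direct summation over the parameter table."""
    dh = ds = 0.0
    for step in (seq[i : i + 2] for i in range(len(seq) - 1)):
        if step in _NN:
            h, s = _NN[step]
        else:
            h, s = _NN[rc(step)]
        dh += h
        ds += s
    for end in (seq[0], seq[-1]):
        if end in "GC":
            dh += 0.1
            ds += -2.8
        else:
            dh += 2.3
            ds += 4.1
    selfcomp = seq == rc(seq)
    if selfcomp:
        ds += -1.4
    ds += 0.368 * (len(seq) - 1) * math.log(salt)
    ct = conc if selfcomp else conc / 4.0
    return dh * 1000.0 / (ds + 1.9872 * math.log(ct)) - 273.15


def brute_hairpin(seq: str, min_stem: int = 4, min_loop: int = 3):
    """Exhaustive scan over all (stem start, stem start, stem length)."""
    n = len(seq)
    best = 0
    for s in range(1, n // 2 + 1):
        for p in range(n - s + 1):
            for q in range(p + s + min_loop, n - s + 1):
                if seq[p : p + s] == rc(seq[q : q + s]):
                    best = max(best, s)
    return best >= min_stem, best


def brute_dimer(a: str, b: str):
    """Exhaustive antiparallel complementary-run scan over all offsets."""
    best = best3 = 0
    for k in range(1, min(len(a), len(b)) + 1):
        for i in range(len(a) - k + 1):
            for j in range(len(b) - k + 1):
                if a[i : i + k] == rc(b[j : j + k]):
                    best = max(best, k)
                    if i + k == len(a) or j + k == len(b):
                        best3 = max(best3, k)
    return best, best3


# --------------------------------------------------------------------------
# Site scanning and in-silico PCR
# --------------------------------------------------------------------------

def naive_mismatches(primer: str, site: str) -> int:
    return sum(
        1 for p, s in zip(primer, site) if s not in "ACGT" or p != s
    )


def brute_best_site(primer_plus: str, template: str) -> int:
    """Minimum mismatches of a plus-strand footprint over both orientations."""
    best = len(primer_plus) + 1
    for tmpl in (template, rc(template)):
        for off in range(len(tmpl) - len(primer_plus) + 1):
            best = min(best, naive_mismatches(primer_plus, tmpl[off : off + len(primer_plus)]))
    return best


def brute_insilico_pcr(
    fwd: str,
    rev: str,
    template: str,
    max_mm: int = 3,
    max_product: int = 300,
    end3: int = 3,
):
    """All products by naive site-pair scan; (start, end, fmm, rmm, strand)."""
    hits = []
    rsite = rc(rev)
    n = len(template)
    for strand, tmpl in (("+", template), ("-", rc(template))):
        f_sites = []
        for off in range(n - len(fwd) + 1):
            site = tmpl[off : off + len(fwd)]
            if naive_mismatches(fwd, site) <= max_mm and (
                end3 == 0 or site[len(fwd) - end3 :] == fwd[len(fwd) - end3 :]
            ):
                f_sites.append((off, naive_mismatches(fwd, site)))
        r_sites = []
        for off in range(n - len(rsite) + 1):
            site = tmpl[off : off + len(rsite)]
            if naive_mismatches(rsite, site) <= max_mm and (
                end3 == 0 or site[:end3] == rsite[:end3]
            ):
                r_sites.append((off, naive_mismatches(rsite, site)))
        for f_off, f_mm in f_sites:
            for r_off, r_mm in r_sites:
                start, end = f_off, r_off + len(rsite)
                product = end - start
                if r_off < f_off or product > max_product:
                    continue
                if product < max(len(fwd), len(rsite)):
                    continue
                if strand == "-":
                    start, end = n - end, n - start
                hits.append((start, end, f_mm, r_mm, strand))
    return sorted(hits)


# --------------------------------------------------------------------------
# Alignment identity
# --------------------------------------------------------------------------

def enumerate_identity(a: str, b: str):
    """Best (score, matches, −columns) by exhaustive alignment enumeration.

    End gaps (an initial run of gaps confined to one sequence, and likewise
    a final run) are score-free but count as columns.  Exponential — only
    for very short strings.
    """
    best = [None]

    def consider(path):
        # path: list of ('D', match) / ('U',) / ('L',)
        lead = 0
        while lead < len(path) and path[lead][0] == path[0][0] != "D":
            lead += 1
        if path and path[0][0] == "D":
            lead = 0
        trail = 0
        while trail < len(path) - lead and path[-1 - trail][0] == path[-1][0] != "D":
            trail += 1
        if path and path[-1][0] == "D":
            trail = 0
        score = matches = 0
        for idx, move in enumerate(path):
            if move[0] == "D":
                score += 1 if move[1] else 0
                matches += 1 if move[1] else 0
            elif idx >= lead and idx < len(path) - trail:
                score -= 1
        key = (score, matches, -len(path))
        if best[0] is None or key > best[0]:
            best[0] = key

    n, m = len(a), len(b)

    def walk(i, j, path):
        if i == n and j == m:
            consider(path)
            return
        if i < n and j < m:
            walk(i + 1, j + 1, path + [("D", a[i] == b[j])])
        if i < n:
            walk(i + 1, j, path + [("U",)])
        if j < m:
            walk(i, j + 1, path + [("L",)])

    walk(0, 0, [])
    s, t, negc = best[0]
    return s, t, -negc


def dp_identity_ref(a: str, b: str) -> float:
    """Reference identity via a suffix-recursion DP (independent structure)."""
    n, m = len(a), len(b)

    @lru_cache(maxsize=None)
    def suffix(i, j):
        if i == n:
            return (0, 0, -(m - j))  # free trailing gaps in a
        if j == m:
            return (0, 0, -(n - i))
        ds, dt, dc = suffix(i + 1, j + 1)
        match = a[i] == b[j]
        cand = (ds + (1 if match else 0), dt + (1 if match else 0), dc - 1)
        us, ut, uc = suffix(i + 1, j)
        cand = max(cand, (us - 1, ut, uc - 1))
        ls, lt, lc = suffix(i, j + 1)
        cand = max(cand, (ls - 1, lt, lc - 1))
        return cand

    best = None
    for i in range(n + 1):
        s, t, c = suffix(i, 0)
        key = (s, t, c - i)  # free leading gaps in b side: i columns
        best = key if best is None else max(best, key)
    for j in range(m + 1):
        s, t, c = suffix(0, j)
        key = (s, t, c - j)
        best = key if best is None else max(best, key)
    suffix.cache_clear()
    s, t, negc = best
    return t / -negc if negc else 1.0


def brute_classify(centroid: str, db):
    """Best-hit genus by exhaustive scan with the reference identity."""
    best = None
    for rec in db:
        ident = dp_identity_ref(centroid, rec.seq)
        key = (-ident, rec.id)
        if best is None or key < best[0]:
            best = (key, rec.taxon.split()[0], ident)
    return best[1], best[2]


def brute_cluster(seq_abund_id, radius=0.03):
    """Greedy clustering re-run with the reference identity.

    ``seq_abund_id``: iterable of (seq, abundance, rep_id).  Returns the list
    of (centroid sequence, member rep_ids) in founding order.
    """
    ordered = sorted(seq_abund_id, key=lambda x: (-x[1], x[2]))
    clusters = []
    for seq, _, rep in ordered:
        for cent, members in clusters:
            if dp_identity_ref(seq, cent) >= 1 - radius:
                members.append(rep)
                break
        else:
            clusters.append((seq, [rep]))
    return clusters


# --------------------------------------------------------------------------
# Diversity / statistics closed forms
# --------------------------------------------------------------------------

def expected_richness(counts, depth: int) -> float:
    """Hypergeometric expectation of observed OTUs at a subsampling depth."""
    N = sum(counts)
    total = 0.0
    for ni in counts:
        if ni == 0:
            continue
        total += 1.0 - math.comb(N - ni, depth) / math.comb(N, depth)
    return total


def rank_then_pearson(x, y) -> float:
    """Spearman rho as Pearson correlation of average ranks."""
    import numpy as np
    from scipy.stats import rankdata

    rx, ry = rankdata(x), rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])
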