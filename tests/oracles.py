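"""Independent brute-force oracles used to validate the implementation.

Everything here is written from the definitions, deliberately without
reusing the package's lookup tables or vectorized paths: NG86 counting in
plain Python over codon strings, the empty-circumsphere test by direct
linear algebra over all 4-subsets, and the exact Wilcoxon rank-sum null
by enumeration of all group assignments.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

# ---------------------------------------------------------------------------
# genetic code (standard table, written out independently)

_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


class OracleSaturated(Exception):
    pass


def _codon_sites(codon: str) -> tuple[float, float]:
    """(nonsyn sites, syn sites): per position, the fraction of the three
    alternative nucleotides that preserve the amino acid is synonymous;
    changes producing stop codons are nonsynonymous."""
    aa = _CODE[codon]
    syn = 0.0
    for pos in range(3):
        for alt in "ACGT":
            if alt == codon[pos]:
                continue
            mutated = codon[:pos] + alt + codon[pos + 1 :]
            if _CODE[mutated] == aa:
                syn += 1.0 / 3.0
    return 3.0 - syn, syn


def _pair_differences(c1: str, c2: str) -> tuple[float, float]:
    """(nonsyn, syn) differences averaged over all minimal pathways,
    excluding pathways through intermediate stop codons (falling back to
    all pathways when every one is blocked)."""
    diff = [p for p in range(3) if c1[p] != c2[p]]
    if not diff:
        return 0.0, 0.0

    def walk(order, allow_stops):
        cur = c1
        nd = sd = 0.0
        for p in order:
            nxt = cur[:p] + c2[p] + cur[p + 1 :]
            if _CODE[nxt] == "*" and nxt != c2 and not allow_stops:
                return None
            if _CODE[nxt] == _CODE[cur]:
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        return nd, sd

    results = [walk(o, False) for o in itertools.permutations(diff)]
    results = [r for r in results if r is not None]
    if not results:
        results = [walk(o, True) for o in itertools.permutations(diff)]
    nd = sum(r[0] for r in results) / len(results)
    sd = sum(r[1] for r in results) / len(results)
    return nd, sd


def ng86_dn_ds(seq_a: str, seq_b: str) -> dict:
    """Brute-force NG86 + Jukes-Cantor on two gap-free coding sequences."""
    assert len(seq_a) == len(seq_b) and len(seq_a) % 3 == 0
    codons_a = [seq_a[i : i + 3] for i in range(0, len(seq_a), 3)]
    codons_b = [seq_b[i : i + 3] for i in range(0, len(seq_b), 3)]
    n = s = nd = sd = 0.0
    for ca, cb in zip(codons_a, codons_b):
        na, sa = _codon_sites(ca)
        nb, sb = _codon_sites(cb)
        n += (na + nb) / 2.0
        s += (sa + sb) / 2.0
        d_n, d_s = _pair_differences(ca, cb)
        nd += d_n
        sd += d_s
    pn = nd / n if n else 0.0
    ps = sd / s if s else 0.0
    if pn >= 0.75 or ps >= 0.75:
        raise OracleSaturated
    dn = -0.75 * math.log(1.0 - 4.0 * pn / 3.0)
    ds = -0.75 * math.log(1.0 - 4.0 * ps / 3.0)
    return {"dn": dn, "ds": ds, "n": n, "s": s, "nd": nd, "sd": sd}


# ---------------------------------------------------------------------------
# Delaunay / circumsphere


def circumsphere(quad: np.ndarray) -> tuple[np.ndarray, float]:
    """Center and radius of the sphere through 4 points (linear solve)."""
    a = quad[0]
    m = 2.0 * (quad[1:] - a)
    b = (quad[1:] ** 2).sum(axis=1) - (a**2).sum()
    center = np.linalg.solve(m, b)
    return center, float(np.linalg.norm(quad[0] - center))


def simplex_has_empty_circumsphere(
    points: np.ndarray, simplex: np.ndarray, tol: float = 1e-7
) -> bool:
    """True if no other point lies strictly inside the circumsphere."""
    quad = points[simplex]
    try:
        center, radius = circumsphere(quad)
    except np.linalg.LinAlgError:
        return False
    others = np.setdiff1d(np.arange(len(points)), simplex)
    if others.size == 0:
        return True
    dists = np.linalg.norm(points[others] - center, axis=1)
    return bool(np.all(dists >= radius * (1.0 - tol)))


# ---------------------------------------------------------------------------
# exact Wilcoxon rank-sum by enumeration


def exact_rank_sum_p(sample_a, sample_b) -> float:
    """Two-sided exact Mann-Whitney p by enumerating all group assignments.

    Valid only for tie-free pooled samples. p = 2 * min(P(U <= u), P(U >= u)),
    capped at 1, matching the usual exact two-sided convention.
    """
    a = list(sample_a)
    b = list(sample_b)
    pooled = sorted(a + b)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    n_a = len(a)
    rank = {v: i + 1 for i, v in enumerate(pooled)}
    u_obs = sum(rank[v] for v in a) - n_a * (n_a + 1) / 2.0
    us = []
    for combo in itertools.combinations(range(len(pooled)), n_a):
        u = sum(c + 1 for c in combo) - n_a * (n_a + 1) / 2.0
        us.append(u)
    us = np.array(us)
    p_le = np.mean(us <= u_obs)
    p_ge = np.mean(us >= u_obs)
    return float(min(1.0, 2.0 * min(p_le, p_ge)))
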