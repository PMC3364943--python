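"""Pairwise dN/dS estimation on concatenated codon alignments.

Rates are estimated by Nei-Gojobori (1986) counting: every codon is
apportioned into synonymous and nonsynonymous *sites* (the fraction of the
three possible single-nucleotide changes at each position that preserve the
amino acid), codon-pair *differences* are split into synonymous and
nonsynonymous counts by averaging over all minimal mutational pathways, and
the resulting proportions pN and pS are corrected for multiple hits with the
Jukes-Cantor distance d = -(3/4) ln(1 - (4/3) p).

Conventions (fixed, documented here because NG86 leaves them open):

* single-nucleotide changes that create a stop codon count as nonsynonymous
  in site counting;
* mutational pathways passing through an intermediate stop codon are
  excluded from the pathway average (if every pathway is blocked, all
  pathways are used);
* sites are averaged over the two sequences.

The module also builds the concatenated alignments the analysis runs on:
back-translation of protein alignments to codon alignments, concatenation of
codon columns by structural category / RSA bin / age class, and the
robustness filters (>=60 aa, dN <= 0.5, dS <= 2, >=50% protein identity).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import log
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

__all__ = [
    "CodonAlignment",
    "RateEstimate",
    "RateError",
    "SaturatedAlignmentError",
    "estimate_dn_ds",
    "backtranslate_alignment",
    "concatenate_by_category",
    "apply_rate_filters",
    "pairwise_identity",
    "write_rate_table",
]

BASES = "TCAG"
CODONS = ["".join(p) for p in itertools.product(BASES, repeat=3)]
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}

_standard = CodonTable.unambiguous_dna_by_id[1]
AA_OF = np.array(
    [_standard.forward_table.get(c, "*") for c in CODONS], dtype="U1"
)
STOP_CODONS = frozenset(_standard.stop_codons)
SENSE_CODON_IDX = np.array([i for i, c in enumerate(CODONS) if c not in STOP_CODONS])


class RateError(ValueError):
    """Invalid input to rate estimation."""


class SaturatedAlignmentError(RateError):
    """Raised when pN or pS >= 3/4 so the Jukes-Cantor distance is undefined."""


def _single_nt_neighbours(idx: int) -> list[int]:
    """The 9 codons one nucleotide change away, in a fixed order."""
    out = []
    digits = [(idx >> 4) & 3, (idx >> 2) & 3, idx & 3]
    for pos in range(3):
        for b in range(4):
            if b == digits[pos]:
                continue
            d = digits.copy()
            d[pos] = b
            out.append((d[0] << 4) | (d[1] << 2) | d[2])
    return out


def _count_sites() -> tuple[np.ndarray, np.ndarray]:
    syn = np.zeros(64)
    for i in range(64):
        if AA_OF[i] == "*":
            continue
        s = 0.0
        for j in _single_nt_neighbours(i):
            if AA_OF[j] == AA_OF[i]:  # change to a stop is nonsynonymous
                s += 1.0
        syn[i] = s / 3.0
    return syn, 3.0 - syn


S_SITES, N_SITES = _count_sites()


def _pathway_counts(i: int, j: int) -> tuple[float, float]:
    """(nonsyn, syn) difference counts for one codon pair, pathway-averaged."""
    di = [(i >> 4) & 3, (i >> 2) & 3, i & 3]
    dj = [(j >> 4) & 3, (j >> 2) & 3, j & 3]
    diff_pos = [p for p in range(3) if di[p] != dj[p]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff_pos):
        cur = di.copy()
        nd = sd = 0.0
        blocked = False
        prev = i
        for p in order:
            cur[p] = dj[p]
            nxt = (cur[0] << 4) | (cur[1] << 2) | cur[2]
            if AA_OF[nxt] == "*" and nxt != j:
                blocked = True
                break
            if AA_OF[nxt] == AA_OF[prev]:
                sd += 1.0
            else:
                nd += 1.0
            prev = nxt
        if not blocked:
            paths.append((nd, sd))
    if not paths:  # every pathway crosses a stop codon: fall back to all
        for order in itertools.permutations(diff_pos):
            cur = di.copy()
            nd = sd = 0.0
            prev = i
            for p in order:
                cur[p] = dj[p]
                nxt = (cur[0] << 4) | (cur[1] << 2) | cur[2]
                if AA_OF[nxt] == AA_OF[prev]:
                    sd += 1.0
                else:
                    nd += 1.0
                prev = nxt
            paths.append((nd, sd))
    nd = sum(p[0] for p in paths) / len(paths)
    sd = sum(p[1] for p in paths) / len(paths)
    return nd, sd


def _build_diff_tables() -> tuple[np.ndarray, np.ndarray]:
    nd = np.zeros((64, 64))
    sd = np.zeros((64, 64))
    for i in range(64):
        for j in range(64):
            if AA_OF[i] == "*" or AA_OF[j] == "*":
                continue
            nd[i, j], sd[i, j] = _pathway_counts(i, j)
    return nd, sd


N_DIFFS, S_DIFFS = _build_diff_tables()

_BASE_LOOKUP = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(BASES):
    _BASE_LOOKUP[ord(_b)] = _i
    _BASE_LOOKUP[ord(_b.lower())] = _i


def encode_codons(seq: str) -> np.ndarray:
    """Map a gap-free nucleotide string to an array of codon indices (0..63)."""
    if len(seq) % 3:
        raise RateError(f"sequence length {len(seq)} not divisible by 3")
    raw = _BASE_LOOKUP[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if (raw < 0).any():
        bad = int(np.argmax(raw < 0))
        raise RateError(f"non-ACGT character {seq[bad]!r} at position {bad + 1}")
    trip = raw.reshape(-1, 3)
    return (trip[:, 0] << 4) | (trip[:, 1] << 2) | trip[:, 2]


def decode_codons(idx: np.ndarray) -> str:
    return "".join(CODONS[i] for i in idx)


def translate_codon_indices(idx: np.ndarray) -> str:
    return "".join(AA_OF[idx])


@dataclass
class CodonAlignment:
    """A pair of aligned coding sequences with per-column provenance."""

    seq_a: str
    seq_b: str
    columns: pd.DataFrame | None = None  # one row per codon column

    def __post_init__(self) -> None:
        if len(self.seq_a) != len(self.seq_b):
            raise RateError("aligned sequences differ in length")
        if len(self.seq_a) % 3:
            raise RateError("alignment length not divisible by 3")

    @property
    def n_codons(self) -> int:
        return len(self.seq_a) // 3

    def drop_gap_columns(self) -> "CodonAlignment":
        """Remove codon columns containing a gap in either sequence."""
        a = [self.seq_a[i : i + 3] for i in range(0, len(self.seq_a), 3)]
        b = [self.seq_b[i : i + 3] for i in range(0, len(self.seq_b), 3)]
        keep = [k for k in range(len(a)) if "-" not in a[k] and "-" not in b[k]]
        cols = self.columns.iloc[keep].reset_index(drop=True) if self.columns is not None else None
        return CodonAlignment(
            "".join(a[k] for k in keep), "".join(b[k] for k in keep), cols
        )


@dataclass
class RateEstimate:
    """NG86 counting result for one concatenated alignment."""

    dn: float
    ds: float
    n_sites: float
    s_sites: float
    n_diffs: float
    s_diffs: float
    n_codons: int

    @property
    def omega(self) -> float | None:
        """dN/dS, or None when dS = 0 (undefined)."""
        if self.ds > 0:
            return self.dn / self.ds
        return None


def jukes_cantor(p: float) -> float:
    """Multiple-hit correction d = -(3/4) ln(1 - (4/3) p); requires p < 3/4."""
    if p >= 0.75:
        raise SaturatedAlignmentError(f"proportion {p:.4f} >= 3/4")
    return -0.75 * log(1.0 - (4.0 / 3.0) * p) + 0.0  # +0.0 normalizes -0.0


def estimate_from_indices(idx_a: np.ndarray, idx_b: np.ndarray) -> RateEstimate:
    """NG86+JC estimate from codon-index arrays (fast path for large data)."""
    if idx_a.shape != idx_b.shape:
        raise RateError("index arrays differ in length")
    if idx_a.size == 0:
        raise RateError("empty alignment")
    for name, idx in (("a", idx_a), ("b", idx_b)):
        if (AA_OF[idx] == "*").any():
            pos = int(np.argmax(AA_OF[idx] == "*"))
            raise RateError(f"internal stop codon in sequence {name} at codon {pos + 1}")
    n = 0.5 * (N_SITES[idx_a].sum() + N_SITES[idx_b].sum())
    s = 0.5 * (S_SITES[idx_a].sum() + S_SITES[idx_b].sum())
    nd = N_DIFFS[idx_a, idx_b].sum()
    sd = S_DIFFS[idx_a, idx_b].sum()
    pn = nd / n if n > 0 else 0.0
    ps = sd / s if s > 0 else 0.0
    return RateEstimate(
        dn=jukes_cantor(pn),
        ds=jukes_cantor(ps),
        n_sites=n,
        s_sites=s,
        n_diffs=nd,
        s_diffs=sd,
        n_codons=int(idx_a.size),
    )


def estimate_dn_ds(alignment: CodonAlignment) -> RateEstimate:
    """Estimate dN, dS and dN/dS for a gap-free codon alignment.

    Raises :class:`SaturatedAlignmentError` when pN or pS reaches 3/4
    (the Jukes-Cantor correction diverges).
    """
    if "-" in alignment.seq_a or "-" in alignment.seq_b:
        raise RateError("alignment contains gaps; call drop_gap_columns() first")
    return estimate_from_indices(
        encode_codons(alignment.seq_a), encode_codons(alignment.seq_b)
    )


def backtranslate_alignment(
    protein_alignment: tuple[str, str], cds_a: str, cds_b: str
) -> CodonAlignment:
    """Expand an aligned protein pair to the codon level.

    Each aligned residue column becomes the source codon triplet; protein
    gaps become 3-column codon gaps. The CDSs must translate exactly to the
    ungapped protein rows.
    """
    prot_a, prot_b = protein_alignment
    if len(prot_a) != len(prot_b):
        raise RateError("protein alignment rows differ in length")
    out = []
    for name, prot, cds in (("a", prot_a, cds_a), ("b", prot_b, cds_b)):
        ungapped = prot.replace("-", "")
        if len(cds) != 3 * len(ungapped):
            raise RateError(f"CDS {name} length {len(cds)} != 3 x {len(ungapped)} residues")
        translated = translate_codon_indices(encode_codons(cds))
        for k, (expect, got) in enumerate(zip(ungapped, translated)):
            if expect != got:
                raise RateError(
                    f"CDS {name} translation mismatch at residue {k + 1}: "
                    f"{got!r} != {expect!r}"
                )
        row = []
        i = 0
        for aa in prot:
            if aa == "-":
                row.append("---")
            else:
                row.append(cds[3 * i : 3 * i + 3])
                i += 1
        out.append("".join(row))
    return CodonAlignment(out[0], out[1])


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Fraction of exact matches over aligned non-gap columns."""
    if len(seq_a) != len(seq_b):
        raise RateError("aligned sequences differ in length")
    pairs = [(a, b) for a, b in zip(seq_a, seq_b) if a != "-" and b != "-"]
    if not pairs:
        return 0.0
    return sum(a == b for a, b in pairs) / len(pairs)


def concatenate_by_category(
    features: dict[str, list],
    alignments: dict[str, CodonAlignment],
    grouping: str,
    ages: dict[str, str] | None = None,
    min_identity: float = 0.5,
) -> dict:
    """Concatenate codon columns sharing a structural category.

    ``grouping`` is one of ``ss_category``, ``exposure`` or ``rsa_bin``;
    passing ``ages`` additionally splits each group by the structure's age
    class (keys become ``(category, age)`` tuples). Alignment columns are
    taken at each residue's feature position, so positions dropped during
    the feature join (structure/protein disagreement) contribute nothing.
    Source pairs whose protein identity is below ``min_identity`` are
    excluded entirely. Empty groups are omitted.
    """
    if grouping not in ("ss_category", "exposure", "rsa_bin"):
        raise RateError(f"unknown grouping {grouping!r}")
    parts_a: dict = {}
    parts_b: dict = {}
    meta: dict = {}
    for sid, feats in features.items():
        aln = alignments.get(sid)
        if aln is None:
            continue
        prot_a = translate_codon_indices(encode_codons(aln.seq_a))
        prot_b = translate_codon_indices(encode_codons(aln.seq_b))
        if pairwise_identity(prot_a, prot_b) < min_identity:
            continue
        for f in feats:
            key = getattr(f, grouping)
            if ages is not None:
                key = (key, ages[sid])
            i = 3 * (f.position - 1)
            parts_a.setdefault(key, []).append(aln.seq_a[i : i + 3])
            parts_b.setdefault(key, []).append(aln.seq_b[i : i + 3])
            meta.setdefault(key, []).append((sid, f.position))
    groups = {}
    for key in parts_a:
        cols = pd.DataFrame(meta[key], columns=["structure", "position"])
        groups[key] = CodonAlignment("".join(parts_a[key]), "".join(parts_b[key]), cols)
    return groups


def apply_rate_filters(
    estimate: RateEstimate,
    aa_length: int,
    max_dn: float = 0.5,
    max_ds: float = 2.0,
    min_length: int = 60,
) -> tuple[bool, str]:
    """Robustness filters on a rate estimate.

    Discards estimates from alignments shorter than 60 amino acids
    (unreliable), with dN > 0.5 (doubtful homology) or dS > 2 (saturation).
    Returns ``(retained, reason)``.
    """
    if aa_length < min_length:
        return False, "length"
    if estimate.dn > max_dn:
        return False, "dN"
    if estimate.ds > max_ds:
        return False, "dS"
    return True, ""


def write_rate_table(rows: list[dict], path: str | Path) -> pd.DataFrame:
    """Write a per-group rate TSV (group, n codons, dN, dS, omega, status)."""
    table = pd.DataFrame(rows)
    table.to_csv(path, sep="\t", index=False)
    return table
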