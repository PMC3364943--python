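"""Coarse-grained four-body knowledge-based stability potential.

Each protein chain is reduced to its alpha-carbon point set and Delaunay-
tessellated; every retained tetrahedron (all six edges within a cutoff,
8.5 A by default, suppressing artifactual surface-spanning simplices)
contributes its unordered amino-acid quadruplet. Training counts quadruplet
compositions over a corpus and scores each of the C(20+4-1, 4) = 8,855
compositions by the log-odds

    score(q) = ln( f_q / p_q )

where f_q is the (add-one smoothed) observed quadruplet frequency and p_q
the multinomial expectation from the corpus amino-acid frequencies,
including the multiset multiplicity factor 4!/(k_1! ... k_m!).

A (conformation, sequence) pair is scored as

    delta_G = - sum over retained simplices of score(quadruplet)

so lower delta_G means greater compatibility of sequence with structure,
i.e. greater predicted stability. The sequence may differ from the native
one: mutants are scored on the fixed native conformation.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass
from math import lgamma, log
from pathlib import Path

import numpy as np
from scipy.spatial import Delaunay, QhullError

from .features import Structure
from .synthetic import AA_ALPHABET

__all__ = [
    "Tessellation",
    "PotentialModel",
    "StabilityScore",
    "TessellationError",
    "tessellate",
    "train_potential",
    "score_structure",
    "save_model",
    "load_model",
    "N_COMPOSITIONS",
]

AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}
N_AA = 20

#: all unordered quadruplet compositions of 20 amino acids
COMPOSITIONS: list[tuple[int, int, int, int]] = list(
    itertools.combinations_with_replacement(range(N_AA), 4)
)
N_COMPOSITIONS = len(COMPOSITIONS)  # C(23, 4) = 8855
COMPOSITION_INDEX = {c: i for i, c in enumerate(COMPOSITIONS)}

# dense map from a sorted quadruplet packed in base 20 to composition index,
# for vectorized scoring
_PACKED_TO_COMP = np.full(N_AA**4, -1, dtype=np.int64)
for _i, (_a, _b, _c, _d) in enumerate(COMPOSITIONS):
    _PACKED_TO_COMP[((_a * N_AA + _b) * N_AA + _c) * N_AA + _d] = _i


class TessellationError(ValueError):
    pass


@dataclass
class Tessellation:
    """Delaunay tetrahedra of an alpha-carbon point set, edge-filtered."""

    simplices: np.ndarray  # (n, 4) residue indices, each row sorted
    max_edge: np.ndarray  # (n,) longest edge per retained simplex, A
    cutoff: float

    def __len__(self) -> int:
        return len(self.simplices)


@dataclass
class PotentialModel:
    """Log-odds score table over quadruplet compositions plus metadata."""

    scores: np.ndarray  # (8855,)
    counts: np.ndarray  # (8855,) raw observed counts
    n_structures: int
    n_simplices: int
    pseudocount: float
    cutoff: float
    aa_frequencies: np.ndarray  # (20,)

    def score_of(self, quadruplet: str) -> float:
        """Score of an unordered amino-acid quadruplet, e.g. ``"ACDE"``."""
        key = tuple(sorted(AA_INDEX[a] for a in quadruplet))
        return float(self.scores[COMPOSITION_INDEX[key]])


@dataclass
class StabilityScore:
    delta_g: float
    n_simplices: int


def _max_edges(points: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    pairs = list(itertools.combinations(range(4), 2))
    edges = np.stack(
        [
            np.linalg.norm(points[simplices[:, i]] - points[simplices[:, j]], axis=1)
            for i, j in pairs
        ]
    )
    return edges.max(axis=0)


def tessellate(
    structure: Structure | np.ndarray, cutoff: float = 8.5
) -> Tessellation:
    """Delaunay tetrahedralization of the alpha-carbon points.

    Simplices with any edge longer than ``cutoff`` are discarded. Exactly
    degenerate point sets get one retry after a deterministic 1e-6 A
    jitter (seeded from the structure id).
    """
    if isinstance(structure, Structure):
        points = structure.ca_coords()
        sid = structure.id
    else:
        points = np.asarray(structure, dtype=float)
        sid = "points"
    if len(points) < 4:
        raise TessellationError(f"need >= 4 residues, got {len(points)}")
    try:
        tri = Delaunay(points)
    except QhullError:
        # a truly flat point set stays degenerate no matter the jitter;
        # jitter only rescues precision failures on genuinely 3-D sets
        centered = points - points.mean(axis=0)
        if np.linalg.matrix_rank(centered, tol=1e-9) < 3:
            raise TessellationError(
                f"{sid}: degenerate point configuration (coplanar point set)"
            ) from None
        rng = np.random.default_rng(zlib.crc32(sid.encode()))
        jittered = points + rng.normal(0.0, 1e-6, size=points.shape)
        try:
            tri = Delaunay(jittered)
        except QhullError:
            raise TessellationError(
                f"{sid}: degenerate point configuration (still flat after jitter)"
            ) from None
    simplices = np.sort(tri.simplices, axis=1)
    max_edge = _max_edges(points, simplices)
    keep = max_edge <= cutoff
    return Tessellation(simplices[keep], max_edge[keep], cutoff)


def _sequence_indices(sequence: str) -> np.ndarray:
    try:
        return np.array([AA_INDEX[a] for a in sequence], dtype=np.int64)
    except KeyError as exc:
        raise TessellationError(f"nonstandard amino acid {exc.args[0]!r}") from None


def _composition_ids(seq_idx: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    quad = np.sort(seq_idx[simplices], axis=1)
    packed = ((quad[:, 0] * N_AA + quad[:, 1]) * N_AA + quad[:, 2]) * N_AA + quad[:, 3]
    return _PACKED_TO_COMP[packed]


def _log_multinomial_expectation(aa_freq: np.ndarray) -> np.ndarray:
    """log p_q for every composition under independent draws from aa_freq."""
    log_freq = np.log(np.maximum(aa_freq, 1e-300))
    out = np.empty(N_COMPOSITIONS)
    lg4 = lgamma(5.0)  # ln 4!
    for i, comp in enumerate(COMPOSITIONS):
        mult = np.bincount(np.array(comp), minlength=N_AA)
        log_coeff = lg4 - sum(lgamma(k + 1.0) for k in mult if k)
        out[i] = log_coeff + float(mult @ log_freq)
    return out


def train_potential(
    training_structures: list[Structure],
    cutoff: float = 8.5,
    pseudocount: float = 1.0,
) -> PotentialModel:
    """Train the four-body log-odds table on a structure corpus.

    For each composition q: score(q) = ln(f_q / p_q), with f_q the add-one
    smoothed observed frequency of q among retained simplices and p_q the
    multinomial expectation from the corpus amino-acid frequencies.
    """
    if not training_structures:
        raise TessellationError("empty training corpus")
    counts = np.zeros(N_COMPOSITIONS)
    aa_counts = np.zeros(N_AA)
    n_simplices = 0
    for st in training_structures:
        tess = tessellate(st, cutoff=cutoff)
        seq_idx = _sequence_indices(st.sequence)
        comp_ids = _composition_ids(seq_idx, tess.simplices)
        counts += np.bincount(comp_ids, minlength=N_COMPOSITIONS)
        aa_counts += np.bincount(seq_idx, minlength=N_AA)
        n_simplices += len(tess)
    aa_freq = aa_counts / aa_counts.sum()
    f_q = (counts + pseudocount) / (counts.sum() + pseudocount * N_COMPOSITIONS)
    log_p_q = _log_multinomial_expectation(aa_freq)
    scores = np.log(f_q) - log_p_q
    return PotentialModel(
        scores=scores,
        counts=counts,
        n_structures=len(training_structures),
        n_simplices=n_simplices,
        pseudocount=pseudocount,
        cutoff=cutoff,
        aa_frequencies=aa_freq,
    )


def score_structure(
    structure: Structure | Tessellation,
    sequence: str,
    model: PotentialModel,
) -> StabilityScore:
    """delta_G of a sequence threaded on a (fixed) conformation.

    ``structure`` may be a pre-computed :class:`Tessellation` to avoid
    re-tessellating when scoring many sequences on one conformation.
    """
    if isinstance(structure, Tessellation):
        tess = structure
        n_res = int(structure.simplices.max()) + 1 if len(structure) else 0
        if len(sequence) < n_res:
            raise TessellationError(
                f"sequence length {len(sequence)} shorter than tessellated chain"
            )
    else:
        if len(sequence) != len(structure):
            raise TessellationError(
                f"sequence length {len(sequence)} != structure length {len(structure)}"
            )
        tess = tessellate(structure, cutoff=model.cutoff)
    seq_idx = _sequence_indices(sequence)
    comp_ids = _composition_ids(seq_idx, tess.simplices)
    delta_g = -float(model.scores[comp_ids].sum())
    return StabilityScore(delta_g=delta_g, n_simplices=len(tess))


def save_model(model: PotentialModel, path: str | Path) -> None:
    """Persist the model as a TSV with a metadata header."""
    with open(path, "w") as fh:
        fh.write("# structage four-body potential v1\n")
        fh.write(f"# n_structures\t{model.n_structures}\n")
        fh.write(f"# n_simplices\t{model.n_simplices}\n")
        fh.write(f"# pseudocount\t{model.pseudocount}\n")
        fh.write(f"# cutoff\t{model.cutoff}\n")
        fh.write("# aa_frequencies\t" + ",".join(f"{f:.8e}" for f in model.aa_frequencies) + "\n")
        fh.write("composition\tcount\tscore\n")
        for i, comp in enumerate(COMPOSITIONS):
            key = "".join(AA_ALPHABET[a] for a in comp)
            fh.write(f"{key}\t{model.counts[i]:.0f}\t{model.scores[i]:.10e}\n")


def load_model(path: str | Path) -> PotentialModel:
    meta: dict[str, str] = {}
    counts = np.zeros(N_COMPOSITIONS)
    scores = np.zeros(N_COMPOSITIONS)
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                parts = line[1:].strip().split("\t")
                if len(parts) == 2:
                    meta[parts[0]] = parts[1]
                continue
            if line.startswith("composition"):
                continue
            key, count, score = line.split("\t")
            comp = tuple(sorted(AA_INDEX[a] for a in key))
            i = COMPOSITION_INDEX[comp]
            counts[i] = float(count)
            scores[i] = float(score)
    return PotentialModel(
        scores=scores,
        counts=counts,
        n_structures=int(meta["n_structures"]),
        n_simplices=int(meta["n_simplices"]),
        pseudocount=float(meta["pseudocount"]),
        cutoff=float(meta["cutoff"]),
        aa_frequencies=np.array([float(x) for x in meta["aa_frequencies"].split(",")]),
    )
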