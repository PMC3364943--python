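"""Mutational robustness of the native sequence on its structure.

Robustness is assessed by comparing the native delta_G to a population of
mutant sequences scored on the fixed native conformation:

* per-site scans: every position mutated (one random substitution each),
  recording |delta_delta_G| = |delta_G(native) - delta_G(mutant)|;
* mutant populations: 1000 replicate sequences, each carrying one random
  substitution per 50 (or per 10) residues, giving the Z-score
  Z = (delta_G_native - <delta_G_mut>) / sigma and the rank of the native
  among the mutants (1 = native more stable than every mutant).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import Structure
from .potential import (
    PotentialModel,
    Tessellation,
    _composition_ids,
    _sequence_indices,
    tessellate,
)
from .synthetic import AA_ALPHABET

__all__ = [
    "MutantPopulation",
    "MutationScan",
    "RobustnessError",
    "mutate_sequence",
    "scan_point_mutations",
    "build_mutant_population",
]


class RobustnessError(ValueError):
    pass


@dataclass
class MutationScan:
    """Per-position random single mutants and their |delta_delta_G|."""

    positions: np.ndarray  # 1-based
    mutant_aa: list[str]
    ddg_abs: np.ndarray
    native_dg: float


@dataclass
class MutantPopulation:
    """Native delta_G against a population of multiply-mutated sequences."""

    native_dg: float
    mutant_dgs: np.ndarray
    mutation_rate_denominator: int

    @property
    def z_score(self) -> float:
        """(native - mean) / sd over the mutant population; NaN when sd = 0."""
        sd = float(np.std(self.mutant_dgs, ddof=1))
        if sd == 0.0:
            return float("nan")
        return (self.native_dg - float(np.mean(self.mutant_dgs))) / sd

    @property
    def rank(self) -> int:
        """1 + number of mutants strictly more stable than the native.

        Ties count as less stable than the native, so a native matching
        every mutant exactly still ranks 1.
        """
        return 1 + int(np.sum(self.mutant_dgs < self.native_dg))


def mutate_sequence(
    sequence: str,
    denominator: int,
    rng: np.random.Generator | int,
) -> str:
    """Substitute k = max(1, floor(L/denominator)) distinct positions.

    Positions are uniform without replacement; each mutated residue is
    replaced by a uniformly chosen *different* amino acid.
    """
    if len(sequence) < 1:
        raise RobustnessError("empty sequence")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    k = max(1, len(sequence) // denominator)
    positions = rng.choice(len(sequence), size=k, replace=False)
    seq = list(sequence)
    for p in positions:
        alternatives = [a for a in AA_ALPHABET if a != seq[p]]
        seq[p] = alternatives[rng.integers(0, len(alternatives))]
    return "".join(seq)


def _mutant_matrix(
    seq_idx: np.ndarray,
    denominator: int,
    n_replicates: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """(n_replicates, L) mutated index matrix, same scheme as mutate_sequence."""
    length = seq_idx.size
    k = max(1, length // denominator)
    out = np.tile(seq_idx, (n_replicates, 1))
    for r in range(n_replicates):
        positions = rng.choice(length, size=k, replace=False)
        offsets = rng.integers(1, 20, size=k)  # skip the native residue
        out[r, positions] = (seq_idx[positions] + offsets) % 20
    return out


def _score_many(
    tess: Tessellation, seq_matrix: np.ndarray, model: PotentialModel
) -> np.ndarray:
    """delta_G for each row of a sequence-index matrix on one tessellation."""
    n_aa = 20
    quad = seq_matrix[:, tess.simplices]  # (n, m, 4)
    quad = np.sort(quad, axis=2)
    packed = (
        (quad[..., 0] * n_aa + quad[..., 1]) * n_aa + quad[..., 2]
    ) * n_aa + quad[..., 3]
    from .potential import _PACKED_TO_COMP

    comp = _PACKED_TO_COMP[packed]
    return -model.scores[comp].sum(axis=1)


def scan_point_mutations(
    structure: Structure,
    model: PotentialModel,
    seed: int = 0,
) -> MutationScan:
    """One random single-residue mutant per position on the fixed conformation.

    The mutant amino acid is always different from the native one (forcing
    identity would give ddg_abs = 0 by construction).
    """
    rng = np.random.default_rng(seed)
    tess = tessellate(structure, cutoff=model.cutoff)
    seq_idx = _sequence_indices(structure.sequence)
    native_dg = -float(model.scores[_composition_ids(seq_idx, tess.simplices)].sum())

    # per-position simplex membership, for incremental rescoring
    length = len(seq_idx)
    members: list[list[int]] = [[] for _ in range(length)]
    for s, quad in enumerate(tess.simplices):
        for r in quad:
            members[r].append(s)

    ddg = np.zeros(length)
    mutant_aa: list[str] = []
    for pos in range(length):
        native_aa = seq_idx[pos]
        new = (native_aa + rng.integers(1, 20)) % 20
        mutant_aa.append(AA_ALPHABET[new])
        affected = np.array(members[pos], dtype=np.int64)
        if affected.size == 0:
            ddg[pos] = 0.0
            continue
        old_comp = _composition_ids(seq_idx, tess.simplices[affected])
        seq_idx[pos] = new
        new_comp = _composition_ids(seq_idx, tess.simplices[affected])
        seq_idx[pos] = native_aa
        delta = -(model.scores[new_comp].sum() - model.scores[old_comp].sum())
        ddg[pos] = abs(delta)
    return MutationScan(
        positions=np.arange(1, length + 1),
        mutant_aa=mutant_aa,
        ddg_abs=ddg,
        native_dg=native_dg,
    )


def build_mutant_population(
    structure: Structure,
    model: PotentialModel,
    denominator: int = 50,
    n_replicates: int = 1000,
    seed: int = 0,
) -> MutantPopulation:
    """Score ``n_replicates`` mutant sequences on the native conformation.

    Each mutant carries max(1, floor(L/denominator)) random substitutions
    (positions without replacement, never the native residue). Z-score and
    rank follow from the resulting delta_G population.
    """
    if n_replicates < 2:
        raise RobustnessError(f"n_replicates {n_replicates} < 2")
    if denominator not in (10, 50):
        raise RobustnessError(f"mutation-rate denominator must be 10 or 50, got {denominator}")
    rng = np.random.default_rng(seed)
    tess = tessellate(structure, cutoff=model.cutoff)
    seq_idx = _sequence_indices(structure.sequence)
    native_dg = -float(model.scores[_composition_ids(seq_idx, tess.simplices)].sum())
    mutants = _mutant_matrix(seq_idx, denominator, n_replicates, rng)
    mutant_dgs = _score_many(tess, mutants, model)
    return MutantPopulation(
        native_dg=native_dg,
        mutant_dgs=mutant_dgs,
        mutation_rate_denominator=denominator,
    )
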