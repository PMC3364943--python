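"""Synthetic data with the statistical structure the analysis expects.

Every input the pipeline consumes can be generated here, so the full
analysis is exercisable without any download:

* compact single-chain "protein" structures grown as a collapsed
  self-avoiding walk, with a planted buried hydrophobic core and
  DSSP-style annotations (accessibility and secondary structure) emitted
  directly by the generator;
* orthologous codon sequence pairs in which the per-codon substitution
  probability is ``base_rate + rsa_slope * RSA`` — a linear
  solvent-exposure effect with an age-class-dependent slope and overall
  rate;
* homolog presence/absence hit tables whose phylogenetic width encodes a
  chosen age class;
* decoy sequences/structures for validating the stability potential;
* large vectorized codon datasets (per RSA bin, or per pseudo-structure)
  for the statistical analyses that need many codons per group.

All generators are deterministic under a fixed seed.

The age-class presets encode the study conditions: slopes 0.0025 / 0.003 /
0.006 (eukarya / metazoa / vertebrata) for the RSA effect, overall rates
increasing from old to young, and core fractions decreasing from old to
young (younger structures more exposed).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import rates
from .features import Structure, Residue, ResidueFeature, reference_asa
from .homology import DEFAULT_SPECIES_GROUPS, AgeClass, HitRecord
from .rates import (
    AA_OF,
    CODONS,
    SENSE_CODON_IDX,
    CodonAlignment,
    _single_nt_neighbours,
    decode_codons,
    estimate_from_indices,
)

__all__ = [
    "SimulationConfig",
    "AGE_PRESETS",
    "InvalidConfigError",
    "generate_toy_structure",
    "generate_ortholog_pair",
    "generate_homolog_profile",
    "generate_decoy_set",
    "generate_binned_codon_data",
    "simulate_structure_rate_samples",
    "write_pdb",
    "write_dssp",
    "write_fasta",
    "write_blast_tab",
]

HYDROPHOBIC = "AVLIMFWC"
POLAR = "RNDQEGHKPSTY"
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


class InvalidConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for one age class / dataset.

    ``base_rate`` is the expected number of substitutions per codon for a
    fully buried residue (RSA = 0); ``rsa_slope`` adds to the per-codon
    substitution probability linearly in RSA. ``nonsyn_fraction`` is the
    probability that a planted substitution is nonsynonymous (0.75 is
    close to the random single-nucleotide expectation).
    """

    chain_length: int = 150
    core_fraction: float = 0.40
    age_class: AgeClass = AgeClass.eukarya
    base_rate: float = 0.02
    rsa_slope: float = 0.0025
    seed: int = 0
    nonsyn_fraction: float = 0.75

    def __post_init__(self) -> None:
        if self.chain_length < 10:
            raise InvalidConfigError(f"chain_length {self.chain_length} < 10")
        if not 0.0 <= self.core_fraction <= 1.0:
            raise InvalidConfigError(f"core_fraction {self.core_fraction} outside [0, 1]")
        if self.base_rate < 0 or self.rsa_slope < 0:
            raise InvalidConfigError("base_rate and rsa_slope must be nonnegative")
        if not 0.0 <= self.nonsyn_fraction <= 1.0:
            raise InvalidConfigError("nonsyn_fraction outside [0, 1]")


#: Study conditions per age class (see module docstring).
AGE_PRESETS: dict[AgeClass, SimulationConfig] = {
    AgeClass.eukarya: SimulationConfig(
        age_class=AgeClass.eukarya, base_rate=0.02, rsa_slope=0.0025, core_fraction=0.45
    ),
    AgeClass.metazoa: SimulationConfig(
        age_class=AgeClass.metazoa, base_rate=0.03, rsa_slope=0.003, core_fraction=0.40
    ),
    AgeClass.vertebrata: SimulationConfig(
        age_class=AgeClass.vertebrata, base_rate=0.05, rsa_slope=0.006, core_fraction=0.34
    ),
    AgeClass.mammalia: SimulationConfig(
        age_class=AgeClass.mammalia, base_rate=0.06, rsa_slope=0.007, core_fraction=0.30
    ),
}


def config_for_age(age: AgeClass, **overrides) -> SimulationConfig:
    return replace(AGE_PRESETS[age], **overrides)


@dataclass
class SyntheticStructure(Structure):
    """A generated chain carrying its planted annotations.

    ``asa`` holds the per-residue solvent accessibility (A^2) the generator
    plants (emitted as the DSSP ACC column); ``ss_letters`` the DSSP class
    letters; ``core_mask`` flags the residues designated as hydrophobic
    core.
    """

    asa: np.ndarray = field(default_factory=lambda: np.array([]))
    ss_letters: list[str] = field(default_factory=list)
    core_mask: np.ndarray = field(default_factory=lambda: np.array([], dtype=bool))
    rsa_planted: np.ndarray = field(default_factory=lambda: np.array([]))


# ---------------------------------------------------------------------------
# chain geometry


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.array([1.0, 0.0, 0.0])


def _grow_chain(length: int, rng: np.random.Generator) -> np.ndarray:
    """Collapsed self-avoiding walk: compact globule, CA-CA ~= 3.8 A."""
    target_radius = 3.3 * length ** (1.0 / 3.0)
    coords = np.zeros((length, 3))
    direction = _unit(rng.normal(size=3))
    for i in range(1, length):
        pos = coords[i - 1]
        placed = False
        for relax, attempts in ((3.55, 60), (3.2, 60)):
            best, best_sep = None, -1.0
            for _ in range(attempts):
                step = float(np.clip(3.8 + rng.normal(0.0, 0.07), 3.65, 3.95))
                r = np.linalg.norm(pos)
                pull = 1.5 * (r / target_radius) ** 2 if r > 0 else 0.0
                d = _unit(
                    0.4 * direction + rng.normal(size=3) - pull * _unit(pos)
                )
                cand = pos + step * d
                if i > 1:
                    sep = float(np.min(np.linalg.norm(coords[: i - 1] - cand, axis=1)))
                else:
                    sep = np.inf
                if sep >= relax:
                    coords[i] = cand
                    direction = d
                    placed = True
                    break
                if sep > best_sep:
                    best, best_sep = (cand, d), sep
            if placed:
                break
        if not placed:  # accept the least-clashing candidate to guarantee progress
            coords[i], direction = best
    return coords


def _backbone_atoms(coords: np.ndarray) -> list[dict[str, np.ndarray]]:
    """Idealized N, C, O placement around each alpha-carbon."""
    length = len(coords)
    atoms = []
    for i in range(length):
        ca = coords[i]
        prev = coords[i - 1] if i > 0 else ca - (coords[i + 1] - ca)
        nxt = coords[i + 1] if i < length - 1 else ca + (ca - coords[i - 1])
        to_prev = _unit(prev - ca)
        to_next = _unit(nxt - ca)
        perp = np.cross(to_prev, to_next)
        if np.linalg.norm(perp) < 1e-8:
            perp = np.cross(to_prev, np.array([0.0, 0.0, 1.0]))
            if np.linalg.norm(perp) < 1e-8:
                perp = np.array([0.0, 1.0, 0.0])
        perp = _unit(perp)
        n_at = ca + 1.46 * _unit(to_prev + 0.4 * perp)
        c_at = ca + 1.53 * _unit(to_next + 0.4 * perp)
        o_at = c_at + 1.23 * _unit(perp - 0.4 * to_next)
        atoms.append({"N": n_at, "CA": ca, "C": c_at, "O": o_at})
    return atoms


def _sample_ss_letters(length: int, rng: np.random.Generator) -> list[str]:
    letters: list[str] = []
    while len(letters) < length:
        cat = rng.choice(4, p=[0.35, 0.20, 0.20, 0.25])
        seg = max(3, int(rng.geometric(1.0 / 7.0)))
        if cat == 0:
            letter = ["H"] * seg
        elif cat == 1:
            letter = ["E"] * seg
        elif cat == 2:
            letter = [str(rng.choice(["T", "S"]))] * seg
        else:
            letter = [str(rng.choice([" ", "B", "G", "I"], p=[0.7, 0.1, 0.1, 0.1]))] * seg
        letters.extend(letter)
    return letters[:length]


def generate_toy_structure(config: SimulationConfig, seed: int | None = None) -> SyntheticStructure:
    """Generate one compact chain with a planted buried hydrophobic core.

    The chain is a collapsed self-avoiding walk (consecutive alpha-carbon
    distance 3.8 +/- 0.2 A; radius of gyration ~ L^(1/3)). Residues are
    ranked by burial (contact count within 8.5 A, ties by centroid
    distance); the ``core_fraction`` most buried are assigned hydrophobic
    amino acids and low planted RSA, the rest polar amino acids and higher
    RSA, so that the fraction of residues with RSA < 0.25 is approximately
    ``core_fraction``. Full backbone atoms are placed by idealized
    geometry and DSSP-style annotations (ACC, SS letter) are planted for
    direct emission.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    length = config.chain_length
    coords = _grow_chain(length, rng)
    coords = coords - coords.mean(axis=0)

    dists = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    nonadj = ~np.eye(length, dtype=bool)
    for k in (1,):
        nonadj &= ~np.eye(length, k=k, dtype=bool) & ~np.eye(length, k=-k, dtype=bool)
    contacts = ((dists < 8.5) & nonadj).sum(axis=1)
    centroid_dist = np.linalg.norm(coords, axis=1)
    # burial rank: most contacts first, nearer the centroid breaks ties
    order = np.lexsort((centroid_dist, -contacts))
    q = np.empty(length)
    q[order] = np.arange(length) / max(length - 1, 1)

    cf = config.core_fraction
    if cf <= 0.0:
        rsa = np.interp(q, [0.0, 1.0], [0.26, 0.95])
    elif cf >= 1.0:
        rsa = np.interp(q, [0.0, 1.0], [0.02, 0.24])
    else:
        rsa = np.interp(q, [0.0, cf, 1.0], [0.02, 0.25, 0.95])
    rsa = np.clip(rsa + rng.normal(0.0, 0.02, size=length), 0.0, 1.0)

    core = q < cf
    aa = np.empty(length, dtype="U1")
    n_core = int(core.sum())
    aa[core] = rng.choice(list(HYDROPHOBIC), size=n_core)
    aa[~core] = rng.choice(list(POLAR), size=length - n_core)

    asa = np.array([rsa[i] * reference_asa(aa[i]) for i in range(length)])
    ss_letters = _sample_ss_letters(length, rng)
    atoms = _backbone_atoms(coords)
    residues = [Residue(i + 1, aa[i], atoms[i]) for i in range(length)]
    return SyntheticStructure(
        id=f"synth{config.age_class.name[:3]}{rng.integers(0, 10**6):06d}",
        residues=residues,
        experiment_type="xray",
        model_index=1,
        asa=asa,
        ss_letters=ss_letters,
        core_mask=core,
        rsa_planted=rsa,
    )


# ---------------------------------------------------------------------------
# codon machinery (built on the rates module's tables)


def _build_neighbour_tables() -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    syn = np.zeros((64, 9), dtype=np.int64)
    nonsyn = np.zeros((64, 9), dtype=np.int64)
    syn_n = np.zeros(64, dtype=np.int64)
    nonsyn_n = np.zeros(64, dtype=np.int64)
    for i in range(64):
        if AA_OF[i] == "*":
            continue
        for j in _single_nt_neighbours(i):
            if AA_OF[j] == "*":
                continue
            if AA_OF[j] == AA_OF[i]:
                syn[i, syn_n[i]] = j
                syn_n[i] += 1
            else:
                nonsyn[i, nonsyn_n[i]] = j
                nonsyn_n[i] += 1
    return syn, syn_n, nonsyn, nonsyn_n


_SYN_NB, _SYN_N, _NONSYN_NB, _NONSYN_N = _build_neighbour_tables()

_CODONS_OF_AA: dict[str, np.ndarray] = {
    a: np.array([i for i in SENSE_CODON_IDX if AA_OF[i] == a])
    for a in AA_ALPHABET
}


def _mutate_codon_indices(
    idx: np.ndarray,
    p_sub: np.ndarray | float,
    nonsyn_fraction: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Apply single-nucleotide substitutions with per-codon probability."""
    n = idx.size
    out = idx.copy()
    hit = rng.random(n) < p_sub
    want_nonsyn = rng.random(n) < nonsyn_fraction
    want_nonsyn |= _SYN_N[idx] == 0  # Met/Trp have no synonymous neighbour
    u = rng.random(n)
    m = hit & want_nonsyn
    out[m] = _NONSYN_NB[idx[m], (u[m] * _NONSYN_N[idx[m]]).astype(np.int64)]
    m = hit & ~want_nonsyn
    out[m] = _SYN_NB[idx[m], (u[m] * _SYN_N[idx[m]]).astype(np.int64)]
    return out


def _backtranslate_aa(aa_seq: str, rng: np.random.Generator) -> np.ndarray:
    """Random codon choice for each amino acid."""
    out = np.empty(len(aa_seq), dtype=np.int64)
    for i, a in enumerate(aa_seq):
        choices = _CODONS_OF_AA[a]
        out[i] = choices[rng.integers(0, len(choices))]
    return out


def generate_ortholog_pair(
    structure: Structure,
    features: list[ResidueFeature],
    config: SimulationConfig,
    seed: int | None = None,
) -> CodonAlignment:
    """Emit a gap-free aligned codon pair planted with the RSA-rate relation.

    Sequence A back-translates exactly to the structure's amino-acid
    sequence; sequence B applies, at each codon i, a single-nucleotide
    substitution with probability ``min(1, base_rate + rsa_slope*RSA_i)``,
    nonsynonymous with probability ``nonsyn_fraction``.
    """
    if len(features) != len(structure):
        raise InvalidConfigError(
            f"features cover {len(features)} residues, structure has {len(structure)}"
        )
    rng = np.random.default_rng(config.seed if seed is None else seed)
    idx_a = _backtranslate_aa(structure.sequence, rng)
    rsa = np.array([f.rsa for f in features])
    p = np.minimum(1.0, config.base_rate + config.rsa_slope * rsa)
    idx_b = _mutate_codon_indices(idx_a, p, config.nonsyn_fraction, rng)
    return CodonAlignment(decode_codons(idx_a), decode_codons(idx_b))


def generate_binned_codon_data(
    config: SimulationConfig,
    n_codons_per_bin: int,
    seed: int | None = None,
    n_bins: int = 20,
) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    """Large-scale codon pairs per RSA bin (vectorized, no geometry).

    For the analyses that need very many codons per RSA bin, codon pairs
    are planted directly at each bin midpoint RSA with the same
    substitution model as :func:`generate_ortholog_pair`. Returns
    {bin (1..n_bins): (codon indices A, codon indices B)}.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    out = {}
    for b in range(1, n_bins + 1):
        mid = (b - 0.5) / n_bins
        p = min(1.0, config.base_rate + config.rsa_slope * mid)
        idx_a = SENSE_CODON_IDX[rng.integers(0, len(SENSE_CODON_IDX), size=n_codons_per_bin)]
        idx_b = _mutate_codon_indices(idx_a, p, config.nonsyn_fraction, rng)
        out[b] = (idx_a, idx_b)
    return out


def simulate_structure_rate_samples(
    config: SimulationConfig,
    n_structures: int,
    codons_per_structure: int | None = None,
    seed: int | None = None,
    mean_rsa: float = 0.4,
) -> np.ndarray:
    """Per-pseudo-structure dN samples under the planted substitution model.

    Generates ``n_structures`` independent codon alignments (each standing
    for one structure's mapped region, at a typical RSA of ``mean_rsa``)
    and returns their dN estimates. Used for group-level comparisons
    (Wilcoxon across age classes, null calibration) where geometry is
    irrelevant.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n_codons = codons_per_structure or config.chain_length
    p = min(1.0, config.base_rate + config.rsa_slope * mean_rsa)
    dn = np.empty(n_structures)
    idx_a = SENSE_CODON_IDX[
        rng.integers(0, len(SENSE_CODON_IDX), size=(n_structures, n_codons))
    ]
    idx_b = _mutate_codon_indices(
        idx_a.ravel(), p, config.nonsyn_fraction, rng
    ).reshape(idx_a.shape)
    for i in range(n_structures):
        dn[i] = estimate_from_indices(idx_a[i], idx_b[i]).dn
    return dn


# ---------------------------------------------------------------------------
# homolog profiles


def generate_homolog_profile(
    age_class: AgeClass | str,
    seed: int = 0,
    query_id: str = "query",
) -> tuple[list[HitRecord], dict[str, str]]:
    """Emit a hit table whose phylogenetic width encodes ``age_class``.

    Hits are emitted in the named group and in every younger group (a
    homolog detectable in a distant clade is also detectable in close
    relatives), none in older groups, all with e-value <= 1e-4. Returns
    the hits plus the subject-id -> species map needed to read them back
    from BLAST tabular form.
    """
    if isinstance(age_class, str):
        try:
            age_class = AgeClass[age_class]
        except KeyError:
            raise InvalidConfigError(f"unknown age class {age_class!r}") from None
    rng = np.random.default_rng(seed)
    by_group: dict[AgeClass, list[str]] = {}
    for sp, grp in DEFAULT_SPECIES_GROUPS.items():
        by_group.setdefault(grp, []).append(sp)
    hits: list[HitRecord] = []
    species_map: dict[str, str] = {}
    for grp, species in sorted(by_group.items()):
        if grp > age_class:
            continue
        k = int(rng.integers(1, len(species) + 1))
        chosen = rng.choice(species, size=k, replace=False)
        for sp in chosen:
            sid = f"{sp.split()[0][0]}{sp.split()[1][:4]}_{rng.integers(0, 10**4):04d}"
            start = int(rng.integers(1, 30))
            end = start + int(rng.integers(50, 200))
            hits.append(
                HitRecord(
                    query_id=query_id,
                    subject_id=sid,
                    subject_species=sp,
                    percent_identity=float(np.round(rng.uniform(30, 95), 1)),
                    query_start=start,
                    query_end=end,
                    e_value=float(10.0 ** rng.uniform(-50, -4)),
                    bitscore=float(np.round(rng.uniform(50, 500), 1)),
                )
            )
            species_map[sid] = sp
    return hits, species_map


# ---------------------------------------------------------------------------
# decoys


def generate_decoy_set(
    structure: Structure,
    n: int,
    mode: str = "shuffle_sequence",
    seed: int = 0,
    displacement_bound: float = 1.0,
) -> list[Structure]:
    """Decoys for potential validation.

    ``shuffle_sequence`` permutes the amino-acid sequence on the fixed
    native coordinates (composition preserved exactly);
    ``perturb_coordinates`` keeps the sequence and displaces every atom by
    a bounded uniform random vector (chain connectivity preserved for
    bounds well below the 3.8 A virtual bond).
    """
    if n <= 0:
        raise InvalidConfigError(f"decoy count {n} <= 0")
    if mode not in ("shuffle_sequence", "perturb_coordinates"):
        raise InvalidConfigError(f"unknown decoy mode {mode!r}")
    rng = np.random.default_rng(seed)
    decoys = []
    seq = list(structure.sequence)
    for d in range(n):
        if mode == "shuffle_sequence":
            perm = rng.permutation(len(seq))
            residues = [
                Residue(r.number, seq[perm[i]], r.atoms)
                for i, r in enumerate(structure.residues)
            ]
        else:
            residues = []
            for r in structure.residues:
                shift = {
                    name: xyz + rng.uniform(-displacement_bound, displacement_bound, 3)
                    for name, xyz in r.atoms.items()
                }
                residues.append(Residue(r.number, r.amino_acid, shift))
        decoys.append(
            Structure(
                id=f"{structure.id}_decoy{d:04d}",
                residues=residues,
                experiment_type=structure.experiment_type,
            )
        )
    return decoys


# ---------------------------------------------------------------------------
# file emission

AA_1TO3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


def write_pdb(models: Structure | list[Structure], path: str | Path, chain_id: str = "A") -> None:
    """Write PDB-format ATOM records; a list of structures becomes MODELs."""
    if isinstance(models, Structure):
        models = [models]
    multi = len(models) > 1
    lines = []
    for m_idx, st in enumerate(models, start=1):
        if multi:
            lines.append(f"MODEL     {m_idx:4d}")
        serial = 1
        for res in st.residues:
            res3 = AA_1TO3[res.amino_acid]
            for name in ("N", "CA", "C", "O"):
                if name not in res.atoms:
                    continue
                x, y, z = res.atoms[name]
                element = name[0]
                lines.append(
                    f"ATOM  {serial:5d} {name:^4s} {res3:>3s} {chain_id}{res.number:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {element:>2s}"
                )
                serial += 1
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_dssp(structure: SyntheticStructure, path: str | Path, chain_id: str = "A") -> None:
    """Emit a DSSP-format file carrying the planted ACC and SS columns.

    The fixed-column layout matches what DSSP writes (including dummy
    H-bond and phi/psi fields), so standard DSSP readers parse it.
    """
    header = [
        "==== Secondary Structure Definition, synthetic record ====",
        f"  {len(structure):4d}  1  0  0  0  TOTAL NUMBER OF RESIDUES",
        "  #  RESIDUE AA STRUCTURE BP1 BP2  ACC     N-H-->O    O-->H-N    "
        "N-H-->O    O-->H-N    TCO  KAPPA ALPHA  PHI   PSI    X-CA   Y-CA   Z-CA",
    ]
    lines = list(header)
    for i, res in enumerate(structure.residues):
        acc = int(round(structure.asa[i]))
        ss = structure.ss_letters[i]
        buf = [" "] * 116
        buf[0:5] = f"{i + 1:5d}"
        buf[5:10] = f"{res.number:5d}"
        buf[11] = chain_id
        buf[13] = res.amino_acid
        buf[16] = ss
        buf[34:38] = f"{acc:4d}"
        buf[38:50] = "      0, 0.0"  # N-H-->O relidx, energy
        buf[50:61] = "     0, 0.0"  # O-->H-N
        buf[61:72] = "     0, 0.0"  # N-H-->O (2nd)
        buf[72:83] = "     0, 0.0"  # O-->H-N (2nd)
        buf[103:109] = f"{360.0:6.1f}"
        buf[109:115] = f"{360.0:6.1f}"
        lines.append("".join(buf))
    Path(path).write_text("\n".join(lines) + "\n")


def write_fasta(records: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_blast_tab(hits: list[HitRecord], path: str | Path) -> None:
    """Write hits in BLAST tabular (outfmt 6) layout."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    [
                        h.query_id,
                        h.subject_id,
                        f"{h.percent_identity:.1f}",
                        str(h.aln_length),
                        "0",
                        "0",
                        str(h.query_start),
                        str(h.query_end),
                        "1",
                        str(h.aln_length),
                        f"{h.e_value:.2e}",
                        f"{h.bitscore:.1f}",
                    ]
                )
                + "\n"
            )
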