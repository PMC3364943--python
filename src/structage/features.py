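"""Residue-level structural features: RSA, burial, secondary structure.

This module turns a protein chain (PDB format) plus its DSSP record into a
per-residue feature table: absolute and relative solvent accessibility,
the buried/exposed call at the 25% RSA threshold, the 20-bin RSA
discretization, and a four-way secondary-structure category
(helix / sheet / turn / coil).

RSA is the DSSP accessibility (ACC, in A^2) normalized by the residue's
maximum accessibility in an extended Gly-X-Gly peptide (Miller et al.
reference values shipped with the package); values above 1 are clamped to 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser
from Bio.PDB.DSSP import make_dssp_dict
from Bio.PDB.Polypeptide import protein_letters_3to1

__all__ = [
    "Structure",
    "Residue",
    "ResidueFeature",
    "StructureError",
    "reference_asa",
    "parse_structure",
    "parse_dssp",
    "validate_structure",
    "compute_rsa",
    "classify_residue",
    "fraction_exposed",
    "build_feature_table",
    "write_feature_table",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O")

#: Four-way secondary-structure mapping of DSSP class letters.
#: Helix is DSSP H; sheet is E; turn covers S and T; everything else
#: (B, G, I and the blank/'.' class) is coil.
SS_CATEGORY = {
    "H": "helix",
    "E": "sheet",
    "S": "turn",
    "T": "turn",
    "B": "coil",
    "G": "coil",
    "I": "coil",
    ".": "coil",
    "-": "coil",  # Biopython's spelling of the blank DSSP class
    " ": "coil",
}

N_RSA_BINS = 20
EXPOSURE_THRESHOLD = 0.25


class StructureError(ValueError):
    """Raised for unparseable or structurally invalid inputs."""


@dataclass
class Residue:
    number: int
    amino_acid: str
    atoms: dict[str, np.ndarray]

    @property
    def ca(self) -> np.ndarray:
        return self.atoms["CA"]

    def has_complete_backbone(self) -> bool:
        return all(a in self.atoms for a in BACKBONE_ATOMS)


@dataclass
class Structure:
    """A single protein chain with ordered residues and backbone coordinates."""

    id: str
    residues: list[Residue]
    experiment_type: str = "xray"  # "xray" or "nmr"
    model_index: int = 1

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.amino_acid for r in self.residues)

    def ca_coords(self) -> np.ndarray:
        return np.array([r.ca for r in self.residues], dtype=float)


@dataclass
class ResidueFeature:
    position: int  # 1-based index into the chain
    amino_acid: str
    asa: float  # A^2
    rsa: float  # in [0, 1] after clamping
    exposure: str  # "buried" | "exposed"
    rsa_bin: int  # 1..20
    ss_category: str  # helix | sheet | turn | coil


def _load_reference_asa() -> dict[str, float]:
    with resources.files("structage.data").joinpath("miller_asa.tsv").open() as fh:
        table = pd.read_csv(fh, sep="\t", comment="#")
    return dict(zip(table["aa"], table["asa_ref"]))


_REF_ASA: dict[str, float] = _load_reference_asa()


def reference_asa(amino_acid: str) -> float:
    """Maximum Gly-X-Gly accessibility (A^2) for a standard amino acid."""
    try:
        return _REF_ASA[amino_acid]
    except KeyError:
        raise StructureError(f"no reference ASA for amino acid {amino_acid!r}") from None


def parse_structure(pdb_file: str | Path, chain_id: str | None = None) -> Structure:
    """Read one chain from a PDB-format file.

    For multi-model (NMR) files only the first model is used. Residues with
    nonstandard identities are skipped with a warning; water and other
    heteroatoms are ignored.
    """
    pdb_file = Path(pdb_file)
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(pdb_file.stem, str(pdb_file))
    models = list(structure)
    if not models:
        raise StructureError(f"{pdb_file}: no models/ATOM records found")
    model = models[0]
    chains = list(model)
    if not chains:
        raise StructureError(f"{pdb_file}: no chains found")
    if chain_id is None:
        chain = chains[0]
    else:
        try:
            chain = model[chain_id]
        except KeyError:
            raise StructureError(f"{pdb_file}: no chain {chain_id!r}") from None

    residues: list[Residue] = []
    for res in chain:
        hetflag, resseq, _icode = res.get_id()
        if hetflag != " ":
            continue
        resname = res.get_resname()
        if resname not in protein_letters_3to1:
            warnings.warn(
                f"{pdb_file.name}: skipping nonstandard residue {resname} {resseq}",
                stacklevel=2,
            )
            continue
        atoms = {
            atom.get_name(): atom.get_coord().astype(float)
            for atom in res
            if atom.get_name() in BACKBONE_ATOMS
        }
        residues.append(Residue(resseq, protein_letters_3to1[resname], atoms))
    if not residues:
        raise StructureError(f"{pdb_file}: no standard protein residues")
    residues.sort(key=lambda r: r.number)
    experiment = "nmr" if len(models) > 1 else "xray"
    return Structure(pdb_file.stem, residues, experiment_type=experiment, model_index=1)


def parse_dssp(dssp_file: str | Path, chain_id: str = "A") -> dict[int, tuple[str, str, float]]:
    """Read a DSSP file into {residue_number: (aa, ss_letter, acc)}."""
    dssp_dict, _keys = make_dssp_dict(str(dssp_file))
    out: dict[int, tuple[str, str, float]] = {}
    for (cid, res_id), values in dssp_dict.items():
        if cid != chain_id:
            continue
        aa, ss, acc = values[0], values[1], values[2]
        out[res_id[1]] = (aa, ss, float(acc))
    return out


def validate_structure(structure: Structure) -> tuple[bool, str]:
    """Apply the chain-level quality filters.

    A chain is rejected if it is shorter than 50 residues, if its residue
    numbering is discontinuous (gapped chain), or if any residue lacks one
    of the four backbone atoms. Returns ``(accepted, reason)`` where
    ``reason`` names the first failed rule ("" on acceptance).
    """
    if len(structure) < 50:
        return False, "length"
    numbers = [r.number for r in structure.residues]
    if any(b - a != 1 for a, b in zip(numbers, numbers[1:])):
        return False, "gapped chain"
    if any(not r.has_complete_backbone() for r in structure.residues):
        return False, "incomplete backbone"
    return True, ""


def compute_rsa(amino_acid: str, asa: float) -> float:
    """Relative solvent accessibility: ASA over the Gly-X-Gly reference.

    Values above 1 (possible for distorted conformations) are clamped to 1.
    """
    if asa < 0:
        raise StructureError(f"negative ASA {asa}")
    rsa = asa / reference_asa(amino_acid)
    return min(rsa, 1.0)


def rsa_bin(rsa: float) -> int:
    """Index (1..20) of the equal-width RSA bin on [0, 1].

    Bins are half-open [lo, hi) except the top bin, which is closed so
    clamped RSA = 1 lands in bin 20.
    """
    if not 0.0 <= rsa <= 1.0:
        raise StructureError(f"RSA {rsa} outside [0, 1]")
    return min(int(rsa * N_RSA_BINS), N_RSA_BINS - 1) + 1


def classify_residue(rsa: float, dssp_class_letter: str) -> tuple[str, int, str]:
    """Classify one residue: exposure at the 25% RSA rule, RSA bin, SS category.

    RSA exactly at the 0.25 threshold is classified exposed (the buried
    class is strictly below threshold).
    """
    if dssp_class_letter not in SS_CATEGORY:
        raise StructureError(f"unknown DSSP class letter {dssp_class_letter!r}")
    exposure = "buried" if rsa < EXPOSURE_THRESHOLD else "exposed"
    return exposure, rsa_bin(rsa), SS_CATEGORY[dssp_class_letter]


def fraction_exposed(features: list[ResidueFeature] | pd.DataFrame) -> float:
    """Percentage of exposed residues: 100 * exposed / (exposed + buried)."""
    if isinstance(features, pd.DataFrame):
        exposures = features["exposure"].tolist()
    else:
        exposures = [f.exposure for f in features]
    if not exposures:
        raise StructureError("empty feature list")
    n_exposed = sum(e == "exposed" for e in exposures)
    return 100.0 * n_exposed / len(exposures)


def build_feature_table(
    structure: Structure,
    dssp_records: dict[int, tuple[str, str, float]],
) -> list[ResidueFeature]:
    """Join a chain with its DSSP record into per-residue features.

    Positions where the DSSP amino acid disagrees with the coordinate file,
    or that have no DSSP record, are dropped (only positions with a
    consistent identity are analyzed).
    """
    features: list[ResidueFeature] = []
    for pos, res in enumerate(structure.residues, start=1):
        rec = dssp_records.get(res.number)
        if rec is None:
            continue
        aa, ss, acc = rec
        if aa != res.amino_acid:
            continue
        rsa = compute_rsa(aa, acc)
        exposure, rbin, category = classify_residue(rsa, ss)
        features.append(ResidueFeature(pos, aa, acc, rsa, exposure, rbin, category))
    return features


def write_feature_table(
    features_by_structure: dict[str, list[ResidueFeature]], path: str | Path
) -> pd.DataFrame:
    """Write the per-residue feature TSV (one row per structure x position)."""
    rows = []
    for sid, feats in features_by_structure.items():
        for f in feats:
            rows.append(
                (sid, f.position, f.amino_acid, f.asa, f.rsa, f.exposure, f.rsa_bin, f.ss_category)
            )
    table = pd.DataFrame(
        rows,
        columns=["structure", "position", "aa", "asa", "rsa", "exposure", "rsa_bin", "ss_category"],
    )
    table.to_csv(path, sep="\t", index=False)
    return table
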