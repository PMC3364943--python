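"""Structure-mapping hit filters and phylostratigraphic age assignment.

A protein's evolutionary age class is the phylogenetic width of its homolog
distribution: the oldest species group (mammalia < vertebrata < metazoa <
eukarya, youngest to oldest) that contains at least one significant homolog
(e-value <= 1e-4). The mammalia class is retained in the data model but
flagged as excluded from downstream analyses, since too few structures fall
in it for meaningful statistics.

Hit tables arrive in BLAST tabular ("outfmt 6") form. A separate filter
selects structure-mapping hits: only hits with >= 99% identity are kept and
mutually overlapping hits are reduced to the single best one.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from pathlib import Path

import pandas as pd

__all__ = [
    "HitRecord",
    "AgeClass",
    "AGE_ORDER",
    "DEFAULT_SPECIES_GROUPS",
    "UnassignableError",
    "filter_structure_hits",
    "assign_age",
    "read_blast_tab",
    "write_age_table",
]

E_VALUE_CUTOFF = 1e-4
IDENTITY_CUTOFF = 99.0


class AgeClass(IntEnum):
    """Age classes ordered youngest (mammalia) to oldest (eukarya)."""

    mammalia = 0
    vertebrata = 1
    metazoa = 2
    eukarya = 3

    def __str__(self) -> str:  # friendlier table labels
        return self.name


AGE_ORDER = [AgeClass.mammalia, AgeClass.vertebrata, AgeClass.metazoa, AgeClass.eukarya]

#: Species scanned for homolog presence, grouped by clade.
DEFAULT_SPECIES_GROUPS: dict[str, AgeClass] = {
    # mammals
    "Mus musculus": AgeClass.mammalia,
    "Rattus norvegicus": AgeClass.mammalia,
    # non-mammalian vertebrates
    "Gallus gallus": AgeClass.vertebrata,
    "Xenopus tropicalis": AgeClass.vertebrata,
    "Danio rerio": AgeClass.vertebrata,
    "Takifugu rubripes": AgeClass.vertebrata,
    # other metazoans
    "Ciona intestinalis": AgeClass.metazoa,
    "Drosophila melanogaster": AgeClass.metazoa,
    "Anopheles gambiae": AgeClass.metazoa,
    "Caenorhabditis elegans": AgeClass.metazoa,
    # other eukaryotes
    "Schizosaccharomyces pombe": AgeClass.eukarya,
    "Saccharomyces cerevisiae": AgeClass.eukarya,
    "Oryza sativa": AgeClass.eukarya,
    "Arabidopsis thaliana": AgeClass.eukarya,
}


class UnassignableError(ValueError):
    """No significant homolog in any species group."""


@dataclass
class HitRecord:
    """One BLAST tabular hit."""

    query_id: str
    subject_id: str
    subject_species: str
    percent_identity: float
    query_start: int  # 1-based inclusive
    query_end: int
    e_value: float
    aln_length: int = 0
    bitscore: float = 0.0

    def __post_init__(self) -> None:
        if self.query_start > self.query_end:
            raise ValueError(
                f"query_start {self.query_start} > query_end {self.query_end}"
            )
        if not self.aln_length:
            self.aln_length = self.query_end - self.query_start + 1


def _overlaps(a: HitRecord, b: HitRecord) -> bool:
    # >= 1 shared query position, 1-based inclusive intervals
    return a.query_start <= b.query_end and b.query_start <= a.query_end


def filter_structure_hits(
    hits: list[HitRecord], identity_cutoff: float = IDENTITY_CUTOFF
) -> list[HitRecord]:
    """Keep near-identical, non-overlapping structure-mapping hits.

    Hits below the identity cutoff (99% by default) are removed. Among
    mutually overlapping survivors the hit closest to the query protein is
    kept, interpreted as: highest percent identity, ties broken by longer
    alignment, then by lower e-value. Retained hits are pairwise
    non-overlapping on the query.
    """
    survivors = [h for h in hits if h.percent_identity >= identity_cutoff]
    # best-first greedy selection guarantees pairwise non-overlap
    survivors.sort(key=lambda h: (-h.percent_identity, -h.aln_length, h.e_value))
    kept: list[HitRecord] = []
    for h in survivors:
        if not any(_overlaps(h, k) for k in kept):
            kept.append(h)
    kept.sort(key=lambda h: h.query_start)
    return kept


def assign_age(
    hits: list[HitRecord],
    species_groups: dict[str, AgeClass] | None = None,
    e_value_cutoff: float = E_VALUE_CUTOFF,
) -> tuple[AgeClass, bool]:
    """Assign the age class from the phylogenetic width of the homolog hits.

    Hits with e-value above the cutoff are ignored; the result is the
    oldest group with at least one surviving hit. Returns
    ``(age_class, excluded_from_analysis)`` where the flag is True for
    mammalia. Raises :class:`UnassignableError` if no hit survives.
    """
    groups = DEFAULT_SPECIES_GROUPS if species_groups is None else species_groups
    surviving = [h for h in hits if h.e_value <= e_value_cutoff]
    unknown = {h.subject_species for h in surviving} - set(groups)
    if unknown:
        raise ValueError(f"species not covered by species_groups: {sorted(unknown)}")
    if not surviving:
        raise UnassignableError("no hit at or below the e-value cutoff")
    oldest = max(groups[h.subject_species] for h in surviving)
    return oldest, oldest == AgeClass.mammalia


def read_blast_tab(
    path: str | Path, species_of_subject: dict[str, str]
) -> list[HitRecord]:
    """Read a BLAST tabular (outfmt 6) file into hit records.

    ``species_of_subject`` maps subject ids to species names (BLAST output
    itself does not carry the species).
    """
    cols = [
        "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
        "qstart", "qend", "sstart", "send", "evalue", "bitscore",
    ]
    table = pd.read_csv(path, sep="\t", names=cols, comment="#")
    hits = []
    for row in table.itertuples(index=False):
        hits.append(
            HitRecord(
                query_id=str(row.qseqid),
                subject_id=str(row.sseqid),
                subject_species=species_of_subject[str(row.sseqid)],
                percent_identity=float(row.pident),
                query_start=int(row.qstart),
                query_end=int(row.qend),
                e_value=float(row.evalue),
                aln_length=int(row.length),
                bitscore=float(row.bitscore),
            )
        )
    return hits


def write_age_table(
    assignments: dict[str, tuple[AgeClass, bool]],
    hits_per_group: dict[str, dict[str, int]] | None,
    path: str | Path,
) -> pd.DataFrame:
    """Write the age-assignment TSV (structure, age class, hits per group)."""
    rows = []
    for sid, (age, excluded) in assignments.items():
        row = {"structure": sid, "age_class": str(age), "excluded": excluded}
        if hits_per_group is not None:
            for g in AGE_ORDER:
                row[f"n_hits_{g}"] = hits_per_group.get(sid, {}).get(str(g), 0)
        rows.append(row)
    table = pd.DataFrame(rows)
    table.to_csv(path, sep="\t", index=False)
    return table
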