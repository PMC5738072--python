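"""Celiac-disease epitope scanning and census tables.

α-type gliadins carry short proline/glutamine-rich peptides that survive
gastrointestinal digestion and either damage the mucosa directly
("toxic" peptides) or stimulate HLA-DQ2/DQ8-restricted T cells
("immunogenic" peptides).  This module scans deduced protein sequences
for a configurable panel of such peptides (default: seven toxic and
five immunogenic epitopes, including the digestion-resistant 33-mer),
builds per-sequence occurrence matrices, aggregates them per genotype
given the locus assignments, and computes percent reductions of each
deletion genotype relative to the full-complement reference.

Matching is exact string matching, overlapping occurrences allowed: the
panel nests (the 33-mer contains overlapping copies of Glia-α2 and
Glia-α9), so an occurrence census must not skip overlaps.  No
deamidation (Q→E) expansion is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .records import GenotypeDesign, UNASSIGNED

TOXIC = "toxic"
IMMUNOGENIC = "immunogenic"

_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class EpitopeDefinition:
    name: str
    epitope_class: str
    peptide: str

    def __post_init__(self) -> None:
        if not self.peptide:
            raise ValueError(f"epitope {self.name}: empty peptide")
        bad = set(self.peptide) - _AA
        if bad:
            raise ValueError(f"epitope {self.name}: non-amino-acid symbols {sorted(bad)}")
        if self.epitope_class not in (TOXIC, IMMUNOGENIC):
            raise ValueError(f"epitope {self.name}: unknown class {self.epitope_class}")


# The default panel.  Names keep the conventional residue-number spans of
# the reference α-gliadin; a-Glia(51-70) is the 18-residue peptide as
# conventionally printed, despite its 20-residue name span.
DEFAULT_EPITOPES: tuple[EpitopeDefinition, ...] = (
    EpitopeDefinition("a-Glia(31-43)", TOXIC, "PGQQQPFPPQQPY"),
    EpitopeDefinition("a-Glia(31-49)", TOXIC, "PGQQQPFPPQQPYPQPQPF"),
    EpitopeDefinition("a-Glia(31-55)", TOXIC, "PGQQQPFPPQQPYPQPQPFPSQQPY"),
    EpitopeDefinition("a-Glia(44-55)", TOXIC, "PQPQPFPSQQPY"),
    EpitopeDefinition("a-Glia(51-70)", TOXIC, "SQQPYLQLQPFPQPQLPY"),
    EpitopeDefinition("a-Glia(56-75)", TOXIC, "LQLQPFPQPQLPYPQPQLPY"),
    EpitopeDefinition("a-Glia(206-217)", TOXIC, "LGQGSFRPSQQN"),
    EpitopeDefinition("Glia-a", IMMUNOGENIC, "QGSFQPSQQ"),
    EpitopeDefinition("Glia-a2", IMMUNOGENIC, "PQPQLPYPQPQLPY"),
    EpitopeDefinition("Glia-a9", IMMUNOGENIC, "PFPQPQLPY"),
    EpitopeDefinition("Glia-a20", IMMUNOGENIC, "PFRPQQPYPQ"),
    EpitopeDefinition("33-mer", IMMUNOGENIC, "LQLQPFPQPQLPYPQPQLPYPQPQLPYPQPQPF"),
)

EPITOPE_BY_NAME = {e.name: e for e in DEFAULT_EPITOPES}


def scan_epitope(protein: str, peptide: str) -> list[int]:
    """All 0-based start positions of ``peptide`` in ``protein``,
    overlapping occurrences included, sorted ascending."""
    if not peptide:
        raise ValueError("empty epitope peptide")
    positions = []
    start = protein.find(peptide)
    while start != -1:
        positions.append(start)
        start = protein.find(peptide, start + 1)
    return positions


@dataclass
class CensusTable:
    """Per-(gene, epitope) occurrence and presence matrices.

    ``occurrences``: int DataFrame, rows gene ids, columns epitope names.
    ``presence``: boolean DataFrame of the same shape (``occurrences >= 1``).
    """

    occurrences: pd.DataFrame
    presence: pd.DataFrame
    epitopes: tuple[EpitopeDefinition, ...]

    def carriers(self, epitope_name: str) -> int:
        return int(self.presence[epitope_name].sum())


def census(
    proteins: dict[str, str],
    epitopes: tuple[EpitopeDefinition, ...] = DEFAULT_EPITOPES,
) -> CensusTable:
    """Scan every protein for every epitope.

    Presence counts each sequence at most once per epitope regardless of
    how many times the peptide occurs in it.
    """
    names = [e.name for e in epitopes]
    data = {
        gid: [len(scan_epitope(prot, e.peptide)) for e in epitopes]
        for gid, prot in proteins.items()
    }
    occ = pd.DataFrame.from_dict(data, orient="index", columns=names).astype(int)
    return CensusTable(occurrences=occ, presence=occ >= 1, epitopes=tuple(epitopes))


def genotype_summary(
    table: CensusTable,
    assignments: dict[str, str],
    design: GenotypeDesign,
) -> pd.DataFrame:
    """Per-genotype census: protein count, per-epitope carrier counts and
    class totals, restricted to the genes whose assigned locus the
    genotype retains.

    Genes that are unassigned/ambiguous are excluded from every genotype
    and counted in the ``n_excluded`` column.
    """
    names = [e.name for e in table.epitopes]
    cls = {e.name: e.epitope_class for e in table.epitopes}
    excluded = [g for g in table.presence.index if assignments.get(g, UNASSIGNED) not in
                ("Gli-A2", "Gli-B2", "Gli-D2")]
    rows = {}
    for genotype in design.genotypes:
        loci = design.retains(genotype)
        members = [
            g for g in table.presence.index
            if assignments.get(g, UNASSIGNED) in loci
        ]
        sub = table.presence.loc[members, names]
        carriers = sub.sum(axis=0).astype(int)
        row = {"n_proteins": len(members)}
        row.update(carriers.to_dict())
        row["immunogenic_total"] = int(
            sum(carriers[n] for n in names if cls[n] == IMMUNOGENIC))
        row["toxic_total"] = int(
            sum(carriers[n] for n in names if cls[n] == TOXIC))
        row["n_excluded"] = len(excluded)
        rows[genotype] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def reduction_stats(summary: pd.DataFrame, reference: str) -> pd.DataFrame:
    """Percent reduction of each count relative to the reference genotype:
    ``100 * (1 - count / count_reference)``.

    Columns where the reference count is zero are reported as NaN
    (not applicable).  The reference row is zero by construction.
    """
    if reference not in summary.index:
        raise ValueError(f"reference genotype {reference!r} not in summary")
    cols = [c for c in summary.columns if c != "n_excluded"]
    ref = summary.loc[reference, cols].astype(float)
    out = 100.0 * (1.0 - summary[cols].astype(float).div(ref, axis=1))
    out[ref.index[ref == 0]] = float("nan")
    return out


def read_epitope_table(path) -> tuple[EpitopeDefinition, ...]:
    """Read a custom epitope panel from a TSV with columns
    ``name``, ``class``, ``peptide``."""
    df = pd.read_csv(path, sep="\t")
    required = {"name", "class", "peptide"}
    if not required <= set(df.columns):
        raise ValueError(f"epitope table needs columns {sorted(required)}")
    return tuple(
        EpitopeDefinition(str(r["name"]), str(r["class"]), str(r["peptide"]).upper())
        for _, r in df.iterrows()
    )
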