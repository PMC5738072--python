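"""Locus assignment by presence/absence over deletion genotypes.

Each unique gene is observed in some subset of the sequenced genotypes.
A genotype can only express genes at loci it retains, so the candidate
loci of a gene are the intersection of the retained-locus sets of the
genotypes where it *was* observed.  Under the completeness assumption
(a gene expressed at a retained locus is always sampled), loci retained
by a genotype where the gene was *not* observed can additionally be
excluded.  A single surviving candidate is the assignment; more than
one is AMBIGUOUS, none is INCONSISTENT.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .records import GeneRecord, GenotypeDesign, UNASSIGNED

AMBIGUOUS = "AMBIGUOUS"
INCONSISTENT = "INCONSISTENT"


@dataclass(frozen=True)
class Assignment:
    status: str  # locus name, AMBIGUOUS, or INCONSISTENT
    candidates: frozenset[str]

    @property
    def locus(self) -> str:
        return self.status if self.status not in (AMBIGUOUS, INCONSISTENT) else UNASSIGNED


def assign_locus(
    observed_in: set[str],
    design: GenotypeDesign,
    assume_complete: bool = True,
) -> Assignment:
    """Assign one gene given the set of genotypes it was observed in."""
    if not observed_in:
        raise ValueError("gene observed in no genotype")
    unknown = observed_in - set(design.genotypes)
    if unknown:
        raise ValueError(f"unknown genotypes {sorted(unknown)}")
    candidates: set[str] | None = None
    for genotype in observed_in:
        loci = set(design.retains(genotype))
        candidates = loci if candidates is None else candidates & loci
    assert candidates is not None
    if assume_complete:
        for genotype in design.genotypes:
            if genotype not in observed_in:
                candidates -= set(design.retains(genotype))
    if not candidates:
        return Assignment(INCONSISTENT, frozenset())
    if len(candidates) > 1:
        return Assignment(AMBIGUOUS, frozenset(candidates))
    return Assignment(next(iter(candidates)), frozenset(candidates))


def build_presence_matrix(
    genes: list[GeneRecord], design: GenotypeDesign
) -> pd.DataFrame:
    """Boolean gene x genotype matrix of observation (support > 0)."""
    data = {
        gene.gene_id: {g: gene.support.get(g, 0) > 0 for g in design.genotypes}
        for gene in genes
    }
    df = pd.DataFrame.from_dict(data, orient="index", columns=design.genotypes)
    return df.astype(bool)


def assign_all(
    genes: list[GeneRecord],
    design: GenotypeDesign,
    assume_complete: bool = True,
) -> dict[str, Assignment]:
    return {
        gene.gene_id: assign_locus(gene.observed_in, design, assume_complete)
        for gene in genes
    }


def label_genes(
    genes: list[GeneRecord], assignments: dict[str, Assignment]
) -> tuple[list[GeneRecord], dict[str, Assignment]]:
    """Rename genes as ``<locus>-<rank>`` (e.g. ``Gli-B2-1``), ranked in
    the deterministic dereplication order within each locus.  Unassigned
    genes keep their provisional ids.  Updates ``locus`` and ``gene_id``
    in place; returns the gene list and the re-keyed assignments."""
    counters: dict[str, int] = {}
    relabeled: dict[str, Assignment] = {}
    for gene in genes:
        a = assignments[gene.gene_id]
        gene.locus = a.locus
        if a.locus != UNASSIGNED:
            counters[a.locus] = counters.get(a.locus, 0) + 1
            gene.gene_id = f"{a.locus}-{counters[a.locus]}"
        relabeled[gene.gene_id] = a
    return genes, relabeled


def genotype_protein_set(
    assignments: dict[str, Assignment],
    design: GenotypeDesign,
    genotype: str,
) -> tuple[set[str], int]:
    """Gene ids whose assigned locus the genotype retains, plus a count
    of genes excluded because they are ambiguous or inconsistent."""
    loci = design.retains(genotype)
    members: set[str] = set()
    n_excluded = 0
    for gene_id, a in assignments.items():
        if a.status in (AMBIGUOUS, INCONSISTENT):
            n_excluded += 1
        elif a.status in loci:
            members.add(gene_id)
    return members, n_excluded


def assignment_table(
    genes: list[GeneRecord],
    assignments: dict[str, Assignment],
    design: GenotypeDesign,
) -> pd.DataFrame:
    """Report table: gene id, per-genotype presence, assigned locus."""
    rows = []
    for gene in genes:
        a = assignments[gene.gene_id]
        row = {"gene_id": gene.gene_id}
        for g in design.genotypes:
            row[g] = int(gene.support.get(g, 0))
        row["assigned_locus"] = a.status
        row["candidates"] = ";".join(sorted(a.candidates))
        rows.append(row)
    return pd.DataFrame(rows)
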