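"""Core record types shared across the pipeline.

A *clone* is a single sequenced amplicon from one genotype's RT-PCR
library; a *gene* is a validated unique coding sequence obtained after
ORF validation, chimera/pseudogene removal and dereplication.  The
*genotype design* records which of the three homoeologous ``Gli-2``
loci (short arms of the group-6 chromosomes) each genotype retains;
deletion lines lack one or two of them, which is what makes
presence/absence locus assignment possible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

GLI2_LOCI = ("Gli-A2", "Gli-B2", "Gli-D2")

#: Genotype labels used throughout: the euploid cultivar and the three
#: deletion lines derived from it.
PEGASO = "Pegaso"
DEL_A2 = "dGliA2"
DEL_D2 = "dGliD2"
DEL_A2D2 = "dGliA2D2"

UNASSIGNED = "UNASSIGNED"

_DNA_ALPHABET = set("ACGTN")


@dataclass(frozen=True)
class CloneRecord:
    """One raw amplicon clone from a genotype's library."""

    clone_id: str
    genotype: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"clone {self.clone_id}: empty sequence")
        bad = set(self.sequence) - _DNA_ALPHABET
        if bad:
            raise ValueError(
                f"clone {self.clone_id}: non-IUPAC DNA characters {sorted(bad)}"
            )


@dataclass
class GeneRecord:
    """A validated unique gene: nucleotide ORF, deduced protein, provenance.

    ``support`` counts how many clones of each genotype collapsed onto
    this sequence during dereplication.
    """

    gene_id: str
    orf: str
    protein: str
    support: dict[str, int] = field(default_factory=dict)
    locus: str = UNASSIGNED

    @property
    def total_support(self) -> int:
        return sum(self.support.values())

    @property
    def observed_in(self) -> set[str]:
        return {g for g, n in self.support.items() if n > 0}


@dataclass(frozen=True)
class GenotypeDesign:
    """Map genotype -> retained ``Gli-2`` loci, plus the full-complement reference."""

    retained: dict[str, frozenset[str]]
    reference: str

    def __post_init__(self) -> None:
        for genotype, loci in self.retained.items():
            unknown = set(loci) - set(GLI2_LOCI)
            if unknown:
                raise ValueError(f"{genotype}: unknown loci {sorted(unknown)}")
        if self.reference not in self.retained:
            raise ValueError(f"reference genotype {self.reference!r} not in design")
        if set(self.retained[self.reference]) != set(GLI2_LOCI):
            raise ValueError(
                f"reference genotype {self.reference!r} must retain all loci"
            )

    @property
    def genotypes(self) -> list[str]:
        return list(self.retained)

    def retains(self, genotype: str) -> frozenset[str]:
        return self.retained[genotype]


def study_design() -> GenotypeDesign:
    """The four-genotype study design: euploid Pegaso plus the
    Gli-A2, Gli-D2 and Gli-A2/Gli-D2 deletion lines."""
    return GenotypeDesign(
        retained={
            PEGASO: frozenset(GLI2_LOCI),
            DEL_A2: frozenset({"Gli-B2", "Gli-D2"}),
            DEL_D2: frozenset({"Gli-A2", "Gli-B2"}),
            DEL_A2D2: frozenset({"Gli-B2"}),
        },
        reference=PEGASO,
    )
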