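"""FASTA and manifest I/O.

Internal coordinates throughout the package are 0-based half-open;
report output uses 1-based inclusive positions.  FASTA parsing goes
through Biopython; sequences are upper-cased on read and validated
against the requested alphabet, with errors naming the offending
record.
"""

from __future__ import annotations

import os

import yaml
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord
from Bio.Seq import Seq

from .records import GLI2_LOCI, GenotypeDesign

_ALPHABETS = {
    "dna": set("ACGTN"),
    "protein": set("ACDEFGHIKLMNPQRSTVWY*"),
}


def read_fasta(path, alphabet: str = "dna") -> list[tuple[str, str]]:
    """Read a FASTA file into an ordered list of ``(id, sequence)``.

    Duplicate ids or characters outside the alphabet raise ``ValueError``.
    """
    allowed = _ALPHABETS[alphabet]
    out: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(os.fspath(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        bad = set(seq) - allowed
        if bad:
            raise ValueError(
                f"record {rec.id!r} in {path}: characters {sorted(bad)} "
                f"not in {alphabet} alphabet"
            )
        out.append((rec.id, seq))
    return out


def write_fasta(path, records: list[tuple[str, str]], width: int = 60) -> None:
    """Write ``(id, sequence)`` pairs as FASTA (fixed line wrapping)."""
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_genotype_manifest(path) -> GenotypeDesign:
    """Read a YAML manifest mapping each genotype to the ``Gli-2`` loci
    it retains, e.g.::

        Pegaso:   [Gli-A2, Gli-B2, Gli-D2]
        dGliA2:   [Gli-B2, Gli-D2]

    The reference genotype is the one retaining all three loci; its
    absence is an error.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or not raw:
        raise ValueError(f"manifest {path}: expected a genotype -> loci mapping")
    retained = {}
    for genotype, loci in raw.items():
        if isinstance(loci, str):
            loci = [loci]
        retained[str(genotype)] = frozenset(str(l) for l in loci)
    reference = None
    for genotype, loci in retained.items():
        if set(loci) == set(GLI2_LOCI):
            reference = genotype
            break
    if reference is None:
        raise ValueError(
            f"manifest {path}: no genotype retains all loci {GLI2_LOCI} "
            "(a full-complement reference is required)"
        )
    return GenotypeDesign(retained=retained, reference=reference)


def write_genotype_manifest(path, design: GenotypeDesign) -> None:
    raw = {g: sorted(loci) for g, loci in design.retained.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)
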