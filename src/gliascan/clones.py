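"""Clone-library cleanup: ORF validation, translation, chimera
detection and dereplication.

RT-PCR amplicon libraries of a multigene family contain, besides
faithful copies of expressed genes, (i) clones of pseudogenes carrying
premature in-frame stop codons, (ii) artificial chimeras produced by
template switching during PCR, and (iii) many redundant clones of the
same gene.  This module turns a raw clone library into validated unique
genes by discarding (i) and (ii) and collapsing (iii) with per-genotype
support counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from Bio.Data import CodonTable

from .records import CloneRecord, GeneRecord

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_STANDARD.stop_codons)  # TAA, TAG, TGA


class OrfStatus(Enum):
    COMPLETE = "COMPLETE"
    PSEUDOGENE = "PSEUDOGENE"
    MALFORMED = "MALFORMED"


@dataclass(frozen=True)
class OrfValidation:
    status: OrfStatus
    start: int
    end: int
    #: codon index of the first premature stop, if any (0-based)
    premature_stop_codon: int | None = None


def validate_orf(sequence: str) -> OrfValidation:
    """Classify a putative full-length coding sequence.

    COMPLETE: starts with ATG, length divisible by 3, ends with exactly
    one stop codon and has no internal in-frame stop.  PSEUDOGENE:
    ATG-initiated in-frame sequence whose defining lesion is a premature
    in-frame stop codon.  Everything else is MALFORMED.
    """
    seq = sequence.upper()
    n = len(seq)
    if n < 6 or not seq.startswith("ATG") or n % 3 != 0:
        return OrfValidation(OrfStatus.MALFORMED, 0, n)
    internal = [
        i // 3 for i in range(3, n - 3, 3) if seq[i : i + 3] in STOP_CODONS
    ]
    if internal:
        return OrfValidation(OrfStatus.PSEUDOGENE, 0, n, internal[0])
    if seq[n - 3 :] not in STOP_CODONS:
        return OrfValidation(OrfStatus.MALFORMED, 0, n)
    return OrfValidation(OrfStatus.COMPLETE, 0, n)


def translate(orf: str) -> str:
    """Translate a COMPLETE ORF with the standard genetic code and strip
    the terminal stop.  Ambiguous or unknown codons raise ``ValueError``
    naming the offending codon position (1-based codon index)."""
    seq = orf.upper()
    if len(seq) % 3 != 0:
        raise ValueError("ORF length not divisible by 3")
    protein = []
    n_codons = len(seq) // 3
    for i in range(n_codons):
        codon = seq[3 * i : 3 * i + 3]
        if codon in STOP_CODONS:
            if i == n_codons - 1:
                break
            raise ValueError(f"internal stop codon {codon} at codon {i + 1}")
        try:
            protein.append(_STANDARD.forward_table[codon])
        except KeyError:
            raise ValueError(
                f"ambiguous or invalid codon {codon!r} at codon {i + 1}"
            ) from None
    else:
        raise ValueError("ORF does not end with a stop codon")
    return "".join(protein)


def _encode_padded(seqs: list[str], length: int, pad: int) -> np.ndarray:
    arr = np.full((len(seqs), length), pad, dtype=np.uint8)
    for k, s in enumerate(seqs):
        arr[k, : len(s)] = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
    return arr


def detect_chimeras(
    clones: list[CloneRecord], max_mismatch: int = 1
) -> set[str]:
    """Flag clones explainable as single-crossover PCR chimeras.

    A clone is flagged iff there exist two *distinct other* sequences
    P1 != P2 in the library and an interior breakpoint ``b`` such that
    ``P1[:b] + P2[b:]`` matches the clone with at most ``max_mismatch``
    total mismatches, and the clone differs from both parents.
    Sequences of unequal length are compared anchored at the 5' end over
    the candidate's length; positions beyond a shorter parent's end
    count as mismatches.

    Parents are never flagged by their own children: a sequence that is
    itself explainable as a chimera *using the candidate as one of its
    parents*, and that is not better supported (clone count) than the
    candidate, is disqualified from serving as a parent of that
    candidate.  Without this guard every chimera would symmetrically
    implicate the genuine sequences it was copied from; the abundance
    condition resolves ties the way PCR artifacts behave (chimeras are
    rare relative to their templates).
    """
    if len(clones) < 3:
        return set()
    distinct = sorted({c.sequence for c in clones})
    n = len(distinct)
    if n < 3:
        return set()
    L = max(len(s) for s in distinct)
    parents = _encode_padded(distinct, L, pad=1)
    lengths = np.array([len(s) for s in distinct])
    counts: dict[str, int] = {}
    for c in clones:
        counts[c.sequence] = counts.get(c.sequence, 0) + 1
    support = np.array([counts[s] for s in distinct])

    # explain[c][i, j] = candidate c matches P_i[:b] + P_j[b:] for some
    # interior b with <= max_mismatch mismatches, with all validity
    # conditions (i != j != c, candidate differs from both parents)
    explain = np.zeros((n, n, n), dtype=bool)
    for ci, cand in enumerate(distinct):
        Lc = len(cand)
        carr = np.frombuffer(cand.encode("ascii"), dtype=np.uint8)
        mism = parents[:, :Lc] != carr[None, :]
        prefix = np.zeros((n, Lc + 1), dtype=np.int32)
        np.cumsum(mism, axis=1, out=prefix[:, 1:])
        total = prefix[:, -1]
        differs = (total > 0) | (lengths != Lc)
        differs[ci] = False
        if differs.sum() < 2:
            continue
        suffix = total[:, None] - prefix
        pre = prefix[:, 1:Lc]
        suf = suffix[:, 1:Lc]
        ok = np.zeros((n, n), dtype=bool)
        for i in np.flatnonzero(differs):
            best = (pre[i][None, :] + suf).min(axis=1)
            ok[i] = best <= max_mismatch
        ok &= differs[None, :] & differs[:, None]
        np.fill_diagonal(ok, False)
        explain[ci] = ok

    # child_of[p, x]: p is explainable as a chimera with x as a parent
    child_of = explain.any(axis=1) | explain.any(axis=2)
    flagged_seqs = set()
    for ci in range(n):
        # disqualified parents: plausible children of the candidate that
        # are not better supported than it
        allowed = ~(child_of[:, ci] & (support <= support[ci]))
        if (explain[ci] & allowed[:, None] & allowed[None, :]).any():
            flagged_seqs.add(distinct[ci])
    return {c.clone_id for c in clones if c.sequence in flagged_seqs}


def dereplicate(
    clones: list[CloneRecord], min_support: int = 1
) -> list[GeneRecord]:
    """Collapse clones at exact nucleotide identity into unique genes.

    Input clones must already be COMPLETE and non-chimeric.  One
    ``GeneRecord`` per distinct sequence, with per-genotype clone
    support; groups whose total support is below ``min_support`` are
    dropped.  Output order is deterministic (sorted by sequence), and
    provisional ids ``g001, g002, ...`` follow that order.
    """
    groups: dict[str, dict[str, int]] = {}
    for clone in clones:
        support = groups.setdefault(clone.sequence, {})
        support[clone.genotype] = support.get(clone.genotype, 0) + 1
    genes = []
    for rank, seq in enumerate(sorted(groups), start=1):
        support = groups[seq]
        if sum(support.values()) < min_support:
            continue
        genes.append(
            GeneRecord(
                gene_id=f"g{rank:03d}",
                orf=seq,
                protein=translate(seq),
                support=dict(sorted(support.items())),
            )
        )
    return genes


@dataclass(frozen=True)
class FilterResult:
    """Outcome of the full cleanup of one or more clone libraries."""

    genes: list[GeneRecord]
    audit: list[tuple[str, str, str]]  # (clone id, status, reason)

    def status_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for _, status, _ in self.audit:
            out[status] = out.get(status, 0) + 1
        return out


def filter_libraries(
    libraries: dict[str, list[CloneRecord]],
    min_support: int = 1,
    max_mismatch: int = 1,
) -> FilterResult:
    """Full cleanup: ORF-validate every clone, drop pseudogenes and
    malformed clones, flag and drop chimeras within each library, then
    dereplicate the surviving clones across all genotypes."""
    audit: list[tuple[str, str, str]] = []
    kept: list[CloneRecord] = []
    for genotype, clones in libraries.items():
        complete: list[CloneRecord] = []
        for clone in clones:
            v = validate_orf(clone.sequence)
            if v.status is OrfStatus.COMPLETE:
                complete.append(clone)
            elif v.status is OrfStatus.PSEUDOGENE:
                audit.append(
                    (clone.clone_id, "PSEUDOGENE",
                     f"premature stop at codon {v.premature_stop_codon + 1}")
                )
            else:
                audit.append((clone.clone_id, "MALFORMED", "not a full-length ORF"))
        chimeric = detect_chimeras(complete, max_mismatch=max_mismatch)
        for clone in complete:
            if clone.clone_id in chimeric:
                audit.append((clone.clone_id, "CHIMERA", "single-crossover artifact"))
            else:
                audit.append((clone.clone_id, "COMPLETE", "kept"))
                kept.append(clone)
    return FilterResult(genes=dereplicate(kept, min_support=min_support), audit=audit)
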