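"""Domain architecture of α-type gliadin proteins.

The deduced protein of an α-type gliadin decomposes into a 20-residue
signal peptide (P) followed by five domains: the repetitive N-terminal
domain (R1), polyglutamine domain 1 (QR1), unique domain 1 (NR1),
polyglutamine domain 2 (QR2) and the unique C-terminal domain (NR2).
Segmentation exploits the fact that the two polyglutamine domains are
the only long glutamine-rich runs in the protein: QR1 and QR2 are found
as the two best non-overlapping Q-rich runs of the mature protein, and
the remaining stretches become R1, NR1 and NR2.

The module also counts the QPQLPYP heptapeptide (responsible for R1
length polymorphism on the D genome), censuses cysteines — six at
conserved positions, with a diagnostic seventh in NR2 caused by a
TCC(Ser)→TGC(Cys) point mutation — and computes the average molecular
weight of the deduced protein.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from Bio.SeqUtils import molecular_weight as _bio_mw

DOMAIN_ORDER = ("P", "R1", "QR1", "NR1", "QR2", "NR2")

#: Conserved-size expectations used only for soft validation warnings.
_NR1_EXPECTED = (68, 69)
_NR2_EXPECTED = (76, 78)

HEPTAPEPTIDE = "QPQLPYP"


class SegmentationError(ValueError):
    """Raised when a protein cannot be decomposed into the six segments."""


@dataclass(frozen=True)
class DomainPartition:
    """Six contiguous, exhaustive intervals over the protein
    (0-based half-open)."""

    intervals: dict[str, tuple[int, int]]
    warnings_: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        prev_end = 0
        for name in DOMAIN_ORDER:
            start, end = self.intervals[name]
            if start != prev_end or end < start:
                raise ValueError(f"domain {name}: intervals must tile the protein")
            prev_end = end

    def length(self, name: str) -> int:
        start, end = self.intervals[name]
        return end - start

    @property
    def lengths(self) -> dict[str, int]:
        return {name: self.length(name) for name in DOMAIN_ORDER}

    def extract(self, protein: str, name: str) -> str:
        start, end = self.intervals[name]
        return protein[start:end]

    def domain_of(self, position: int) -> str:
        for name in DOMAIN_ORDER:
            start, end = self.intervals[name]
            if start <= position < end:
                return name
        raise ValueError(f"position {position} outside protein")


def _q_rich_runs(
    seq: str, min_len: int, min_q_fraction: float, max_gap: int
) -> list[tuple[int, int]]:
    """Maximal glutamine-rich runs: intervals starting and ending with Q,
    with at most ``max_gap`` consecutive non-Q residues, length >=
    ``min_len`` and overall Q fraction >= ``min_q_fraction``.  A maximal
    interval failing the Q-fraction constraint is split at its widest
    internal non-Q gap and the parts are reconsidered."""
    # maximal Q-blocks, then merge across gaps of <= max_gap
    blocks: list[tuple[int, int]] = []
    i = 0
    n = len(seq)
    while i < n:
        if seq[i] == "Q":
            j = i
            while j < n and seq[j] == "Q":
                j += 1
            blocks.append((i, j))
            i = j
        else:
            i += 1
    merged: list[list[tuple[int, int]]] = []
    for b in blocks:
        if merged and b[0] - merged[-1][-1][1] <= max_gap:
            merged[-1].append(b)
        else:
            merged.append([b])

    runs: list[tuple[int, int]] = []

    def consider(group: list[tuple[int, int]]) -> None:
        start, end = group[0][0], group[-1][1]
        length = end - start
        n_q = sum(e - s for s, e in group)
        if length >= min_len and n_q / length >= min_q_fraction:
            runs.append((start, end))
        elif len(group) > 1:
            gaps = [group[k + 1][0] - group[k][1] for k in range(len(group) - 1)]
            k = max(range(len(gaps)), key=gaps.__getitem__)
            consider(group[: k + 1])
            consider(group[k + 1 :])

    for group in merged:
        consider(group)
    return sorted(runs)


def segment_domains(
    protein: str,
    signal_peptide_length: int = 20,
    min_run_length: int = 6,
    min_q_fraction: float = 0.8,
    max_gap: int = 2,
) -> DomainPartition:
    """Decompose a deduced α-gliadin protein into P + R1 + QR1 + NR1 +
    QR2 + NR2.

    QR1 and QR2 are the two best (longest; leftmost on ties)
    non-overlapping Q-rich runs of the mature protein, taken left to
    right.  Fewer than two qualifying runs is a ``SegmentationError``.
    """
    if len(protein) <= signal_peptide_length + 2 * min_run_length:
        raise SegmentationError(
            f"protein of {len(protein)} aa too short for segmentation"
        )
    mature = protein[signal_peptide_length:]
    runs = _q_rich_runs(mature, min_run_length, min_q_fraction, max_gap)
    if len(runs) < 2:
        raise SegmentationError(
            f"found {len(runs)} qualifying glutamine-rich run(s); "
            "two are required (QR1 and QR2)"
        )
    # two best by length (leftmost-longest on ties), then left-to-right
    best = sorted(runs, key=lambda r: (-(r[1] - r[0]), r[0]))[:2]
    (q1s, q1e), (q2s, q2e) = sorted(best)
    off = signal_peptide_length
    intervals = {
        "P": (0, off),
        "R1": (off, off + q1s),
        "QR1": (off + q1s, off + q1e),
        "NR1": (off + q1e, off + q2s),
        "QR2": (off + q2s, off + q2e),
        "NR2": (off + q2e, len(protein)),
    }
    warns = []
    nr1 = intervals["NR1"][1] - intervals["NR1"][0]
    nr2 = intervals["NR2"][1] - intervals["NR2"][0]
    if not (_NR1_EXPECTED[0] <= nr1 <= _NR1_EXPECTED[1]):
        warns.append(f"NR1 length {nr1} outside conserved range {_NR1_EXPECTED}")
    if not (_NR2_EXPECTED[0] <= nr2 <= _NR2_EXPECTED[1]):
        warns.append(f"NR2 length {nr2} outside conserved range {_NR2_EXPECTED}")
    return DomainPartition(intervals=intervals, warnings_=tuple(warns))


def count_heptapeptide(region: str, motif: str = HEPTAPEPTIDE) -> int:
    """Number of (possibly overlapping) exact occurrences of the motif."""
    count = 0
    start = region.find(motif)
    while start != -1:
        count += 1
        start = region.find(motif, start + 1)
    return count


@dataclass(frozen=True)
class CysteineCensus:
    total: int
    positions_by_domain: dict[str, tuple[int, ...]]
    extra_nr2_cysteine: bool
    #: codon (from the ORF) at the extra NR2 cysteine, if flagged
    extra_codon: str | None = None
    extra_position: int | None = None

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(
            sorted(p for ps in self.positions_by_domain.values() for p in ps)
        )


def cysteine_census(
    protein: str, partition: DomainPartition, orf: str
) -> CysteineCensus:
    """Census cysteine residues per domain and detect the diagnostic
    seventh cysteine of the NR2 domain.

    The extra flag is set iff the protein has seven cysteines and the
    odd one lies in NR2; the underlying codon is reported (TGC is the
    expected mutant of the conserved TCC serine codon).
    """
    if len(orf) != 3 * (len(protein) + 1):
        raise ValueError(
            f"ORF of {len(orf)} nt does not encode a {len(protein)} aa protein"
        )
    by_domain: dict[str, list[int]] = {name: [] for name in DOMAIN_ORDER}
    for pos, aa in enumerate(protein):
        if aa == "C":
            by_domain[partition.domain_of(pos)].append(pos)
    total = sum(len(v) for v in by_domain.values())
    extra = total == 7 and len(by_domain["NR2"]) >= 1
    codon = position = None
    if extra:
        # the odd cysteine is the last one of NR2 (the six conserved
        # cysteines occupy the earlier conserved positions)
        position = by_domain["NR2"][-1]
        codon = orf[3 * position : 3 * position + 3]
    return CysteineCensus(
        total=total,
        positions_by_domain={k: tuple(v) for k, v in by_domain.items()},
        extra_nr2_cysteine=extra,
        extra_codon=codon,
        extra_position=position,
    )


def molecular_weight(protein: str) -> float:
    """Average molecular weight (Da) of the deduced protein, signal
    peptide included: sum of average residue masses plus one water."""
    if not protein:
        raise ValueError("empty protein")
    try:
        return float(_bio_mw(protein, seq_type="protein"))
    except ValueError as err:
        raise ValueError(f"cannot compute molecular weight: {err}") from err


def domain_report_row(
    gene_id: str, protein: str, orf: str, **segment_kwargs
) -> dict:
    """One row of the per-gene domain report (lengths, heptapeptide and
    cysteine censuses, molecular weight)."""
    partition = segment_domains(protein, **segment_kwargs)
    census = cysteine_census(protein, partition, orf)
    row = {"gene_id": gene_id, "protein_length": len(protein)}
    row.update({name: partition.length(name) for name in DOMAIN_ORDER})
    row["heptapeptide_count"] = count_heptapeptide(partition.extract(protein, "R1"))
    row["n_cysteines"] = census.total
    row["extra_nr2_cysteine"] = census.extra_nr2_cysteine
    row["extra_codon"] = census.extra_codon or ""
    row["mw_da"] = round(molecular_weight(protein), 1)
    if partition.warnings_:
        warnings.warn(f"{gene_id}: " + "; ".join(partition.warnings_))
    return row
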