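"""Synthetic α-gliadin gene families, clone libraries and qPCR tables.

The generator emulates the statistical structure of an RT-PCR clone
study of the α-gliadin multigene family in a euploid wheat cultivar and
its Gli-2 deletion lines, with complete ground truth for every
downstream stage:

* a gene family split across the three ``Gli-2`` loci (default
  18/12/19), each gene a complete ORF whose deduced protein is
  signal peptide + R1 + QR1 + NR1 + QR2 + NR2 with locus-specific
  domain-length ranges and protein lengths spanning 281–319 aa
  (846–960 bp);
* celiac epitopes planted into R1 (and the C-terminal epitope into
  NR2) so that per-locus carrier counts equal configured marginals
  exactly; the containment structure of the panel (33-mer ⊃
  a-Glia(56-75) ⊃ Glia-α2/Glia-α9, ...) is honored, and every
  template is verified by a full scan after construction;
* six conserved cysteines per protein, with a seventh NR2 cysteine
  (TCC→TGC) in designated genes;
* clone libraries per genotype containing faithful copies, exact
  duplicates, single-crossover PCR chimeras and pseudogenized copies
  (one induced in-frame stop) at configured rates;
* tidy Cq tables with planted fold changes for the ΔΔCq module.

Planting strategy for R1: epitope strings are concatenated as blocks
separated by ``GG``.  No epitope of the panel contains ``GG`` or starts
with G, so no epitope match can cross a separator; the filler used to
pad R1 to its target length uses only {P,Q,F}, and every epitope of the
panel contains at least one of G/L/S/R/Y, so the filler can never
contain an epitope.  The only deliberate junction is
a-Glia(31-55) + a-Glia(56-75)/33-mer written adjacently, which recreates
the natural overlap a-Glia(51-70) spanning them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clones import OrfStatus, translate, validate_orf
from .domains import count_heptapeptide, cysteine_census, segment_domains
from .epitopes import DEFAULT_EPITOPES, EPITOPE_BY_NAME, scan_epitope
from .records import (
    CloneRecord,
    DEL_A2,
    DEL_A2D2,
    DEL_D2,
    GLI2_LOCI,
    GeneRecord,
    GenotypeDesign,
    PEGASO,
    study_design,
)


class ConfigurationError(ValueError):
    pass


class GenerationError(RuntimeError):
    pass


SIGNAL_PEPTIDE = "MKTFLILALLAIVATTATTA"  # 20 aa, starts with Met

#: Most-frequent wheat codon per residue (small built-in table; the
#: conserved NR2 serine uses TCC so that the Ser->Cys mutation is the
#:  documented TCC->TGC change).
CODON = {
    "A": "GCC", "R": "AGG", "N": "AAC", "D": "GAC", "C": "TGC",
    "Q": "CAA", "E": "GAG", "G": "GGC", "H": "CAC", "I": "ATC",
    "L": "CTC", "K": "AAG", "M": "ATG", "F": "TTC", "P": "CCA",
    "S": "TCC", "T": "ACC", "W": "TGG", "Y": "TAC", "V": "GTG",
}
STOP = "TAA"

_SEP = "GG"
_FILLER_UNIT = "PQQPFP"
_NR_ALPHABET = "AVILFPSTNHE"  # background letters; Q added sparsely, C planted

NR2_EPITOPE = "a-Glia(206-217)"
R1_EPITOPES = tuple(e.name for e in DEFAULT_EPITOPES if e.name != NR2_EPITOPE)

#: cysteine offsets within NR1 / NR2, and the mutable serine site
_NR1_CYS = (8, 25, 47)
_NR2_CYS = (30, 45, 60)
_NR2_EXTRA_SITE = 66
_NR2_EPITOPE_OFFSET = 5


def _implied() -> dict[str, frozenset[str]]:
    """name -> names of strictly contained panel epitopes."""
    out = {}
    for e in DEFAULT_EPITOPES:
        out[e.name] = frozenset(
            f.name
            for f in DEFAULT_EPITOPES
            if f.name != e.name and f.peptide in e.peptide
        )
    return out


_IMPLIED = _implied()
#: containers first: an epitope always follows everything that contains it
_TOPO_ORDER = tuple(
    sorted(
        (e.name for e in DEFAULT_EPITOPES),
        key=lambda n: (-len(_IMPLIED[n]), -len(EPITOPE_BY_NAME[n].peptide), n),
    )
)


def default_epitope_marginals() -> dict[tuple[str, str], int]:
    """Per-(locus, epitope) carrier counts of the reference family.

    Derived from the published per-locus specificity of the panel;
    summed over loci they give 96 immunogenic and 111 toxic carriers
    for the full complement and 13/17 for the Gli-B2-only set.
    """
    a2 = {"Glia-a9": 12, "Glia-a20": 15, "a-Glia(44-55)": 10,
          "a-Glia(51-70)": 6, NR2_EPITOPE: 18}
    b2 = {"Glia-a": 11, "Glia-a9": 1, "Glia-a20": 1, "a-Glia(31-43)": 6,
          "a-Glia(31-49)": 5, "a-Glia(44-55)": 5, "a-Glia(51-70)": 1}
    d2 = {"Glia-a": 13, "Glia-a2": 13, "Glia-a9": 17, "Glia-a20": 9,
          "33-mer": 4, "a-Glia(31-43)": 16, "a-Glia(31-49)": 9,
          "a-Glia(31-55)": 9, "a-Glia(44-55)": 12, "a-Glia(51-70)": 9,
          "a-Glia(56-75)": 5}
    out: dict[tuple[str, str], int] = {}
    for locus, table in (("Gli-A2", a2), ("Gli-B2", b2), ("Gli-D2", d2)):
        for name, count in table.items():
            out[(locus, name)] = count
    return out


def default_domain_length_ranges() -> dict[tuple[str, str], tuple[int, int]]:
    return {
        ("Gli-A2", "R1"): (92, 92),
        ("Gli-A2", "QR1"): (18, 29),
        ("Gli-A2", "NR1"): (68, 68),
        ("Gli-A2", "QR2"): (8, 8),
        ("Gli-A2", "NR2"): (77, 77),
        ("Gli-B2", "QR1"): (21, 33),
        ("Gli-B2", "NR1"): (68, 69),
        ("Gli-B2", "QR2"): (7, 33),
        ("Gli-B2", "NR2"): (76, 78),
        ("Gli-D2", "QR1"): (12, 25),
        ("Gli-D2", "NR1"): (68, 69),
        ("Gli-D2", "QR2"): (8, 18),
        ("Gli-D2", "NR2"): (76, 78),
    }


def default_effect_sizes() -> dict[tuple[str, str], float]:
    """True fold changes vs the euploid calibrator for the seven assays:
    the α-gliadin assay (Gli), four γ-gliadin assays (G1-G4) and two
    ω-gliadin assays (Q18, Q21)."""
    folds: dict[tuple[str, str], float] = {}
    assays = ("Gli", "G1", "G2", "G3", "G4", "Q18", "Q21")
    for a in assays:
        folds[(PEGASO, a)] = 1.0
    folds.update({(DEL_A2, a): 1.0 for a in assays})
    folds[(DEL_A2, "Gli")] = 0.75
    folds.update({(DEL_D2, a): 1.0 for a in assays})
    folds.update({(DEL_D2, "Gli"): 0.38, (DEL_D2, "G1"): 2.0,
                  (DEL_D2, "G2"): 3.0, (DEL_D2, "G3"): 4.0, (DEL_D2, "G4"): 6.0})
    folds.update({(DEL_A2D2, a): 1.0 for a in assays})
    folds.update({(DEL_A2D2, "Gli"): 0.20, (DEL_A2D2, "G1"): 2.5,
                  (DEL_A2D2, "G2"): 3.5, (DEL_A2D2, "G3"): 5.0,
                  (DEL_A2D2, "G4"): 6.0, (DEL_A2D2, "Q18"): 1.8,
                  (DEL_A2D2, "Q21"): 1.6})
    return folds


@dataclass
class SyntheticConfig:
    per_locus_gene_counts: dict[str, int] = field(
        default_factory=lambda: {"Gli-A2": 18, "Gli-B2": 12, "Gli-D2": 19})
    domain_length_ranges: dict[tuple[str, str], tuple[int, int]] = field(
        default_factory=default_domain_length_ranges)
    total_length_ranges: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {"Gli-A2": (283, 294), "Gli-B2": (312, 319),
                                 "Gli-D2": (282, 309)})
    #: per-gene overrides of the protein-length range (e.g. the three
    #: short Gli-B2 genes)
    total_length_overrides: dict[tuple[str, int], tuple[int, int]] = field(
        default_factory=lambda: {("Gli-B2", 7): (284, 300),
                                 ("Gli-B2", 8): (284, 300)})
    #: per-gene exact domain lengths pinning the family's length extremes
    domain_length_anchors: dict[tuple[str, int], dict[str, int]] = field(
        default_factory=lambda: {
            ("Gli-B2", 0): {"R1": 89, "QR1": 21, "NR1": 68, "QR2": 7, "NR2": 76},
            ("Gli-B2", 1): {"R1": 90, "QR1": 33, "NR1": 69, "QR2": 29, "NR2": 78},
            ("Gli-A2", 0): {"QR1": 18},
            ("Gli-A2", 1): {"QR1": 29},
        })
    heptapeptide_copy_range: tuple[int, int] = (1, 3)
    heptapeptide_carriers: dict[str, int] = field(
        default_factory=lambda: {"Gli-D2": 16})
    planted_epitope_marginals: dict[tuple[str, str], int] = field(
        default_factory=default_epitope_marginals)
    extra_cysteine_assignments: tuple[tuple[str, int], ...] = (
        ("Gli-B2", 0), ("Gli-D2", 3), ("Gli-D2", 4), ("Gli-D2", 5),
        ("Gli-D2", 6), ("Gli-D2", 7))
    clone_library_sizes: dict[str, int] = field(
        default_factory=lambda: {PEGASO: 104, DEL_A2: 101, DEL_D2: 107,
                                 DEL_A2D2: 69})
    pseudogene_rate: float = 0.03
    chimera_rate: float = 0.03
    #: "coverage_first": duplicate slots first bring every retained
    #: template to two clones (deep-library behavior, which also gives
    #: chimera detection its abundance asymmetry), then draw uniformly;
    #: "uniform": all duplicate slots drawn uniformly.
    redundancy_model: str = "coverage_first"
    design: GenotypeDesign = field(default_factory=study_design)
    signal_peptide: str = SIGNAL_PEPTIDE
    seed: int = 0

    def validate(self) -> None:
        for locus, n in self.per_locus_gene_counts.items():
            if locus not in GLI2_LOCI or n < 0:
                raise ConfigurationError(f"bad locus gene count {locus}={n}")
        for (locus, name), count in self.planted_epitope_marginals.items():
            if name not in EPITOPE_BY_NAME:
                raise ConfigurationError(f"unknown epitope {name!r}")
            if count < 0 or count > self.per_locus_gene_counts.get(locus, 0):
                raise ConfigurationError(
                    f"marginal {name}@{locus}={count} exceeds locus size")
        for key, (lo, hi) in self.domain_length_ranges.items():
            if lo > hi or lo < 0:
                raise ConfigurationError(f"bad length range {key}: ({lo}, {hi})")
        for rate in (self.pseudogene_rate, self.chimera_rate):
            if not 0.0 <= rate < 1.0:
                raise ConfigurationError(f"rate {rate} outside [0, 1)")
        lo, hi = self.heptapeptide_copy_range
        if not (0 <= lo <= hi):
            raise ConfigurationError("bad heptapeptide copy range")
        if len(self.signal_peptide) < 1 or not self.signal_peptide.startswith("M"):
            raise ConfigurationError("signal peptide must start with Met")
        if self.redundancy_model not in ("coverage_first", "uniform"):
            raise ConfigurationError(
                f"unknown redundancy model {self.redundancy_model!r}")

    @classmethod
    def zero_noise(cls, **overrides) -> "SyntheticConfig":
        """The noise-free limit: no chimeras, no pseudogenes, and one
        clone per retained template, so each library equals its retained
        template set exactly."""
        cfg = cls(pseudogene_rate=0.0, chimera_rate=0.0, **overrides)
        cfg.clone_library_sizes = {
            genotype: sum(
                cfg.per_locus_gene_counts.get(locus, 0)
                for locus in cfg.design.retains(genotype)
            )
            for genotype in cfg.design.genotypes
        }
        return cfg


@dataclass
class TemplateTruth:
    """Ground truth for one synthetic gene template."""

    template_id: str
    locus: str
    orf: str
    protein: str
    boundaries: dict[str, tuple[int, int]]
    domain_lengths: dict[str, int]
    epitopes: frozenset[str]
    heptapeptide_count: int
    extra_cysteine: bool


@dataclass(frozen=True)
class CloneTruth:
    """Ground truth label for one emitted clone.

    ``label`` is one of faithful, duplicate, pseudogene, chimera;
    ``parents`` and ``breakpoint`` are set for chimeras only.
    """

    clone_id: str
    genotype: str
    label: str
    template_id: str | None = None
    parents: tuple[str, str] | None = None
    breakpoint: int | None = None


# ---------------------------------------------------------------- planting

def plant_carriers(
    n_genes: int, marginals: dict[str, int]
) -> dict[str, set[int]]:
    """Assign epitope carriers to gene indices, honoring containment:
    a gene planted with a container epitope necessarily carries every
    contained epitope, so contained marginals must be at least as large.
    Assignment is deterministic (lowest free index first)."""
    carriers: dict[str, set[int]] = {}
    for name in _TOPO_ORDER:
        m = marginals.get(name, 0)
        required: set[int] = set()
        for done, members in carriers.items():
            if name in _IMPLIED[done]:
                required |= members
        if len(required) > m:
            raise ConfigurationError(
                f"marginal {name}={m} contradicts the {len(required)} carriers "
                "implied by containing epitopes"
            )
        members = set(required)
        for g in range(n_genes):
            if len(members) == m:
                break
            members.add(g) if g not in members else None
        if len(members) != m:
            raise ConfigurationError(f"marginal {name}={m} exceeds locus size {n_genes}")
        carriers[name] = members
    return carriers


def _r1_blocks(designated: set[str]) -> list[str]:
    """Epitope strings to write into R1, containers first; the natural
    a-Glia(31-55)+a-Glia(56-75)/33-mer adjacency is used when (and only
    when) the spanning a-Glia(51-70) is itself designated."""
    pep = {n: EPITOPE_BY_NAME[n].peptide for n in R1_EPITOPES}
    blocks: list[str] = []

    def covered() -> set[str]:
        joined = _SEP + _SEP.join(blocks) + _SEP if blocks else ""
        return {n for n in R1_EPITOPES if pep[n] in joined}

    if ("a-Glia(31-55)" in designated and "a-Glia(51-70)" in designated
            and ("33-mer" in designated or "a-Glia(56-75)" in designated)):
        tail = "33-mer" if "33-mer" in designated else "a-Glia(56-75)"
        blocks.append(pep["a-Glia(31-55)"] + pep[tail])
    for name in _TOPO_ORDER:
        if name in designated and name in R1_EPITOPES and name not in covered():
            blocks.append(pep[name])
    got = covered()
    if got != designated:
        raise ConfigurationError(
            f"cannot plant epitope set {sorted(designated)} exactly "
            f"(construction yields {sorted(got)}); marginals are contradictory"
        )
    return blocks


def _filler(length: int) -> str:
    s = (_FILLER_UNIT * (length // len(_FILLER_UNIT) + 1))[:length]
    # a Q-free tail of width 3 (> the segmenter's gap tolerance) keeps
    # the filler from being absorbed into the adjacent polyglutamine run
    k = min(3, length)
    return s[: length - k] + s[length - k :].replace("Q", "P")


def _build_r1(blocks: list[str], length: int) -> str:
    core = _SEP + _SEP.join(blocks) + _SEP if blocks else ""
    if len(core) + 3 > length:
        raise ConfigurationError(
            f"planted epitopes need {len(core) + 3} aa but R1 is only {length} aa"
        )
    return core + _filler(length - len(core))


def _qr(length: int) -> str:
    if length >= 14:
        half = length // 2
        return "Q" * half + "L" + "Q" * (length - half - 1)
    return "Q" * length


def _background(rng: np.random.Generator, length: int, q_prob: float = 0.08) -> list[str]:
    letters = list(_NR_ALPHABET)
    chars = [letters[i] for i in rng.integers(0, len(letters), size=length)]
    for i in np.flatnonzero(rng.random(length) < q_prob):
        chars[int(i)] = "Q"
    # isolate glutamines and keep domain edges non-Q so that the
    # polyglutamine domains stay the only qualifying Q-rich runs
    for i in range(1, length):
        if chars[i] == "Q" and chars[i - 1] == "Q":
            chars[i] = "S"
    if chars[0] == "Q":
        chars[0] = "V"
    if chars[-1] == "Q":
        chars[-1] = "P"
    return chars


# ------------------------------------------------------------- family build

def _sample_lengths(
    config: SyntheticConfig,
    locus: str,
    idx: int,
    content_len: int,
    rng: np.random.Generator,
) -> dict[str, int]:
    anchor = config.domain_length_anchors.get((locus, idx), {})
    ranges = config.domain_length_ranges

    def draw(domain: str) -> int:
        if domain in anchor:
            return anchor[domain]
        lo, hi = ranges[(locus, domain)]
        return int(rng.integers(lo, hi + 1))

    lengths = {d: draw(d) for d in ("QR1", "NR1", "QR2", "NR2")}
    sig = len(config.signal_peptide)
    if "R1" in anchor:
        # anchored R1 is exact; infeasible planted content surfaces as a
        # configuration error during assembly
        lengths["R1"] = anchor["R1"]
    else:
        if (locus, "R1") in ranges:
            lo, hi = ranges[(locus, "R1")]
            lengths["R1"] = int(rng.integers(lo, hi + 1))
        else:
            lo, hi = config.total_length_overrides.get(
                (locus, idx), config.total_length_ranges[locus])
            total = int(rng.integers(lo, hi + 1))
            lengths["R1"] = total - sig - sum(lengths.values())
        lengths["R1"] = max(lengths["R1"], content_len + 3, 40)
    return lengths


def _verify_template(
    truth: TemplateTruth, designated: set[str], config: SyntheticConfig
) -> None:
    if validate_orf(truth.orf).status is not OrfStatus.COMPLETE:
        raise GenerationError(f"{truth.template_id}: ORF not COMPLETE")
    if translate(truth.orf) != truth.protein:
        raise GenerationError(f"{truth.template_id}: translation mismatch")
    found = {e.name for e in DEFAULT_EPITOPES
             if scan_epitope(truth.protein, e.peptide)}
    if found != designated:
        raise GenerationError(
            f"{truth.template_id}: epitope scan {sorted(found)} != "
            f"designated {sorted(designated)}"
        )
    part = segment_domains(
        truth.protein, signal_peptide_length=len(config.signal_peptide))
    if part.intervals != truth.boundaries:
        raise GenerationError(f"{truth.template_id}: segmentation drifted")
    cys = cysteine_census(truth.protein, part, truth.orf)
    expected = 7 if truth.extra_cysteine else 6
    if cys.total != expected or cys.extra_nr2_cysteine != truth.extra_cysteine:
        raise GenerationError(f"{truth.template_id}: cysteine census drifted")
    if truth.extra_cysteine and cys.extra_codon != "TGC":
        raise GenerationError(f"{truth.template_id}: extra codon is not TGC")


def _build_locus(
    config: SyntheticConfig, locus: str, rng: np.random.Generator
) -> list[TemplateTruth]:
    n = config.per_locus_gene_counts[locus]
    if n == 0:
        return []
    marginals = {
        name: count
        for (loc, name), count in config.planted_epitope_marginals.items()
        if loc == locus
    }
    carriers = plant_carriers(n, marginals)
    extra_cys = {i for (loc, i) in config.extra_cysteine_assignments if loc == locus}
    bad = {i for i in extra_cys if i >= n}
    if bad:
        raise ConfigurationError(f"extra-cysteine gene indices {sorted(bad)} "
                                 f"outside locus {locus} of size {n}")

    designated = [
        {name for name, members in carriers.items() if i in members}
        for i in range(n)
    ]
    blocks = [_r1_blocks(d - {NR2_EPITOPE}) for d in designated]

    # standalone heptapeptide copies to reach the configured carrier count
    target_hepta = config.heptapeptide_carriers.get(locus, 0)
    lo_copies, hi_copies = config.heptapeptide_copy_range
    has_hepta = [count_heptapeptide(_SEP.join(b)) > 0 for b in blocks]
    need = target_hepta - sum(has_hepta)
    if need > n - sum(has_hepta):
        raise ConfigurationError(
            f"heptapeptide carrier target {target_hepta} exceeds locus size {n}")
    for i in range(n):
        if need <= 0:
            break
        if not has_hepta[i]:
            copies = int(rng.integers(max(lo_copies, 1), hi_copies + 1))
            blocks[i].extend(["QPQLPYP"] * copies)
            need -= 1

    sig = config.signal_peptide
    base_nr1 = _background(rng, 69)
    base_nr2 = _background(rng, 78)
    # disjoint per-gene mutation slots, one in NR1 and one in NR2, keep
    # any two same-locus templates >= 4 substitutions apart with >= 2 on
    # either side of any crossover point (see chimera detection); slots
    # stay clear of junction margins, cysteines and the NR2 epitope site
    free_nr1 = [p for p in range(3, 63) if p not in _NR1_CYS]
    free_nr2 = [p for p in range(3, 63)
                if p not in _NR2_CYS
                and not (_NR2_EPITOPE_OFFSET <= p <
                         _NR2_EPITOPE_OFFSET + len(EPITOPE_BY_NAME[NR2_EPITOPE].peptide))]
    sub_cycle = "AVILFPSTN"

    templates: list[TemplateTruth] = []
    for i in range(n):
        core = _SEP + _SEP.join(blocks[i]) + _SEP if blocks[i] else ""
        lengths = _sample_lengths(config, locus, i, len(core), rng)
        r1 = _build_r1(blocks[i], lengths["R1"])
        qr1 = _qr(lengths["QR1"])
        qr2 = _qr(lengths["QR2"])

        nr1 = list(base_nr1[: lengths["NR1"]])
        nr2 = list(base_nr2[: lengths["NR2"]])
        for arr, free in ((nr1, free_nr1), (nr2, free_nr2)):
            if i < len(free):
                pos = free[i]
            else:  # very large custom locus: fall back to a random slot
                pos = int(rng.choice(free))
            old = arr[pos]
            new = sub_cycle[(sub_cycle.find(old) + 1 + i) % len(sub_cycle)]
            arr[pos] = new if new != old else sub_cycle[
                (sub_cycle.find(old) + 2 + i) % len(sub_cycle)]
        for pos in _NR1_CYS:
            nr1[pos] = "C"
        for pos in _NR2_CYS:
            nr2[pos] = "C"
        nr2[_NR2_EXTRA_SITE] = "C" if i in extra_cys else "S"
        if NR2_EPITOPE in designated[i]:
            pep = EPITOPE_BY_NAME[NR2_EPITOPE].peptide
            nr2[_NR2_EPITOPE_OFFSET : _NR2_EPITOPE_OFFSET + len(pep)] = list(pep)
        # Q-free margins (width 3 > segmenter gap tolerance) around the
        # polyglutamine-domain junctions keep boundaries exact
        for arr, positions in ((nr1, (0, 1, 2, -3, -2, -1)),
                               (nr2, (0, 1, 2))):
            for p in positions:
                if arr[p] == "Q":
                    arr[p] = "P" if p < 0 else "V"

        protein = sig + r1 + qr1 + "".join(nr1) + qr2 + "".join(nr2)
        orf = "".join(CODON[aa] for aa in protein) + STOP
        bounds, pos = {}, 0
        for name, part in (("P", sig), ("R1", r1), ("QR1", qr1),
                           ("NR1", "".join(nr1)), ("QR2", qr2),
                           ("NR2", "".join(nr2))):
            bounds[name] = (pos, pos + len(part))
            pos += len(part)
        truth = TemplateTruth(
            template_id=f"{locus}-{i + 1}",
            locus=locus,
            orf=orf,
            protein=protein,
            boundaries=bounds,
            domain_lengths={k: e - s for k, (s, e) in bounds.items()},
            epitopes=frozenset(designated[i]),
            heptapeptide_count=count_heptapeptide(r1),
            extra_cysteine=i in extra_cys,
        )
        _verify_template(truth, designated[i], config)
        templates.append(truth)
    return templates


def generate_gene_family(
    config: SyntheticConfig | None = None,
) -> tuple[list[GeneRecord], dict[str, TemplateTruth]]:
    """Generate the template gene family with full ground truth.

    Returns the templates as ``GeneRecord``s (locus set from truth,
    no clone support) plus the truth records keyed by template id.
    Identical config and seed give byte-identical output.
    """
    config = config or SyntheticConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes: list[GeneRecord] = []
    truth: dict[str, TemplateTruth] = {}
    for locus in GLI2_LOCI:
        if config.per_locus_gene_counts.get(locus, 0) == 0:
            continue
        for attempt in range(8):
            try:
                templates = _build_locus(config, locus, rng)
                break
            except GenerationError:
                if attempt == 7:
                    raise
        for t in templates:
            truth[t.template_id] = t
            genes.append(GeneRecord(gene_id=t.template_id, orf=t.orf,
                                    protein=t.protein, locus=t.locus))
    return genes, truth


# ------------------------------------------------------------ clone library

def generate_clone_library(
    templates: dict[str, TemplateTruth],
    config: SyntheticConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, list[CloneRecord]], dict[str, CloneTruth]]:
    """Emit one clone library per genotype of the design.

    Every retained template appears at least once (libraries are larger
    than the family); remaining slots are filled with exact duplicates,
    single-crossover chimeras between co-sampled templates, and
    pseudogenized copies, at the configured rates.  Library order is
    shuffled; truth labels are returned per clone id.
    """
    config = config or SyntheticConfig()
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    template_seqs = {t.orf for t in templates.values()}
    libraries: dict[str, list[CloneRecord]] = {}
    clone_truth: dict[str, CloneTruth] = {}
    for genotype in config.design.genotypes:
        retained_loci = config.design.retains(genotype)
        pool = [t for t in templates.values() if t.locus in retained_loci]
        size = config.clone_library_sizes.get(genotype, len(pool))
        if not pool:
            warnings.warn(
                f"genotype {genotype}: no templates at its retained loci, "
                "emitting an empty library")
            libraries[genotype] = []
            continue
        if size < len(pool):
            idx = rng.choice(len(pool), size=size, replace=False)
            pool = [pool[int(i)] for i in sorted(idx)]
        n_chimera = round(config.chimera_rate * size) if len(pool) >= 2 else 0
        n_pseudo = round(config.pseudogene_rate * size)
        spare = size - len(pool)
        n_chimera = min(n_chimera, spare)
        n_pseudo = min(n_pseudo, spare - n_chimera)
        n_dup = spare - n_chimera - n_pseudo

        entries: list[tuple[str, CloneTruth]] = []  # (sequence, truth template)
        for t in pool:
            entries.append((t.orf, CloneTruth("", genotype, "faithful", t.template_id)))
        dup_templates: list[TemplateTruth] = []
        if config.redundancy_model == "coverage_first":
            dup_templates.extend(pool[: n_dup])  # second copy of each template
        while len(dup_templates) < n_dup:
            dup_templates.append(pool[int(rng.integers(0, len(pool)))])
        for t in dup_templates:
            entries.append((t.orf, CloneTruth("", genotype, "duplicate", t.template_id)))
        for _ in range(n_pseudo):
            t = pool[int(rng.integers(0, len(pool)))]
            n_codons = len(t.orf) // 3
            codon_idx = int(rng.integers(1, n_codons - 1))
            seq = t.orf[: 3 * codon_idx] + STOP + t.orf[3 * codon_idx + 3 :]
            entries.append((seq, CloneTruth("", genotype, "pseudogene", t.template_id)))
        made = 0
        for _ in range(200 * n_chimera):
            if made == n_chimera:
                break
            i, j = rng.choice(len(pool), size=2, replace=False)
            t1, t2 = pool[int(i)], pool[int(j)]
            b = int(rng.integers(3, min(len(t1.orf), len(t2.orf)) - 3))
            child = t1.orf[:b] + t2.orf[b:]
            if (child == t1.orf or child == t2.orf or child in template_seqs
                    or validate_orf(child).status is not OrfStatus.COMPLETE):
                continue
            entries.append(
                (child, CloneTruth("", genotype, "chimera",
                                   parents=(t1.template_id, t2.template_id),
                                   breakpoint=b)))
            made += 1
        if made < n_chimera:
            raise GenerationError(
                f"{genotype}: could not inject {n_chimera} valid chimeras")

        order = rng.permutation(len(entries))
        clones: list[CloneRecord] = []
        for k, e in enumerate(order):
            seq, t = entries[int(e)]
            cid = f"{genotype}_c{k + 1:04d}"
            clones.append(CloneRecord(clone_id=cid, genotype=genotype, sequence=seq))
            clone_truth[cid] = CloneTruth(cid, genotype, t.label, t.template_id,
                                          t.parents, t.breakpoint)
        libraries[genotype] = clones
    return libraries, clone_truth


# ------------------------------------------------------------------- qPCR

def generate_cq_table(
    effect_sizes: dict[tuple[str, str], float] | None = None,
    noise_sd: float = 0.2,
    n_bio: int = 3,
    n_tech: int = 3,
    seed: int | None = 0,
    rng: np.random.Generator | None = None,
    reference_assay: str = "Ref",
    calibrator: str = PEGASO,
    base_cq: float = 20.0,
    assay_offset: float = 2.0,
    block_sd: float = 0.5,
) -> pd.DataFrame:
    """Simulate a tidy Cq table with planted fold changes.

    ``Cq_target = Cq_ref + dCq(calibrator) - log2(fold) + N(0, noise_sd)``
    per technical replicate, with a shared per-(genotype, biological
    replicate) baseline shift that the ΔCq normalization removes.
    """
    effect_sizes = effect_sizes if effect_sizes is not None else default_effect_sizes()
    if n_bio < 1 or n_tech < 1:
        raise ConfigurationError("replicate counts must be >= 1")
    for (g, a), fold in effect_sizes.items():
        if fold <= 0:
            raise ConfigurationError(f"fold change {fold} for {g}/{a} must be > 0")
    genotypes = sorted({g for g, _ in effect_sizes})
    if calibrator not in genotypes:
        raise ConfigurationError(f"calibrator {calibrator!r} has no effect sizes")
    assays = sorted({a for _, a in effect_sizes})
    if rng is None:
        rng = np.random.default_rng(seed)
    rows = []
    for g in genotypes:
        for b in range(1, n_bio + 1):
            shift = float(rng.normal(0.0, block_sd))
            baseline = base_cq + shift
            for t in range(1, n_tech + 1):
                rows.append((g, b, t, reference_assay,
                             baseline + float(rng.normal(0.0, noise_sd))))
            for a in assays:
                fold = effect_sizes.get((g, a))
                if fold is None:
                    continue
                mu = baseline + assay_offset - float(np.log2(fold))
                for t in range(1, n_tech + 1):
                    rows.append((g, b, t, a, mu + float(rng.normal(0.0, noise_sd))))
    return pd.DataFrame(rows, columns=["genotype", "bio_rep", "tech_rep",
                                       "assay", "cq"])
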