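# Methods

This note documents the models, algorithms and design choices behind
gliascan, in the order the pipeline runs them, followed by the
synthetic-data model and known limitations.

## Clone filtering

**ORF validation.** A clone is COMPLETE iff it starts with ATG, its
length is divisible by 3, it ends with exactly one stop codon
(TAA/TAG/TGA) and contains no internal in-frame stop. A PSEUDOGENE is
an ATG-initiated, in-frame sequence whose defining lesion is a
premature in-frame stop — the terminal codon need not be a stop, since
the premature stop is what inactivates the gene. Everything else is
MALFORMED. Translation uses the standard genetic code and reports the
1-based codon index of any ambiguous codon.

**Chimera detection.** The artifact model is a single template switch
during PCR: a chimera equals `P1[:b] + P2[b:]` for two genuine
templates and one interior breakpoint *b*. A clone is flagged when two
distinct other sequences of the same library reconstruct it this way
within `max_mismatch` total mismatches (default 1; sequences of unequal
length are compared anchored at the 5' end over the candidate's length,
with positions beyond a shorter parent counting as mismatches). The
search is exact and exhaustive over all ordered parent pairs and
breakpoints, implemented with prefix/suffix mismatch cumulative sums
(O(n²·L) per library after an O(n·L) precompute).

The naive symmetric rule is unusable on real mixtures: once a chimera
is present, each of its parents is itself "explainable" as a chimera of
the child plus any sequence sharing its other half. We therefore apply
a parent-eligibility guard: a sequence that is explainable as a chimera
*using the candidate as one of its parents* cannot serve as a parent of
that candidate, unless it has strictly greater clone support. The
abundance condition reflects how the artifact arises — chimeras form in
late PCR cycles and are rare relative to their templates — and is the
same asymmetry UCHIME-style detectors rely on. Detection runs on
COMPLETE clones only (pseudogenes are removed first), and flagged
clones are discarded before dereplication.

**Dereplication** groups clones at exact nucleotide identity — no
similarity threshold, because "unique genes" is an exact notion here;
collapsing sequencing errors is delegated to the `min_support`
parameter (default 1: every unique sequence is kept, since the source
libraries are Sanger-sequenced plasmid clones with low error rates).
Output order is sorted by sequence, making the whole filter stage
independent of input order.

## Locus assignment

Let R(g) be the loci retained by genotype g. A gene observed in the
genotype set O has candidate loci ⋂_{g∈O} R(g); under the completeness
assumption (default on), loci retained by any genotype where the gene
was *not* observed are removed as well. One survivor is the assignment;
several are AMBIGUOUS; none is INCONSISTENT — we report rather than
guess, because a gene seen only in the reference contradicts every
single-locus explanation under completeness. The completeness flag
exists because clone sampling is finite; with it off, non-observation
is treated as missing data and the intersection-only candidate set is
reported. Presence across genotypes is exact nucleotide identity,
consistent with dereplication.

## Domain segmentation

The α-gliadin architecture is P (signal peptide, fixed 20 aa by
configuration, not prediction — its size is strongly conserved) + R1 +
QR1 + NR1 + QR2 + NR2. The two polyglutamine domains are the only long
glutamine-rich runs, so segmentation finds maximal runs that start and
end with Q, allow at most 2 consecutive non-Q residues, have length ≥ 6
and overall Q fraction ≥ 0.8; a maximal run failing the fraction test
is split at its widest internal gap and the parts reconsidered. The two
longest qualifying runs (leftmost wins ties), taken left to right, are
QR1 and QR2; R1, NR1 and NR2 are the remainders. The run parameters are
chosen so that a 7-aa all-Q QR2 (the B-genome minimum) qualifies while
the scattered Q·P repeats of R1 do not; all three are configurable.
Soft warnings flag NR1 outside 68–69 aa or NR2 outside 76–78 aa, the
conserved ranges.

The cysteine census counts C residues per domain; the extra-cysteine
flag requires exactly 7 cysteines with the odd one in NR2, and reports
the codon at that position (TGC is the expected mutant of the conserved
TCC serine codon). Molecular weight uses average residue masses plus
one water, on the full deduced protein including the signal peptide
(the convention for deduced-protein masses; computing it on the mature
protein is a matter of slicing `partition.extract(protein, ...)`).

## Epitope census

Scanning is exact substring matching with overlapping occurrences
counted — the panel nests (the 33-mer contains two overlapping copies
of Glia-a2 and one of Glia-a9), so skipping overlaps would undercount.
No mismatch tolerance and no Q→E deamidation expansion are applied:
the census is a presence/absence catalogue, not a binding predictor.
Genotype summaries count *carriers* (each protein at most once per
epitope), which is what the per-genotype class totals add up;
occurrence counts remain available per sequence. Percent reduction of
a count n versus the reference count n_ref is 100·(1 − n/n_ref),
reported as not-applicable when n_ref = 0. The a-Glia(51-70) peptide
is used exactly as its 18-residue printed string.

## Phylogeny

Distances come from pairwise global alignment rather than a multiple
alignment: neighbor joining needs only a distance matrix, and pairwise
Needleman–Wunsch with linear gap costs (defaults match 1, mismatch 0,
gap −1) is exactly optimal per pair. The DP fills rows with a
running-maximum trick that keeps the linear-gap recurrence vectorized;
traceback preference is diagonal, then up, then left (deterministic
among co-optimal alignments). p-distance is mismatches over compared
columns, excluding any column with a gap; an all-gap comparison is an
error. Distances are computed on full deduced proteins (configurable to
mature proteins by slicing).

Neighbor joining is the classical algorithm: at each step join the pair
minimizing Q_ij = (n−2)·d_ij − r_i − r_j (ties: lowest index pair),
with branch lengths l_i = d_ij/2 + (r_i − r_j)/(2(n−2)) and the
three-point closed form at the end. On additive matrices this recovers
the unique generating tree with exact branch lengths (verified against
random trees and against an independent NJ implementation). Negative
computed branch lengths are clamped to zero and counted in the result.

Cluster purity asks, for each locus, whether some edge bipartition of
the unrooted tree (including the trivial whole-set split) separates
exactly that locus's leaves; the symmetric difference of the best
bipartition side names the misplaced leaves, and a configurable number
of exceptions is tolerated.

## Relative expression

The 2^−ΔΔCq method with amplification efficiency fixed at 2.0
(configurable): technical replicates are averaged per (genotype,
biological replicate, assay); ΔCq subtracts the reference assay within
the block, which removes any per-block loading shift (scale
invariance); ΔΔCq subtracts the calibrator's mean ΔCq per assay; the
per-replicate fold is 2^−ΔΔCq, summarized by its mean and two standard
errors. `fold_se` is the conventional SEM of the per-replicate folds.
`fold_se_total` additionally propagates the calibrator's mean-ΔCq
uncertainty by the delta method (se_log2² = s²_target/n + s²_cal/n_cal,
fold_se_total = ln2 · fold · se_log2); the calibrator term shifts all
of a genotype's replicate folds together, so SEM alone underestimates
the estimator's sampling variability. Significance is Welch's
unequal-variance two-sample t test of the per-replicate log2 folds
against the calibrator's, two-sided at α = 0.05, with the direction
reported; the calibrator itself is the baseline and never flagged. The
reference gene and the exact test of the original quantification are
configuration choices, documented here rather than inferred.

## Synthetic data model

The generator emulates an RT-PCR clone study of a three-locus gene
family with known ground truth. Defaults are the study conditions:
18/12/19 templates on Gli-A2/B2/D2; protein totals 283–294 aa (A),
312–319 aa (B, with three shorter genes including the 281-aa outlier
that carries the extra cysteine), 282–309 aa (D), pinning the global
extremes 281/319 aa = 846/960 bp; A-genome R1 fixed at 92 aa and QR2 at
8 aa; NR1 68–69 and NR2 76–78 aa; QR1 ranges 18–29/21–33/12–25;
libraries of 104/101/107/69 clones; chimera and pseudogene rates 0.03
each; α-assay fold changes 0.75/0.38/0.20 and γ up-regulation up to
6-fold with a milder ω increase in the double deletion.

**Epitope planting.** Per-locus carrier marginals are assigned to gene
indices deterministically, processing container epitopes before the
peptides they contain so that implied carriers are consistent
(contradictory marginals are rejected). Each gene's R1 is built from
its designated epitope strings as blocks separated by `GG`: no panel
epitope contains `GG` or begins with G, so no match can cross a
separator, and the filler padding R1 to its target length uses only
{P,Q,F}, an alphabet that cannot contain any panel epitope (each
contains at least one of G/L/S/R/Y). The one deliberate junction writes
a-Glia(31-55) directly against a-Glia(56-75) (or the 33-mer), which
recreates the natural overlap peptide a-Glia(51-70) spanning them — and
is used only when that peptide is itself designated. The C-terminal
epitope a-Glia(206-217) is written into NR2. QPQLPYP heptapeptide
copies arise from the planted D-genome epitopes (2 per Glia-a2, 3 per
33-mer) and are topped up with standalone copies to reach 16 carrier
genes with 1–3 copies each. Junction margins of three non-Q residues
around the polyglutamine domains keep segmentation boundaries exact.
After assembly every template is *verified*: full 12-epitope scan
against the designated set, exact boundary recovery by the segmenter,
cysteine count, and translation round trip — generation fails loudly on
any drift.

**Divergence structure.** NR1/NR2 backgrounds are drawn per locus
(random letters with sparse, isolated glutamines and no cysteines
except the planted ones), so between-locus distances are large and the
NJ tree separates loci cleanly. Within a locus, each gene owns one
private substitution slot in NR1 and one in NR2 (disjoint across
genes), so any two same-locus templates differ at ≥ 4 positions with
≥ 2 on either side of any crossover point — which makes "a faithful
template is never flagged as a chimera of two other templates" a
structural guarantee rather than a probabilistic one. Reverse
translation uses a fixed most-frequent-codon table (codon bias is not
modeled; downstream stages need valid ORFs, not realistic wobble), with
TCC at the mutable NR2 serine site so the extra-cysteine variants show
the TCC→TGC change.

**Clone libraries.** Every retained template is emitted once; remaining
slots are duplicates, chimeras and pseudogenes. The default redundancy
model is coverage-first: duplicate slots first bring each retained
template to two clones, then draw uniformly — deep-library behavior
that also grounds the abundance asymmetry the chimera guard uses.
Chimeras take two distinct co-sampled templates and a uniform interior
breakpoint, re-drawn until the child is a COMPLETE ORF differing from
both parents and from every template; pseudogenes replace one internal
codon of a template with TAA. Truth labels (faithful / duplicate /
chimera with parents and breakpoint / pseudogene) are recorded per
clone.

**Cq tables.** Cq_target = Cq_ref + ΔCq_cal − log2(fold) + ε with
ε ~ N(0, noise_sd) per technical replicate, a shared N(0, 0.5)
per-(genotype, replicate) baseline shift (removed by ΔCq), reference
Cq 20 and calibrator ΔCq 2.0.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: sequencing errors within clones (every
non-artifact clone is an exact template copy), codon usage bias,
indel-mutated or partially deleted genes, multi-crossover chimeras,
pseudogenes with lesions other than a point stop, primer or cloning
bias in library composition, and amplification-efficiency differences
between assays. Real NR domains are more conserved in composition than
the random backgrounds used here; only their lengths and cysteine
architecture are faithful.

## Problem sizes and determinism

All randomness flows through numpy Generators seeded explicitly; equal
config and seed give byte-identical FASTA and report output. The test
suite exercises the full 49-gene family and the 104/101/107/69
libraries directly (a full pipeline run takes a few seconds, dominated
by the 1,176 pairwise alignments of the distance matrix), 100 random
additive matrices of 4–8 taxa for NJ exactness, 1,000 random strings
for the scanner oracle, and 200 seeded Cq simulations at the 3×3
replicate design for expression recovery; the SE-calibration check uses
10 biological replicates, where a ±2·SE interval is nominally ~95%
(at 3 replicates no exact-SE method can reach 90% coverage, since
P(|t₂| < 2) ≈ 0.82).

## Known limitations

* Chimera detection is defined for the single-crossover model only and,
  at support ties, genuinely cannot distinguish a singleton parent from
  a singleton chimera; the coverage-first default sidesteps this, but
  shallow libraries (every sequence a singleton) will under- or
  over-flag.
* Locus assignment under the completeness assumption misclassifies
  genes whose absence from a library is a sampling artifact; turn the
  flag off to see the uncollapsed candidate sets.
* Segmentation assumes exactly two polyglutamine domains; γ- or ω-type
  prolamins need different run parameters.
* The extra-cysteine flag keys on the 7-cysteine count with the odd
  residue in NR2; a hypothetical extra cysteine elsewhere would not be
  flagged (it is reported in the per-domain positions).
* p-distances ignore alignment uncertainty and multiple substitutions;
  the NJ tree is a descriptive clustering, not a model-based phylogeny,
  and no bootstrap support is computed.
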