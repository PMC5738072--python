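"""End-to-end orchestration: filter → assign → domains → epitopes →
phylo (→ expression), with every stage table written to the output
directory and a machine-readable summary.

Input is either a set of per-genotype clone-library FASTA files plus a
genotype manifest, or a synthetic specification (in which case the
generator's ground truth is also written for auditing).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .clones import FilterResult, filter_libraries
from .domains import domain_report_row
from .epitopes import (
    DEFAULT_EPITOPES,
    census,
    genotype_summary,
    read_epitope_table,
    reduction_stats,
)
from .expression import delta_delta_cq, read_cq_table
from .loci import assign_all, assignment_table, label_genes
from .phylo import cluster_purity, neighbor_joining, protein_distance_matrix, write_newick
from .records import CloneRecord, GenotypeDesign, UNASSIGNED
from .seq_io import read_fasta, read_genotype_manifest, write_fasta
from .synthetic import (
    SyntheticConfig,
    generate_clone_library,
    generate_cq_table,
    generate_gene_family,
)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineResult:
    out_dir: Path
    genes: list
    filter_result: FilterResult
    assignments: dict
    domain_table: pd.DataFrame
    summary_table: pd.DataFrame
    reductions: pd.DataFrame
    purity: list
    expression: object | None = None
    summary: dict = field(default_factory=dict)


def _load_libraries(config: dict, out_dir: Path, seed: int):
    """Returns (libraries, design, cq_table or None, synthetic truth or None)."""
    if "synthetic" in config:
        overrides = dict(config["synthetic"] or {})
        overrides.setdefault("seed", seed)
        syn = SyntheticConfig(**overrides)
        templates, truth = generate_gene_family(syn)
        libraries, clone_truth = generate_clone_library(truth, syn)
        lib_dir = out_dir / "libraries"
        lib_dir.mkdir(parents=True, exist_ok=True)
        for genotype, clones in libraries.items():
            write_fasta(lib_dir / f"{genotype}.fasta",
                        [(c.clone_id, c.sequence) for c in clones])
        cq = generate_cq_table(seed=seed)
        return libraries, syn.design, cq, (truth, clone_truth)
    inputs = config.get("inputs")
    if not inputs:
        raise PipelineError("input", "config needs a 'synthetic' or 'inputs' section")
    design = read_genotype_manifest(inputs["manifest"])
    libraries = {}
    for genotype, path in inputs["libraries"].items():
        libraries[genotype] = [
            CloneRecord(clone_id=rid, genotype=genotype, sequence=seq)
            for rid, seq in read_fasta(path)
        ]
    cq = read_cq_table(inputs["cq_table"]) if inputs.get("cq_table") else None
    return libraries, design, cq, None


def run_pipeline(config: dict, out_dir, seed: int = 0) -> PipelineResult:
    """Run every stage and write the report bundle under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    min_support = int(config.get("min_support", 1))
    assume_complete = bool(config.get("assume_complete", True))
    sp_len = int(config.get("signal_peptide_length", 20))
    allowed_exceptions = int(config.get("allowed_exceptions", 0))
    epitopes = (read_epitope_table(config["epitopes"])
                if config.get("epitopes") else DEFAULT_EPITOPES)

    libraries, design, cq, _truth = _load_libraries(config, out_dir, seed)
    if not any(libraries.values()):
        raise PipelineError("filter", "all clone libraries are empty")

    # filter
    result = filter_libraries(libraries, min_support=min_support)
    pd.DataFrame(result.audit, columns=["clone_id", "status", "reason"]).to_csv(
        out_dir / "filter_audit.tsv", sep="\t", index=False)
    if not result.genes:
        raise PipelineError("filter", "no COMPLETE unique genes survived filtering")

    # assign
    assignments = assign_all(result.genes, design, assume_complete=assume_complete)
    genes, assignments = label_genes(result.genes, assignments)
    assignment_table(genes, assignments, design).to_csv(
        out_dir / "assignments.tsv", sep="\t", index=False)
    write_fasta(out_dir / "genes.fasta", [(g.gene_id, g.orf) for g in genes])
    write_fasta(out_dir / "proteins.fasta", [(g.gene_id, g.protein) for g in genes])

    # domains
    rows = []
    for g in genes:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rows.append(domain_report_row(
                    g.gene_id, g.protein, g.orf, signal_peptide_length=sp_len))
        except ValueError as err:
            raise PipelineError("domains", f"{g.gene_id}: {err}") from err
    domain_table = pd.DataFrame(rows)
    domain_table.to_csv(out_dir / "domains.tsv", sep="\t", index=False)

    # epitopes
    table = census({g.gene_id: g.protein for g in genes}, epitopes)
    table.occurrences.rename_axis("gene_id").to_csv(
        out_dir / "epitope_matrix.tsv", sep="\t")
    locus_of = {g.gene_id: g.locus for g in genes}
    summary_table = genotype_summary(table, locus_of, design)
    summary_table.rename_axis("genotype").to_csv(
        out_dir / "genotype_summary.tsv", sep="\t")
    reductions = reduction_stats(summary_table, design.reference)
    reductions.rename_axis("genotype").to_csv(
        out_dir / "reductions.tsv", sep="\t")

    # phylogeny (needs >= 3 genes)
    purity = []
    if len(genes) >= 3:
        dm = protein_distance_matrix({g.gene_id: g.protein for g in genes})
        nj = neighbor_joining(dm)
        write_newick(nj.tree, out_dir / "tree.nwk")
        assigned = {g.gene_id: g.locus for g in genes if g.locus != UNASSIGNED}
        if len(assigned) == len(genes):
            purity = cluster_purity(nj.tree, assigned, allowed_exceptions)
            pd.DataFrame(
                [{"locus": p.locus, "pure": p.pure,
                  "exceptions": ";".join(p.exceptions)} for p in purity]
            ).to_csv(out_dir / "purity.tsv", sep="\t", index=False)

    # expression
    expression = None
    if cq is not None:
        expr_cfg = config.get("expression", {})
        expression = delta_delta_cq(
            cq,
            reference_assay=expr_cfg.get("reference_assay", "Ref"),
            calibrator=expr_cfg.get("calibrator", design.reference),
        )
        expression.table.reset_index().to_csv(
            out_dir / "expression.tsv", sep="\t", index=False)

    per_locus = {}
    for g in genes:
        per_locus[g.locus] = per_locus.get(g.locus, 0) + 1
    summary = {
        "version": __version__,
        "seed": seed,
        "parameters": {"min_support": min_support,
                       "assume_complete": assume_complete,
                       "signal_peptide_length": sp_len},
        "n_unique_genes": len(genes),
        "genes_per_locus": per_locus,
        "clone_status_counts": result.status_counts(),
        "cluster_purity": {p.locus: p.pure for p in purity},
        "class_reductions": {
            genotype: {
                "immunogenic": round(float(reductions.loc[genotype, "immunogenic_total"]), 1),
                "toxic": round(float(reductions.loc[genotype, "toxic_total"]), 1),
            }
            for genotype in summary_table.index
        },
    }
    if expression is not None:
        summary["expression_percent_change"] = {
            f"{g}/{a}": round(float(r["percent_change"]), 1)
            for (g, a), r in expression.table.iterrows()
        }
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)

    return PipelineResult(
        out_dir=out_dir, genes=genes, filter_result=result,
        assignments=assignments, domain_table=domain_table,
        summary_table=summary_table, reductions=reductions,
        purity=purity, expression=expression, summary=summary,
    )
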