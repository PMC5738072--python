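"""Relative quantification of gliadin transcripts (2^-ΔΔCq).

Real-time PCR quantification cycle (Cq) values are converted to fold
changes versus a calibrator genotype with the standard ΔΔCq method at
fixed amplification efficiency 2.0: technical replicates are averaged
per (genotype, biological replicate, assay); ΔCq subtracts the
reference assay within the same block; ΔΔCq subtracts the calibrator's
mean ΔCq for the same assay; the per-replicate fold is 2^-ΔΔCq,
summarized by its mean and standard error over biological replicates.

Significance is a two-sided unequal-variance (Welch) location test of
the per-replicate log2 folds of a genotype against the calibrator's at
level 0.05, with the direction of change reported.  The table carries
two uncertainties: ``fold_se``, the conventional standard error of the
per-replicate folds, and ``fold_se_total``, a delta-method standard
error that additionally propagates the calibrator's mean-ΔCq
uncertainty (which shifts all of a genotype's replicate folds
together and is therefore invisible to ``fold_se``).  The calibrator's
own mean log2 fold is zero by construction and is never flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

CQ_COLUMNS = ("genotype", "bio_rep", "tech_rep", "assay", "cq")


def read_cq_table(path) -> pd.DataFrame:
    """Read a Cq TSV with columns genotype, bio_rep, tech_rep, assay, cq."""
    df = pd.read_csv(path, sep="\t")
    return validate_cq_table(df)


def validate_cq_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = set(CQ_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"Cq table missing columns {sorted(missing)}")
    cq = pd.to_numeric(df["cq"], errors="coerce")
    if not np.isfinite(cq).all() or (cq <= 0).any():
        raise ValueError("Cq values must be finite and > 0")
    return df.assign(cq=cq)


@dataclass
class ExpressionResult:
    """Per-(genotype, assay) relative expression versus the calibrator.

    ``table`` columns: fold (mean of per-replicate 2^-ΔΔCq), fold_se,
    log2_fold, p_value, significant, direction, percent_change.
    ``per_replicate`` keeps the per-biological-replicate log2 folds that
    the significance test uses.
    """

    table: pd.DataFrame
    per_replicate: pd.DataFrame
    reference_assay: str
    calibrator: str
    alpha: float = 0.05
    notes: list[str] = field(default_factory=list)

    def fold(self, genotype: str, assay: str) -> float:
        return float(self.table.loc[(genotype, assay), "fold"])

    def percent_reduction(self, genotype: str, assay: str) -> float:
        return 100.0 * (1.0 - self.fold(genotype, assay))

    def summary(self) -> str:
        lines = [
            f"Relative expression (2^-ddCq) vs calibrator {self.calibrator!r}, "
            f"reference assay {self.reference_assay!r}",
            "",
            self.table.round(4).to_string(),
        ]
        if self.notes:
            lines += [""] + [f"note: {n}" for n in self.notes]
        return "\n".join(lines)


def delta_delta_cq(
    cq_table: pd.DataFrame,
    reference_assay: str,
    calibrator: str,
    alpha: float = 0.05,
) -> ExpressionResult:
    """Apply the 2^-ΔΔCq method to a tidy Cq table."""
    df = validate_cq_table(cq_table)
    if calibrator not in set(df["genotype"]):
        raise ValueError(f"calibrator genotype {calibrator!r} absent from table")
    # average technical replicates
    mean_cq = (
        df.groupby(["genotype", "bio_rep", "assay"], sort=True)["cq"]
        .mean()
        .rename("cq")
        .reset_index()
    )
    wide = mean_cq.pivot_table(
        index=["genotype", "bio_rep"], columns="assay", values="cq"
    )
    if reference_assay not in wide.columns or wide[reference_assay].isna().any():
        raise ValueError(
            f"reference assay {reference_assay!r} missing from some "
            "(genotype, biological replicate) block"
        )
    assays = [a for a in wide.columns if a != reference_assay]
    dcq = wide[assays].sub(wide[reference_assay], axis=0)
    calibrator_mean = dcq.loc[calibrator].mean(axis=0)
    ddcq = dcq.sub(calibrator_mean, axis=1)
    log2_fold = -ddcq
    per_rep = log2_fold.stack().rename("log2_fold").reset_index()

    notes: list[str] = []
    rows = {}
    for (genotype, assay), grp in per_rep.groupby(["genotype", "assay"], sort=True):
        vals = grp["log2_fold"].to_numpy(dtype=float)
        cal_vals = log2_fold.loc[calibrator, assay].to_numpy(dtype=float)
        folds = 2.0 ** vals
        n = len(vals)
        n_cal = len(cal_vals)
        fold_mean = float(folds.mean())
        fold_se = float(folds.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
        fold_se_total = np.nan
        if n > 1 and n_cal > 1:
            se_log2 = float(np.sqrt(vals.var(ddof=1) / n
                                    + cal_vals.var(ddof=1) / n_cal))
            fold_se_total = float(np.log(2.0)) * fold_mean * se_log2
        significant = False
        p_value = np.nan
        if genotype == calibrator:
            p_value = np.nan  # calibrator is the baseline by construction
        elif n < 2 or n_cal < 2:
            notes.append(
                f"{genotype}/{assay}: <2 biological replicates, "
                "significance flag suppressed"
            )
        elif np.allclose(vals.std(ddof=1), 0.0) and np.allclose(
                cal_vals.std(ddof=1), 0.0):
            notes.append(f"{genotype}/{assay}: zero variance, test skipped")
        else:
            p_value = float(
                stats.ttest_ind(vals, cal_vals, equal_var=False).pvalue)
            significant = p_value < alpha
        mean_log2 = float(vals.mean())
        rows[(genotype, assay)] = {
            "fold": fold_mean,
            "fold_se": fold_se,
            "fold_se_total": fold_se_total,
            "log2_fold": mean_log2,
            "n_bio_reps": n,
            "p_value": p_value,
            "significant": significant,
            "direction": "up" if mean_log2 > 0 else ("down" if mean_log2 < 0 else "none"),
            "percent_change": 100.0 * (fold_mean - 1.0),
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index = pd.MultiIndex.from_tuples(table.index, names=["genotype", "assay"])
    return ExpressionResult(
        table=table,
        per_replicate=per_rep,
        reference_assay=reference_assay,
        calibrator=calibrator,
        alpha=alpha,
        notes=notes,
    )


def compensation_test(result: ExpressionResult) -> pd.DataFrame:
    """Per-(genotype, assay) up/down-regulation flags.

    Convenience view over the significance columns of the result table:
    a flagged assay in a deletion genotype with direction "up" indicates
    compensatory up-regulation relative to the calibrator.
    """
    return result.table[["log2_fold", "p_value", "significant", "direction"]].copy()


def plot_expression(result: ExpressionResult, ax=None):
    """Grouped bar chart of fold changes with +-1 SE bars; the dashed
    line marks the calibrator level (fold = 1)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    table = result.table.reset_index()
    assays = sorted(table["assay"].unique())
    genotypes = [g for g in table["genotype"].unique()]
    if ax is None:
        _, ax = plt.subplots(figsize=(1.6 * len(assays) + 2, 4))
    width = 0.8 / len(genotypes)
    x = np.arange(len(assays))
    for k, genotype in enumerate(genotypes):
        sub = table[table["genotype"] == genotype].set_index("assay")
        vals = [sub.loc[a, "fold"] if a in sub.index else np.nan for a in assays]
        errs = [sub.loc[a, "fold_se"] if a in sub.index else np.nan for a in assays]
        ax.bar(x + k * width, vals, width=width, yerr=errs, capsize=2, label=genotype)
    ax.axhline(1.0, linestyle="--", color="grey", linewidth=1)
    ax.set_xticks(x + 0.4 - width / 2)
    ax.set_xticklabels(assays)
    ax.set_ylabel("fold change vs calibrator")
    ax.legend(fontsize=8)
    return ax
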