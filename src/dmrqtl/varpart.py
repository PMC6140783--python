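"""Incremental-R2 variance partitioning of CpG methylation across SNPs.

A linear model of percent methylation on risk-allele dosages is grown one
SNP at a time; the contribution of the k-th SNP is the gain in R2 when it
enters, expressed as a percentage. Because the fits are nested, the
contributions sum exactly to the full-model R2. The full-model R2 is
invariant to entry order; the split between correlated SNPs is not, so the
order used is recorded in the result (default: descending marginal
log-worth, i.e. most strongly associated SNP first). Each SNP's log-worth
is -log10 of its marginal t-test p-value in the full model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .tables_io import GenotypeTable, MethylationTable, ValidationError

__all__ = ["VariancePartitionResult", "fit_partition", "partition_all", "partition_heatmap"]

_NEG_TOL = 1e-10
_RANK_TOL = 1e-8


@dataclass
class CpgPartition:
    """Partition of one CpG's methylation variance."""

    cpg: str
    combined_r2: float  # percent, [0, 100]
    contributions: dict[str, float]  # snp -> incremental R2 (percent)
    log_worth: dict[str, float]  # snp -> -log10 p (marginal test, full model)
    entry_order: list[str]
    n: int
    collinear: list[str] = field(default_factory=list)


@dataclass
class VariancePartitionResult:
    tissue: str
    snps: list[str]
    per_cpg: dict[str, CpgPartition]

    def to_frame(self) -> pd.DataFrame:
        """CpG-by-(SNP..., combined) percentage-effect matrix."""
        rows = {}
        for cpg, part in self.per_cpg.items():
            row = {s: part.contributions.get(s, np.nan) for s in self.snps}
            row["combined"] = part.combined_r2
            rows[cpg] = row
        return pd.DataFrame.from_dict(rows, orient="index")


def _r2(y: np.ndarray, X: np.ndarray) -> float:
    """R2 of OLS with intercept, via residual sums of squares."""
    n = len(y)
    design = np.column_stack([np.ones(n), X]) if X.size else np.ones((n, 1))
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        return 0.0
    return 1.0 - float(np.sum(resid ** 2)) / sst


def _marginal_pvalues(y: np.ndarray, X: np.ndarray, cols: list[str]) -> dict[str, float]:
    """Two-sided t-test p of each coefficient in the full OLS model.

    Rank-deficient designs fall back to the pseudoinverse; the p-value of
    an aliased column is reported as 1 (no independent information).
    """
    n, k = X.shape
    design = np.column_stack([np.ones(n), X])
    rank = np.linalg.matrix_rank(design, tol=None)
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    dof = n - rank
    if dof <= 0:
        return {c: np.nan for c in cols}
    sigma2 = float(np.sum(resid ** 2)) / dof
    cov = sigma2 * np.linalg.pinv(design.T @ design)
    out = {}
    aliased = rank < design.shape[1]
    for j, col in enumerate(cols, start=1):
        se = np.sqrt(max(cov[j, j], 0.0))
        if se == 0.0 or (aliased and np.isclose(beta[j], 0.0)):
            out[col] = 1.0
            continue
        t = beta[j] / se
        out[col] = float(2.0 * stats.t.sf(abs(t), dof))
    return out


def fit_partition(
    meth: MethylationTable,
    geno: GenotypeTable,
    snps: list[str],
    cpg: str,
    order: list[str] | None = None,
    coding: str = "additive",
) -> CpgPartition:
    """Sequential-OLS variance partition for one CpG.

    SNPs enter the model in ``order`` (default: descending marginal
    log-worth, ties broken by the given ``snps`` order); the k-th SNP's
    contribution is R2(1..k) - R2(1..k-1), scaled to percent. A SNP whose
    dosage column is collinear with those already entered (e.g. a
    perfect-LD proxy) receives contribution 0 and a collinearity flag.
    ``coding='categorical'`` enters each SNP as genotype-class indicator
    columns instead of a single additive dosage.
    """
    if coding not in ("additive", "categorical"):
        raise ValidationError(f"unknown coding {coding!r}")
    if cpg not in meth.cpgs:
        raise ValidationError(f"CpG {cpg!r} not in methylation table")
    dosage = geno.dosage()[snps]
    y_all = meth.values[cpg]
    shared = [s for s in meth.samples if s in dosage.index]
    df = pd.concat([y_all.loc[shared].rename("y"), dosage.loc[shared]], axis=1).dropna()
    n = len(df)
    n_params = 1 + (len(snps) if coding == "additive" else 2 * len(snps))
    if n < n_params + 2:
        raise ValidationError(
            f"{cpg}: {n} complete cases < {n_params + 2} required for {len(snps)} SNP(s)"
        )
    y = df["y"].to_numpy(float)

    def columns_for(snp: str) -> np.ndarray:
        d = df[snp].to_numpy(float)
        if coding == "additive":
            return d[:, None]
        return np.column_stack([(d == 1.0).astype(float), (d == 2.0).astype(float)])

    if order is None:
        marg = {s: _r2(y, columns_for(s)) for s in snps}
        order = sorted(snps, key=lambda s: (-marg[s], snps.index(s)))
    else:
        if set(order) != set(snps):
            raise ValidationError("order must be a permutation of snps")

    contributions: dict[str, float] = {}
    collinear: list[str] = []
    X = np.empty((n, 0))
    r2_prev = 0.0
    for snp in order:
        cols = columns_for(snp)
        X_new = np.column_stack([X, cols])
        rank_old = np.linalg.matrix_rank(np.column_stack([np.ones(n), X]))
        rank_new = np.linalg.matrix_rank(np.column_stack([np.ones(n), X_new]))
        if rank_new == rank_old:
            contributions[snp] = 0.0
            collinear.append(snp)
            X = X_new
            continue
        r2_new = _r2(y, X_new)
        delta = r2_new - r2_prev
        if delta < 0.0:
            if delta < -_NEG_TOL:
                warnings.warn(
                    f"{cpg}/{snp}: negative incremental R2 {delta:.3e} clamped to 0",
                    stacklevel=2,
                )
            delta = 0.0
        contributions[snp] = 100.0 * delta
        r2_prev = r2_prev + delta
        X = X_new
    combined = 100.0 * r2_prev
    full_cols = []
    blocks = []
    for snp in order:
        full_cols.append(snp)
        blocks.append(columns_for(snp))
    X_full = np.hstack(blocks)
    if coding == "additive":
        pvals = _marginal_pvalues(y, X_full, full_cols)
    else:
        # categorical: report the worth of each SNP's first indicator column
        expanded = [f"{s}__{lvl}" for s in order for lvl in ("het", "hom")]
        p_all = _marginal_pvalues(y, X_full, expanded)
        pvals = {s: min(p_all[f"{s}__het"], p_all[f"{s}__hom"]) for s in order}
    log_worth = {
        s: float(-np.log10(max(p, np.finfo(float).tiny))) if not np.isnan(p) else np.nan
        for s, p in pvals.items()
    }
    return CpgPartition(
        cpg=cpg, combined_r2=combined, contributions=contributions,
        log_worth=log_worth, entry_order=list(order), n=n, collinear=collinear,
    )


def partition_all(
    meth: MethylationTable,
    geno: GenotypeTable,
    snps: list[str],
    cpgs: list[str] | None = None,
    order: list[str] | None = None,
    coding: str = "additive",
) -> VariancePartitionResult:
    """Partition every requested CpG (default: all) in one tissue."""
    per_cpg = {}
    for cpg in cpgs or meth.cpgs:
        per_cpg[cpg] = fit_partition(meth, geno, snps, cpg, order=order, coding=coding)
    return VariancePartitionResult(tissue=meth.tissue, snps=snps, per_cpg=per_cpg)


def partition_heatmap(
    result: VariancePartitionResult,
    tsv_path=None,
    plot_path=None,
) -> pd.DataFrame:
    """Percentage-effect matrix (rows: CpGs; columns: SNPs + combined).

    Optionally written as TSV and rendered as a heat map image.
    """
    frame = result.to_frame()
    if tsv_path is not None:
        frame.to_csv(tsv_path, sep="\t", index_label="cpg")
    if plot_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(1.2 * len(frame.columns) + 2, 0.4 * len(frame) + 2))
        im = ax.imshow(frame.to_numpy(float), cmap="viridis", vmin=0, vmax=100, aspect="auto")
        ax.set_xticks(range(len(frame.columns)), frame.columns, rotation=45, ha="right")
        ax.set_yticks(range(len(frame)), frame.index)
        fig.colorbar(im, ax=ax, label="% methylation variance explained")
        ax.set_title(f"Genotype effect on methylation ({result.tissue})")
        fig.tight_layout()
        fig.savefig(plot_path, dpi=150)
        plt.close(fig)
    return frame
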