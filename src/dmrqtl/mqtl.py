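"""Per-CpG genotype-stratified ANOVA and DMR boundary calling.

Each CpG's percent methylation is stratified by genotype at one SNP and
tested with a classic one-way (pooled-variance) ANOVA. Grouping is either
three genotype classes (dosage 0/1/2) or, for cohorts where the rare
homozygote class is too small, a two-class comparison of non-carriers
against carriers of the risk allele; in the two-class mode the ANOVA F is
the square of the pooled two-sample t statistic. P-values are Bonferroni
corrected across the CpGs tested in one run (one tissue), and the region
boundaries are the first and last significant sites in genomic order, with
any interior non-significant sites reported as gaps rather than truncating
the call.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .tables_io import DmrCall, GenomicInterval, GenotypeTable, MethylationTable, ValidationError

__all__ = ["MqtlResult", "mqtl_anova", "call_dmr"]

MODES = ("3class", "2class")


@dataclass
class MqtlResult:
    """Per-CpG ANOVA results for one tissue and one SNP.

    ``table`` columns: cpg, f, p_raw, p_adj, n, n_classes, testable,
    degenerate, plus mean_<class> / sem_<class> / n_<class> per genotype
    class. ``m`` is the Bonferroni multiplier (CpGs actually tested).
    """

    snp: str
    tissue: str
    mode: str
    table: pd.DataFrame
    m: int
    cpg_intervals: dict[str, GenomicInterval] = field(default_factory=dict)


def _group_labels(dosage: pd.Series, spec, mode: str) -> pd.Series:
    """Map risk-allele dosage to genotype class labels."""
    a, b = sorted(spec.alleles, key=lambda x: x != spec.risk_allele)
    risk, other = a, b
    if mode == "3class":
        labels = {0.0: other * 2, 1.0: "".join(sorted(other + risk)), 2.0: risk * 2}
    else:
        carrier = f"{''.join(sorted(other + risk))}/{risk * 2}"
        labels = {0.0: other * 2, 1.0: carrier, 2.0: carrier}
    return dosage.map(lambda d: labels.get(d, np.nan))


def mqtl_anova(
    meth: MethylationTable,
    geno: GenotypeTable,
    snp: str,
    mode: str = "3class",
) -> MqtlResult:
    """One-way ANOVA of percent methylation across genotype classes, per CpG.

    Complete cases are taken per CpG (samples with both a genotype call and
    a methylation value). Genotype classes with a single sample are dropped
    with a warning — a class of one contributes no within-group variance.
    A CpG with fewer than two populated classes (each n >= 2) is flagged
    untestable rather than raising; all-identical values give F = 0, p = 1
    with a degenerate flag. Bonferroni correction multiplies each raw p by
    the number of CpGs actually tested in this run, capped at 1.
    """
    if mode not in MODES:
        raise ValidationError(f"mode must be one of {MODES}, got {mode!r}")
    if snp not in geno.snps:
        raise ValidationError(f"SNP {snp!r} not in genotype table")
    dosage = geno.dosage(snp)
    classes = _group_labels(dosage, geno.specs[snp], mode)
    shared = [s for s in meth.samples if s in classes.index]
    rows = []
    for cpg in meth.cpgs:
        vals = meth.values.loc[shared, cpg]
        cls = classes.loc[shared]
        ok = vals.notna() & cls.notna()
        sub_vals, sub_cls = vals[ok], cls[ok]
        groups: dict[str, np.ndarray] = {}
        for label in sorted(sub_cls.dropna().unique()):
            g = sub_vals[sub_cls == label].to_numpy(float)
            if len(g) == 1:
                warnings.warn(
                    f"{cpg}: genotype class {label} has n=1 and was dropped",
                    stacklevel=2,
                )
                continue
            if len(g) >= 2:
                groups[label] = g
        row: dict = {"cpg": cpg, "degenerate": False}
        for label, g in groups.items():
            row[f"mean_{label}"] = float(np.mean(g))
            row[f"sem_{label}"] = float(np.std(g, ddof=1) / np.sqrt(len(g)))
            row[f"n_{label}"] = int(len(g))
        row["n"] = int(sum(len(g) for g in groups.values()))
        row["n_classes"] = len(groups)
        if len(groups) < 2:
            row.update(testable=False, f=np.nan, p_raw=np.nan)
        else:
            arrays = list(groups.values())
            pooled = np.concatenate(arrays)
            if np.ptp(pooled) == 0.0:
                row.update(testable=True, degenerate=True, f=0.0, p_raw=1.0)
            else:
                f, p = stats.f_oneway(*arrays)
                if np.isnan(f):  # zero within-group variance, unequal means
                    row.update(testable=True, degenerate=True, f=np.inf, p_raw=0.0)
                else:
                    row.update(testable=True, f=float(f), p_raw=float(p))
        rows.append(row)
    table = pd.DataFrame(rows)
    m = int(table["testable"].sum())
    table["p_adj"] = np.where(
        table["testable"], np.minimum(1.0, table["p_raw"] * m), np.nan
    )
    return MqtlResult(
        snp=snp, tissue=meth.tissue, mode=mode, table=table, m=m,
        cpg_intervals=dict(meth.cpg_intervals),
    )


def call_dmr(result: MqtlResult, alpha: float = 0.05) -> DmrCall:
    """Call region boundaries from the per-CpG adjusted p-values.

    Significant set = {CpG : adjusted p < alpha}. The 5'/3' boundaries are
    the first and last significant CpG in genomic order; interior
    non-significant CpGs are listed as gaps and the contiguity flag is
    cleared, but they do not truncate the call. When the CpGs carry
    genomic coordinates the spanned interval (start of the 5' site to end
    of the 3' site, 1-based inclusive) is attached.
    """
    if not (0.0 < alpha < 1.0):
        raise ValidationError(f"alpha must be in (0,1), got {alpha}")
    table = result.table
    sig_mask = table["testable"] & (table["p_adj"] < alpha)
    cpgs = table["cpg"].tolist()
    sig = [c for c, s in zip(cpgs, sig_mask) if s]
    if not sig:
        return DmrCall(
            tissue=result.tissue, significant=[], boundary_5p=None,
            boundary_3p=None, contiguous=True, gaps=[],
        )
    i0, i1 = cpgs.index(sig[0]), cpgs.index(sig[-1])
    gaps = [c for c in cpgs[i0:i1 + 1] if c not in sig]
    interval = None
    iv0 = result.cpg_intervals.get(sig[0])
    iv1 = result.cpg_intervals.get(sig[-1])
    if iv0 is not None and iv1 is not None:
        interval = GenomicInterval(
            chrom=iv0.chrom, start=iv0.start, end=iv1.end, assembly=iv0.assembly
        )
    return DmrCall(
        tissue=result.tissue, significant=sig, boundary_5p=sig[0],
        boundary_3p=sig[-1], contiguous=not gaps, gaps=gaps, interval=interval,
    )
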