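"""Per-CpG regression of allelic expression ratios on methylation (meQTL).

For samples with matched methylation and AEI measurements, the normalized
cDNA allelic ratio is regressed on percent methylation at each CpG by
simple OLS; the p-value comes from the slope's t-test. When the transcript
SNP is unlinked to the regulatory variant the ratios are first inverted to
a unidirectional scale (see :func:`dmrqtl.aei.invert_ratios`); for a
perfect-LD transcript SNP the signed ratios are used as-is. The flag is
explicit, never inferred.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .aei import invert_ratios
from .tables_io import MethylationTable, ValidationError

__all__ = ["MeqtlResult", "meqtl_regression"]


@dataclass
class MeqtlResult:
    """Per-CpG OLS results: slope, intercept, r2, p, n (+ optional Bonferroni)."""

    gene: str
    tissue: str
    inverted: bool
    table: pd.DataFrame


def meqtl_regression(
    meth: MethylationTable,
    ratios: pd.Series,
    cpg_set: list[str] | None = None,
    invert: bool = False,
    gene: str = "",
    bonferroni: bool = True,
) -> MeqtlResult:
    """Regress per-sample allelic ratios on percent methylation, per CpG.

    ``ratios`` is indexed by sample ID (one mean normalized ratio per
    sample). Complete cases are taken per CpG. A CpG with fewer than three
    matched samples is flagged untestable; zero methylation variance (or
    zero ratio variance) is flagged degenerate with slope 0 and p = 1.
    Raw per-CpG p-values are reported; a Bonferroni column over the CpGs
    tested is appended for convenience.
    """
    ratios = ratios.dropna().astype(float)
    if (ratios <= 0).any():
        raise ValidationError("allelic ratios must be positive")
    if invert:
        ratios = pd.Series(invert_ratios(ratios.to_numpy()), index=ratios.index)
    cpgs = cpg_set or meth.cpgs
    unknown = [c for c in cpgs if c not in meth.cpgs]
    if unknown:
        raise ValidationError(f"CpG(s) not in methylation table: {unknown}")
    rows = []
    for cpg in cpgs:
        x = meth.values[cpg]
        shared = x.index.intersection(ratios.index)
        pair = pd.concat([x.loc[shared].rename("meth"), ratios.loc[shared].rename("r")],
                         axis=1).dropna()
        n = len(pair)
        row = {"cpg": cpg, "n": n, "testable": True, "degenerate": False}
        if n < 3:
            row.update(testable=False, slope=np.nan, intercept=np.nan, r2=np.nan, p=np.nan)
        else:
            xv = pair["meth"].to_numpy(float)
            yv = pair["r"].to_numpy(float)
            if np.ptp(xv) == 0.0 or np.ptp(yv) == 0.0:
                row.update(degenerate=True, slope=0.0,
                           intercept=float(np.mean(yv)), r2=0.0, p=1.0)
            else:
                fit = stats.linregress(xv, yv)
                row.update(slope=float(fit.slope), intercept=float(fit.intercept),
                           r2=float(fit.rvalue ** 2), p=float(fit.pvalue))
        rows.append(row)
    table = pd.DataFrame(rows)
    if bonferroni:
        m = int(table["testable"].sum())
        table["p_bonferroni"] = np.where(
            table["testable"], np.minimum(1.0, table["p"] * max(m, 1)), np.nan
        )
    return MeqtlResult(gene=gene, tissue=meth.tissue, inverted=invert, table=table)
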