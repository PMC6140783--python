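"""Reductions for functional readouts: qPCR relative expression and
dual-reporter luciferase normalization.

Relative expression uses the 2^-dCt convention: per sample, dCt is the
target Ct minus the arithmetic mean of the housekeeper Cts (equivalent to
a geometric mean of housekeeper expression on the linear scale), and
relative expression is 2^-dCt. Condition effects across genes/isoforms are
tested by two-way ANOVA with Type II sums of squares (identical to Type I
when balanced).

Luciferase wells are normalized per well as firefly/renilla, then divided
by the mean ratio of the empty-vector control sharing the same in-vitro
methylation state; construct-vs-control comparisons use the two-sided
exact Mann-Whitney U test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .tables_io import CtTable, LuminescenceTable, ValidationError

__all__ = [
    "ExpressionResult",
    "LuciferaseResult",
    "ddct_expression",
    "twoway_anova",
    "luciferase_normalize",
    "mann_whitney_exact",
]


@dataclass
class ExpressionResult:
    """Per-sample 2^-dCt values and per-gene condition fold changes."""

    per_sample: pd.DataFrame  # sample, gene, condition, delta_ct, rel_expr
    fold_change: dict[str, float]  # gene -> mean(cond_b)/mean(cond_a)
    condition_pair: tuple[str, str]  # (reference a, comparison b)
    housekeepers: tuple[str, ...]
    anova: pd.DataFrame | None = None


@dataclass
class LuciferaseResult:
    """Per-well normalized activities and construct-vs-control tests."""

    per_well: pd.DataFrame  # well, construct, state, ratio, normalized
    summary: pd.DataFrame  # construct, state, mean_activity, sem, n, p_vs_control


# --------------------------------------------------------------------------
# qPCR
# --------------------------------------------------------------------------

def ddct_expression(
    ct: CtTable,
    targets: list[str] | None = None,
    condition_pair: tuple[str, str] | None = None,
    housekeeper_aggregate: str = "ct_mean",
) -> ExpressionResult:
    """Relative expression of each target by the 2^-dCt method.

    Technical replicates are averaged to one Ct per sample-gene first. The
    housekeeper aggregate is the arithmetic mean of housekeeper Cts per
    sample (``ct_mean``, default) or the Ct of the geometric mean of
    linear housekeeper expression (``geometric_linear``) — the two
    coincide, so both are accepted for interface clarity. A sample missing
    the target Ct is dropped for that gene with a warning.

    The fold change for a ``condition_pair`` (a, b) is
    mean(2^-dCt | condition b) / mean(2^-dCt | condition a); default pair
    is the first two condition labels in order of appearance.
    """
    if housekeeper_aggregate not in ("ct_mean", "geometric_linear"):
        raise ValidationError(f"unknown housekeeper aggregate {housekeeper_aggregate!r}")
    data = ct.data.copy()
    data["ct"] = data["ct"].astype(float)
    per = data.groupby(["sample", "gene", "condition"], sort=False)["ct"].mean().reset_index()
    hk = per[per["gene"].isin(ct.housekeepers)]
    hk_agg = hk.groupby("sample")["ct"].mean()
    targets = targets or ct.targets
    rows = []
    for gene in targets:
        sub = per[per["gene"] == gene]
        present = set(sub["sample"])
        missing = set(per["sample"]) - present
        if missing:
            warnings.warn(
                f"{gene}: no target Ct for sample(s) {sorted(missing)}; dropped",
                stacklevel=2,
            )
        for _, r in sub.iterrows():
            dct = r["ct"] - hk_agg[r["sample"]]
            rows.append((r["sample"], gene, r["condition"], dct, 2.0 ** (-dct)))
    per_sample = pd.DataFrame(
        rows, columns=["sample", "gene", "condition", "delta_ct", "rel_expr"]
    )
    conds = list(dict.fromkeys(per_sample["condition"]))
    if condition_pair is None:
        if len(conds) < 2:
            condition_pair = (conds[0], conds[0]) if conds else ("", "")
        else:
            condition_pair = (conds[0], conds[1])
    a, b = condition_pair
    fold = {}
    for gene in targets:
        sub = per_sample[per_sample["gene"] == gene]
        mean_a = sub.loc[sub["condition"] == a, "rel_expr"].mean()
        mean_b = sub.loc[sub["condition"] == b, "rel_expr"].mean()
        fold[gene] = float(mean_b / mean_a) if mean_a and not np.isnan(mean_a) else np.nan
    anova = None
    if len(conds) >= 2 and len(targets) >= 2:
        anova = twoway_anova(per_sample, factor_gene="gene", factor_condition="condition")
    return ExpressionResult(
        per_sample=per_sample, fold_change=fold, condition_pair=(a, b),
        housekeepers=ct.housekeepers, anova=anova,
    )


def twoway_anova(
    values: pd.DataFrame,
    factor_gene: str = "gene",
    factor_condition: str = "condition",
    response: str = "rel_expr",
) -> pd.DataFrame:
    """Two-way ANOVA (gene/isoform x condition) with Type II sums of squares.

    Requires at least two levels per factor and at least two replicates in
    every cell; an empty cell is an error naming the cell. Returns the
    statsmodels ANOVA table (sum_sq, df, F, PR(>F)) with rows for both
    main effects, the interaction and the residual.
    """
    df = values[[factor_gene, factor_condition, response]].dropna().copy()
    df.columns = ["g", "c", "y"]
    levels_g = df["g"].unique()
    levels_c = df["c"].unique()
    if len(levels_g) < 2 or len(levels_c) < 2:
        raise ValidationError("two-way ANOVA needs >=2 levels per factor")
    counts = df.groupby(["g", "c"]).size()
    for g in levels_g:
        for c in levels_c:
            n = counts.get((g, c), 0)
            if n == 0:
                raise ValidationError(f"empty cell in two-way ANOVA: gene={g!r}, condition={c!r}")
            if n < 2:
                raise ValidationError(
                    f"cell gene={g!r}, condition={c!r} has {n} replicate(s); >=2 required"
                )
    if np.ptp(df["y"].to_numpy(float)) == 0.0:
        # all responses identical: no variance to attribute
        idx = ["C(g)", "C(c)", "C(g):C(c)", "Residual"]
        out = pd.DataFrame(
            {"sum_sq": [0.0] * 4, "df": [len(levels_g) - 1, len(levels_c) - 1,
                                         (len(levels_g) - 1) * (len(levels_c) - 1),
                                         len(df) - len(levels_g) * len(levels_c)],
             "F": [0.0, 0.0, 0.0, np.nan],
             "PR(>F)": [1.0, 1.0, 1.0, np.nan]},
            index=idx,
        )
        return out
    model = smf.ols("y ~ C(g) * C(c)", data=df).fit()
    return sm.stats.anova_lm(model, typ=2)


# --------------------------------------------------------------------------
# Luciferase
# --------------------------------------------------------------------------

def mann_whitney_exact(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U with an exact null distribution.

    Without ties the exact distribution is used directly; with ties (where
    the classical exact distribution is undefined) an exact permutation of
    the mid-rank statistic is used for n+m <= 20, falling back to the
    tie-corrected normal approximation for larger samples.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    if not has_ties:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    elif len(x) + len(y) <= 20:
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided",
            method=stats.PermutationMethod(n_resamples=np.inf),
        )
    else:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def luciferase_normalize(lum: LuminescenceTable) -> LuciferaseResult:
    """Normalize dual-reporter wells to the matched empty-vector control.

    Per-well ratio = firefly / renilla; wells with renilla <= 0 are
    excluded with a warning. Within each methylation state, every well's
    ratio is divided by the mean ratio of the empty-construct wells in the
    same state (so the control's mean normalized activity is exactly 1).
    Each non-empty construct is compared against its matched control with
    a two-sided exact Mann-Whitney U test. At least three wells per
    construct-state are required.
    """
    df = lum.data.copy()
    df["firefly"] = df["firefly"].astype(float)
    df["renilla"] = df["renilla"].astype(float)
    bad = df["renilla"] <= 0
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} well(s) with non-positive renilla excluded", stacklevel=2
        )
        df = df[~bad]
    df["ratio"] = df["firefly"] / df["renilla"]
    states = df["methylation_state"].unique()
    control_mean = {}
    for state in states:
        ctrl = df[(df["construct"] == "empty") & (df["methylation_state"] == state)]
        if ctrl.empty:
            raise ValidationError(f"no empty-vector control wells for state {state!r}")
        control_mean[state] = float(ctrl["ratio"].mean())
    df["normalized"] = df.apply(
        lambda r: r["ratio"] / control_mean[r["methylation_state"]], axis=1
    )
    summary_rows = []
    for (construct, state), grp in df.groupby(["construct", "methylation_state"], sort=False):
        n = len(grp)
        if n < 3:
            raise ValidationError(
                f"construct {construct!r} / state {state!r} has {n} well(s); >=3 required"
            )
        vals = grp["normalized"].to_numpy(float)
        row = {
            "construct": construct,
            "methylation_state": state,
            "mean_activity": float(vals.mean()),
            "sem": float(vals.std(ddof=1) / np.sqrt(n)),
            "n": n,
        }
        if construct == "empty":
            row["u_statistic"] = np.nan
            row["p_vs_control"] = np.nan
        else:
            ctrl_vals = df.loc[
                (df["construct"] == "empty") & (df["methylation_state"] == state),
                "normalized",
            ].to_numpy(float)
            u, p = mann_whitney_exact(vals, ctrl_vals)
            row["u_statistic"] = u
            row["p_vs_control"] = p
        summary_rows.append(row)
    per_well = df[["well", "construct", "methylation_state", "ratio", "normalized"]]
    return LuciferaseResult(per_well=per_well, summary=pd.DataFrame(summary_rows))
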