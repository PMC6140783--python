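"""Allelic expression imbalance (AEI) statistics.

AEI compares the two alleles of a gene within heterozygous individuals:
pyrosequencing reports the percentage of a designated numerator allele in
genomic DNA (expected ~50:50) and in cDNA. The per-sample cDNA allelic
ratio is normalized to the DNA ratio of the same sample, cancelling assay
bias. Two cohort tests are provided:

* **paired mode** — for a transcript SNP in known LD with the regulatory
  variant, a two-sided paired t-test of per-sample cDNA vs DNA ratios;
  direction is meaningful and reported.
* **variance mode** — for an unlinked transcript SNP the direction of
  imbalance is unknowable, so ratios below 1 are inverted to a
  unidirectional scale and the spread of ratios in compound heterozygotes
  (heterozygous at both transcript and association SNP) is compared with
  that in association-SNP homozygotes. The default test is a two-sided
  F-test of variance equality; a Brown–Forsythe (median-centred Levene)
  alternative is offered because the F-test is sensitive to non-normality.

Replicate QC follows the pyrosequencing convention: a sample-material whose
replicate allele percentages span more than a threshold (default 5
percentage points) is excluded, and a sample missing either material after
QC is dropped entirely.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .tables_io import GenotypeTable, ValidationError

__all__ = [
    "AlleleQuantSet",
    "AeiResult",
    "replicate_qc",
    "normalized_ratio",
    "sample_ratios",
    "paired_aei_test",
    "invert_ratios",
    "variance_aei_test",
    "stratify_by_association",
]

MATERIALS = ("DNA", "cDNA")


@dataclass
class AlleleQuantSet:
    """Triplicate allele-percentage readings at one transcript SNP.

    ``data`` is long format with columns sample, material (DNA/cDNA),
    replicate, pct — the percentage of the numerator allele.
    ``linked_association_snp`` declares the association SNP this transcript
    SNP tags (perfect-LD proxy); when absent, the direction of any
    imbalance cannot be assigned to a risk allele.
    """

    gene: str
    snp_id: str
    alleles: tuple[str, str]
    numerator_allele: str
    data: pd.DataFrame
    linked_association_snp: str | None = None

    REQUIRED = ("sample", "material", "replicate", "pct")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValidationError(f"allele quant table missing columns: {missing}")
        pct = self.data["pct"].astype(float)
        if ((pct < 0) | (pct > 100)).any():
            raise ValidationError("allele percentage outside [0,100]")
        bad = set(self.data["material"]) - set(MATERIALS)
        if bad:
            raise ValidationError(f"unknown material(s): {sorted(bad)}")
        if self.numerator_allele not in self.alleles:
            raise ValidationError(
                f"numerator allele {self.numerator_allele!r} not in {self.alleles}"
            )

    @property
    def samples(self) -> list[str]:
        return list(dict.fromkeys(self.data["sample"]))


@dataclass
class AeiResult:
    """Cohort-level AEI summary."""

    gene: str
    mode: str  # "paired_linked" | "variance_unlinked"
    per_sample: pd.DataFrame  # sample, dna_ratio, cdna_ratio, normalized_ratio
    test_name: str
    statistic: float
    p_value: float
    mean_fold: float
    n: int
    direction_reported: bool
    direction: str | None = None
    strata: dict[str, dict] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)


# --------------------------------------------------------------------------
# Replicate QC
# --------------------------------------------------------------------------

def replicate_qc(
    quant: AlleleQuantSet, threshold: float = 5.0
) -> tuple[AlleleQuantSet, pd.DataFrame]:
    """Exclude sample-materials whose replicate range exceeds ``threshold``.

    The range is max minus min of the allele percentage across PCR
    replicates, in percentage points. A sample retaining only one material
    is dropped entirely (a normalized ratio needs both). Returns the
    filtered set and an exclusion report (sample, material, range, reason).
    """
    if threshold <= 0:
        raise ValidationError(f"QC threshold must be positive, got {threshold}")
    df = quant.data
    records = []
    keep_pairs = set()
    for (sample, material), grp in df.groupby(["sample", "material"], sort=False):
        rng = grp["pct"].max() - grp["pct"].min()
        if len(grp) < 2:
            records.append((sample, material, rng, "fewer than 2 replicates"))
        elif rng > threshold:
            records.append((sample, material, rng, f"replicate range {rng:.2f} > {threshold}"))
        else:
            keep_pairs.add((sample, material))
    # pairing requirement: both materials must survive
    complete = {s for s in df["sample"].unique()
                if (s, "DNA") in keep_pairs and (s, "cDNA") in keep_pairs}
    for sample, material in sorted(keep_pairs):
        if sample not in complete:
            records.append((sample, material, np.nan, "other material failed QC"))
    mask = df.apply(lambda r: r["sample"] in complete, axis=1)
    filtered = AlleleQuantSet(
        gene=quant.gene,
        snp_id=quant.snp_id,
        alleles=quant.alleles,
        numerator_allele=quant.numerator_allele,
        data=df[mask].reset_index(drop=True),
        linked_association_snp=quant.linked_association_snp,
    )
    report = pd.DataFrame(records, columns=["sample", "material", "range", "reason"])
    return filtered, report


# --------------------------------------------------------------------------
# Ratios
# --------------------------------------------------------------------------

def _pct_to_ratio(p: float) -> float:
    return p / (100.0 - p)


def normalized_ratio(dna_pcts: Sequence[float], cdna_pcts: Sequence[float]) -> float:
    """Normalized allelic ratio for one sample.

    Each material's allele percentage is averaged over replicates, mapped
    to an odds-style ratio p/(100-p), and the cDNA ratio is divided by the
    DNA ratio. A mean percentage of exactly 0 or 100 is monoallelic and
    has no finite ratio.
    """
    p_dna = float(np.mean(dna_pcts))
    p_cdna = float(np.mean(cdna_pcts))
    for p, mat in ((p_dna, "DNA"), (p_cdna, "cDNA")):
        if p <= 0.0 or p >= 100.0:
            raise ValidationError(f"monoallelic {mat} percentage {p}; ratio undefined")
    return _pct_to_ratio(p_cdna) / _pct_to_ratio(p_dna)


def sample_ratios(quant: AlleleQuantSet) -> pd.DataFrame:
    """Per-sample mean DNA/cDNA ratios and the normalized ratio.

    Samples with a monoallelic mean percentage are flagged and excluded
    from downstream ratio tests (their row carries NaN ratios).
    """
    rows = []
    for sample in quant.samples:
        sub = quant.data[quant.data["sample"] == sample]
        p_dna = sub.loc[sub["material"] == "DNA", "pct"].astype(float).mean()
        p_cdna = sub.loc[sub["material"] == "cDNA", "pct"].astype(float).mean()
        if any(pd.isna(p) for p in (p_dna, p_cdna)):
            continue
        mono = (p_dna <= 0 or p_dna >= 100 or p_cdna <= 0 or p_cdna >= 100)
        if mono:
            rows.append((sample, np.nan, np.nan, np.nan, True))
        else:
            r_dna = _pct_to_ratio(p_dna)
            r_cdna = _pct_to_ratio(p_cdna)
            rows.append((sample, r_dna, r_cdna, r_cdna / r_dna, False))
    return pd.DataFrame(
        rows, columns=["sample", "dna_ratio", "cdna_ratio", "normalized_ratio", "monoallelic"]
    )


# --------------------------------------------------------------------------
# Paired test (linked transcript SNP)
# --------------------------------------------------------------------------

def paired_aei_test(quant: AlleleQuantSet, log2: bool = False) -> AeiResult:
    """Two-sided paired t-test of per-sample cDNA vs DNA allelic ratios.

    Appropriate when the transcript SNP is a perfect-LD proxy for the
    regulatory variant, so every heterozygote is informative and imbalance
    has a common direction. ``log2`` applies the test on log2 ratios for a
    symmetric scale. The mean fold is the mean normalized ratio.
    """
    ratios = sample_ratios(quant)
    usable = ratios[~ratios["monoallelic"]]
    flags = []
    if ratios["monoallelic"].any():
        flags.append(f"{int(ratios['monoallelic'].sum())} monoallelic sample(s) excluded")
    n = len(usable)
    if n < 3:
        return AeiResult(
            gene=quant.gene, mode="paired_linked", per_sample=ratios,
            test_name="paired t-test", statistic=np.nan, p_value=np.nan,
            mean_fold=float(usable["normalized_ratio"].mean()) if n else np.nan,
            n=n, direction_reported=False, flags=flags + ["untestable: n < 3"],
        )
    a = usable["cdna_ratio"].to_numpy(float)
    b = usable["dna_ratio"].to_numpy(float)
    if log2:
        a, b = np.log2(a), np.log2(b)
    if np.allclose(a, b):
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_rel(a, b)
    mean_fold = float(usable["normalized_ratio"].mean())
    direction = None
    if quant.linked_association_snp is not None:
        direction = (
            f"increased {quant.numerator_allele} allele" if mean_fold > 1
            else f"decreased {quant.numerator_allele} allele"
        )
    return AeiResult(
        gene=quant.gene, mode="paired_linked", per_sample=ratios,
        test_name="paired t-test" + (" (log2)" if log2 else ""),
        statistic=float(t), p_value=float(p), mean_fold=mean_fold, n=n,
        direction_reported=quant.linked_association_snp is not None,
        direction=direction, flags=flags,
    )


# --------------------------------------------------------------------------
# Unidirectional inversion + variance test (unlinked transcript SNP)
# --------------------------------------------------------------------------

def invert_ratios(ratios: Iterable[float]) -> np.ndarray:
    """Map each ratio r to max(r, 1/r), giving a unidirectional imbalance.

    Used when transcript and association SNP are unphased/unlinked, so r
    and 1/r describe the same biology. Idempotent; fixed point at 1.
    """
    arr = np.asarray(list(ratios), dtype=float)
    if (arr <= 0).any():
        raise ValidationError("ratios must be positive")
    return np.where(arr < 1.0, 1.0 / arr, arr)


def stratify_by_association(
    quant: AlleleQuantSet, genotypes: GenotypeTable, association_snp: str
) -> dict[str, list[str]]:
    """Split transcript-SNP heterozygotes by association-SNP genotype.

    ``compound_het`` — heterozygous at the association SNP too (these carry
    one risk and one non-risk regulatory allele, so imbalance is expected);
    ``assoc_hom`` — homozygous at the association SNP (no cis difference,
    the null stratum).
    """
    het_assoc = set(genotypes.heterozygotes(association_snp))
    dosage = genotypes.dosage(association_snp)
    hom_assoc = {s for s, d in dosage.items() if not pd.isna(d) and d in (0.0, 2.0)}
    samples = quant.samples
    return {
        "compound_het": [s for s in samples if s in het_assoc],
        "assoc_hom": [s for s in samples if s in hom_assoc],
    }


def _two_sided_f_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float, bool]:
    """Two-sided F-test of variance equality; returns (F, p, degenerate)."""
    vx, vy = np.var(x, ddof=1), np.var(y, ddof=1)
    dfx, dfy = len(x) - 1, len(y) - 1
    if vx == 0.0 and vy == 0.0:
        return np.nan, 1.0, True
    if vy == 0.0:
        return np.inf, 0.0, True
    f = vx / vy
    if vx == 0.0:
        # limiting F: numerator variance exactly zero
        p = float(min(1.0, 2 * stats.f.cdf(0.0, dfx, dfy)))
        return 0.0, max(p, 0.0), True
    p = 2.0 * min(stats.f.cdf(f, dfx, dfy), stats.f.sf(f, dfx, dfy))
    return float(f), float(min(1.0, p)), False


def variance_aei_test(
    quant: AlleleQuantSet,
    genotypes: GenotypeTable,
    association_snp: str,
    method: str = "f",
) -> AeiResult:
    """Compare spread of inverted normalized ratios between genotype strata.

    Ratios are inverted to >= 1 first (direction is unknowable without LD),
    then the variance in compound heterozygotes is tested against that in
    association-SNP homozygotes. ``method='f'`` is the default two-sided
    F-test of variance equality; ``method='levene'`` uses the
    Brown–Forsythe statistic, robust to non-normal ratios.
    """
    ratios = sample_ratios(quant)
    usable = ratios[~ratios["monoallelic"]].set_index("sample")
    strata = stratify_by_association(quant, genotypes, association_snp)
    flags = []
    groups = {}
    for name, samples in strata.items():
        vals = usable.loc[[s for s in samples if s in usable.index], "normalized_ratio"]
        groups[name] = invert_ratios(vals.to_numpy(float)) if len(vals) else np.array([])
    x, y = groups["compound_het"], groups["assoc_hom"]
    per_stratum = {
        name: {"n": int(len(g)),
               "variance": float(np.var(g, ddof=1)) if len(g) > 1 else np.nan,
               "mean_inverted_ratio": float(np.mean(g)) if len(g) else np.nan}
        for name, g in groups.items()
    }
    if len(x) < 3 or len(y) < 3:
        return AeiResult(
            gene=quant.gene, mode="variance_unlinked", per_sample=ratios,
            test_name="F-test of variances", statistic=np.nan, p_value=np.nan,
            mean_fold=float(np.mean(x)) if len(x) else np.nan, n=len(x) + len(y),
            direction_reported=False, strata=per_stratum,
            flags=flags + ["untestable: a stratum has n < 3"],
        )
    if method == "f":
        stat, p, degenerate = _two_sided_f_test(x, y)
        test_name = "F-test of variances"
        if degenerate:
            flags.append("zero-variance stratum: p from limiting F")
    elif method == "levene":
        if np.var(x) == 0.0 and np.var(y) == 0.0:
            stat, p = np.nan, 1.0
            flags.append("both strata constant")
        else:
            stat, p = stats.levene(x, y, center="median")
        test_name = "Brown-Forsythe (Levene, median-centred)"
    else:
        raise ValidationError(f"unknown variance test method {method!r}")
    return AeiResult(
        gene=quant.gene, mode="variance_unlinked", per_sample=ratios,
        test_name=test_name, statistic=float(stat), p_value=float(p),
        mean_fold=float(np.mean(x)), n=len(x) + len(y),
        direction_reported=False, strata=per_stratum, flags=flags,
    )
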