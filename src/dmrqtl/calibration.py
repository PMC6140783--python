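"""Simulation-based validation utilities.

Monte-Carlo checks that the pipeline's tests hold their nominal size under
null generating configurations (no genotype effect on methylation, allelic
fold 1) and that known generating parameters are recovered: the allelic
fold-imbalance, the qPCR condition fold, and the identity of the causal
SNP in the variance partition. These run the same estimators users run,
on cohorts from :mod:`dmrqtl.simulate`.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import aei, assays, mqtl, simulate as sim, varpart
from .tables_io import GenotypeTable

__all__ = [
    "mqtl_null_rejection_rate",
    "paired_aei_null_rejection_rate",
    "variance_aei_null_rejection_rate",
    "recover_aei_fold",
    "recover_expression_fold",
    "dominant_snp_recovery_rate",
    "monte_carlo_band",
]


def monte_carlo_band(alpha: float, n_sim: int, k: float = 2.0) -> float:
    """Half-width of the +/- k * MC-SE band around the nominal level."""
    return k * float(np.sqrt(alpha * (1 - alpha) / n_sim))


def _het_genotypes(n: int, assoc_dosage: list[int], transcript_snp: str) -> GenotypeTable:
    specs = sim.default_config(n_samples=1, seed=0).snp_specs
    samples = [f"S{i + 1:03d}" for i in range(n)]
    spec_t = specs[transcript_snp]
    het_t = "".join(sorted(spec_t.alleles))
    spec_a = specs["rs10948172"]
    other_a = "A"
    amap = {0: other_a * 2, 1: "AG", 2: "GG"}
    calls = pd.DataFrame({
        transcript_snp: [het_t] * n,
        "rs10948172": [amap[d] for d in assoc_dosage],
    }, index=samples)
    return GenotypeTable(calls=calls, specs={transcript_snp: spec_t,
                                             "rs10948172": spec_a})


def mqtl_null_rejection_rate(
    n_cohorts: int = 1000, n: int = 60, alpha: float = 0.05, seed: int = 0
) -> float:
    """Fraction of null cohorts (zero genotype effects) where the per-CpG
    ANOVA raw p falls below alpha. Should sit near alpha."""
    cfg = sim.default_config(n_samples=n, seed=0)
    cfg.cpg_baseline = {"CpG9": 65.0}
    cfg.cpg_effects = {"CpG9": {}}
    children = np.random.SeedSequence(seed).spawn(n_cohorts)
    rej = 0
    with warnings.catch_warnings():
        # singleton rare-homozygote classes are routinely dropped at n=60
        warnings.simplefilter("ignore", UserWarning)
        for ss in children:
            rng = np.random.default_rng(ss)
            geno = sim.simulate_genotypes(cfg, rng)
            meth = sim.simulate_methylation(geno, cfg, rng=rng)
            row = mqtl.mqtl_anova(meth, geno, "rs10948172").table.iloc[0]
            if row["testable"] and row["p_raw"] < alpha:
                rej += 1
    return rej / n_cohorts


def paired_aei_null_rejection_rate(
    n_cohorts: int = 1000, n_het: int = 10, alpha: float = 0.05, seed: int = 0
) -> float:
    """Size of the paired cDNA-vs-DNA ratio test under allelic fold 1."""
    cfg = sim.default_config(n_samples=n_het, seed=0)
    cfg.aei_genes["SUPT3H"].fold = 1.0
    geno = _het_genotypes(n_het, [1] * n_het, "rs529125")
    children = np.random.SeedSequence([seed, 1]).spawn(n_cohorts)
    rej = 0
    for ss in children:
        q = sim.simulate_allele_quant(geno, cfg, "SUPT3H", rng=np.random.default_rng(ss))
        if aei.paired_aei_test(q).p_value < alpha:
            rej += 1
    return rej / n_cohorts


def variance_aei_null_rejection_rate(
    n_cohorts: int = 1000, n_per_stratum: int = 10, alpha: float = 0.05,
    seed: int = 0, method: str = "levene",
) -> float:
    """Size of the between-stratum variance test under fold 1 in both strata.

    Inversion folds the null ratio distribution, which makes the plain
    F-test anti-conservative; the Brown-Forsythe method (default here)
    holds its size. Both are available for comparison.
    """
    n = 2 * n_per_stratum
    cfg = sim.default_config(n_samples=n, seed=0)
    cfg.aei_genes["RUNX2"].fold = 1.0
    geno = _het_genotypes(n, [1] * n_per_stratum + [0] * n_per_stratum, "rs1200428")
    children = np.random.SeedSequence([seed, 2]).spawn(n_cohorts)
    rej = 0
    for ss in children:
        q = sim.simulate_allele_quant(geno, cfg, "RUNX2", rng=np.random.default_rng(ss))
        res = aei.variance_aei_test(q, geno, "rs10948172", method=method)
        if res.p_value < alpha:
            rej += 1
    return rej / n_cohorts


def recover_aei_fold(
    fold: float, n_het: int = 8, n_sim: int = 200, seed: int = 0,
    replicate_sd: float = 1.5,
) -> float:
    """Mean normalized allelic ratio recovered over simulated cohorts with a
    known generating fold."""
    cfg = sim.default_config(n_samples=n_het, seed=0, replicate_sd=replicate_sd)
    cfg.aei_genes["SUPT3H"].fold = fold
    geno = _het_genotypes(n_het, [1] * n_het, "rs529125")
    children = np.random.SeedSequence([seed, 3]).spawn(n_sim)
    means = []
    for ss in children:
        q = sim.simulate_allele_quant(geno, cfg, "SUPT3H", rng=np.random.default_rng(ss))
        means.append(aei.sample_ratios(q)["normalized_ratio"].mean())
    return float(np.mean(means))


def recover_expression_fold(
    n_sim: int = 100, seed: int = 0, gene: str = "RUNX2_P1"
) -> float:
    """Mean fold change recovered by the 2^-dCt reduction from simulated
    deletion experiments (true shift -log2(3.9) cycles by default)."""
    cfg = sim.default_config(n_samples=4, seed=0)
    children = np.random.SeedSequence([seed, 4]).spawn(n_sim)
    folds = []
    for ss in children:
        ct = sim.simulate_ct(cfg, rng=np.random.default_rng(ss))
        res = assays.ddct_expression(ct, condition_pair=("+DMR", "-DMR"))
        folds.append(res.fold_change[gene])
    return float(np.mean(folds))


def dominant_snp_recovery_rate(
    n_sim: int = 100, n: int = 60, effect: float = 5.0, noise_sd: float = 3.0,
    seed: int = 0, causal: str = "rs10948172",
) -> float:
    """Fraction of simulations where the variance partition assigns the
    largest percentage effect to the SNP carrying the (single) true effect,
    despite LD with the other modelled SNPs."""
    snps = ["rs10948172", "rs10948155", "rs62435998"]
    cfg = sim.default_config(n_samples=n, seed=0, meth_noise_sd=noise_sd)
    cfg.cpg_baseline = {"CpG9": 65.0}
    cfg.cpg_effects = {"CpG9": {causal: effect}}
    children = np.random.SeedSequence([seed, 5]).spawn(n_sim)
    hits = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        for ss in children:
            rng = np.random.default_rng(ss)
            geno = sim.simulate_genotypes(cfg, rng)
            meth = sim.simulate_methylation(geno, cfg, rng=rng)
            part = varpart.fit_partition(meth, geno, snps, "CpG9")
            if max(part.contributions, key=part.contributions.get) == causal:
                hits += 1
    return hits / n_sim
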