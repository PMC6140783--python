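"""Synthetic cohort generator with known ground truth.

Emulates the data structure of a targeted bisulphite-pyrosequencing mQTL
study of an osteoarthritis-associated regulatory region: LD-structured
genotypes drawn as haplotype pairs under Hardy–Weinberg equilibrium,
genotype-dependent CpG methylation with additive per-risk-allele effects
and Gaussian noise, triplicate pyrosequencing allele-percentage readings
with replicate noise, allele-specific expression with a configurable
fold-imbalance, qPCR Ct values and dual-reporter luminescence counts.
Every generated cohort carries a truth record sufficient to recompute the
expected value of each downstream estimator.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .aei import AlleleQuantSet
from .tables_io import (
    CtTable,
    GenomicInterval,
    GenotypeTable,
    LuminescenceTable,
    MethylationTable,
    SnpSpec,
    ValidationError,
)

__all__ = [
    "SimulationConfig",
    "SyntheticCohort",
    "default_config",
    "simulate_genotypes",
    "simulate_methylation",
    "simulate_allele_quant",
    "simulate_ct",
    "simulate_luminescence",
    "simulate_cohort",
    "realized_r2",
    "DEFAULT_CPG_POSITIONS",
]

FREQ_TOL = 1e-9


# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------

@dataclass
class AeiGeneConfig:
    """AEI generating parameters for one gene's transcript SNP."""

    transcript_snp: str
    fold: float  # true allelic fold-imbalance (risk/non-risk expression)
    linked: bool  # transcript SNP in perfect LD with the association SNP?
    association_snp: str


@dataclass
class ExpressionConfig:
    """qPCR generating parameters: per-gene mean Ct and condition shifts."""

    target_mean_ct: dict[str, float]
    housekeeper_mean_ct: dict[str, float]
    # condition -> gene -> additive Ct shift (negative shift = higher expression)
    condition_ct_shift: dict[str, dict[str, float]]
    ct_noise_sd: float = 0.2
    n_experiments: int = 6


@dataclass
class LuminescenceConfig:
    """Dual-reporter parameters: per construct x state activity multiplier."""

    # (construct, methylation_state) -> mean activity relative to matched empty
    activity: dict[tuple[str, str], float]
    ratio_noise_sd: float = 0.25  # sd of lognormal noise on the well ratio
    n_wells: int = 21
    renilla_mean: float = 1e5
    renilla_cv: float = 0.1
    base_ratio: float = 0.5


@dataclass
class SimulationConfig:
    """Full generating model for a synthetic cohort."""

    n_samples: int
    seed: int
    snp_order: list[str]  # SNPs on the haplotypes, in haplotype-string order
    snp_specs: dict[str, SnpSpec]
    haplotypes: list[tuple[str, float]]  # ("A-T-C-T", freq); freqs sum to 1
    unlinked_snps: dict[str, float]  # snp_id -> risk-allele frequency (HWE, no LD)
    cpg_baseline: dict[str, float]  # CpG id -> baseline % methylation
    cpg_effects: dict[str, dict[str, float]]  # CpG id -> snp -> % per risk allele
    cpg_positions: dict[str, GenomicInterval]
    meth_noise_sd: float = 4.0
    tissues: tuple[str, ...] = ("synovium",)
    aei_genes: dict[str, AeiGeneConfig] = field(default_factory=dict)
    replicate_sd: float = 1.5
    n_replicates: int = 3
    expression: ExpressionConfig | None = None
    luminescence: LuminescenceConfig | None = None

    def __post_init__(self) -> None:
        total = sum(f for _, f in self.haplotypes)
        if any(f < 0 for _, f in self.haplotypes):
            raise ValidationError("haplotype frequencies must be non-negative")
        if abs(total - 1.0) > FREQ_TOL:
            raise ValidationError(f"haplotype frequencies sum to {total}, not 1")
        for hap, _ in self.haplotypes:
            alleles = hap.split("-")
            if len(alleles) != len(self.snp_order):
                raise ValidationError(
                    f"haplotype {hap!r} has {len(alleles)} alleles for "
                    f"{len(self.snp_order)} SNPs"
                )
            for snp, a in zip(self.snp_order, alleles):
                if a not in self.snp_specs[snp].alleles:
                    raise ValidationError(f"haplotype allele {a!r} undeclared for {snp}")
        if self.meth_noise_sd <= 0:
            raise ValidationError("meth_noise_sd must be > 0")
        if self.n_replicates < 2:
            raise ValidationError("n_replicates must be >= 2")
        for gene, cfg in self.aei_genes.items():
            if cfg.fold <= 0:
                raise ValidationError(f"aei fold for {gene} must be > 0")


# Synthetic CpG coordinates (hg19-style, single C position per site), laid
# out so that sites 2..12 span exactly the 572 bp a boundary call should
# report under the default significance pattern.
DEFAULT_CPG_POSITIONS: dict[str, int] = {
    "CpG1": 44_695_085, "CpG2": 44_695_120, "CpG3": 44_695_180,
    "CpG4": 44_695_230, "CpG5": 44_695_280, "CpG6": 44_695_330,
    "CpG7": 44_695_400, "CpG8": 44_695_440, "CpG9": 44_695_480,
    "CpG10": 44_695_530, "CpG11": 44_695_600, "CpG12": 44_695_691,
    "CpG13": 44_695_720, "CpG14": 44_695_760, "CpG15": 44_695_820,
}


def default_config(n_samples: int = 60, seed: int = 0, **overrides) -> SimulationConfig:
    """Study-structured default configuration.

    Four haplotype SNPs: the association SNP rs10948172 (A/G, risk G), the
    flanking SNP rs10948155 (T/C, risk C), the intra-region SNP rs62435998
    (C/T, risk T) and the transcript SNP rs529125 (T/C, risk C) in perfect
    LD with rs10948172. Haplotype frequencies are chosen to realize the
    reported pairwise LD (r2 ~ 0.7-0.9 between the flanking/intra-region
    SNPs, r2 = 1 for the proxy pair). The transcript SNP rs1200428 (G/T)
    segregates independently at MAF 0.23.

    Methylation: baseline 65% at every site; the association SNP lowers
    methylation by 8% per risk allele at sites 2-12 (2% only at the weak
    site 6), with small additional contributions from the other two SNPs;
    sites 1 and 13-15 carry no genotype effect. Gaussian noise sd 4%.

    AEI: SUPT3H-like gene with fold 2.2 through the linked transcript SNP;
    RUNX2-like gene with fold 1.3 through the unlinked transcript SNP
    (random phase per heterozygote).
    """
    specs = {
        "rs10948172": SnpSpec("rs10948172", ("A", "G"), "G"),
        "rs10948155": SnpSpec("rs10948155", ("T", "C"), "C"),
        "rs62435998": SnpSpec("rs62435998", ("C", "T"), "T"),
        "rs529125": SnpSpec("rs529125", ("T", "C"), "C", proxy_for="rs10948172"),
        "rs1200428": SnpSpec("rs1200428", ("G", "T"), "T"),
    }
    snp_order = ["rs10948172", "rs10948155", "rs62435998", "rs529125"]
    haplotypes = [
        ("A-T-C-T", 0.65),
        ("G-C-T-C", 0.28),
        ("A-C-T-T", 0.05),
        ("A-C-C-T", 0.02),
    ]
    cpgs = list(DEFAULT_CPG_POSITIONS)
    dmr_sites = {f"CpG{i}" for i in range(2, 13)}
    baseline = {c: 65.0 for c in cpgs}
    effects = {}
    for c in cpgs:
        if c not in dmr_sites:
            effects[c] = {"rs10948172": 0.0, "rs10948155": 0.0, "rs62435998": 0.0}
        elif c == "CpG6":
            effects[c] = {"rs10948172": -2.0, "rs10948155": 0.0, "rs62435998": 0.0}
        else:
            effects[c] = {"rs10948172": -8.0, "rs10948155": -1.0, "rs62435998": -0.8}
    positions = {
        c: GenomicInterval("chr6", p, p) for c, p in DEFAULT_CPG_POSITIONS.items()
    }
    aei_genes = {
        "SUPT3H": AeiGeneConfig("rs529125", 2.2, True, "rs10948172"),
        "RUNX2": AeiGeneConfig("rs1200428", 1.3, False, "rs10948172"),
    }
    expression = ExpressionConfig(
        target_mean_ct={"SUPT3H": 26.0, "RUNX2_ALL": 25.0, "RUNX2_P1": 28.0},
        housekeeper_mean_ct={"18S": 10.0, "GAPDH": 18.0, "HPRT1": 24.0},
        condition_ct_shift={
            "+DMR": {},
            "-DMR": {"RUNX2_P1": -math.log2(3.9)},  # 3.9-fold increase on deletion
        },
    )
    luminescence = LuminescenceConfig(
        activity={
            ("empty", "non-methylated"): 1.0,
            ("CT", "non-methylated"): 1.0,
            ("TG", "non-methylated"): 3.2,
            ("empty", "methylated"): 1.0,
            ("CT", "methylated"): 1.79,
            ("TG", "methylated"): 8.24,
        },
    )
    kwargs = dict(
        n_samples=n_samples,
        seed=seed,
        snp_order=snp_order,
        snp_specs=specs,
        haplotypes=haplotypes,
        unlinked_snps={"rs1200428": 0.23},
        cpg_baseline=baseline,
        cpg_effects=effects,
        cpg_positions=positions,
        aei_genes=aei_genes,
        expression=expression,
        luminescence=luminescence,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


# --------------------------------------------------------------------------
# Cohort container
# --------------------------------------------------------------------------

@dataclass
class SyntheticCohort:
    genotypes: GenotypeTable
    methylation: dict[str, MethylationTable]
    allele_quant: dict[str, AlleleQuantSet]
    ct: CtTable | None
    luminescence: LuminescenceTable | None
    truth: dict

    def write(self, outdir: str | Path) -> None:
        """Write the cohort as the standard delimited tables + truth sidecar."""
        from . import tables_io as tio

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        tio.write_genotypes(self.genotypes, outdir / "genotypes.csv")
        for tissue, table in self.methylation.items():
            tio.write_methylation(table, outdir / f"methylation_{tissue}.csv")
        for gene, quant in self.allele_quant.items():
            quant.data.to_csv(outdir / f"allele_quant_{gene}.csv", index=False)
        if self.ct is not None:
            tio.write_ct(self.ct, outdir / "ct.csv")
        if self.luminescence is not None:
            tio.write_luminescence(self.luminescence, outdir / "luminescence.csv")
        (outdir / "truth.json").write_text(json.dumps(self.truth, indent=2, default=str))


def _stage_rngs(seed: int, names: Sequence[str]) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


# --------------------------------------------------------------------------
# Genotypes
# --------------------------------------------------------------------------

def simulate_genotypes(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> GenotypeTable:
    """Draw each sample as two independent haplotypes (HWE).

    Haplotype-SNP genotypes inherit the configured LD; unlinked SNPs are
    drawn independently from their allele frequency.
    """
    rng = rng or np.random.default_rng(config.seed)
    freqs = np.array([f for _, f in config.haplotypes])
    hap_alleles = [h.split("-") for h, _ in config.haplotypes]
    n = config.n_samples
    idx1 = rng.choice(len(freqs), size=n, p=freqs)
    idx2 = rng.choice(len(freqs), size=n, p=freqs)
    samples = [f"S{i + 1:03d}" for i in range(n)]
    calls: dict[str, list[str]] = {snp: [] for snp in config.snp_order}
    for i in range(n):
        a1, a2 = hap_alleles[idx1[i]], hap_alleles[idx2[i]]
        for j, snp in enumerate(config.snp_order):
            calls[snp].append("".join(sorted((a1[j], a2[j]))))
    for snp, p_risk in config.unlinked_snps.items():
        spec = config.snp_specs[snp]
        other = spec.alleles[0] if spec.alleles[1] == spec.risk_allele else spec.alleles[1]
        draws = rng.random((n, 2)) < p_risk
        calls[snp] = [
            "".join(sorted(spec.risk_allele if d else other for d in row))
            for row in draws
        ]
    df = pd.DataFrame(calls, index=samples)
    return GenotypeTable(calls=df, specs=dict(config.snp_specs))


def realized_r2(genotypes: GenotypeTable, snp1: str, snp2: str) -> float:
    """Squared Pearson correlation of risk-allele dosages (genotype r2).

    Returns NaN when either SNP is monomorphic in the cohort (degenerate).
    """
    d1 = genotypes.dosage(snp1).to_numpy(float)
    d2 = genotypes.dosage(snp2).to_numpy(float)
    ok = ~(np.isnan(d1) | np.isnan(d2))
    d1, d2 = d1[ok], d2[ok]
    if np.std(d1) == 0.0 or np.std(d2) == 0.0:
        return float("nan")
    return float(np.corrcoef(d1, d2)[0, 1] ** 2)


# --------------------------------------------------------------------------
# Methylation
# --------------------------------------------------------------------------

def simulate_methylation(
    genotypes: GenotypeTable,
    config: SimulationConfig,
    tissue: str = "synovium",
    rng: np.random.Generator | None = None,
) -> MethylationTable:
    """Percent methylation = clip(baseline + sum(effect x dosage) + noise, 0, 100)."""
    rng = rng or np.random.default_rng(config.seed + 1)
    dosages = genotypes.dosage()
    cpgs = list(config.cpg_baseline)
    n = len(genotypes.samples)
    values = np.empty((n, len(cpgs)))
    for j, cpg in enumerate(cpgs):
        mu = np.full(n, config.cpg_baseline[cpg])
        for snp, eff in config.cpg_effects.get(cpg, {}).items():
            mu = mu + eff * dosages[snp].to_numpy(float)
        values[:, j] = np.clip(mu + rng.normal(0.0, config.meth_noise_sd, n), 0.0, 100.0)
    df = pd.DataFrame(values, index=genotypes.samples, columns=cpgs)
    return MethylationTable(values=df, tissue=tissue, cpg_intervals=dict(config.cpg_positions))


# --------------------------------------------------------------------------
# Allele quantification (AEI input)
# --------------------------------------------------------------------------

def simulate_allele_quant(
    genotypes: GenotypeTable,
    config: SimulationConfig,
    gene: str,
    rng: np.random.Generator | None = None,
) -> AlleleQuantSet:
    """Triplicate DNA/cDNA allele percentages for transcript-SNP heterozygotes.

    DNA replicates are drawn around 50%. For a linked transcript SNP the
    cDNA risk-allele fraction is f/(1+f) for fold f in every heterozygote.
    For an unlinked SNP the imbalance only manifests in samples that are
    also heterozygous at the association SNP, and the phase between the
    two SNPs is random, so each such sample's cDNA ratio is f or 1/f with
    equal probability; association-SNP homozygotes stay balanced.
    """
    if gene not in config.aei_genes:
        raise ValidationError(f"no AEI fold configured for gene {gene!r}")
    cfg = config.aei_genes[gene]
    rng = rng or np.random.default_rng(config.seed + 2)
    hets = genotypes.heterozygotes(cfg.transcript_snp)
    spec = config.snp_specs[cfg.transcript_snp]
    assoc_dosage = genotypes.dosage(cfg.association_snp)
    rows = []
    for sample in hets:
        if cfg.linked:
            ratio = cfg.fold
        else:
            d = assoc_dosage.get(sample)
            if pd.isna(d) or d in (0.0, 2.0):
                ratio = 1.0
            else:
                ratio = cfg.fold if rng.random() < 0.5 else 1.0 / cfg.fold
        cdna_frac = 100.0 * ratio / (1.0 + ratio)
        for material, center in (("DNA", 50.0), ("cDNA", cdna_frac)):
            for rep in range(1, config.n_replicates + 1):
                pct = float(np.clip(center + rng.normal(0.0, config.replicate_sd), 0.5, 99.5))
                rows.append((sample, material, rep, pct))
    data = pd.DataFrame(rows, columns=["sample", "material", "replicate", "pct"])
    return AlleleQuantSet(
        gene=gene,
        snp_id=cfg.transcript_snp,
        alleles=spec.alleles,
        numerator_allele=spec.risk_allele,
        data=data,
        linked_association_snp=cfg.association_snp if cfg.linked else None,
    )


# --------------------------------------------------------------------------
# Ct and luminescence
# --------------------------------------------------------------------------

def simulate_ct(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> CtTable:
    """Ct values for targets and housekeepers across conditions.

    Each biological repeat experiment contributes one Ct per gene per
    condition; target Cts receive the configured per-condition shift
    (a -log2(k) shift realizes a k-fold expression increase).
    """
    if config.expression is None:
        raise ValidationError("expression parameters not configured")
    ex = config.expression
    rng = rng or np.random.default_rng(config.seed + 3)
    rows = []
    for cond in ex.condition_ct_shift:
        shifts = ex.condition_ct_shift[cond]
        for exp_i in range(1, ex.n_experiments + 1):
            sample = f"{cond}_exp{exp_i}"
            for gene, mu in ex.target_mean_ct.items():
                ct = mu + shifts.get(gene, 0.0) + rng.normal(0.0, ex.ct_noise_sd)
                rows.append((sample, gene, cond, 1, ct))
            for gene, mu in ex.housekeeper_mean_ct.items():
                ct = mu + rng.normal(0.0, ex.ct_noise_sd)
                rows.append((sample, gene, cond, 1, ct))
    data = pd.DataFrame(rows, columns=["sample", "gene", "condition", "replicate", "ct"])
    return CtTable(data=data, housekeepers=tuple(ex.housekeeper_mean_ct))


def simulate_luminescence(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> LuminescenceTable:
    """Per-well firefly/renilla counts with lognormal ratio noise."""
    if config.luminescence is None:
        raise ValidationError("luminescence parameters not configured")
    lum = config.luminescence
    rng = rng or np.random.default_rng(config.seed + 4)
    rows = []
    w = 0
    for (construct, state), mult in lum.activity.items():
        for _ in range(lum.n_wells):
            w += 1
            renilla = max(rng.normal(lum.renilla_mean, lum.renilla_cv * lum.renilla_mean), 1.0)
            ratio = lum.base_ratio * mult * rng.lognormal(0.0, lum.ratio_noise_sd)
            rows.append((f"W{w:03d}", construct, state, renilla * ratio, renilla))
    data = pd.DataFrame(
        rows, columns=["well", "construct", "methylation_state", "firefly", "renilla"]
    )
    return LuminescenceTable(data=data)


# --------------------------------------------------------------------------
# Full cohort
# --------------------------------------------------------------------------

def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate the full cohort deterministically from config.seed.

    One master seed expands to independent per-stage generators, so the
    cohort is bit-identical under a fixed config and the stages do not
    share random streams.
    """
    stage_names = (
        ["genotypes"]
        + [f"methylation_{t}" for t in config.tissues]
        + [f"aei_{g}" for g in config.aei_genes]
        + ["ct", "luminescence"]
    )
    rngs = _stage_rngs(config.seed, stage_names)
    genotypes = simulate_genotypes(config, rngs["genotypes"])
    methylation = {
        t: simulate_methylation(genotypes, config, t, rngs[f"methylation_{t}"])
        for t in config.tissues
    }
    allele_quant = {
        g: simulate_allele_quant(genotypes, config, g, rngs[f"aei_{g}"])
        for g in config.aei_genes
    }
    ct = simulate_ct(config, rngs["ct"]) if config.expression else None
    lum = simulate_luminescence(config, rngs["luminescence"]) if config.luminescence else None
    truth = {
        "seed": config.seed,
        "n_samples": config.n_samples,
        "haplotypes": config.haplotypes,
        "unlinked_snps": config.unlinked_snps,
        "cpg_baseline": config.cpg_baseline,
        "cpg_effects": config.cpg_effects,
        "meth_noise_sd": config.meth_noise_sd,
        "aei_folds": {g: c.fold for g, c in config.aei_genes.items()},
        "replicate_sd": config.replicate_sd,
        "expression_shifts": (
            config.expression.condition_ct_shift if config.expression else None
        ),
        "luminescence_activity": (
            {f"{c}|{s}": v for (c, s), v in config.luminescence.activity.items()}
            if config.luminescence else None
        ),
    }
    return SyntheticCohort(
        genotypes=genotypes,
        methylation=methylation,
        allele_quant=allele_quant,
        ct=ct,
        luminescence=lum,
        truth=truth,
    )
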