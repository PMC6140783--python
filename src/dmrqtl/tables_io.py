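"""Tabular input/output and genomic-interval arithmetic.

All tables travel as delimited text (comma or tab, auto-detected, header
mandatory). Coordinates are 1-based inclusive internally, matching the
hg19-style notation used in targeted bisulphite assay designs; BED export
converts to 0-based half-open. Missing data are propagated, never imputed.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicInterval",
    "SnpSpec",
    "GenotypeTable",
    "MethylationTable",
    "CtTable",
    "LuminescenceTable",
    "DmrCall",
    "read_genotypes",
    "write_genotypes",
    "read_methylation",
    "write_methylation",
    "read_ct",
    "write_ct",
    "read_luminescence",
    "write_luminescence",
    "interval_length",
    "write_dmr_bed",
    "read_dmr_bed",
    "load_snp_specs",
]


class ValidationError(ValueError):
    """Raised when an input table violates a schema invariant."""


# --------------------------------------------------------------------------
# Genomic intervals
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    """A 1-based, fully inclusive genomic interval.

    ``chr6:44,695,068-44,695,721`` spans 654 bp: both endpoints count.
    """

    chrom: str
    start: int
    end: int
    assembly: str = "hg19"

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValidationError(
                f"interval end < start: {self.chrom}:{self.start}-{self.end}"
            )
        if self.start < 1:
            raise ValidationError(f"1-based start must be >= 1, got {self.start}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def interval_length(iv: GenomicInterval) -> int:
    """Number of base pairs in the inclusive interval (end - start + 1)."""
    return iv.length


# --------------------------------------------------------------------------
# SNP declarations
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SnpSpec:
    """Declared alleles and risk allele for one SNP.

    ``proxy_for`` records that this SNP was assayed as a perfect-LD stand-in
    for another (e.g. a transcript SNP genotyped in place of the association
    SNP); the substitution is explicit, never silent.
    """

    snp_id: str
    alleles: tuple[str, str]
    risk_allele: str
    proxy_for: str | None = None

    def __post_init__(self) -> None:
        if self.risk_allele not in self.alleles:
            raise ValidationError(
                f"risk allele {self.risk_allele!r} not among declared alleles "
                f"{self.alleles} for {self.snp_id}"
            )


def load_snp_specs(path: str | Path) -> dict[str, SnpSpec]:
    """Load SNP declarations (alleles, risk allele, alias map) from YAML/JSON.

    Expected structure::

        snps:
          rs10948172: {alleles: [A, G], risk: G}
          rs529125:   {alleles: [T, C], risk: C, proxy_for: rs10948172}
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    specs: dict[str, SnpSpec] = {}
    for snp_id, entry in data["snps"].items():
        alleles = tuple(str(a) for a in entry["alleles"])
        if len(alleles) != 2:
            raise ValidationError(f"{snp_id}: exactly two alleles required")
        specs[snp_id] = SnpSpec(
            snp_id=snp_id,
            alleles=alleles,  # type: ignore[arg-type]
            risk_allele=str(entry["risk"]),
            proxy_for=entry.get("proxy_for"),
        )
    return specs


# --------------------------------------------------------------------------
# Genotype table
# --------------------------------------------------------------------------

@dataclass
class GenotypeTable:
    """Sample-by-SNP genotype calls stored as unordered allele pairs.

    ``calls`` holds strings like ``"AG"`` (sorted allele pair) or ``NaN`` for
    missing. The risk-allele dosage in {0,1,2} is a derived view.
    """

    calls: pd.DataFrame  # index: samples, columns: snp ids, values: str|NaN
    specs: dict[str, SnpSpec]

    def __post_init__(self) -> None:
        if self.calls.index.duplicated().any():
            dupes = self.calls.index[self.calls.index.duplicated()].tolist()
            raise ValidationError(f"duplicate sample IDs: {dupes}")
        for snp in self.calls.columns:
            if snp not in self.specs:
                raise ValidationError(f"no declaration for SNP {snp!r}")
            allowed = set(self.specs[snp].alleles)
            for sample, call in self.calls[snp].items():
                if pd.isna(call):
                    continue
                if not set(call) <= allowed:
                    raise ValidationError(
                        f"undeclared allele in call {call!r} for sample "
                        f"{sample!r} at {snp}"
                    )

    @property
    def samples(self) -> list[str]:
        return list(self.calls.index)

    @property
    def snps(self) -> list[str]:
        return list(self.calls.columns)

    def dosage(self, snp: str | None = None) -> pd.DataFrame | pd.Series:
        """Count of risk alleles per call (0/1/2; NaN where missing)."""
        def _dose(col: pd.Series, spec: SnpSpec) -> pd.Series:
            return col.map(
                lambda c: np.nan if pd.isna(c) else float(c.count(spec.risk_allele))
            )

        if snp is not None:
            return _dose(self.calls[snp], self.specs[snp])
        return pd.DataFrame(
            {s: _dose(self.calls[s], self.specs[s]) for s in self.calls.columns},
            index=self.calls.index,
        )

    def heterozygotes(self, snp: str) -> list[str]:
        spec = self.specs[snp]
        het = "".join(sorted(spec.alleles))
        col = self.calls[snp]
        return [s for s, c in col.items() if not pd.isna(c) and "".join(sorted(c)) == het]


def _read_delimited(path: str | Path) -> pd.DataFrame:
    """Read a comma- or tab-delimited table with a mandatory header row."""
    text = Path(path).read_text()
    first_line = text.splitlines()[0] if text.splitlines() else ""
    if not first_line:
        raise ValidationError(f"{path}: empty file (header row required)")
    try:
        dialect = csv.Sniffer().sniff(first_line, delimiters=",\t")
        sep = dialect.delimiter
    except csv.Error:
        sep = ","
    return pd.read_csv(path, sep=sep, dtype=str, index_col=0, skipinitialspace=True)


def read_genotypes(path: str | Path, snp_specs: Mapping[str, SnpSpec]) -> GenotypeTable:
    """Read sample-by-SNP genotype calls from delimited text.

    Header row carries SNP IDs; first column carries sample IDs. Calls must
    be two-character allele pairs drawn from the declared alleles.
    Unparseable calls (wrong length, placeholder symbols such as ``NA`` or
    ``--``) become missing with a logged warning count; a call using an
    undeclared nucleotide raises :class:`ValidationError` naming the sample
    and SNP.
    """
    raw = _read_delimited(path)
    n_unparseable = 0
    parsed = {}
    missing_tokens = {"", "na", "nan", "--", ".", "nn", "n/a"}
    for snp in raw.columns:
        if snp not in snp_specs:
            raise ValidationError(f"{path}: SNP {snp!r} has no declaration")
        spec = snp_specs[snp]
        col = {}
        for sample, val in raw[snp].items():
            if pd.isna(val) or str(val).strip().lower() in missing_tokens:
                col[sample] = np.nan
                continue
            call = str(val).strip().replace("/", "")
            if len(call) != 2:
                n_unparseable += 1
                col[sample] = np.nan
                continue
            if not set(call) <= set(spec.alleles):
                raise ValidationError(
                    f"{path}: undeclared allele in call {val!r} for sample "
                    f"{sample!r} at {snp} (declared {spec.alleles})"
                )
            col[sample] = "".join(sorted(call))
        parsed[snp] = col
    if n_unparseable:
        logger.warning("%s: %d unparseable genotype call(s) set to missing", path, n_unparseable)
    calls = pd.DataFrame(parsed, index=raw.index)
    calls.index = calls.index.astype(str)
    calls.index.name = None
    return GenotypeTable(calls=calls, specs=dict(snp_specs))


def write_genotypes(table: GenotypeTable, path: str | Path) -> None:
    out = table.calls.copy()
    out.index.name = "sample"
    out.to_csv(path)


# --------------------------------------------------------------------------
# Methylation table
# --------------------------------------------------------------------------

@dataclass
class MethylationTable:
    """Sample-by-CpG percent methylation for one tissue.

    CpG columns are kept in genomic order; values lie in [0, 100] with
    missing allowed. ``cpg_intervals`` optionally maps CpG IDs to genomic
    coordinates (needed for BED export of called regions).
    """

    values: pd.DataFrame  # index: samples, columns: CpG ids, float
    tissue: str
    cpg_intervals: dict[str, GenomicInterval] = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = self.values.to_numpy(dtype=float)
        bad = np.argwhere((arr < 0) | (arr > 100))
        if bad.size:
            i, j = bad[0]
            raise ValidationError(
                f"methylation value out of [0,100] at sample "
                f"{self.values.index[i]!r}, CpG {self.values.columns[j]!r}: "
                f"{arr[i, j]}"
            )

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def cpgs(self) -> list[str]:
        return list(self.values.columns)


def read_methylation(
    path: str | Path,
    tissue: str,
    cpg_intervals: Mapping[str, GenomicInterval] | None = None,
) -> MethylationTable:
    """Read a sample-by-CpG percent-methylation matrix.

    Cells must be numeric in [0, 100] or empty (missing). Out-of-range
    values are an error reporting the offending cell, never clipped.
    """
    raw = _read_delimited(path)
    vals = {}
    for cpg in raw.columns:
        col = {}
        for sample, cell in raw[cpg].items():
            if pd.isna(cell) or str(cell).strip() == "":
                col[sample] = np.nan
                continue
            try:
                v = float(cell)
            except ValueError as exc:
                raise ValidationError(
                    f"{path}: non-numeric methylation value {cell!r} at "
                    f"sample {sample!r}, CpG {cpg!r}"
                ) from exc
            if not (0.0 <= v <= 100.0):
                raise ValidationError(
                    f"{path}: methylation value {v} outside [0,100] at "
                    f"sample {sample!r}, CpG {cpg!r}"
                )
            col[sample] = v
        vals[cpg] = col
    df = pd.DataFrame(vals, index=raw.index).astype(float)
    df.index = df.index.astype(str)
    df.index.name = None
    return MethylationTable(values=df, tissue=tissue, cpg_intervals=dict(cpg_intervals or {}))


def write_methylation(table: MethylationTable, path: str | Path) -> None:
    out = table.values.copy()
    out.index.name = "sample"
    out.to_csv(path)


# --------------------------------------------------------------------------
# Ct table (RT-qPCR)
# --------------------------------------------------------------------------

@dataclass
class CtTable:
    """Long-format qPCR cycle-threshold readings.

    Columns: sample, gene, condition, replicate, ct. ``housekeepers`` flags
    which genes act as the reference aggregate for the 2^-dCt reduction.
    """

    data: pd.DataFrame
    housekeepers: tuple[str, ...]

    REQUIRED = ("sample", "gene", "condition", "replicate", "ct")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValidationError(f"Ct table missing columns: {missing}")
        ct = self.data["ct"].astype(float)
        if (ct <= 0).any():
            bad = self.data.loc[ct <= 0].iloc[0]
            raise ValidationError(
                f"non-positive Ct {bad['ct']} for sample {bad['sample']!r}, gene {bad['gene']!r}"
            )
        hk = set(self.housekeepers) & set(self.data["gene"])
        if not hk:
            raise ValidationError("no housekeeper measurements present in Ct table")
        per_sample = self.data[self.data["gene"].isin(self.housekeepers)].groupby("sample").size()
        absent = set(self.data["sample"]) - set(per_sample.index)
        if absent:
            raise ValidationError(f"samples without any housekeeper Ct: {sorted(absent)}")

    @property
    def targets(self) -> list[str]:
        return [g for g in self.data["gene"].unique() if g not in self.housekeepers]


def read_ct(path: str | Path, housekeepers: Sequence[str]) -> CtTable:
    raw = _read_delimited(path).reset_index()
    raw["ct"] = raw["ct"].astype(float)
    return CtTable(data=raw, housekeepers=tuple(housekeepers))


def write_ct(table: CtTable, path: str | Path) -> None:
    table.data.to_csv(path, index=False)


# --------------------------------------------------------------------------
# Luminescence table (dual-reporter)
# --------------------------------------------------------------------------

@dataclass
class LuminescenceTable:
    """Per-well firefly/renilla luminescence counts.

    Columns: well, construct, methylation_state, firefly, renilla. The
    ``empty`` construct in each methylation state is the normalization
    control.
    """

    data: pd.DataFrame
    STATES = ("methylated", "non-methylated")
    REQUIRED = ("well", "construct", "methylation_state", "firefly", "renilla")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValidationError(f"luminescence table missing columns: {missing}")
        bad_state = set(self.data["methylation_state"]) - set(self.STATES)
        if bad_state:
            raise ValidationError(f"unknown methylation state(s): {sorted(bad_state)}")
        if (self.data["firefly"].astype(float) < 0).any():
            raise ValidationError("negative firefly counts")


def read_luminescence(path: str | Path) -> LuminescenceTable:
    raw = _read_delimited(path).reset_index()
    raw["firefly"] = raw["firefly"].astype(float)
    raw["renilla"] = raw["renilla"].astype(float)
    return LuminescenceTable(data=raw)


def write_luminescence(table: LuminescenceTable, path: str | Path) -> None:
    table.data.to_csv(path, index=False)


# --------------------------------------------------------------------------
# DMR calls and BED export
# --------------------------------------------------------------------------

@dataclass
class DmrCall:
    """Boundaries of the contiguous run of genotype-associated CpGs.

    ``significant`` lists CpG IDs with adjusted p below threshold, in
    genomic order. Boundaries are the first and last significant CpG;
    interior non-significant CpGs are reported as ``gaps`` rather than
    truncating the call.
    """

    tissue: str
    significant: list[str]
    boundary_5p: str | None
    boundary_3p: str | None
    contiguous: bool
    gaps: list[str] = field(default_factory=list)
    interval: GenomicInterval | None = None

    @property
    def empty(self) -> bool:
        return not self.significant

    def to_json(self) -> str:
        d = {
            "tissue": self.tissue,
            "significant": self.significant,
            "boundary_5p": self.boundary_5p,
            "boundary_3p": self.boundary_3p,
            "contiguous": self.contiguous,
            "gaps": self.gaps,
        }
        if self.interval is not None:
            d["interval"] = {
                "chrom": self.interval.chrom,
                "start": self.interval.start,
                "end": self.interval.end,
                "assembly": self.interval.assembly,
            }
        return json.dumps(d, indent=2)


def write_dmr_bed(call: DmrCall, path: str | Path, name: str | None = None) -> None:
    """Write the called region as a 3(+1)-column BED line.

    BED is 0-based half-open, so the 1-based inclusive interval
    ``[start, end]`` becomes ``start-1, end``. An empty call writes an
    empty file.
    """
    path = Path(path)
    if call.empty:
        path.write_text("")
        return
    if call.interval is None:
        raise ValidationError(
            "DmrCall has no genomic interval; supply CpG coordinates "
            "(cpg_intervals on the methylation table) to enable BED export"
        )
    iv = call.interval
    fields = [iv.chrom, str(iv.start - 1), str(iv.end)]
    if name is not None:
        fields.append(name)
    path.write_text("\t".join(fields) + "\n")


def read_dmr_bed(path: str | Path, assembly: str = "hg19") -> list[GenomicInterval]:
    """Read BED lines back as 1-based inclusive intervals."""
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        chrom, start0, end = parts[0], int(parts[1]), int(parts[2])
        out.append(GenomicInterval(chrom=chrom, start=start0 + 1, end=end, assembly=assembly))
    return out
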