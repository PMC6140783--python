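import numpy as np
import pandas as pd
import pytest

from dmrqtl import simulate as sim
from dmrqtl.tables_io import GenotypeTable, MethylationTable, SnpSpec


STUDY_SPECS = {
    "rs10948172": SnpSpec("rs10948172", ("A", "G"), "G"),
    "rs10948155": SnpSpec("rs10948155", ("T", "C"), "C"),
    "rs62435998": SnpSpec("rs62435998", ("C", "T"), "T"),
    "rs529125": SnpSpec("rs529125", ("T", "C"), "C", proxy_for="rs10948172"),
    "rs1200428": SnpSpec("rs1200428", ("G", "T"), "T"),
}


def genotype_table_from_dosages(dosages: dict[str, list[int]],
                                specs: dict[str, SnpSpec] | None = None) -> GenotypeTable:
    """Build a GenotypeTable directly from risk-allele dosages."""
    specs = specs or STUDY_SPECS
    n = len(next(iter(dosages.values())))
    samples = [f"S{i + 1:03d}" for i in range(n)]
    calls = {}
    for snp, dose in dosages.items():
        spec = specs[snp]
        other = spec.alleles[0] if spec.alleles[1] == spec.risk_allele else spec.alleles[1]
        mapping = {
            0: other * 2,
            1: "".join(sorted(other + spec.risk_allele)),
            2: spec.risk_allele * 2,
        }
        calls[snp] = [mapping[d] for d in dose]
    return GenotypeTable(calls=pd.DataFrame(calls, index=samples), specs=specs)


def methylation_from_values(values: dict[str, list[float]], samples=None,
                            tissue="synovium") -> MethylationTable:
    n = len(next(iter(values.values())))
    samples = samples or [f"S{i + 1:03d}" for i in range(n)]
    return MethylationTable(values=pd.DataFrame(values, index=samples), tissue=tissue)


@pytest.fixture(scope="session")
def study_specs():
    return STUDY_SPECS


@pytest.fixture(scope="session")
def cohort():
    """A mid-size default cohort reused by read-only tests."""
    return sim.simulate_cohort(sim.default_config(n_samples=120, seed=7))
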