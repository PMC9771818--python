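import numpy as np
import pandas as pd
import pytest

from transmeta.summary_io import CohortSummary, VariantRecord


def make_record(pos=100, chrom="1", ref="A", alt="G", freq=0.3, beta=0.1, se=0.05, rsq=0.95):
    return VariantRecord(
        chrom=chrom, pos=pos, ref=ref, alt=alt, freq=freq,
        beta=beta, se=se, z=beta / se, rsq=rsq,
    )


def make_cohort(study_id="s1", n=10_000, lam=1.0, records=None):
    if records is None:
        records = [make_record(pos=100 + i) for i in range(3)]
    return CohortSummary(study_id=study_id, n=n, lambda_gc=lam, records=records)


@pytest.fixture
def rng():
    return np.random.default_rng(1)


@pytest.fixture
def random_cohort_pair(rng):
    """Two simulated cohorts sharing 50 variants, with random allele
    orientations, for harmonisation oracle tests."""
    n_var = 50
    cohorts = []
    for sid in ("A", "B"):
        records = []
        for j in range(n_var):
            freq = rng.uniform(0.05, 0.95)
            beta = rng.normal(0, 0.05)
            se = rng.uniform(0.01, 0.1)
            flip = bool(rng.integers(2)) and sid == "B"
            if flip:
                records.append(
                    VariantRecord("1", 1000 + j, "G", "A", 1 - freq, -beta, se, -beta / se, 0.9)
                )
            else:
                records.append(
                    VariantRecord("1", 1000 + j, "A", "G", freq, beta, se, beta / se, 0.9)
                )
        cohorts.append(CohortSummary(sid, 5000, 1.0, records))
    return cohorts
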