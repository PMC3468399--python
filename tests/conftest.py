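import numpy as np
import pandas as pd
import pytest

import protpair as pp


def make_random_cohort(rng, n_peptides=None, n_patients=None, n_replicates=2,
                       missing_rate=0.1, zero_rate=0.05):
    """Small random table + annotation for oracle/property tests."""
    n_pep = int(n_peptides if n_peptides is not None else rng.integers(3, 21))
    n_pat = int(n_patients if n_patients is not None else rng.integers(4, 6))
    labels = ["C", "C", "P", "P"] + list(rng.choice(["C", "P"], n_pat - 4))
    peptides = [f"pep{i}" for i in range(n_pep)]
    records = []
    for pat, lab in enumerate(labels):
        for r in range(n_replicates):
            records.append((f"pt{pat}_r{r + 1}", f"pt{pat}", lab, r + 1))
    sample_ids = [rec[0] for rec in records]
    values = np.exp(rng.normal(10.0, 2.0, size=(n_pep, len(sample_ids))))
    values[rng.random(values.shape) < missing_rate] = np.nan
    values[rng.random(values.shape) < zero_rate] = 0.0
    table = pp.IntensityTable(
        pd.DataFrame(values, index=peptides, columns=sample_ids)
    )
    annot = pp.SampleAnnotation(
        pd.DataFrame(
            records,
            columns=["sample_id", "patient_id", "class_label", "replicate_index"],
        )
    )
    return table, annot


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (8 C / 13 P patients, 2 replicates)."""
    return pp.generate_cohort(pp.SimConfig(seed=11))


@pytest.fixture(scope="session")
def small_cohort():
    """A fast cohort for pipeline tests: 10 proteins, 5+5 patients."""
    cfg = pp.SimConfig(
        seed=3, n_control=5, n_progressor=5, n_proteins=10,
        planted_pairs=[("PROT001", "PROT002", 1.5)],
    )
    return pp.generate_cohort(cfg)


@pytest.fixture()
def toy_annotation():
    return pp.SampleAnnotation(
        pd.DataFrame(
            {
                "sample_id": ["a1", "a2", "b1", "b2", "c1", "c2", "d1", "d2"],
                "patient_id": ["a", "a", "b", "b", "c", "c", "d", "d"],
                "class_label": ["C", "C", "C", "C", "P", "P", "P", "P"],
                "replicate_index": [1, 2, 1, 2, 1, 2, 1, 2],
            }
        )
    )
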