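import numpy as np
import pandas as pd
import pytest

from spongescan.data_io import (
    ExpressionMatrix,
    InputBundle,
    SampleAnnotation,
    validate_site_table,
)
from spongescan.synthetic import FixtureConfig, generate_fixture


def make_expr(rna_type, ids, samples, values):
    return ExpressionMatrix(
        rna_type, pd.DataFrame(np.asarray(values, dtype=float), index=ids, columns=samples)
    )


def make_sites(rows):
    """rows of (mirna, target, target_type, score); site_index auto-assigned.

    Identifiers are not validated so tests can use short synthetic names.
    """
    counter = {}
    out = []
    for mirna, target, ttype, score in rows:
        key = (mirna, target)
        counter[key] = counter.get(key, 0) + 1
        out.append((mirna, target, ttype, score, counter[key]))
    df = pd.DataFrame(
        out, columns=["mirna_id", "target_id", "target_type", "raw_score", "site_index"]
    )
    return df.sort_values(["mirna_id", "target_id", "target_type"]).reset_index(drop=True)


@pytest.fixture
def samples6():
    return [f"S{i}" for i in range(1, 7)]


@pytest.fixture
def annotation6(samples6):
    return SampleAnnotation(
        {s: ("condition_1" if i < 3 else "condition_2") for i, s in enumerate(samples6)}
    )


@pytest.fixture
def toy_bundle(samples6, annotation6):
    """5 circRNAs x 6 samples, 8 mRNAs, 4 miRNAs, 3+3 split."""
    rng = np.random.default_rng(42)
    circ_ids = [f"hsa_circ_{i:07d}" for i in range(1, 6)]
    mrna_ids = [f"GENE{i}" for i in range(1, 9)]
    mirna_ids = [f"hsa-miR-{i}-5p" for i in range(1, 5)]
    circ = make_expr("circRNA", circ_ids, samples6, rng.uniform(2, 10, (5, 6)))
    mrna = make_expr("mRNA", mrna_ids, samples6, rng.uniform(2, 10, (8, 6)))
    mirna = make_expr("miRNA", mirna_ids, samples6, rng.uniform(4, 10, (4, 6)))
    circ_sites = make_sites(
        [
            (m, c, "circRNA", float(sc))
            for m in mirna_ids
            for c, sc in zip(circ_ids, rng.uniform(-0.5, -0.05, 5))
        ]
    )
    mrna_sites = make_sites(
        [
            (m, g, "mRNA", float(sc))
            for m in mirna_ids
            for g, sc in zip(mrna_ids, rng.uniform(-0.5, -0.05, 8))
        ]
    )
    lengths = {c: int(length) for c, length in zip(circ_ids, rng.integers(300, 2000, 5))}
    return InputBundle(
        circ_expr=circ,
        mrna_expr=mrna,
        annotation=annotation6,
        circ_sites=circ_sites,
        mrna_sites=mrna_sites,
        circ_lengths=lengths,
        mirna_expr=mirna,
    )


@pytest.fixture(scope="session")
def small_fixture():
    """Small but complete synthetic bundle for fast end-to-end tests."""
    cfg = FixtureConfig(
        n_circ=40, n_mrna=80, n_mirna=15, n_samples_per_condition=3, seed=7
    )
    return generate_fixture(cfg)
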