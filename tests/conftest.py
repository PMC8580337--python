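import numpy as np
import pandas as pd
import pytest

import physioage as pa


@pytest.fixture(scope="session")
def small_cohort():
    """Complete 600-individual cohort with a strong latent aging signal."""
    cfg = pa.SimulationConfig(
        n_individuals=600, seed=11,
        n_continuous=20, n_ordinal=5, n_binary=3,
    )
    cohort, truth = pa.generate_cohort(cfg)
    return cohort, truth, cfg


@pytest.fixture(scope="session")
def small_predictions(small_cohort):
    """Ensemble physiological ages on the small cohort (fast linear family)."""
    cohort, truth, _ = small_cohort
    preds = pa.ensemble_physio_age(
        cohort, pa.ModelSpec(family="linear"), m=150, seed=3
    )
    return pa.rescale_trim(preds, mode="rescale")


@pytest.fixture
def toy_tables(tmp_path):
    """3x2 trait TSV with one NA cell plus matching metadata."""
    trait = tmp_path / "traits.tsv"
    meta = tmp_path / "meta.tsv"
    trait.write_text(
        "id\tbmi\tpwv\n"
        "a\t21.5\t6.1\n"
        "b\tNA\t7.3\n"
        "c\t24.0\t8.8\n"
    )
    meta.write_text(
        "id\tage\tsex\tdeceased\tlifespan\twave\n"
        "a\t40\t0\t0\tNA\t1\n"
        "b\t55\t1\t0\tNA\t1\n"
        "c\t70\t1\t1\t74.2\t1\n"
    )
    return trait, meta
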