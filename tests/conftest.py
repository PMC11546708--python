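import numpy as np
import pytest

import lipidsig as ls


@pytest.fixture(scope="session")
def planted_small():
    """An 80-sample, 50-lipid cohort with 5 strongly planted lipids.

    No batch effects, technical noise or within-class correlation, so the
    planted log2 fold change of 1.5 is the only structure separating the
    groups.
    """
    schema = ls.build_lipid_schema(50, 5, isomer_rate=0.0, seed=1)
    cfg = ls.GeneratorConfig(
        n_control=40,
        n_cancer=40,
        n_lipids=50,
        n_classes=5,
        n_informative=5,
        effect_log2fc=1.5,
        within_class_corr=0.0,
        sigma_bio=1.0,
        sigma_tech_plasma=0.0,
        sigma_tech_ev=0.0,
        n_batches=2,
        batch_sd=0.0,
        seed=7,
    )
    table, truth = ls.simulate_cohort(cfg, schema, "plasma")
    return cfg, schema, table, truth


@pytest.fixture(scope="session")
def planted_xy(planted_small):
    """Log-scale matrix/labels view of the planted cohort."""
    _, _, table, truth = planted_small
    bio = ls.log_transform(table).biological()
    X = bio.values.to_numpy()
    y = bio.labels().to_numpy()
    names = list(bio.values.columns)
    return X, y, names, truth
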