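import numpy as np
import pytest

from vancopta.pk import DosingRegimen, PopulationParameters, SubjectRealization, default_population
from vancopta.surrogate import (
    evaluate_surrogate,
    generate_surrogate_dataset,
    select_architecture,
    split_and_normalize,
)


@pytest.fixture(scope="session")
def pop():
    return default_population()


@pytest.fixture()
def typical_subject(pop):
    return SubjectRealization(cl=pop.theta0_cl, q=pop.q, v1=pop.v1, v2=pop.v2, egfr=144.0)


@pytest.fixture()
def regimen_1g_q12h():
    return DosingRegimen.from_daily_dose(2000.0, 12.0, 2.0, horizon=96.0)


@pytest.fixture(scope="session")
def surrogate_bundle():
    """Desk-scale surrogate pipeline shared across test modules.

    500 regimens labelled with 300 simulated subjects each; both surrogate
    models trained with architecture selection over A-D.
    """
    dataset = generate_surrogate_dataset(n_regimens=500, n_subjects=300, rng_seed=42)
    bundle = {"dataset": dataset}
    for model_id in (1, 2):
        xtr, ytr, xte, yte, mean, std = split_and_normalize(dataset, model_id, rng_seed=42)
        arch, fitted, per_arch = select_architecture(
            xtr, ytr, xte, yte, mean, std, rng_seed=1
        )
        bundle[model_id] = {
            "X_train": xtr,
            "y_train": ytr,
            "X_test": xte,
            "y_test": yte,
            "architecture": arch,
            "model": fitted,
            "per_architecture": per_arch,
            "train_metrics": evaluate_surrogate(fitted, xtr, ytr),
            "test_metrics": evaluate_surrogate(fitted, xte, yte),
        }
    return bundle


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260923)
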