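import numpy as np
import pandas as pd
import pytest

import pollscape as ps
from pollscape.pipeline import _matching_with_scores, build_model_data


@pytest.fixture(scope="session")
def dataset():
    """Study-scale synthetic dataset: 3 species, 3/9/8 birds, 5 trials."""
    return ps.generate_dataset(seed=1)


@pytest.fixture(scope="session")
def metrics(dataset):
    return ps.compute_metrics(dataset["trials"])


@pytest.fixture(scope="session")
def matching(dataset):
    donor, donor_pc = _matching_with_scores(
        dataset["birds"], dataset["flowers"], dataset["trials"], "donor")
    recv, recv_pc = _matching_with_scores(
        dataset["birds"], dataset["flowers"], dataset["trials"], "receiver")
    return {"donor": donor, "receiver": recv,
            "donor_pc": donor_pc, "receiver_pc": recv_pc}


@pytest.fixture(scope="session")
def model_data(metrics, matching, dataset):
    per_trial, per_visit = build_model_data(
        metrics, matching["donor"], matching["receiver"], dataset["trials"])
    return {"per_trial": per_trial, "per_visit": per_visit}


def simulate_nb_glmm(n_species=3, birds_per_species=15, n_trials=5,
                     offsets=(2.0, 1.0, 1.5), theta=1.0, sigma=0.5, seed=0):
    """Direct NB2 random-intercept simulator, independent of the package."""
    rng = np.random.default_rng(seed)
    rows = []
    for k in range(n_species):
        for b in range(birds_per_species):
            u = rng.normal(0.0, sigma)
            mu = np.exp(offsets[k] + u)
            y = rng.negative_binomial(theta, theta / (theta + mu), size=n_trials)
            for v in y:
                rows.append({"bird_id": f"S{k}B{b}", "species": f"sp{k}",
                             "y": float(v)})
    return pd.DataFrame(rows)
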