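import numpy as np
import pytest

from gulltrack import behavior as bh
from gulltrack.synthetic import SimConfig, generate_landscape, simulate_bird_days


@pytest.fixture(scope="session")
def landscape():
    return generate_landscape(seed=7)


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig(seed=7)


@pytest.fixture(scope="session")
def gull_days(sim_config, landscape):
    """A small multi-bird dataset shared across tests."""
    fixes, bursts, truth, birds = simulate_bird_days(
        sim_config, n_birds=4, n_days=2, rules=landscape)
    return {"fixes": fixes, "bursts": bursts, "truth": truth, "birds": birds}


@pytest.fixture(scope="session")
def burst_features(gull_days):
    feats = bh.features_table(gull_days["bursts"])
    labels = gull_days["truth"].fixes.set_index("fix_id")["fine"]
    return feats, labels.loc[feats.index]


@pytest.fixture(scope="session")
def labeled_burst_bank(sim_config):
    """A balanced labeled burst set: 40 bursts per fine behavior."""
    from gulltrack.synthetic import simulate_acc_burst

    rows, labels = [], []
    for li, lab in enumerate(sim_config.behavior_acc_params):
        for j in range(40):
            burst = simulate_acc_burst(lab, sim_config, seed=1000 * li + j)
            rows.append(bh.extract_features(burst))
            labels.append(lab)
    return np.asarray(rows), np.asarray(labels, dtype=object)


@pytest.fixture(scope="session")
def trained_classifier(labeled_burst_bank):
    X, y = labeled_burst_bank
    return bh.train_classifier(X, y, seed=3)
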