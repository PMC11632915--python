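import numpy as np
import pandas as pd
import pytest

from cirbe import ModelParameters, SyntheticConfig, TrainingDataset, generate_synthetic_dataset
from cirbe.data_io import SurvivalRecord


@pytest.fixture(scope="session")
def published():
    return ModelParameters.published()


@pytest.fixture(scope="session")
def noiseless_dataset(published):
    """60 noiseless records (20 lines x 3 random LETs) from the published truth."""
    cfg = SyntheticConfig(
        n_cell_lines=20,
        lets=None,
        n_lets_per_line=3,
        let_range=(5.0, 200.0),
        endpoint_noise_cv=0.0,
        seed=11,
    )
    return generate_synthetic_dataset(cfg)


@pytest.fixture(scope="session")
def noisy_dataset(published):
    """90 records (30 lines x 3 random LETs) with 5% endpoint noise."""
    cfg = SyntheticConfig(
        n_cell_lines=30,
        lets=None,
        n_lets_per_line=3,
        let_range=(5.0, 200.0),
        endpoint_noise_cv=0.05,
        seed=7,
    )
    return generate_synthetic_dataset(cfg)


@pytest.fixture(scope="session")
def unconstrained_dataset(published):
    """Noiseless records confined to the unconstrained conversion branch.

    Only on this branch does the stored C-ion curve interpolate the
    generating endpoints exactly, so endpoint-space trend relations are
    exact.  Records whose true endpoints trip the beta>=0 constraint are
    dropped (their stored curves are least-squares, not interpolants).
    """
    cfg = SyntheticConfig(
        n_cell_lines=40,
        lets=None,
        n_lets_per_line=3,
        let_range=(5.0, 120.0),
        alpha_x_range=(0.05, 0.3),
        beta_x_range=(0.03, 0.1),
        endpoint_noise_cv=0.0,
        seed=13,
    )
    ds = generate_synthetic_dataset(cfg)
    kept = [r for r in ds if r.alpha_c > 0 and r.beta_c > 0]
    assert len(kept) >= 60
    return TrainingDataset(records=kept)


def _rec(cell_line, let_d=30.0, alpha_x=0.3, beta_x=0.03, alpha_c=0.6,
         beta_c=0.02, kvp=6000.0):
    return SurvivalRecord(
        cell_line=cell_line,
        let_d=let_d,
        alpha_x=alpha_x,
        beta_x=beta_x,
        alpha_c=alpha_c,
        beta_c=beta_c,
        photon_source_kvp=kvp,
    )


@pytest.fixture()
def curation_fixture():
    """10 records with 2/1/3 known violations (first-rule-wins) and 4 retained.

    The retained four exercise the boundary conventions: exactly 200 kVp,
    exactly LET 350, and beta_c exactly 0 are all kept.
    """
    records = [
        _rec("KV100", kvp=100.0),                         # rule 1
        _rec("KV199", kvp=199.9, beta_c=-0.1),            # rule 1 (first wins)
        _rec("LET351", let_d=351.0, kvp=250.0),           # rule 2
        _rec("NEGB1", beta_c=-0.01),                      # rule 3
        _rec("NEGB2", beta_c=-0.5),                       # rule 3
        _rec("NEGB3", kvp=1000.0, beta_c=-0.2),           # rule 3
        _rec("KV200", kvp=200.0),                         # retained (boundary)
        _rec("LET350", let_d=350.0),                      # retained (boundary)
        _rec("ZEROB", beta_c=0.0),                        # retained (boundary)
        _rec("CLEAN"),                                    # retained
    ]
    return TrainingDataset(records=records)
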