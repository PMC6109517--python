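import numpy as np
import pandas as pd
import pytest

from cytometh.containers import BetaMatrix
from cytometh.simulate import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """A small seeded study with planted DMPs and two planted regions."""
    cfg = SimulationConfig(
        n_probes=600,
        n_genes=120,
        frac_dmp=0.05,
        dmr_spec=(("CYT0001", 6, -1), ("CYT0002", 5, 1)),
        rng_seed=11,
    )
    return cfg, simulate_study(cfg)


def make_beta_matrix(values, groups, detection_p=None, beadcount=None, dataset_id="ds1"):
    """Assemble a BetaMatrix from a raw array and a group label list."""
    values = np.asarray(values, dtype=float)
    probes = pd.Index([f"cg{i:04d}" for i in range(values.shape[0])], name="probe_id")
    samples = pd.Index([f"s{j}" for j in range(values.shape[1])], name="sample_id")
    sheet = pd.DataFrame(
        {"group": groups, "dataset_id": dataset_id, "age": 50.0, "sex": "F"},
        index=samples,
    )
    wrap = lambda m: None if m is None else pd.DataFrame(
        np.asarray(m), index=probes, columns=samples
    )
    return BetaMatrix(
        values=pd.DataFrame(values, index=probes, columns=samples),
        sample_sheet=sheet,
        detection_p=wrap(detection_p),
        beadcount=wrap(beadcount),
    )
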