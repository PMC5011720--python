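import numpy as np
import pandas as pd
import pytest

from lobetract import synth


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Small five-band phantom with exact per-band FA/MD ground truth."""
    spec = synth.PhantomSpec(grid_shape=(30, 16, 16), n_streamlines=20,
                             points_per_streamline=60, noise_sd=0.0, seed=11)
    tract, fa, md, labels = synth.gen_tract_phantom(spec)
    return spec, tract, fa, md, labels


@pytest.fixture(scope="session")
def ae_cohort():
    """Large AE-generated univariate twin cohort (a2 = 0.539)."""
    params = synth.AceGenParams(a1=np.sqrt(0.539), c1=0.0, e1=np.sqrt(0.461),
                                n_mz=2000, n_dz=2000, seed=101)
    return params, synth.gen_twin_cohort(params)


@pytest.fixture(scope="session")
def bivariate_cohort():
    """Bivariate cohort with known cross-trait latent correlations."""
    params = synth.AceGenParams(a1=np.sqrt(0.539), c1=0.0, e1=np.sqrt(0.461),
                                a2=np.sqrt(0.375), c2=0.0, e2=np.sqrt(0.625),
                                rg=0.9, re=-0.5, n_mz=2000, n_dz=2000,
                                seed=202)
    return params, synth.gen_twin_cohort(params)


@pytest.fixture
def qc_fixture_trials():
    """Ten-trial table with a hand-enumerated QC outcome.

    Expected retained set (1-based positions): {1, 5, 7, 10};
    removals: incorrect {3, 8}, RT window {2, 6}, post-error {4, 9}.
    """
    rows = [
        # block, trial, rt, correct
        (1, 1, 500.0, True),    # retained
        (1, 2, 150.0, True),    # RT too short
        (1, 3, 600.0, False),   # incorrect
        (1, 4, 520.0, True),    # post-error
        (1, 5, 1500.0, True),   # boundary RT, retained
        (1, 6, 1600.0, True),   # RT too long
        (2, 1, 200.0, True),    # boundary RT; block break clears post-error
        (2, 2, 100.0, False),   # incorrect (attributed before the RT rule)
        (2, 3, 700.0, True),    # post-error
        (2, 4, 800.0, True),    # retained
    ]
    cues = ["none", "center", "spatial", "none", "center",
            "spatial", "none", "center", "spatial", "none"]
    flankers = ["congruent", "incongruent"] * 5
    return pd.DataFrame({
        "subject": "S1",
        "block": [r[0] for r in rows],
        "trial": [r[1] for r in rows],
        "cue": cues,
        "flanker": flankers,
        "rt_ms": [r[2] for r in rows],
        "correct": [r[3] for r in rows],
    })
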