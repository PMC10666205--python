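import numpy as np
import pytest

import regenne as rg


@pytest.fixture(scope="session")
def small_bundle():
    """Small synthetic dataset: 8 pathways x 10 genes, n=200, 1 causal."""
    return rg.simulate_bundle(rg.preset_config("small", seed=7))


@pytest.fixture(scope="session")
def tiny_fitted():
    """A quickly trained two-pathway model on clearly separable data,
    reused by attribution and serialization tests."""
    rng = np.random.default_rng(3)
    n = 120
    coll = rg.PathwayCollection.from_mapping(
        {"PA": [f"A{i}" for i in range(8)], "PB": [f"B{i}" for i in range(8)]}
    )
    import pandas as pd

    latent = rng.standard_normal(n)
    X = pd.DataFrame(
        np.hstack(
            [
                latent[:, None] + 0.7 * rng.standard_normal((n, 8)),
                rng.standard_normal((n, 8)),
            ]
        ),
        columns=[f"A{i}" for i in range(8)] + [f"B{i}" for i in range(8)],
    )
    y = (latent + 0.4 * rng.standard_normal(n) > 0).astype(int)
    clf = rg.PathwayCNNClassifier(
        pathways=coll, epochs=40, lambda_cca=0.1, cca_dim=2, random_state=0
    )
    clf.fit(X, y)
    return clf, X, y
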