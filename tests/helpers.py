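"""Shared helpers for building tiny crafted inputs in tests."""

import numpy as np
import pandas as pd

import mcflfer as m


def make_obs(descriptors: pd.DataFrame, rows: list[dict]) -> m.ObservationSet:
    """Observation set from explicit row dictionaries (log_k required)."""
    return m.observations_from_frame(pd.DataFrame(rows), descriptors)


def random_single_design(rng: np.random.Generator, n: int):
    """A well-conditioned n x 6 single-LFER-shaped matrix and response."""
    X = np.column_stack([np.ones(n), rng.normal(size=(n, 5))])
    beta = rng.normal(size=6)
    y = X @ beta + rng.normal(scale=0.5, size=n)
    return X, y
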