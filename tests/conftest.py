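"""Shared fixtures: small synthetic matrices built at test time."""

import numpy as np
import pandas as pd
import pytest

from circaphase.preprocess import ExpressionMatrix


def make_sinusoid_matrix(
    n_genes=24,
    n_samples=24,
    span_h=24.0,
    noise_sd=0.0,
    seed=0,
    amplitude=1.0,
    shuffle=False,
):
    """Noisy cosine matrix with gene phases spread over the cycle.

    Returns (ExpressionMatrix, true_times_h).  Sample columns are in time
    order unless ``shuffle`` is set.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(n_samples) * span_h / n_samples
    gene_phase = np.arange(n_genes) * 24.0 / n_genes
    vals = amplitude * np.cos(
        2 * np.pi / 24.0 * (t[None, :] + gene_phase[:, None])
    )
    if noise_sd > 0:
        vals = vals + rng.normal(0, noise_sd, vals.shape)
    order = np.arange(n_samples)
    if shuffle:
        order = rng.permutation(n_samples)
    df = pd.DataFrame(
        vals[:, order],
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"s{j}" for j in order],
    )
    return ExpressionMatrix(df, t[order]), t[order]


@pytest.fixture
def sinusoid_matrix():
    return make_sinusoid_matrix()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
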