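import numpy as np
import pytest

import tvgnet as tv


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_dataset():
    """p=8 smooth trajectory with 40 replicates per grid point."""
    traj = tv.generate_graph_trajectory(p=8, n_grid=9, base_edges=6, n_changing=4, seed=1)
    ds = tv.sample_dataset(traj, [40] * 9, seed=2)
    X = tv.ExpressionMatrix(
        gene_ids=[f"g{i}" for i in range(8)],
        sample_ids=[f"s{j}" for j in range(ds.n_samples)],
        values=ds.values,
        times=ds.times,
    )
    return traj, ds, X


def random_spd(p, rng, cond=3.0):
    """Random symmetric positive-definite matrix with bounded conditioning."""
    q, _ = np.linalg.qr(rng.standard_normal((p, p)))
    vals = rng.uniform(1.0, cond, p)
    return (q * vals) @ q.T


@pytest.fixture
def random_cov_factory(rng):
    def make(p, m=1, n=None):
        """m kernel-covariance-like SPD matrices from n Gaussian samples."""
        n = n or 10 * p
        out = []
        for _ in range(m):
            a = rng.standard_normal((p, n))
            out.append(np.cov(a))
        return out

    return make
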