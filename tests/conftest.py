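import numpy as np
import pytest

from rifdecay import decay, synthetic


@pytest.fixture
def noiseless_experiment():
    """Tiny rifampicin-chase simulation with zero noise and no bad spots."""
    truth = [
        synthetic.SyntheticTruth("GENE0001", 2.0, 5000.0),
        synthetic.SyntheticTruth("GENE0002", 5.0, 3000.0),
        synthetic.SyntheticTruth("GENE0003", 10.0, 8000.0),
        synthetic.SyntheticTruth("GENE0004", 25.0, 2000.0),
    ]
    hybs = synthetic.gen_hybridizations(
        truth, noise_sd_log2=0.0, bad_spot_prob=0.0, seed=11)
    return truth, hybs


def make_ok_estimate(gene_id: str, half_life: float) -> decay.HalfLifeEstimate:
    """An accepted estimate with internally consistent slope and status."""
    return decay.HalfLifeEstimate(
        gene_id=gene_id, slope=-1.0 / half_life, intercept=0.0,
        r_squared=1.0, n_points=4, half_life=half_life,
        status=decay.STATUS_OK_4PT)


def closed_form_ols(t, y):
    """Independent OLS oracle from the textbook sums-of-squares formulas."""
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    sxx = np.sum((t - t.mean()) ** 2)
    sxy = np.sum((t - t.mean()) * (y - y.mean()))
    slope = sxy / sxx
    intercept = y.mean() - slope * t.mean()
    resid = y - (intercept + slope * t)
    sstot = np.sum((y - y.mean()) ** 2)
    r2 = None if sstot == 0 else 1.0 - np.sum(resid**2) / sstot
    return slope, intercept, r2
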