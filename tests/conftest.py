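import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    max_examples=50,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def friedman_oracle(arr):
    """Tie-corrected Friedman chi-square computed from first principles
    (explicit ranking loops; independent of scipy's implementation)."""
    arr = np.asarray(arr, dtype=float)
    n, k = arr.shape
    rank_sums = np.zeros(k)
    tie_sum = 0.0
    for row in arr:
        order = sorted(range(k), key=lambda j: row[j])
        j = 0
        while j < k:
            tied = [order[j]]
            while j + len(tied) < k and row[order[j + len(tied)]] == row[order[j]]:
                tied.append(order[j + len(tied)])
            avg = np.mean([j + m + 1 for m in range(len(tied))])
            for col in tied:
                rank_sums[col] += avg
            t = len(tied)
            tie_sum += t**3 - t
            j += t
    chi = (12.0 / (n * k * (k + 1))) * np.sum(rank_sums**2) - 3 * n * (k + 1)
    correction = 1.0 - tie_sum / (n * k * (k**2 - 1))
    if correction == 0:
        return 0.0
    return chi / correction
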