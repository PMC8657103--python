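import math

import numpy as np
import pytest

from lesionkinetics import VoxelPatch, fixture_paper_marginals


@pytest.fixture(scope="session")
def fixture_cohort():
    return fixture_paper_marginals()


@pytest.fixture
def random_patch_factory():
    def make(seed, shape=(6, 10, 10), spacing=(2.0, 0.7, 0.7)):
        rng = np.random.default_rng(seed)
        intensities = rng.normal(30, 80, size=shape)
        mask = rng.random(shape) < 0.6
        if not mask.any():
            mask[tuple(s // 2 for s in shape)] = True
        return VoxelPatch(intensities=intensities, mask=mask, spacing=spacing)

    return make


def naive_histogram_features(values, bin_width=25.0):
    """Independent brute-force recomputation from the sorted value list.

    Deliberately written with plain python loops over sorted values, not
    shared with the package implementation.
    """
    vals = sorted(float(x) for x in values)
    n = len(vals)
    mean = sum(vals) / n
    var = sum((x - mean) ** 2 for x in vals) / n

    def perc(q):
        h = (n - 1) * q / 100.0
        lo, hi = math.floor(h), math.ceil(h)
        return vals[lo] + (h - lo) * (vals[hi] - vals[lo])

    p10, p90 = perc(10), perc(90)
    robust = [x for x in vals if p10 <= x <= p90]
    rmean = sum(robust) / len(robust)
    lo_edge = vals[0]
    counts = {}
    for x in vals:
        counts[math.floor((x - lo_edge) / bin_width)] = (
            counts.get(math.floor((x - lo_edge) / bin_width), 0) + 1
        )
    probs = [c / n for c in counts.values()]
    if var > 0 and n >= 2:
        skew = (sum((x - mean) ** 3 for x in vals) / n) / var**1.5
        kurt = (sum((x - mean) ** 4 for x in vals) / n) / var**2
    else:
        skew = kurt = float("nan")
    return {
        "energy": sum(x * x for x in vals),
        "entropy": -sum(p * math.log2(p) for p in probs),
        "minimum": vals[0],
        "percentile_2_5": perc(2.5),
        "percentile_10": p10,
        "median": perc(50),
        "mean": mean,
        "percentile_90": p90,
        "percentile_97_5": perc(97.5),
        "maximum": vals[-1],
        "interquartile_range": perc(75) - perc(25),
        "range": vals[-1] - vals[0],
        "mean_absolute_deviation": sum(abs(x - mean) for x in vals) / n,
        "robust_mean_absolute_deviation": sum(abs(x - rmean) for x in robust) / len(robust),
        "root_mean_square": math.sqrt(sum(x * x for x in vals) / n),
        "standard_deviation": math.sqrt(var),
        "variance": var,
        "skewness": skew,
        "kurtosis": kurt,
        "uniformity": sum(p * p for p in probs),
    }
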