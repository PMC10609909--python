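import math

import pytest

from cambium import (
    FixtureConfig,
    ParameterSet,
    gen_growth_series,
    predict_supply,
    season_stats,
)

#: Noise-free canonical season: a clean sine arch over DOY 127-285 with a
#: small nonzero rate at the threshold-bounded season edges.
REFERENCE_SEASON_CONFIG = FixtureConfig(
    n_years=1,
    seed=7,
    ar_sigma=0.0,
    dips_range=(0, 0),
    peak_sd=0.0,
    bounds_jitter_sd=0.0,
    baseline_range=(0.0225, 0.0225),
    drought_depth_range=(0.0, 0.0),
)


@pytest.fixture(scope="session")
def params():
    return ParameterSet()


@pytest.fixture(scope="session")
def bell_season():
    return gen_growth_series(REFERENCE_SEASON_CONFIG)[1963]


@pytest.fixture(scope="session")
def bell_supply(bell_season):
    """Supply the default regression assigns to the reference season."""
    return predict_supply(season_stats(bell_season), 0.0).value


def brute_force_stats(xs):
    """Pure-Python summary statistics, independent of numpy/scipy paths."""
    n = len(xs)
    mean = sum(xs) / n
    sd = math.sqrt(sum((x - mean) ** 2 for x in xs) / (n - 1)) if n > 1 else 0.0

    def _median(vals):
        s = sorted(vals)
        mid = len(s) // 2
        return s[mid] if len(s) % 2 else 0.5 * (s[mid - 1] + s[mid])

    med = _median(xs)
    mad = _median([abs(x - med) for x in xs])
    m2 = sum((x - mean) ** 2 for x in xs) / n
    m3 = sum((x - mean) ** 3 for x in xs) / n
    skew = 0.0 if m2 == 0.0 else m3 / m2**1.5
    return {
        "sd": sd, "median": med, "mad": mad, "min": min(xs), "max": max(xs),
        "skew": skew,
    }
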