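import numpy as np
import pytest

from wqikit import SampleRecord, default_config, default_criteria, generate


@pytest.fixture(scope="session")
def criteria():
    return default_criteria()


@pytest.fixture
def at_limit_record(criteria):
    """Every included parameter exactly at its limit; pH mid-band."""
    values = {}
    for p in criteria:
        if not p.included:
            continue
        values[p.name] = 7.0 if p.limit_kind == "band" else p.limit
    return SampleRecord("at-limit", values)


@pytest.fixture(scope="session")
def small_synthetic():
    """200 samples at the default study conditions, fixed seed."""
    return generate(default_config(n=200, seed=11))


def naive_wqi(criteria, values, used):
    """Independent one-shot oracle: 100 * sum(w_i r_i) / sum(w_j).

    r_i is conc/limit for ordinary parameters and the banded pH ratio
    (0 in band, 6.5/pH below, pH/8.5 above).
    """
    num = 0.0
    den = 0.0
    for name in used:
        spec = criteria[name]
        den += spec.weight
        if spec.limit_kind == "band":
            ph = values[name]
            if ph < spec.band_low:
                r = spec.band_low / ph
            elif ph > spec.band_high:
                r = ph / spec.band_high
            else:
                r = 0.0
        else:
            r = values[name] / spec.limit
        num += spec.weight * r
    return 100.0 * num / den


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
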