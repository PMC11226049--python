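import numpy as np
import pandas as pd
import pytest

from landmarkpred import Cohort


def toy_cohort(times, events, baseline=None, measurements=None):
    """Build a small cohort from raw arrays.

    ``baseline`` maps covariate name -> per-subject values; ``measurements``
    is an optional list of (subject_id, time, dict-of-values) tuples for the
    longitudinal table.
    """
    n = len(times)
    surv = pd.DataFrame(
        {"subject_id": np.arange(1, n + 1), "time": times, "event": events}
    )
    for name, vals in (baseline or {}).items():
        surv[name] = vals
    if measurements:
        rows = [{"subject_id": sid, "time": t, **vals} for sid, t, vals in measurements]
        longi = pd.DataFrame(rows)
    else:
        longi = pd.DataFrame({"subject_id": [], "time": []})
    return Cohort(surv, longi)


@pytest.fixture
def rng():
    return np.random.default_rng(20240705)


def random_censored_sample(rng, n, rate=1.0, censor_rate=0.7, with_ties=False):
    t_event = rng.exponential(1.0 / rate, n)
    t_cens = rng.exponential(1.0 / censor_rate, n)
    times = np.minimum(t_event, t_cens)
    events = (t_event <= t_cens).astype(int)
    if with_ties:
        times = np.round(times, 1) + 0.05  # keep times positive, force ties
    return times, events
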