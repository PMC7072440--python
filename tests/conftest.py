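import numpy as np
import pandas as pd
import pytest

from ippscreen.preprocessing import Cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


def make_cohort(rng, n=60, n_genes=5, name="C1", censor=0.3):
    """Small random cohort with independent expression and survival."""
    genes = [f"G{i}" for i in range(n_genes)]
    samples = [f"{name}_S{i:03d}" for i in range(n)]
    expr = pd.DataFrame(rng.standard_normal((n_genes, n)), index=genes, columns=samples)
    t_event = rng.exponential(20.0, size=n)
    t_cens = rng.exponential(20.0 * (1 - censor) / max(censor, 1e-9), size=n) if censor else np.full(n, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return Cohort(
        name=name,
        expr=expr,
        time=pd.Series(time, index=samples),
        event=pd.Series(event, index=samples),
    )


@pytest.fixture
def cohort(rng):
    return make_cohort(rng)


def naive_logrank_z(time_low, event_low, time_high, event_high):
    """Independently coded O/E/V accumulation for the signed log-rank z.

    Plain dictionary loop over distinct event times; kept deliberately
    different in style from the package implementation.
    """
    pts = [(t, e, 0) for t, e in zip(time_low, event_low)]
    pts += [(t, e, 1) for t, e in zip(time_high, event_high)]
    event_times = sorted({t for t, e, _ in pts if e == 1})
    O = E = V = 0.0
    for tj in event_times:
        n_at_risk = sum(1 for t, _, _ in pts if t >= tj)
        n_high = sum(1 for t, _, g in pts if t >= tj and g == 1)
        d = sum(1 for t, e, _ in pts if t == tj and e == 1)
        d_high = sum(1 for t, e, g in pts if t == tj and e == 1 and g == 1)
        O += d_high
        E += d * n_high / n_at_risk
        if n_at_risk > 1:
            V += (
                d
                * (n_high / n_at_risk)
                * (1 - n_high / n_at_risk)
                * (n_at_risk - d)
                / (n_at_risk - 1)
            )
    if V <= 0:
        return None
    return (E - O) / V**0.5
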