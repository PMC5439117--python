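import numpy as np
import pandas as pd
import pytest

from gcnaclass.regions import default_region_map
from gcnaclass.simulate import GeneratorConfig, generate_cohort

OLIGO = "OLIGO_IDHmut_CODEL"
MUT = "ASTRO_IDHmut"
WT = "ASTRO_IDHwt"


@pytest.fixture(scope="session")
def region_map():
    return default_region_map()


@pytest.fixture(scope="session")
def small_clean_cohort():
    """Small noise-free, censoring-free cohort (fast exact-recovery substrate)."""
    cfg = GeneratorConfig(
        n_per_cluster={OLIGO: 20, MUT: 30, WT: 40},
        noise_sd=0.0,
        censoring_rate=0.0,
        seed=11,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def full_clean_cohort():
    """Noise-free cohort at the default cluster sizes (176/251/351), seed 7."""
    cfg = GeneratorConfig(noise_sd=0.0, censoring_rate=0.0, seed=7)
    return generate_cohort(cfg)


# ---------------------------------------------------------------------------
# independent oracles


def brute_force_km(times, events):
    """Product-limit by direct evaluation of Π(1 − d_i/n_i) at each event time."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    event_times = sorted(set(times[events == 1]))
    survival = []
    s = 1.0
    for et in event_times:
        n_i = sum(1 for t in times if t >= et)
        d_i = sum(1 for t, e in zip(times, events) if t == et and e == 1)
        s *= 1 - d_i / n_i
        survival.append(s)
    return np.array(event_times), np.array(survival)


def brute_force_cox_loglik(beta, times, events, x, ties="efron"):
    """Efron/Breslow partial log-likelihood by direct enumeration (small n)."""
    import math

    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    x = np.asarray(x, dtype=float)
    ll = 0.0
    for et in sorted(set(times[events == 1])):
        dead = [i for i in range(len(times)) if times[i] == et and events[i] == 1]
        risk = [i for i in range(len(times)) if times[i] >= et]
        m = len(dead)
        s_risk = sum(math.exp(beta * x[i]) for i in risk)
        s_dead = sum(math.exp(beta * x[i]) for i in dead)
        ll += sum(beta * x[i] for i in dead)
        for ell in range(m):
            f = ell / m if ties == "efron" else 0.0
            ll -= math.log(s_risk - f * s_dead)
    return ll


def grid_maximize_cox(times, events, x, ties="efron", lo=-6.0, hi=6.0):
    """Golden-section refinement of a coarse grid maximizer of the partial
    likelihood (1-covariate models only)."""
    grid = np.linspace(lo, hi, 2001)
    lls = [brute_force_cox_loglik(b, times, events, x, ties) for b in grid]
    k = int(np.argmax(lls))
    a, b = grid[max(k - 1, 0)], grid[min(k + 1, len(grid) - 1)]
    phi = (np.sqrt(5) - 1) / 2
    for _ in range(120):
        c = b - phi * (b - a)
        d = a + phi * (b - a)
        if brute_force_cox_loglik(c, times, events, x, ties) < brute_force_cox_loglik(
            d, times, events, x, ties
        ):
            a = c
        else:
            b = d
    return (a + b) / 2


def make_clinical_frame(times, events, **extra):
    n = len(times)
    df = pd.DataFrame(
        {
            "sample_id": [f"S{i}" for i in range(n)],
            "os_months": times,
            "event": events,
        }
    )
    for k, v in extra.items():
        df[k] = v
    return df
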