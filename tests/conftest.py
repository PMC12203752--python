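import numpy as np
import pandas as pd
import pytest

from metscreen.simulate import SimConfig, simulate_cohort
from metscreen.types import SurvivalRecord


def small_sim_config(seed: int = 0, **overrides) -> SimConfig:
    """A reduced cohort that keeps the full design structure but runs fast."""
    defaults = dict(
        n_genes=400,
        n_met_up=20,
        n_met_down=20,
        n_tissue_specific={"liver": 10, "adrenal": 5, "bone": 10},
        n_prognostic=3,
        n_survival_patients=80,
        seed=seed,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(small_sim_config(seed=11))


@pytest.fixture(scope="session")
def cox_fixture():
    """60 synthetic survival records with expression labels (packaged TSV)."""
    df = pd.read_csv("tests/data/cox_fixture.tsv", sep="\t", dtype=str)
    records = [
        SurvivalRecord(
            sample_id=r.sample_id,
            time=float(r.time),
            event=int(r.event),
            age=float(r.age),
            psa=float(r.psa),
            gleason=None if (pd.isna(r.gleason) or r.gleason == "") else int(float(r.gleason)),
            pt_stage=r.pt_stage,
        )
        for r in df.itertuples(index=False)
    ]
    labels = pd.Series(df.label.values, index=df.sample_id.values)
    return records, labels


def brute_force_bh(p: np.ndarray) -> np.ndarray:
    """Direct step-up: adj_(i) = min_{j>=i} m p_(j)/j, in pure python."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj_sorted = [0.0] * m
    running = float("inf")
    for pos in range(m - 1, -1, -1):
        running = min(running, m * p[order[pos]] / (pos + 1))
        adj_sorted[pos] = min(running, 1.0)
    out = np.empty(m)
    for pos, i in enumerate(order):
        out[i] = adj_sorted[pos]
    return out


def hypergeom_tail_p(a: int, b: int, c: int, d: int) -> float:
    """Exact one-tailed (greater) Fisher p via rational hypergeometric sums."""
    from fractions import Fraction
    from math import comb

    r1, c1, n = a + b, a + c, a + b + c + d
    k_max = min(r1, c1)
    total = Fraction(0)
    denom = comb(n, c1)
    for k in range(a, k_max + 1):
        total += Fraction(comb(r1, k) * comb(n - r1, c1 - k), denom)
    return float(total)
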