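"""Shared fixtures and independent oracle implementations.

The oracles here (brute-force reproducibility filter, closed-form Student
t-test, exhaustive hypergeometric tail, hand step-up BH) are deliberately
written from first principles, independent of the package's code paths,
so tests compare two routes to the same quantity.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from nsafq import SpectralCountMatrix

# ---------------------------------------------------------------------------
# independent oracles


def brute_force_filter(counts: pd.DataFrame, groups: dict[str, list[str]],
                       min_total: int = 5) -> pd.Series:
    """Reproducibility filter re-derived per protein with explicit loops."""
    out = {}
    for pid in counts.index:
        ok = False
        for samples in groups.values():
            vals = [int(counts.loc[pid, s]) for s in samples]
            if all(v > 0 for v in vals) and sum(vals) >= min_total:
                ok = True
        out[pid] = ok
    return pd.Series(out)


def student_t_p(a, b) -> tuple[float, float]:
    """Closed-form equal-variance two-sample t-test (two-sided p).

    Textbook formula: pooled variance with df = n_a + n_b - 2; the p-value
    uses the regularized incomplete beta function for the t tail, so no
    statistics-library test routine is involved.
    """
    a = [float(x) for x in a]
    b = [float(x) for x in b]
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    ssa = sum((x - ma) ** 2 for x in a)
    ssb = sum((x - mb) ** 2 for x in b)
    df = na + nb - 2
    sp2 = (ssa + ssb) / df
    se = math.sqrt(sp2 * (1 / na + 1 / nb))
    if se == 0:
        return (0.0, 1.0) if ma == mb else (math.inf * (1 if ma > mb else -1), 0.0)
    t = (ma - mb) / se
    # two-sided p via the t-distribution tail: P(|T|>|t|) = I_{df/(df+t^2)}(df/2, 1/2)
    from scipy.special import betainc

    x = df / (df + t * t)
    return t, float(betainc(df / 2.0, 0.5, x))


def hypergeom_tail(k: int, N: int, K: int, n: int) -> float:
    """P[X >= k] for X ~ Hypergeometric(N, K, n), by exhaustive enumeration."""
    denom = math.comb(N, n)
    upper = min(K, n)
    return sum(math.comb(K, i) * math.comb(N - K, n - i) for i in range(k, upper + 1)) / denom


def bh_stepup(pvals) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values by the textbook step-up recursion."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        adj[i] = running
    return adj


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture
def toy_counts() -> SpectralCountMatrix:
    """Three proteins, 3+3 replicates, chosen so SpC/L is equal across proteins
    in the first sample and the third protein is absent from condition b."""
    counts = pd.DataFrame(
        {
            "a1": [10, 20, 70],
            "a2": [12, 18, 65],
            "a3": [9, 22, 72],
            "b1": [11, 19, 0],
            "b2": [10, 21, 0],
            "b3": [13, 17, 1],
        },
        index=pd.Index(["P1", "P2", "P3"], name="protein_id"),
    )
    conditions = {s: ("A" if s.startswith("a") else "B") for s in counts.columns}
    length = pd.Series([100.0, 200.0, 700.0], index=counts.index)
    return SpectralCountMatrix(counts=counts, conditions=conditions, length_aa=length)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20150)
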