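"""Reproducibility filtering and per-protein differential expression.

A protein is reproducibly identified when, in at least one condition, it
has a non-zero raw count in every biological replicate and its total raw
count within that same condition reaches a minimum (default 5 spectra).
Filtered proteins are compared between conditions with an unpaired
two-sample t-test on natural-log NSAF (Student's equal-variance test by
default; Welch's available). Fold ratios are computed from the unlogged
condition mean NSAF values and reported as max(a/b, b/a) >= 1 together
with a direction label.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import SpectralCountMatrix
from .nsaf import NsafMatrix, mean_nsaf

__all__ = ["reproducibility_filter", "differential_test", "summarize_counts"]


def reproducibility_filter(
    counts: SpectralCountMatrix,
    min_total: int = 5,
    scope: str = "condition",
) -> pd.Series:
    """Boolean mask of reproducibly identified proteins.

    Parameters
    ----------
    counts
        Raw spectral-count matrix with two conditions.
    min_total
        Minimum total raw spectral count.
    scope
        ``"condition"`` (default): the total is evaluated within the
        condition that satisfies the all-replicates-present clause.
        ``"all"``: the total is evaluated across all samples instead;
        presence in every replicate of some condition is still required.
    """
    if scope not in ("condition", "all"):
        raise ValueError("scope must be 'condition' or 'all'")
    raw = counts.counts
    grand_total = raw.sum(axis=1)
    passed = pd.Series(False, index=raw.index)
    for cond in counts.condition_labels:
        sub = raw[counts.samples_of(cond)]
        present_all = (sub > 0).all(axis=1)
        total = grand_total if scope == "all" else sub.sum(axis=1)
        passed |= present_all & (total >= min_total)
    passed.name = "passed_filter"
    return passed


def differential_test(
    nsaf: NsafMatrix,
    filter_mask: pd.Series,
    alpha: float = 0.05,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-protein two-sample t-tests on log NSAF between the two conditions.

    Returns a DataFrame indexed by protein id with columns
    ``passed_filter``, ``mean_nsaf_a``, ``mean_nsaf_b``, ``ratio``,
    ``direction``, ``t_stat``, ``p_value`` and ``bh_fdr``. Condition "a"
    is the first condition label, "b" the second (recorded in
    ``.attrs["condition_a"]`` / ``.attrs["condition_b"]``). ``ratio`` is
    max(mean_a/mean_b, mean_b/mean_a) of the unlogged condition means;
    ``direction`` is ``up_in_a`` / ``up_in_b`` when p < alpha, else
    ``unchanged``. Statistics are NaN (and direction ``unchanged``) for
    proteins failing the filter; BH adjustment runs over the tested set
    only. Degenerate case: identical values in both groups give p = 1.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    filter_mask = filter_mask.reindex(nsaf.nsaf.index)
    if filter_mask.isna().any():
        raise ValueError("filter mask does not cover the NSAF protein set")
    cond_a, cond_b = nsaf.condition_labels
    if len(nsaf.samples_of(cond_a)) < 2 or len(nsaf.samples_of(cond_b)) < 2:
        raise ValueError("need >= 2 replicates per condition for a t-test")

    mean_a = mean_nsaf(nsaf, cond_a)
    mean_b = mean_nsaf(nsaf, cond_b)
    ratio = np.maximum(mean_a / mean_b, mean_b / mean_a)

    tested = filter_mask.to_numpy(dtype=bool)
    log_a = nsaf.log_nsaf.loc[tested, nsaf.samples_of(cond_a)].to_numpy()
    log_b = nsaf.log_nsaf.loc[tested, nsaf.samples_of(cond_b)].to_numpy()
    t_stat = np.full(len(filter_mask), np.nan)
    p_value = np.full(len(filter_mask), np.nan)
    if tested.any():
        with warnings.catch_warnings():
            # nearly-identical groups trigger a harmless precision warning
            warnings.simplefilter("ignore", RuntimeWarning)
            t, p = stats.ttest_ind(log_a, log_b, axis=1, equal_var=equal_var)
        # zero variance in both groups: identical means -> p=1, else the
        # mean difference is infinitely many pooled SDs away -> p=0
        degenerate = ~np.isfinite(np.atleast_1d(t))
        if degenerate.any():
            diff = log_a.mean(axis=1) - log_b.mean(axis=1)
            inf_signed = np.where(diff == 0, 0.0, np.inf) * np.where(diff < 0, -1.0, 1.0)
            t = np.where(degenerate, inf_signed, t)
            p = np.where(degenerate, np.where(diff == 0, 1.0, 0.0), p)
        t_stat[tested] = t
        p_value[tested] = p

    direction = np.full(len(filter_mask), "unchanged", dtype=object)
    sig = tested & (p_value < alpha)
    up_a = mean_a.to_numpy() > mean_b.to_numpy()
    direction[sig & up_a] = "up_in_a"
    direction[sig & ~up_a] = "up_in_b"

    bh = np.full(len(filter_mask), np.nan)
    if tested.any():
        bh[tested] = multipletests(p_value[tested], method="fdr_bh")[1]

    out = pd.DataFrame(
        {
            "passed_filter": filter_mask.to_numpy(dtype=bool),
            "mean_nsaf_a": mean_a,
            "mean_nsaf_b": mean_b,
            "ratio": ratio,
            "direction": direction,
            "t_stat": t_stat,
            "p_value": p_value,
            "bh_fdr": bh,
        },
        index=nsaf.nsaf.index,
    )
    out.attrs["condition_a"] = cond_a
    out.attrs["condition_b"] = cond_b
    out.attrs["alpha"] = alpha
    return out


def summarize_counts(results: pd.DataFrame) -> dict[str, float]:
    """Stage counts: identified, differential, up per side, percent unchanged.

    ``n_identified`` counts proteins passing the reproducibility filter;
    ``n_diff`` those with p below the test's alpha, split into
    ``n_up_a``/``n_up_b`` by direction; ``pct_unchanged`` is
    100 * (n_identified - n_diff) / n_identified.
    """
    if len(results) == 0:
        return {"n_identified": 0, "n_diff": 0, "n_up_a": 0, "n_up_b": 0,
                "pct_unchanged": 0.0}
    n_identified = int(results["passed_filter"].sum())
    n_up_a = int((results["direction"] == "up_in_a").sum())
    n_up_b = int((results["direction"] == "up_in_b").sum())
    n_diff = n_up_a + n_up_b
    pct = 100.0 * (n_identified - n_diff) / n_identified if n_identified else 0.0
    return {
        "n_identified": n_identified,
        "n_diff": n_diff,
        "n_up_a": n_up_a,
        "n_up_b": n_up_b,
        "pct_unchanged": pct,
    }
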