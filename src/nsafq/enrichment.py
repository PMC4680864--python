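"""Local term enrichment (Fisher exact / hypergeometric) and category abundance.

For a query list of n proteins drawn from a background of N, a term with
K annotated background members and k query hits gets the one-sided
hypergeometric upper-tail p-value

    p = P[X >= k],  X ~ Hypergeometric(N, K, n)

equivalent to a one-sided Fisher exact test for overrepresentation.
Raw p-values are Benjamini-Hochberg adjusted across all tested terms.
The background defaults to the reproducibly identified proteins, not the
whole genome. Category-level abundance sums mean NSAF over a term's
member proteins, giving the share of the per-condition composition that
the category occupies.
"""

from __future__ import annotations

import warnings

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import AnnotationSets
from .nsaf import NsafMatrix, mean_nsaf

__all__ = ["fisher_enrich", "category_abundance"]


def fisher_enrich(
    query: set[str],
    background: set[str],
    sets: AnnotationSets,
    drop_zero_overlap: bool = False,
) -> pd.DataFrame:
    """One-sided overrepresentation test of each annotation term in a query list.

    Returns a DataFrame (one row per term, sorted by p-value) with
    columns ``term_id``, ``term_name``, ``k_in_list``, ``n_list``,
    ``K_in_bg``, ``N_bg``, ``p_value`` and ``bh_fdr``. Annotation members
    outside the background are ignored. Terms with no background members
    are dropped; terms with zero query overlap get p = 1 (upper-tail
    convention) unless ``drop_zero_overlap`` removes them before the BH
    adjustment.
    """
    query = set(query)
    background = set(background)
    if not query <= background:
        extra = sorted(query - background)[:5]
        raise ValueError(f"query proteins missing from background: {extra}")
    N = len(background)
    n = len(query)
    rows = []
    for tid in sets.term_ids:
        members = sets.members[tid] & background
        K = len(members)
        if K == 0:
            continue
        k = len(members & query)
        if k == 0 and drop_zero_overlap:
            continue
        # upper tail P[X >= k] with X ~ Hypergeom(N, K, n); sf(k-1) includes k
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((tid, sets.names[tid], k, n, K, N, min(p, 1.0)))
    out = pd.DataFrame(
        rows,
        columns=["term_id", "term_name", "k_in_list", "n_list", "K_in_bg", "N_bg", "p_value"],
    )
    if len(out):
        out["bh_fdr"] = multipletests(out["p_value"].to_numpy(), method="fdr_bh")[1]
        out = out.sort_values("p_value", kind="stable").reset_index(drop=True)
    else:
        out["bh_fdr"] = pd.Series(dtype=float)
    return out


def category_abundance(
    nsaf: NsafMatrix,
    sets: AnnotationSets,
    condition: str,
) -> pd.Series:
    """Summed mean NSAF over each term's member proteins in one condition.

    Because NSAF is compositional, a term's sum is the fraction of the
    condition's total abundance its members occupy; disjoint terms that
    partition the proteome have sums adding to 1. Terms with no
    quantified member yield 0 with a warning.
    """
    means = mean_nsaf(nsaf, condition)
    out = {}
    for tid in sets.term_ids:
        members = [p for p in sets.members[tid] if p in means.index]
        if not members:
            warnings.warn(f"term {tid!r} has no quantified member proteins", stacklevel=2)
            out[tid] = 0.0
        else:
            out[tid] = float(means.loc[members].sum())
    return pd.Series(out, name=f"summed_nsaf_{condition}")
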