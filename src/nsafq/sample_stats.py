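"""Sample-level diagnostics: condition scatter, Spearman correlation, clustering.

These mirror the standard QC views of a two-condition label-free
experiment: a per-protein scatter of mean log NSAF in one condition
against the other (significant proteins flagged), a pairwise Spearman
correlation matrix over samples, and average-linkage hierarchical
clustering of the samples on the distance 1 - rho. All statistics are
computed on the reproducibly identified (filtered) protein set; Spearman
is rank-based, so it is invariant to any strictly monotone per-sample
transform of NSAF (using NSAF or log NSAF makes no difference).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .nsaf import NsafMatrix

__all__ = ["SampleCorrelation", "scatter_table", "spearman_matrix"]


@dataclass
class SampleCorrelation:
    """Pairwise Spearman correlations between samples and their clustering.

    ``rho`` is symmetric with unit diagonal; ``linkage`` is a SciPy
    linkage matrix over the samples (heights non-decreasing for
    average linkage on the metric 1 - rho).
    """

    rho: pd.DataFrame
    linkage: np.ndarray
    method: str = "average"

    @property
    def sample_names(self) -> list[str]:
        return self.rho.index.tolist()

    def top_clusters(self, k: int = 2) -> dict[str, int]:
        """Cut the sample tree into ``k`` flat clusters (sample -> cluster id)."""
        labels = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return dict(zip(self.sample_names, (int(c) for c in labels)))


def scatter_table(nsaf: NsafMatrix, diff: pd.DataFrame) -> pd.DataFrame:
    """Per-protein mean log NSAF in each condition, with a significance flag.

    One row per protein passing the reproducibility filter: columns
    ``mean_log_nsaf_a`` and ``mean_log_nsaf_b`` (condition order as in
    the differential results) and ``significant`` mirroring p < alpha.
    The protein sets of the NSAF matrix and the differential results must
    match.
    """
    if not nsaf.nsaf.index.equals(diff.index):
        raise ValueError("protein sets of NSAF matrix and differential results differ")
    cond_a = diff.attrs.get("condition_a", nsaf.condition_labels[0])
    cond_b = diff.attrs.get("condition_b", nsaf.condition_labels[1])
    passed = diff["passed_filter"].to_numpy(dtype=bool)
    sub = nsaf.log_nsaf.loc[passed]
    out = pd.DataFrame(
        {
            "mean_log_nsaf_a": sub[nsaf.samples_of(cond_a)].mean(axis=1),
            "mean_log_nsaf_b": sub[nsaf.samples_of(cond_b)].mean(axis=1),
            "significant": (diff.loc[passed, "direction"] != "unchanged"),
        }
    )
    out.attrs["condition_a"] = cond_a
    out.attrs["condition_b"] = cond_b
    return out


def spearman_matrix(
    nsaf: NsafMatrix,
    filter_mask: pd.Series | None = None,
    method: str = "average",
) -> SampleCorrelation:
    """Pairwise Spearman rho between samples plus hierarchical clustering.

    Correlations are computed over the filtered protein set when a mask
    is given, otherwise over all proteins. Clustering is on the distance
    1 - rho with the given linkage method. A sample whose NSAF vector is
    constant has no rank variation and is rejected by name.
    """
    data = nsaf.nsaf if filter_mask is None else nsaf.nsaf.loc[
        filter_mask.reindex(nsaf.nsaf.index).fillna(False).to_numpy(dtype=bool)
    ]
    if data.shape[1] < 2:
        raise ValueError("need at least two samples")
    if data.shape[0] < 2:
        raise ValueError("need at least two proteins to rank")
    for name in data.columns:
        if data[name].nunique() == 1:
            raise ValueError(f"sample {name!r} has a constant NSAF vector; rho undefined")
    rho_arr, _ = stats.spearmanr(data.to_numpy(), axis=0)
    rho_arr = np.atleast_2d(rho_arr)
    rho = pd.DataFrame(rho_arr, index=data.columns, columns=data.columns)
    dist = 1.0 - rho.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)  # enforce exact symmetry
    linkage = hierarchy.linkage(squareform(dist, checks=False), method=method)
    return SampleCorrelation(rho=rho, linkage=linkage, method=method)
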