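"""Proteome-transcriptome concordance classification.

Genes quantified in both layers are classified by the signs of their
protein and mRNA log2 fold changes (first condition over second, "2i
over serum" in the study design), provided both magnitudes reach a fold
threshold (default 2-fold, i.e. |log2 FC| >= 1):

    group i   (both_down):        protein down, mRNA down  (both up in serum)
    group ii  (protein_up_mrna_down): protein up, mRNA down
    group iii (both_up):          protein up, mRNA up      (both up in 2i)
    group iv  (mrna_up_protein_down): protein down, mRNA up

Everything else — below threshold in either layer, or not significant
when the significance gate is on — is ``none``; genes absent from either
table are reported separately as unjoined rather than silently dropped.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["GROUP_LABELS", "classify_concordance", "concordance_summary", "protein_log2fc"]

#: Quadrant labels keyed by (sign of protein log2 FC, sign of mRNA log2 FC).
GROUP_LABELS = {
    (-1, -1): "i",
    (+1, -1): "ii",
    (+1, +1): "iii",
    (-1, +1): "iv",
}

GROUP_DESCRIPTIONS = {
    "i": "both protein and mRNA up in second condition",
    "ii": "protein up in first condition, mRNA up in second",
    "iii": "both protein and mRNA up in first condition",
    "iv": "mRNA up in first condition, protein up in second",
}


def protein_log2fc(diff: pd.DataFrame) -> pd.Series:
    """Signed protein log2 fold change (condition a over b) from differential results.

    Reconstructed losslessly from the stored ratio (>= 1) and direction
    of the unlogged condition means: positive when mean_a > mean_b.
    """
    sign = np.where(diff["mean_nsaf_a"].to_numpy() >= diff["mean_nsaf_b"].to_numpy(), 1.0, -1.0)
    return pd.Series(sign * np.log2(diff["ratio"].to_numpy()), index=diff.index,
                     name="protein_log2fc")


def classify_concordance(
    diff: pd.DataFrame,
    mrna: pd.DataFrame,
    threshold_fold: float = 2.0,
    significant_only: bool = True,
) -> pd.DataFrame:
    """Assign each joinable gene to a concordance quadrant.

    Parameters
    ----------
    diff
        Differential-expression results (index = protein/gene id).
    mrna
        Transcriptome table indexed by gene id with column ``mrna_log2fc``
        on the same condition orientation as the protein fold changes.
    threshold_fold
        Minimum fold change (> 1) required in *both* layers.
    significant_only
        When true (default) only proteins called differential (direction
        not ``unchanged``) can enter a quadrant; others become ``none``.

    Returns
    -------
    DataFrame indexed by gene id with columns ``protein_log2fc``,
    ``mrna_log2fc``, ``group`` (``i``/``ii``/``iii``/``iv``/``none``) and
    ``joined`` (false for genes found in only one table, whose group is
    ``none`` and missing fold change NaN).
    """
    if threshold_fold <= 1:
        raise ValueError("threshold_fold must exceed 1")
    thr = np.log2(threshold_fold)
    prot_fc = protein_log2fc(diff)
    all_ids = diff.index.union(mrna.index)
    out = pd.DataFrame(index=all_ids)
    out.index.name = "gene_id"
    out["protein_log2fc"] = prot_fc.reindex(all_ids)
    out["mrna_log2fc"] = mrna["mrna_log2fc"].reindex(all_ids)
    out["joined"] = out["protein_log2fc"].notna() & out["mrna_log2fc"].notna()

    group = pd.Series("none", index=all_ids, dtype=object)
    eligible = out["joined"].copy()
    if significant_only:
        sig = (diff["direction"] != "unchanged").reindex(all_ids, fill_value=False)
        eligible &= sig.astype(bool)
    p = out["protein_log2fc"].to_numpy()
    m = out["mrna_log2fc"].to_numpy()
    with np.errstate(invalid="ignore"):
        passes = eligible.to_numpy() & (np.abs(p) >= thr) & (np.abs(m) >= thr)
    for (ps, ms), label in GROUP_LABELS.items():
        mask = passes & (np.sign(p) == ps) & (np.sign(m) == ms)
        group[mask] = label
    out["group"] = group
    return out


def concordance_summary(records: pd.DataFrame) -> tuple[dict[str, int], dict[str, list[str]]]:
    """Per-quadrant counts and sorted member lists.

    Quadrants partition the classified genes: every gene with group not
    ``none`` appears in exactly one list, and the counts sum to the
    number of classified genes.
    """
    counts: dict[str, int] = {}
    members: dict[str, list[str]] = {}
    for label in ("i", "ii", "iii", "iv"):
        ids = records.index[records["group"] == label].tolist()
        counts[label] = len(ids)
        members[label] = sorted(ids)
    return counts, members
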