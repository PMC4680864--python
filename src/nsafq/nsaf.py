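"""Normalized spectral abundance factors (NSAF).

For protein k in sample i with spectral count ``SpC_ik`` and length
``L_k`` (residues),

    NSAF_ik = (SpC_ik / L_k) / sum_j (SpC_ij / L_j)

so each sample's NSAF values form a composition summing to 1. A constant
spectral fraction (default 0.5) is added to every raw count *before* the
length division and normalization, so zero-count proteins have finite log
abundance; per-sample sums remain exactly 1. When no explicit sequence
length is known, length is estimated as molecular weight divided by the
average residue mass (default 111.1254 Da).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import SpectralCountMatrix

__all__ = ["NsafMatrix", "estimate_length", "compute_nsaf", "mean_nsaf", "DEFAULT_AVG_AA_MW_DA"]

#: Mean residue mass (Da) used to estimate protein length from molecular weight.
DEFAULT_AVG_AA_MW_DA = 111.1254


@dataclass
class NsafMatrix:
    """Per-sample NSAF abundances and their natural-log transform.

    ``nsaf`` and ``log_nsaf`` are protein x sample DataFrames sharing the
    index and columns of the source count matrix; ``lengths`` holds the
    per-protein length (residues) actually used, whether explicit or
    estimated from molecular weight.
    """

    nsaf: pd.DataFrame
    log_nsaf: pd.DataFrame
    lengths: pd.Series
    conditions: dict[str, str]
    pseudo_fraction: float
    avg_aa_mw_da: float

    @property
    def protein_ids(self) -> list[str]:
        return self.nsaf.index.tolist()

    @property
    def sample_names(self) -> list[str]:
        return self.nsaf.columns.tolist()

    @property
    def condition_labels(self) -> tuple[str, str]:
        seen: list[str] = []
        for s in self.nsaf.columns:
            lab = self.conditions[s]
            if lab not in seen:
                seen.append(lab)
        return seen[0], seen[1]

    def samples_of(self, condition: str) -> list[str]:
        out = [s for s in self.nsaf.columns if self.conditions[s] == condition]
        if not out:
            raise KeyError(f"unknown condition {condition!r}")
        return out


def estimate_length(mw_da: float | np.ndarray, avg_aa_mw_da: float = DEFAULT_AVG_AA_MW_DA) -> float | np.ndarray:
    """Estimate protein length in residues as ``mw_da / avg_aa_mw_da``.

    The result is a real number, deliberately not rounded: NSAF only uses
    length as a relative weight. An explicit sequence length, where
    available, should be preferred over this estimate.
    """
    if avg_aa_mw_da <= 0:
        raise ValueError("avg_aa_mw_da must be positive")
    arr = np.asarray(mw_da, dtype=float)
    if np.any(arr <= 0) or not np.all(np.isfinite(arr)):
        raise ValueError("molecular weight must be positive and finite")
    out = arr / avg_aa_mw_da
    return float(out) if np.isscalar(mw_da) or arr.ndim == 0 else out


def _resolve_lengths(counts: SpectralCountMatrix, avg_aa_mw_da: float) -> pd.Series:
    idx = counts.counts.index
    lengths = pd.Series(np.nan, index=idx, dtype=float)
    if counts.length_aa is not None:
        lengths = counts.length_aa.astype(float).copy()
    if counts.mw_da is not None:
        need = lengths.isna() & counts.mw_da.notna()
        if need.any():
            lengths[need] = estimate_length(counts.mw_da[need].to_numpy(), avg_aa_mw_da)
    if lengths.isna().any():
        missing = idx[lengths.isna()].tolist()
        raise ValueError(f"cannot resolve a length for protein(s): {missing[:5]}")
    return lengths


def compute_nsaf(
    counts: SpectralCountMatrix,
    pseudo_fraction: float = 0.5,
    avg_aa_mw_da: float = DEFAULT_AVG_AA_MW_DA,
) -> NsafMatrix:
    """Convert a spectral-count matrix to per-sample NSAF abundances.

    ``pseudo_fraction`` is added to every raw count before the length
    division and the per-sample normalization. With a positive
    pseudo-fraction all NSAF values are strictly positive and the log
    transform is always finite; with ``pseudo_fraction=0`` a sample whose
    counts are all zero cannot be normalized and raises.
    """
    if pseudo_fraction < 0:
        raise ValueError("pseudo_fraction must be >= 0")
    lengths = _resolve_lengths(counts, avg_aa_mw_da)
    adjusted = counts.counts.to_numpy(dtype=float) + pseudo_fraction
    saf = adjusted / lengths.to_numpy()[:, None]  # SpC/L, the spectral abundance factor
    totals = saf.sum(axis=0)
    if np.any(totals <= 0):
        bad = counts.counts.columns[np.argmin(totals)]
        raise ValueError(
            f"sample {bad!r} has zero total SpC/L; use a positive pseudo_fraction"
        )
    nsaf = pd.DataFrame(
        saf / totals, index=counts.counts.index, columns=counts.counts.columns
    )
    return NsafMatrix(
        nsaf=nsaf,
        log_nsaf=np.log(nsaf),
        lengths=lengths,
        conditions=dict(counts.conditions),
        pseudo_fraction=pseudo_fraction,
        avg_aa_mw_da=avg_aa_mw_da,
    )


def mean_nsaf(nsaf: NsafMatrix, condition: str) -> pd.Series:
    """Arithmetic mean NSAF (not log NSAF) across a condition's replicates.

    This is the per-condition protein abundance summary used for fold
    ratios and category abundance sums; by linearity it sums to 1 over
    proteins within each condition.
    """
    samples = nsaf.samples_of(condition)
    return nsaf.nsaf[samples].mean(axis=1)
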