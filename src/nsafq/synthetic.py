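"""Synthetic spectral-count data with known ground truth.

The generator emulates a two-condition label-free shotgun proteomics
experiment (three biological replicates per condition by default): each
sample's count vector is a single multinomial draw over proteins,
conditioned on the sample's total spectral depth. Spectrum-generation
probabilities are proportional to (molar abundance x sequence length),
because longer proteins yield more tryptic peptides and hence more
spectra — the premise that justifies the length division in NSAF.

A planted fraction of proteins carries a true fold change between the two
conditions (sign-balanced), recorded in the returned truth table so that
downstream recovery, power and error-rate properties can be measured.
"""

from __future__ import annotations

from dataclasses import dataclass
import math

import numpy as np
import pandas as pd

from .io import SpectralCountMatrix

__all__ = ["SimConfig", "simulate_counts", "CONDITION_A", "CONDITION_B"]

#: Condition labels used by the simulator; "2i" is the serum-free
#: dual-inhibitor ESC culture, "serum" the conventional serum/LIF culture.
CONDITION_A = "2i"
CONDITION_B = "serum"


@dataclass
class SimConfig:
    """Parameters of the synthetic experiment.

    Attributes
    ----------
    n_proteins
        Number of proteins in the simulated proteome.
    n_replicates
        Biological replicates per condition (3 matches the study design).
    depth
        Expected total spectra per sample; each sample's counts are one
        multinomial draw with exactly this total.
    frac_diff
        Fraction of proteins with a planted differential abundance.
    fold_levels
        Candidate true fold ratios (> 1) for planted proteins; signs are
        balanced so half are up in the first condition, half in the second.
    abundance_logsd
        Standard deviation of the base natural-log abundance across
        proteins (wide, right-skewed dynamic range).
    replicate_logsd
        Per-replicate lognormal abundance jitter (natural-log sd) on top
        of multinomial sampling; models biological overdispersion.
    mw_log_mean_da, mw_log_sd_da
        Lognormal parameters of molecular weight in Daltons; the default
        mean gives a median of ~50 kDa.
    seed
        RNG seed; all output is deterministic given the seed.
    """

    n_proteins: int = 1800
    n_replicates: int = 3
    depth: int = 30000
    frac_diff: float = 0.1
    fold_levels: tuple[float, ...] = (2.0, 4.0, 8.0)
    abundance_logsd: float = 1.5
    replicate_logsd: float = 0.1
    mw_log_mean_da: float = math.log(50_000.0)
    mw_log_sd_da: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be a positive integer")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be a positive integer")
        if self.depth < 1:
            raise ValueError("depth must be a positive integer")
        if not 0.0 <= self.frac_diff <= 1.0:
            raise ValueError("frac_diff must lie in [0, 1]")
        if any(f <= 1.0 for f in self.fold_levels):
            raise ValueError("all fold_levels must exceed 1")
        if self.abundance_logsd < 0 or self.replicate_logsd < 0:
            raise ValueError("log-scale standard deviations must be non-negative")


# average residue mass used to convert molecular weight to length
_AVG_AA_MW_DA = 111.1254


def simulate_counts(config: SimConfig) -> tuple[SpectralCountMatrix, pd.DataFrame]:
    """Simulate a two-condition spectral-count matrix plus ground truth.

    Returns
    -------
    counts
        Validated :class:`~nsafq.io.SpectralCountMatrix` with
        ``n_replicates`` samples per condition and molecular weights.
    truth
        DataFrame indexed by protein id with columns
        ``true_fold_2i_over_serum`` (positive ratio of molar abundance,
        first condition over second), ``is_diff`` (planted change?), and
        ``expected_count_2i`` / ``expected_count_serum`` (expected
        spectra per replicate under the generative model, jitter aside).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_proteins
    protein_ids = [f"P{i:05d}" for i in range(1, n + 1)]

    # base molar abundance and molecular weight, both lognormal
    base_abundance = np.exp(rng.normal(0.0, config.abundance_logsd, size=n))
    mw_da = np.exp(rng.normal(config.mw_log_mean_da, config.mw_log_sd_da, size=n))
    length_aa = mw_da / _AVG_AA_MW_DA

    # plant sign-balanced fold changes on a random subset
    n_diff = int(round(config.frac_diff * n))
    diff_idx = rng.choice(n, size=n_diff, replace=False)
    fold = np.ones(n)
    if n_diff:
        magnitudes = rng.choice(np.asarray(config.fold_levels, dtype=float), size=n_diff)
        signs = np.ones(n_diff)
        signs[rng.permutation(n_diff)[: n_diff // 2]] = -1.0
        fold[diff_idx] = np.where(signs > 0, magnitudes, 1.0 / magnitudes)
    is_diff = fold != 1.0

    # condition-level abundances; each planted fold is split symmetrically
    # (A x sqrt(f), B x 1/sqrt(f)) so the true A/B ratio is f while the two
    # conditions keep equal expected total spectrum-generation propensity —
    # otherwise sum-normalization would turn the planted mass change into a
    # spurious abundance shift of every unplanted (null) protein
    half_fold = np.sqrt(fold)
    abundance = {
        CONDITION_A: base_abundance * half_fold,
        CONDITION_B: base_abundance / half_fold,
    }

    counts: dict[str, np.ndarray] = {}
    conditions: dict[str, str] = {}
    expected: dict[str, np.ndarray] = {}
    for cond in (CONDITION_A, CONDITION_B):
        weight = abundance[cond] * length_aa  # spectrum-generation propensity
        p = weight / weight.sum()
        expected[cond] = config.depth * p
        for r in range(1, config.n_replicates + 1):
            name = f"{cond}_{r}"
            conditions[name] = cond
            if config.replicate_logsd > 0:
                jitter = np.exp(rng.normal(0.0, config.replicate_logsd, size=n))
                w = weight * jitter
                p_rep = w / w.sum()
            else:
                p_rep = p
            counts[name] = rng.multinomial(config.depth, p_rep)

    count_df = pd.DataFrame(counts, index=pd.Index(protein_ids, name="protein_id"))
    matrix = SpectralCountMatrix(
        counts=count_df,
        conditions=conditions,
        mw_da=pd.Series(mw_da, index=count_df.index, name="mw_da"),
    )
    truth = pd.DataFrame(
        {
            "true_fold_2i_over_serum": fold,
            "is_diff": is_diff,
            "expected_count_2i": expected[CONDITION_A],
            "expected_count_serum": expected[CONDITION_B],
        },
        index=count_df.index,
    )
    return matrix, truth
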