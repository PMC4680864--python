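# Methods

## Quantification model

NSAF treats each LC-MS/MS run as a closed budget of identification
events: a sample yields a total number of confidently matched MS/MS
spectra, and each spectrum is attributed to one protein with probability
roughly proportional to (molar abundance × length), because digestion of
a longer protein exposes more peptides. Dividing counts by length and
renormalizing per sample therefore estimates relative molar abundance:

```
NSAF_ik = ((SpC_ik + f) / L_k) / Σ_j ((SpC_ij + f) / L_j)
```

The pseudo-count `f` (the "spectral fraction", default 0.5) is added to
the raw counts *before* length division and normalization, so per-sample
NSAF sums are exactly 1 and every log NSAF is finite. The alternative —
adding the fraction after the SpC/L step — is available by passing
already-adjusted counts, but the before-division placement is the package
default because it keeps the compositional constraint exact. With `f = 0`
the transform is scale-free per sample (multiplying a sample's counts by
a constant changes nothing), the property that makes spectral counts
comparable across runs of different depth.

Protein length is taken from an explicit `length_aa` column when present;
otherwise it is estimated as `mw_da / 111.1254`, using the average
residue mass of proteins in Daltons. The constant is exposed
(`avg_aa_mw_da`) but uniform across proteins by construction: mixing
per-protein constants would silently re-weight the composition.

Condition-level abundance is the arithmetic mean of NSAF (not log NSAF)
over a condition's replicates; fold ratios are ratios of these means,
reported as `max(a/b, b/a) ≥ 1` plus a direction label, from which the
signed log2 fold change is reconstructed losslessly.

## Statistical testing

A protein enters testing only if it passes the reproducibility filter:
detected in every replicate of at least one condition, with a total of at
least `min_total = 5` raw spectra within that same condition. The
membership clause and the total are evaluated within the same condition
by default; a documented alternative (`scope="all"`, total across all
samples) is provided because the inclusion rule can be read either way.

Per protein, an unpaired two-sample t-test compares natural-log NSAF
between conditions. Student's equal-variance form (df = n_a + n_b − 2) is
the default — the usual choice for 3 v 3 spectral-count designs, where
per-group variance estimates are too unstable for Welch's correction to
help — with Welch available via `equal_var=False`. The log transform is
what makes the t-test reasonable here: NSAF is right-skewed and
multiplicative. Degenerate inputs are resolved by convention: identical
values in both groups give p = 1; zero variance with unequal means gives
p = 0. Significance is called at raw p < α (default 0.05), matching the
headline criterion of the NSAF literature this pipeline follows;
Benjamini–Hochberg adjusted values are always computed over the tested
set and reported alongside, and are the right column to use when FDR
control matters. The BH list at q = 0.05 empirically controls FDR near
0.1 in the default simulation (see below), slightly above nominal because
compositional coupling makes nulls weakly dependent on planted effects.

Enrichment uses the one-sided hypergeometric upper tail
(P[X ≥ k]) per term — equivalent to a one-sided Fisher exact test —
against the background of reproducibly identified proteins, not the whole
genome: identification in shotgun proteomics is itself abundance-biased,
and a whole-genome background would count that bias as biology. Terms
with zero query overlap score p = 1 under the upper-tail convention.
No EASE-style score deflation is applied; the plain hypergeometric is
transparent and exactly testable.

Concordance classification takes the signed protein log2 fold change and
an external mRNA log2 fold change on the same condition orientation,
requires ≥ `threshold_fold` (default 2) in both layers, and assigns one
of four sign quadrants. By default only proteins already called
differential can classify (`significant_only=True`), since quadrant
membership without a supporting test is fragile at the threshold;
the gate can be disabled. Genes present in only one table are kept in the
output with `joined = False` rather than dropped, so joins are auditable.

## Synthetic data

The generator emulates the study design the pipeline assumes: two
conditions × 3 biological replicates, ~1,800 proteins, 30,000 spectra per
sample. Per sample, counts are one multinomial draw conditioned on depth —
not independent Poissons — because spectral counting is compositional;
this is the same assumption that justifies NSAF's per-sample sum
normalization. Spectrum-generation probability is proportional to
abundance × length, so NSAF's length division is exactly the right
inverse; molecular weights are lognormal with median 50 kDa and log-sd
0.4 (5th–95th percentile ≈ 26–96 kDa, typical of a detected proteome),
and base abundances lognormal with log-sd 1.5, giving the several-orders-
of-magnitude dynamic range and the zero-inflated low-count tail seen in
real spectral-count tables.

A fraction `frac_diff = 0.1` of proteins carries a planted fold change
drawn from {2, 4, 8}, half up in each condition. Each fold f is split
symmetrically — condition A × √f, condition B × 1/√f, so the true A/B
ratio is f — rather than applied to one side only. The split is a
deliberate design constraint: a one-sided plant changes one condition's
total spectral mass, and under sum normalization that converts the
planted changes into a genuine NSAF shift of *every* unplanted protein,
making the truth table's "null" label false on the measurement scale.
With the symmetric split the two conditions have equal expected total
spectrum-generation propensity and nulls are genuinely null.

Biological replicate variation beyond multinomial sampling is modelled as
per-replicate lognormal jitter on abundance (log-sd 0.1 by default,
exposed as `replicate_logsd`). Real replicate overdispersion is not well
characterised for this design, so the value is a modelling choice: it is
large enough that the t-test's variance estimate is not dominated by
counting noise alone, small enough that 3 replicates retain power for
4-fold changes.

What the generator does **not** model: identification dropout beyond
multinomial zeros (no separate missingness mechanism), peptide-level
structure, shared peptides, retention-time or m/z effects, and
protein-protein abundance correlation. Passing tests on synthetic data
therefore demonstrate the pipeline's statistical correctness under its
own stated model, not robustness to those real-data pathologies.

## Measured behaviour (recomputed by the test suite and acceptance script)

* NSAF sums per sample deviate from 1 by < 1e-9 on random matrices.
* The filter agrees exactly with a brute-force re-check on 10,000 random
  3 v 3 matrices; t-test p-values agree with an independently coded
  closed-form Student t to 1e-10; Fisher p-values agree with exhaustive
  hypergeometric enumeration (all backgrounds N ≤ 12) to 1e-9.
* Type-I error at α = 0.05 on null simulations (frac_diff = 0, 2,000
  proteins, 20 seeds) is 0.05 ± 0.02.
* Planted 4-fold changes with expected per-replicate count ≥ 20 are
  detected with power ≥ 0.8 at α = 0.05; the BH q < 0.05 list has
  empirical FDR ≤ 0.1 (20 seeds, default configuration).
* Replicates correlate more strongly within than between conditions, and
  the top two clusters of the sample tree recover the two conditions in
  ≥ 95% of seeds.

Problem sizes (1,800–2,000 proteins, 20 simulation seeds per stochastic
measurement) were chosen to make these rates stable to the stated
tolerances while keeping the whole suite fast on one CPU.

## Known limitations

* Raw p < 0.05 as the headline criterion does not control FDR; the BH
  column should be preferred for discovery lists.
* NSAF fold ratios are compositional: a large genuine change in a few
  abundant proteins necessarily shifts all other proteins' NSAF. The
  pipeline follows the standard NSAF convention and does not attempt a
  compositional (e.g. centred log-ratio) correction.
* The t-test treats log NSAF as continuous; for proteins near the filter
  boundary (~5 spectra) count discreteness makes p-values approximate.
* Enrichment assumes the annotation's identifier namespace matches the
  count table's; no identifier mapping is performed.
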