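# Methods

## Quantification model

The pipeline's abundance statistic is the spectral count weight (SCW):
protein *i*'s spectral count in run *r* divided by run *r*'s total spectral
count, computed over the probability-filtered identification list.  Using
the filtered list for the denominator keeps the normalizer consistent with
the protein set actually analyzed.  SCW is compositional: it estimates the
protein's *share* of the sampled proteome, not an absolute amount, and the
columns of the SCW matrix are points on the simplex (each sums to 1, checked
at 1e-12).  Zero imputation — SCW = 0 wherever a protein was not identified
— makes the union protein set comparable across all runs; it conflates
"absent" with "below detection", which is the standard reading for
spectral counting and is the reason for the presence criterion below.

Identification filtering is per (run, protein) record at probability > 0.9,
strict.  A protein can therefore survive in some runs and not others, which
matches per-analysis output of ProteinProphet-style pipelines.  Whether the
upstream search was assembled per analysis or jointly is generally not
knowable from the tables; the per-run record model assumes per-analysis
probabilities.

Peptide support is aggregated across the union of runs: the number of
distinct peptide sequences over all runs in which the protein appears when
sequences are listed, otherwise the maximum per-run distinct-peptide count
(a lower bound on the union).  This is the most permissive reading of
"identified by a single peptide" and is applied dataset-wide.

## Testing and selection

Group comparison uses the two-sided *pooled-variance* Student's t-test
(df = n₁ + n₂ − 2; 8 for the default 5v5 design), implemented explicitly
with the p-value from the t distribution.  "Student's t-test" admits a
Welch reading; pooled variance is that test's classical form and is the
documented choice here.  Degenerate inputs are resolved by continuity: when
both groups have zero variance, p = 1 for equal means and p = 0 otherwise
(the limit of the statistic as the pooled variance shrinks).  No
multiple-testing correction is applied; the report instead states the
expected false-positive count (n_tested × p_cutoff) so the raw cut-off can
be judged.

Fold change is the larger group-mean SCW over the smaller (≥ 1 by
convention, direction carried separately).  When exactly one mean is zero
the fold is +infinity and passes any threshold — the presence criterion is
what actually gates all-absent-vs-present contrasts.  When both means are
zero the protein has fold 1 and no direction.  Fold change is computed from
mean SCW (not summed raw spectra) because SCW is the pipeline's abundance
estimate.

All thresholds are strict inequalities (p < 0.01, fold > 2.5, support ≥ 2);
boundary cases (p = 0.01, fold = 2.5, one peptide) fail.  The four criteria
form a conjunction; every flag is reported per protein so an audit can see
which criterion removed what, and the attrition block of the recovery
report counts failures per criterion (a protein may fail several; the
`any` total counts each unselected protein once).

## Secretome partition

A protein is classified secreted iff both an NN-based and an HMM-based
signal-peptide predictor are positive — the conservative conjunction.
Proteins with no annotation row default to non-secretory with a warning
naming them, so the partition of a differential list is always exhaustive.
Percentages are computed from the integer 2×2 cells and rounded half-up to
one decimal, the usual reporting precision.

The constant worked-example fixture is an 86-protein selected list whose
2×2 cells are *derived at run time* from the printed marginals of a
published perfusate-proteome partition: secreted-decreased =
round(0.704 × 27) = 19, non-secreted-increased = round(0.864 × 59) = 51,
the other two cells by subtraction (8 and 8).  The four printed numbers
overdetermine the table, so the consistency asserts (row sums 59/27,
column sums 27/59) are a genuine cross-check.  The accessions, means and
folds in the fixture are synthetic stand-ins — the underlying protein list
is not public — only the direction-by-secretion structure is real.

## Synthetic data generator

The generator emulates a two-pooled-sample design measured in technical
replicates: per-group variability reflects re-injection of one pooled
digest, not biology, hence a small default overdispersion.

* **Baseline abundances**: log-normal with σ = 1.5 natural-log units,
  normalized to a simplex.  This gives the strongly skewed abundance
  distribution typical of shotgun proteomes (a few proteins carry a large
  share of spectra; the lower tail falls below detection).
* **Spike-ins**: a fraction (default 0.10) of proteins carries a true fold
  change, log2-uniform on [1.4, 3.0] (fold 2.6–8), increased in the model
  group with probability 59/86 (the direction balance of the emulated
  study).  Model-group abundances are the baseline times (or divided by)
  the fold, renormalized within the condition — so spike-ins slightly
  deflate every other protein's share, as real compositional counting does.
  Consequently the *expected* SCW ratio of a spike-in is the true fold
  scaled by the normalizer ratio (≈ 20% deflation for increased proteins at
  the default spiked mass); `GroundTruth` carries the per-condition
  abundance vectors so tests and users can compute that expectation
  exactly.  With few spike-ins the deflation is negligible and the SCW
  ratio recovers the true fold itself.
* **Counts**: per run, a target depth is drawn uniformly on
  16,000–19,500 spectra.  Protein counts get negative-binomial
  (gamma–Poisson) variability conditioned on the run total: gamma weights
  with mean equal to the condition's abundance and squared-CV equal to the
  dispersion (default 0.1) are drawn per protein, and the depth is
  allocated multinomially across them.  Conditioning keeps every run's
  realized total exactly inside the configured window while individual
  proteins retain NB-like replicate noise; dispersion 0 degenerates to a
  plain multinomial (the conditioned Poisson).
* **Detection**: a protein is identified in a run iff it drew ≥ 1
  spectrum — the simplest mechanism that produces abundance-dependent
  dropout and the zero-imputation pattern.  No separate
  identification-failure process is modeled.
* **Identification metadata**: per-run distinct-peptide counts are
  max(1, Poisson(rate × log10(expected count + 1))) with rate 3, a
  monotone, saturating abundance–peptide relationship; probabilities are
  uniform on (0.9, 1], so the default probability filter is exercised but
  non-destructive.
* **Reproducibility**: all draws come from one
  `numpy.random.default_rng(seed)` PCG64 stream in a fixed documented
  order (baselines; spike subset; folds; directions; then per run: depth,
  gamma weights, multinomial, peptides, probabilities).

At the defaults this yields ~700 identified proteins and 16–19.5k spectra
per run, matching the scale of the emulated perfusate study (771/674
proteins, ~16.2k/19.2k spectra on average per group).

What the generator does **not** model: biological replicate variation
(samples are pooled before MS), peptide sequences and shared-peptide
ambiguity, protein-length effects on spectral counts, retention-time or
spectrum-level structure, and batch drift between runs.  Passing recovery
tests therefore demonstrate the pipeline's behaviour under its own
statistical assumptions, not performance on biologically replicated or
length-confounded data.

## Evaluation

Recovery metrics against simulation truth: sensitivity over all truly
differential proteins (detected or not), empirical FDR over the selected
set (absent when nothing is selected), log2-fold RMSE over selected true
positives with finite estimated fold, and per-criterion attrition.
Stratified sensitivity (e.g. fold ≥ 4 spike-ins detected in all ten runs
vs fold ≤ 3) separates test power from detection dropout.

Default problem sizes used by the test suite and the acceptance script —
800 proteins, 5 + 5 runs, single seeds or five-seed sweeps — run the full
pipeline in well under a second per dataset; they are the emulated study's
own scale, and larger sweeps change none of the qualitative conclusions.

## Known limitations

* The raw-p cascade controls nothing family-wise; with ~800 tested
  proteins, ~8 false positives are expected at p < 0.01 before the other
  criteria prune them (measured empirical FDR of the full cascade on
  defaults: ~4–10%).
* The t-test on zero-inflated SCW vectors is approximate for sparsely
  detected proteins; their discrete SCW patterns cannot reach p < 0.01 at
  5v5 and are effectively removed by the presence criterion.
* Fold changes of compositional shares are biased away from the underlying
  amount ratios whenever the spiked mass is material (see generator notes);
  the reported log2-RMSE includes that bias.
* Fixed-threshold selection (p, fold, peptides) is faithful to the
  emulated procedure but is not a calibrated FDR procedure; for new studies
  a count-model test with FDR control would be the modern choice.
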