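# Methods

## The contrast model

The unit of storage and retrieval is the *contrast*: one control-vs-treated
comparison inside a microarray experiment, reduced to two per-probe
vectors. For gene *g* with group means ḡ_treated and ḡ_control on the
natural intensity scale,

    fold(g) = log2( ḡ_treated / ḡ_control ),

so positive values mean upregulation in the treated arrays. Input
matrices declare their scale explicitly: `linear` values are averaged and
then log-ratioed as above; `log2` values (the usual gcrma output) use the
equivalent difference of group means. On the linear scale a non-positive
group mean leaves that probe's fold missing (NaN) with a logged warning —
never zero-filled, because 0 means "no change" and would bias every
downstream correlation.

A contrast is admitted only with **at least two control and two treated
arrays**; thinner designs carry no within-group variance information and
are rejected by name at build time.

## The regularized t-test

P-values come from a Cyber-T-style Bayesian-regularized two-sample t-test.
With 2-3 replicates per group the per-probe sample variance is an
extremely noisy estimate, and ordinary t-tests are dominated by probes
whose variance is small by chance. The regularization borrows strength
from probes of similar expression level:

1. probes are ranked by mean expression over all arrays in the contrast;
2. the background variance s0² of each probe (per group) is the mean
   within-group sample variance over the `window_size` probes nearest in
   rank (edge positions reuse the first/last full window rather than a
   shrunken one);
3. the posterior variance per group is
   (v0·s0² + (n−1)·s²) / (v0 + n − 1), with `prior_df` = v0
   pseudo-observations backing the background estimate;
4. the statistic is the pooled two-sample t with posterior variances in
   place of sample variances, on 2·v0 + n_c + n_t − 2 degrees of freedom;
5. p is two-tailed from the t distribution, floored at the smallest
   positive float so exact zeros are never reported.

The pooled-posterior form is chosen so that `prior_df = 0` reduces
*exactly* to the classical pooled-variance t-test (verified to 1e−10 in
the suite). Defaults are `window_size = 101` and `prior_df = 10`, the
conventional choices for this family of tests; both are configurable
because no single pair is canonical. The default test is **unpaired**: a
paired statistic is meaningless for the unequal group sizes common in
public experiments. A paired mode (differences by list order, v0 + n − 1
degrees of freedom) is available when group sizes match.

Degenerate inputs: a probe with zero posterior variance and a zero mean
difference is 0/0 — its t and p are left missing and counted in a
warning. Under a global null with the default priors the realized
p < 0.05 rate is close to, and slightly below, nominal (the suite asserts
within ±0.02 at 10,000 probes); the shrinkage trades a little conservatism
for large gains in ranking stability.

## Search semantics

**Profile search.** Pearson correlation between the query signature's fold
values and each contrast's fold values, restricted per contrast to the
query probes present and non-missing there. Contrasts with fewer than
`min_overlap = 3` usable probes (r on <3 points is degenerate) or zero
variance on either side are excluded. Ranking is by *signed* r descending
— anticorrelated contrasts sink to the bottom, where an
`--anticorrelated` flag can surface them — truncated to `top_n = 30`,
ties broken by contrast id for reproducibility.

**Probe-list search.** Two readings of "a t-test across all contrasts"
are genuinely defensible, so both are implemented and flag-selectable:

- `one_sample` (default): the listed probes' fold values in each contrast
  are t-tested against 0 (k−1 degrees of freedom, k = non-missing listed
  probes). This is the simplest statistic whose sign directly reports
  collective up/down regulation.
- `background`: Welch's t between the listed probes' folds in the contrast
  and the same probes' folds pooled over all other contrasts, which asks
  "unusual relative to this gene set's behaviour elsewhere" instead of
  "different from zero".

In both modes q-values are Benjamini–Hochberg step-up
(q_(i) = min_{j≥i} p_(j)·m/j, clipped at 1, ties sharing q) over
m = the contrasts actually tested (skips logged), and only hits with
p < `alpha = 0.05` are returned, sorted by p. Display rounding follows
the conventional table layout — r to 8 decimals, p and q to 5, t to 4 —
while stored values keep full precision.

**Annotation searches.** GO and title queries are literal,
case-insensitive substring matches over the stored category/title text
(no stemming or regex, for predictability). GO ids are plain integers;
a `GO:`-prefixed, zero-padded form is accepted and stripped on input.
GenBank queries compose GenBank→Unigene→probe; an id failing either hop
is returned in an explicit unmapped list, and one Unigene mapping to
several probes yields all of them.

## "Most active" selection for the heat map

The heat map shows at most 10 genes × 30 contrasts. "Activity" is mean
absolute log2 fold change: genes are scored over all contrasts (missing
skipped), the top 10 kept, then contrasts are scored by mean |fold| over
those genes and the top 30 kept; ties break by id. This definition is
symmetric in up/down regulation and permutation-invariant to database
order. A counting alternative (|fold| above a threshold) was considered
and rejected as threshold-dependent. The colour scale is a symmetric
blue–white–red map centred at 0; its clip defaults to the 98th percentile
of |fold| over the panel so a single outlier cell cannot wash out the
rest. Rendering is deterministic (fixed backend, DPI and metadata), so
images can be hash-compared.

## Storage layout

A database is a directory of tab-delimited text tables: `contrasts.tsv`
(metadata), `fold.tsv` and `pvalue.tsv` (probe × contrast matrices), and
one TSV per annotation table. Plain TSV is portable, diffable and
mergeable; a relational server adds nothing for an offline library.
Missing values are the literal token `NA`; floats are serialized at
shortest round-trip precision, so save → load is the identity at full
stored precision (property-tested). Probe and sample ids are
case-sensitive exact strings, following array-probe naming convention
(e.g. `248844_s_at`).

## The synthetic generator

`simulate_experiment` emulates a normalized experiment: per-probe log2
baselines ~ N(8, 2²), i.i.d. Gaussian array noise (default sd 0.5 log2
units, a realistic replicate spread for normalized arrays), and planted
log2 effects added to the treated arrays of designated contrasts.
`simulate_fold_database` draws per-contrast fold vectors directly
(i.i.d. N(0, fold_sd²)) — the appropriate null for search-level tests
where only the stored summaries matter. All randomness derives from one
master seed through fixed per-artifact stream offsets, so outputs are
byte-stable and adding one artifact never perturbs another.

What the generator does *not* emulate: probe-level PM/MM structure,
spatial array artifacts, correlated noise across genes, heavy-tailed
intensity distributions, or batch effects. Passing tests therefore
demonstrate correctness of the statistics and plumbing under an idealized
additive-Gaussian model, not robustness to the full messiness of real
array data.

`make_demo_fixtures` writes the worked-example bundle: a ten-probe
signature with large published-style fold changes, four defense-response
GO rows, a GenBank→Unigene→probe chain, a gene-title table, and a
40-contrast × 200-probe synthetic database whose first contrast stores
the signature verbatim — so a self-query must return it at r = 1, an
end-to-end identity check of load → align → correlate → rank → format.

## Problem sizes in the suite

The suite runs the calibration check at 10,000 null probes, planted-
signature recovery at 100 replicates of a 200-contrast database (requiring
≥99 first-place recoveries), type-I checks of the gene-list search at
2,000 null contrasts, and round-trip/determinism properties on small
randomized databases — sizes at which every property it asserts is
already statistically sharp.

## Known limitations

- The engine consumes already-normalized matrices; background correction
  and normalization (gcrma/RMA) and CEL parsing are out of scope.
- Single-species probe space; no cross-platform probe mapping.
- The regularized test assumes roughly homoscedastic noise within an
  expression stratum; strongly variance-heterogeneous data would violate
  the window-averaging step.
- Annotation tables are user-supplied or generated; no live GO/GenBank
  lookups.
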