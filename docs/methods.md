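# Methods

## The classification statistic

All classification in this package reduces to one primitive: for a gene pair
(G_a, G_b) and one sample, compare the two expression values *within that
sample*.  The pattern E_a > E_b (GT) votes for the pair's positive class;
E_a ≤ E_b (LE) votes against.  Ties are deliberately assigned to the LE
branch: GT/LE is an exhaustive dichotomy, and treating equality as "not
greater" keeps the rule total and deterministic.  Because the pattern
depends only on the within-sample ordering, every downstream result is
invariant under any strictly increasing per-sample transformation of the
expression values — the property that makes the method indifferent to
normalisation, platform scale and monotone batch distortions.  This
invariance is enforced by a dedicated test that pushes 1,000 random samples
through random monotone maps (affine, exponential, odd-cubic, and arbitrary
rank-preserving remaps) and requires zero changes in any vote or label.

A signature calls its positive class when **strictly more than half** of its
evaluable pairs show GT.  Three boundary cases are resolved explicitly
rather than silently:

- an exact 50/50 split calls the negative class (a positive call requires a
  majority) and flags the result `borderline-vote`;
- pairs with an undetected or absent gene are removed from the tally
  (`n_missing`), which is the intended behaviour on degraded FFPE or
  low-input biopsy profiles — each gene occurs in at most one pair per
  signature, so one lost gene costs exactly one vote;
- if *no* pair is evaluable the signature abstains and the panel emits the
  `UNDETERMINED` label; defaulting to a class would fabricate a diagnosis.
  Results with fewer than half the pairs evaluable (configurable) carry a
  `low-evaluable` flag.

Panel routing walks the signature chain — NE vs non-NE, then CARCI vs
non-CARCI, then SCLC vs LCNEC — until a terminal label; routing is validated
to be a tree at construction.  Classification of a sample uses only that
sample's column, so batch classification is a map and sample order is
irrelevant.

## Accuracy conventions

Apparent accuracy/sensitivity/specificity are concordances `S/N × 100` with
the reference (pathological) labels, "apparent" because the reference itself
is imperfect.  UNDETERMINED predictions count as incorrect — conservative,
since abstentions are not errors of commission but must not inflate
concordance.  An empty stratum yields an absent statistic (`None`), never
zero.

## Discovery pipeline

Given a two-group labelled matrix:

1. **DE screen.** Pooled-variance (Student) two-sample t test per gene;
   Benjamini–Hochberg adjustment; FDR < 5% defines DE genes.  Fold change is
   the difference of group means when the input is declared log-scale
   (`values_are_log`, default true) and the log2 ratio of means otherwise —
   the scale is declared by the caller, never guessed.  Genes with fewer
   than two detected values in a group or zero variance in both groups are
   excluded (counted in a warning).  The top `n_candidates` (default 1,000)
   DE genes by |log2 FC| become candidates; ties at the cutoff break by
   smaller FDR, then gene id.
2. **Pair mining.** For every unordered candidate pair, a 2×2 table crosses
   the GT/LE pattern (ties in LE, samples with a missing gene excluded) with
   the two groups; two-sided Fisher exact p-values are BH-adjusted across
   all tested pairs and FDR < 5% defines significantly reversed pairs.
   Orientation — which gene is "a" — is applied after testing, so that GT is
   the positive-group pattern.  A guard refuses more than 10^7 pairs unless
   explicitly overridden.  P-values are computed per distinct table (the
   table space is small relative to the pair space, so results are cached);
   an acceptance test checks the p-value path against an independent
   integer-arithmetic hypergeometric summation on every table with margins
   up to 30, to 1e-12.
3. **Scoring.** Each surviving pair gets (i) its apparent accuracy as a
   single-pair predictor (predict positive iff GT; missing values predict
   negative, consistent with the tie convention) and (ii) a rank-difference
   score: within each sample, genes are fractionally ranked over the
   candidate-gene universe; per group, the geometric mean of
   |rank_a − rank_b| is taken and the two group means are multiplied.  Ranks
   are computed over the candidates (not the whole transcriptome) so the
   score is reproducible given only the candidate list; since the score is
   used only to order pairs, any fixed universe gives a consistent
   tie-break.  The printed product of the two group means is used as-is (no
   outer square root): the root is monotone, so ranking is unaffected.
   Zero rank differences (exactly tied expression) are floored at 0.5 before
   the log — the geometric mean is otherwise undefined — giving the score a
   floor of 0.25.
4. **De-redundant selection.** Pairs are sorted by apparent accuracy
   (descending), then rank-difference score (descending), then gene ids, and
   scanned greedily: a pair is kept iff neither gene was already taken.  The
   ordering is total, so the output is deterministic and independent of
   input order, and every gene ends up in at most one pair.  A
   traversal-based removal rule is order-sensitive as usually stated; the
   greedy scan under a declared total order is the deterministic reading
   adopted here.
5. **Training report.** The signature's apparent sensitivity/specificity on
   the training samples are computed with the same majority-vote classifier
   used at prediction time.

Panel training applies the same two-group pipeline three times — NE
(SCLC+LCNEC+CARCI) vs non-NE (ADC+SCC) on all samples, CARCI vs non-CARCI on
the NE samples, SCLC vs LCNEC — and wires the results into the decision
tree.  Any step group below 4 samples is refused.  The pipeline contains no
randomness anywhere.

## Consensus-clustering label cleaning

Pathological training labels are imperfect; before a discovery step, samples
whose transcriptional cluster contradicts their label side can be removed.
Implementation: over the top 1,000 most variable genes (variance across
samples, ties by gene id), draw 80% of samples without replacement 1,000
times (both configurable); each draw is hierarchically clustered with Ward
linkage on Pearson-correlation distance (1 − r between sample profiles;
missing entries are mean-imputed per gene for the correlation only) and cut
at each k; consensus(i,j) is the fraction of co-draws in which i and j
co-clustered.  The final partition Ward-cuts 1 − consensus at the chosen k.

The number of clusters is chosen by minimal PAC (proportion of consensus
values inside the ambiguous band, default (0.1, 0.9)), ties to the smaller
k.  A CDF-area elbow rule was evaluated first but is not decidable by a
fixed threshold: on cleanly separable two-cluster data the area under the
consensus CDF keeps growing well past the true k because forced extra
splits still push consensus mass toward zero, so a relative-gain cutoff
selects spurious k.  PAC directly measures what a good consensus partition
looks like (values concentrated at 0 and 1) and picks the true k on
separable data; the per-k CDF areas are still reported for inspection.

For binary label cleaning the clustering runs directly at k = 2.  Each
cluster is named by the majority label side among its members — an exact
50/50 split raises an error rather than guessing — and samples whose side
differs from their cluster's name are flagged as discordant.

## Synthetic data

The generator produces what the pipeline consumes: a genes × samples matrix
on a log-intensity-like scale (baseline mean 8, sd 1 — arbitrary, since only
orderings matter; Gaussian noise is chosen for analytic tail oracles, not as
a claim about microarray error), subtype labels, and exact planted truth.
For each hierarchy step, `n_planted_pairs` (default 15) disjoint gene pairs
get gene_a shifted up and gene_b down by `effect_size` (default 3) standard
deviations in the step's positive group and the reverse in its negative
group; outside the step's sample universe both genes stay at baseline.
Dropout is missing-at-random; label corruption changes only the *observed*
label, the expression keeps following the true subtype.

The default five-subtype cohort is 20 SCLC, 20 LCNEC, 40 CARCI, 40 ADC,
40 SCC — balanced at every binary split of the hierarchy.  This is a
deliberate identifiability choice: with unbalanced nested groups, a
subtype-specific pair is also statistically "reversed" for its ancestor
steps (its GT frequency in the mixed parent group drifts away from the 50%
of the uninformative side), so ancestor signatures would absorb descendant
pairs that then vote against minority subtypes.  Balancing each split makes
each step's planted pairs informative for exactly that step, which is the
regime the discovery pipeline assumes real cohorts approximate after label
cleaning.

What passing tests on this generator do **not** show: robustness to
structured degradation (3′ bias), probe saturation, batch structure beyond
monotone distortions (covered instead by the REO-invariance property), or
realistic correlation between genes.  The generator is a testing instrument,
not a microarray model.

## Problem sizes and numerical choices

- Acceptance-grade checks run on 30/30 to 80/80-sample simulations with 300
  genes and 15 planted pairs per step — large enough that planted structure
  is unambiguous, small enough for routine re-runs.
- Fisher p-values come from `scipy.stats.fisher_exact`; the exhaustive
  oracle comparison (margins ≤ 30, deduplicated under row/column/transpose
  symmetry) bounds the numeric disagreement at ~4e-16.
- BH adjustment via `statsmodels.stats.multitest.multipletests`.
- Consensus clustering uses `scipy.cluster.hierarchy` Ward linkage on
  precomputed condensed distances.
- Gene identifiers are opaque strings keyed by Entrez id (symbols drift
  across annotation releases); duplicate ids on input are collapsed by
  per-sample arithmetic mean (the common series-matrix convention) unless
  the caller asks for an error.

## Known limitations

- The built-in panel is applied as published; no re-calibration to new
  platforms is attempted (none is needed for the REO statistic, but gene
  coverage varies — the low-evaluable flag surfaces this).
- Typical vs atypical carcinoid is not distinguished.
- The discovery pipeline assumes two clearly contrastable groups per step;
  heavily imbalanced or heterogeneous groups weaken both the Fisher screen
  and the apparent-accuracy ranking (see the balanced-split discussion
  above).
- Vote fractions are not calibrated probabilities and should not be read as
  confidence scores.
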