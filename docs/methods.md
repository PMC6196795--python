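# Methods

## Setting and model

The pipeline targets paired miRNA and mRNA expression matrices from a
two-condition replicated design (treated vs. control, default three
biological replicates, so N = 6 arrays per matrix) on a log2 intensity
scale. The object of inference is a bipartite set of miRNA→mRNA
regulations; in plants these are repressive (transcript cleavage guided by
near-perfect complementarity), so a genuine regulation shows up as (a) a
sequence-level complementary site on the transcript and (b) a strong
negative expression association between regulator and target.

An edge must pass both filters. Sequence candidacy and expression
association are deliberately kept independent: candidacy gates which pairs
may become edges; association and its significance decide which do.

## Preprocessing

* **Background correction** is floor-and-offset subtraction,
  `max(x − background, floor) + offset` with floor 0.5 and offset 16 —
  the conventional safe substitute when only summarised intensities are
  available. Instrument-specific background models (e.g. normexp MLE) are
  out of scope; downstream stages consume already-summarised matrices.
* **log2** is applied after background correction and before quantile
  normalisation (the conventional order).
* **Quantile normalisation** maps every sample column onto the vector of
  cross-column order-statistic means; ties are resolved by rank averaging.
  It is exactly idempotent on tie-free data; with ties the averaged values
  perturb the reference distribution slightly, so idempotence is only
  approximate (observed deviations < 0.1 log2 units on 50×6 matrices).
  Note that quantile normalisation assumes most features do not change
  between samples — see the simulation section for where this fails.
* **Differential expression** uses a moderated two-sample t-test.
  Per-feature pooled variances s² (d = n₁+n₂−2 df) are shrunk toward a
  scaled inverse-chi-square prior (d₀, s₀²) fitted by method of moments:
  marginally s² ~ s₀²·F(d, d₀), and matching the first two moments of the
  observed s² identifies d₀ and s₀² (no excess dispersion ⇒ d₀ = ∞, full
  pooling). The moderated statistic uses the posterior variance
  (d₀s₀² + ds²)/(d₀+d) with d+d₀ degrees of freedom; d₀ → 0 recovers the
  classical pooled t exactly, d₀ → ∞ a z-like statistic. FDR is
  Benjamini–Hochberg; features with adjusted p < 0.05 are called DE.

## Sequence candidacy

Duplexes are scored with an additive expectation penalty (lower = better):
mismatch 1.0, G:U wobble 0.5, gap 2.0, all doubled at miRNA positions
2–13 from the 5′ end (seed plus cleavage region). The transcript is scanned
with an ungapped sliding window on the given strand; windows with
expectation ≤ 2.5 (default cutoff) are reported. The scheme is a
reconstruction of the conventions of the published plant target predictors;
every penalty is configurable (`PenaltyScheme`). Gapped alignment,
site-accessibility energies and translational-inhibition classes are out of
scope. Emulating the use of two independent predictors, two candidate sets
are intersected; candidates are finally restricted to pairs whose both
endpoints are DE.

## PLS association score

For each mRNA the autoscaled miRNA matrix is decomposed into v orthogonal
latent components by NIPALS deflation (for a single response each
component's weight vector is closed-form, ∝ X′y, so no iteration is
needed); each component coefficient is the OLS regression of the response
on the component score. Default v = 3 with v < N enforced.

Two score conventions are exposed, and the distinction matters:

* **pairwise** (default): the standardised single-predictor coefficient for
  each (mRNA, miRNA) pair — the single-predictor collapse of the latent
  regression, identical to the Pearson correlation of the autoscaled
  profiles. It lives on the [−1, 1] scale on which the |Ŝ| > 0.8 edge
  threshold is meaningful, and it is what the significance and network
  stages consume.
* **joint**: the predictor-space coefficients of the joint multi-predictor
  fit, B = W(P′W)⁻¹q. With p ≫ N (30 predictors, 6 samples) regression
  coefficients are unidentifiable and every shrinkage method spreads them
  across the collinear predictors: planted single-regulator couplings of
  strength ~1 yield joint coefficients of magnitude only ~0.2. Joint-mode
  scores therefore *rank* associations but are not comparable to a
  correlation-scale threshold, which is why pairwise is the default.

Autoscaling makes the score unit-free and realises the σ̂x/σ̂y
standardisation: multiplying any profile by a positive constant leaves its
scores unchanged, and negating a miRNA profile negates its score column
(both exact, tested to 1e-12).

## Significance

The null distribution is built by **decoupled resampling**: rows (arrays)
of the miRNA matrix are resampled with replacement and, independently, rows
of the mRNA matrix, then pairs are rescored (1000 resamples by default;
fewer than 100 triggers a warning). This destroys miRNA–mRNA coupling while
preserving each side's marginal structure including its condition response,
so the null embodies "unrelated but possibly condition-responsive
features" — exactly the decoy population that confounds two-condition
designs. A case-bootstrap mode (paired rows) is available for
sampling-variability analyses.

P-values use the add-one estimator. Because a per-pair empirical p has
granularity 1/(B+1) = 1/1001, BH over a few hundred candidate pairs
becomes an all-or-nothing cliff: whether anything survives FDR < 0.05
hinges on how many pairs tie at the minimum achievable p. The default
therefore **pools the null draws across candidate pairs** (the scores are
standardised, hence the pairs' nulls are exchangeable), giving granularity
1/(1+BK) for K pairs; per-pair nulls remain available (`pool_null=False`).

The default alternative is **one-sided in the repression direction**
(p = P(null ≤ observed)): plant miRNA regulation represses its targets, so
positive associations are not evidence of regulation. A significant call
additionally requires **repression consistency** — the pooled
within-condition covariance of the pair must be negative. Rationale: a true
repressive coupling acts on the replicate-level fluctuations inside each
condition, whereas two features that are merely both condition-responsive
correlate only through the treatment contrast and have within-condition
covariance centred on zero. At N = 6 the within-condition information
(≈ 4 residual df) is too weak to carry a test on its own, but its sign is a
cheap, tuning-free consistency check. The classical symmetric test without
these directional conditions is available (`alternative="two-sided"`), in
which mode the significant flag is exactly the triple threshold.

Edges require |Ŝ| > 0.8, p < 0.01, and BH-FDR < 0.05 over the candidate
pairs (thresholds configurable).

## Network analysis

The significant pairs form a bipartite graph (duplicate pairs collapse; an
identifier may not appear on both sides). Out-degree (targets per miRNA)
and in-degree (regulators per mRNA) distributions are fitted by linearised
OLS — log10 frequency on log10 degree for the power law, on raw degree for
the exponential — with R² reported from the same regression;
zero-frequency degrees are excluded (log undefined) and ≥ 3 distinct
degrees are required. Frequencies are raw counts: the intercept absorbs the
scale and the slope is unaffected.

Coregulatory modules are the connected components, with ≥ 2 miRNAs, of the
projection graph linking two miRNAs when they share at least one target;
each module reports the targets shared by at least two of its members.
Singleton miRNAs are not modules.

## ROC and clustering

Each feature's expression is treated as a classifier score for the two
conditions. AUC is the Mann–Whitney pair statistic (ties count ½). The
operating cutoff maximises Youden's J with ties broken toward higher
specificity; accuracy is (TP+TN)/n at that cutoff. When reporting
per-feature marker performance the profile is oriented so AUC ≥ 0.5
(downregulated markers discriminate with low values). Hierarchical
clustering uses centred Pearson correlation distance (1 − r) with average
linkage by default; the uncentred variant (the historical clustering
program's default similarity) and Euclidean distance are options.
Zero-variance features are rejected by name under correlation distance.
Trees export as Newick.

## The synthetic-data generator

`generate_dataset` emulates a deregulated-feature subset of a
two-condition microarray experiment:

* per-feature baseline log2 intensity ~ Normal(8, 1);
* every miRNA carries a ±`effect_size` treated-condition shift
  (default 2.5 log2 units ≈ 5.7-fold, the middle of the 4–8× range typical
  of drought-responsive rice miRNAs), with `up_fraction` (default 9/76)
  drawn upward — the strong downregulation skew of the emulated study;
* replicate noise sd 0.3 log2 units (typical array replicate noise);
* each planted edge makes its target mRNA a decreasing function of the
  regulator: baseline − `regulation_strength` × centred miRNA profile
  (averaged over regulators when several share a target) + noise — so
  regulated mRNAs inherit a condition response *through* their regulator;
* non-target mRNAs are flat by default (`mrna_de_fraction = 0`). This is a
  deliberate identifiability choice: at N = 6 an independently
  condition-shifted decoy mRNA is statistically indistinguishable from a
  regulated one (both correlate ≈ 0.93+ with every condition-responsive
  miRNA through the shared treatment factor), so planting independent DE in
  decoys would make ground-truth recovery impossible for *any* method.
  Setting `mrna_de_fraction > 0` reproduces that confounded regime on
  purpose.
* candidate pairs = all planted edges + uniform decoys at rate
  `candidate_fpr` (default 0.02, matching the implied false-positive rate
  of intersected sequence predictions at study scale);
* identical configuration ⇒ bit-identical output.

What passing tests on this generator show: the pipeline controls its error
rates under the null and recovers planted repressions (precision ≈ 0.85,
recall ≈ 0.81 pooled over 20 simulations at 30×329×6, 50 edges, strength
0.9, noise 0.3). What they do not show: robustness to probe-level
artifacts, batch effects, non-Gaussian intensity distributions, indirect
(transcription-factor-mediated) anticorrelation, or miRNA-induced decay
dynamics — none of which the generator models.

The end-to-end synthetic harness does **not** quantile-normalise the
generated matrices: they are emitted on an already-normalised scale, and
with only 30 features of which ~88% shift in the same direction, quantile
normalisation would equalise the treated and control distributions and
erase the very signal under study (measured: planted-edge recall collapses
from ≈ 0.87 to ≈ 0). On real arrays normalisation happens across the full
probe complement, where the mostly-unchanged majority anchors the
quantiles.

`generate_duplex_sequences` plants complementary target sites with
controlled edits (perfect, core mismatch, core/tail wobble combinations)
into random transcripts and records each site's intended expectation score,
covering scores 0–2 under the default penalties.

## Numerical choices and degenerate inputs

* Autoscaling uses the sample standard deviation (ddof 1); zero-variance
  columns raise a named error in `fit_pls`, while bootstrap resamples that
  happen to draw a constant column score 0 for the affected pairs.
* Empirical p-values can never be 0 (add-one), keeping BH well defined.
* Sorting keys are always (score, identifier) so ties resolve
  deterministically; cluster leaves are pre-sorted by id.
* Fixture files are checksum-verified (SHA-256) at load.
* All randomness flows through `numpy.random.default_rng(seed)`; every CLI
  entry point and the pipeline config carry an explicit seed, and a run's
  manifest hash is reproduced exactly by a re-run with the same
  configuration.

## Default problem sizes

The packaged analyses use 20 simulated datasets at 30×329×6 with 1000
bootstrap resamples for recovery estimates, and 20–50 null datasets at
10×60×6 with 500 resamples for calibration — sizes at which the estimates
are stable across seeds while a full run of the test-and-acceptance suite
completes in well under a minute on one CPU.

## Known limitations

* With N = 6 the per-pair association estimate is extremely noisy; the
  0.8 score threshold and 0.01 p threshold jointly put the operating point
  near the information-theoretic boundary of what the design supports, and
  recovery degrades quickly for regulation strengths below ~0.7.
* The joint PLS coefficients are reported for completeness but should not
  be thresholded on the correlation scale (see above).
* The repression-consistency check assumes a two-condition design with
  replicate-level coupling; it is skipped when no condition labels are
  available and says nothing for positive (stabilising) regulation, which
  is not modelled.
* The degree-distribution fits use naive linearised OLS on binned counts —
  adequate for describing a 13-node network, not for rigorous heavy-tail
  inference.
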