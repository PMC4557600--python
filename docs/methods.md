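# Methods

## Model and procedure

`mirlink` treats a two-layer expression experiment — miRNA and mRNA
matrices over the same samples — as evidence about repressive
miRNA→target interactions that are active in a treatment response. The
chain of inference is:

1. *Which features respond to treatment?* A moderated two-sample t-test
   per feature (treated vs control biological replicates, log2 scale).
2. *Does unsupervised structure track the labels?* Agglomerative
   clustering of samples with a Fisher's exact test of the 2×2
   cluster × label table.
3. *Which responsive miRNA–mRNA pairs anti-correlate?* Pearson r across
   all samples of a culture; r ≤ −0.5 (inclusive) defines a candidate
   edge, a permutation test calibrates how many such edges chance would
   give, and a curated interaction table (strong/NGS evidence only)
   filters candidates to biologically validated pairs.
4. *What do the targets do?* Hypergeometric over-representation against
   pathway collections.
5. *Do orthogonal measurements agree?* 2^−ΔΔCt qPCR fold changes and
   Spearman anti-correlation (ρ ≤ −0.5) of paired fold-change series.

### Assumptions

- Expression values are log2-scale and approximately Gaussian within a
  condition; fold changes act additively on this scale.
- Repression is monotone and fast relative to sampling, so an active
  interaction produces negative cross-sample correlation; positive
  co-variation (co-activation, shared upstream drivers) is deliberately
  not an edge.
- Technical replicates of one biological replicate share the biological
  deviation and differ only by measurement noise; they are therefore
  averaged before differential testing (avoiding pseudoreplication) but
  kept as individual samples for clustering and correlation, matching
  the 12-array-per-culture layout the heatmaps describe.

## Differential expression

The pooled per-feature variance on d = n_T + n_C − 2 df is shrunk toward
the median pooled variance s₀² with a fixed prior of d₀ = 4 df:
s̃² = (d₀s₀² + d·s²)/(d₀ + d), and t = Δmean / (s̃·√(1/n_T + 1/n_C)) is
referred to t with d + d₀ df. This captures the variance-stabilizing
behaviour of hierarchical empirical-Bayes microarray models without
fitting the full hierarchy (a deliberate simplification; the prior df and
the median-variance prior are fixed, not estimated). Benjamini–Hochberg
step-up FDR (via statsmodels) flags significance at α = 0.05.

Degenerate inputs: a feature with no variance anywhere gets p = 1 rather
than an error (keeps null pipelines runnable); a matrix with zero total
within-condition variance is rejected; p-values are clipped away from 0
at the smallest positive double.

## Clustering and label association

Distance is 1 − Pearson between sample profiles with average linkage —
the most common expression-heatmap convention; both are configurable. The
tree is cut into two clusters and the cluster × label table is tested
two-sided by Fisher's exact test (scipy). A constant sample profile makes
correlation distance undefined and raises an error naming the sample.
Feature pre-selection follows the heatmap conventions: top-k by ascending
DE p-value for miRNAs, top-k by cross-sample variance for mRNAs (k = 50
by default), with lexicographic tie-breaks for determinism. The ranking
criterion behind "top deregulated" lists is genuinely ambiguous in such
studies; p-value was chosen as the default and variance kept selectable.

## Network construction

Correlations use all samples of one culture, both conditions and all
technical replicates (n = 12 in the default design). This is a
convention — correlating within conditions only would remove the
treatment-driven component — and is the reading most consistent with an
edge criterion of |r| ≥ 0.5 at n = 12. Zero-variance features give NaN
(undefined) entries which never become edges. The threshold is inclusive:
−1 ≤ r ≤ −0.5.

**Permutation FDR.** The mRNA layer's sample columns are permuted
relative to the miRNA layer, preserving each layer's internal covariance
and destroying cross-layer alignment; the FDR is the mean null edge count
over B = 1000 permutations divided by the observed count (undefined when
no edge is observed, reported as not-applicable; B < 10 is flagged
low-confidence). When a sample design is supplied, permutation moves
*biological-replicate blocks* (the two technical replicates travel
together). This matters: technical replicates are correlated through the
shared biological noise, so single-column permutation produces a null
with a narrower edge-count distribution than the observed data and
understates the FDR denominator — measured as a null-calibration ratio
of 0.39 instead of ~1.0. Block permutation restores the ratio to ~0.99.
The network FDR is a quality annotation of the binary matrix, not an
edge-level filter.

**Evidence filter.** Only pairs recorded with *strong* or *NGS* evidence
in the interaction table are retained; filtering commutes with
thresholding. Each edge is annotated with the sign of both endpoints'
log2 fold change (log2fc > 0 → "up", else "down").

**Combination.** The combined network keeps miRNAs present in both
culture networks and the union of their edges restricted to those
miRNAs, each edge tagged with its culture of origin.

## Over-representation analysis

p = P(X ≥ k) for X ~ Hypergeometric(N = |universe|, K = |pathway|,
n = |list ∩ universe|), computed with scipy's stable survival function
and cross-checked in tests against exhaustive combinatorial enumeration.
The default universe is the union of all pathway genes — the most
consequential unstated parameter of any ORA, surfaced as an explicit
argument. The test is one-sided (over-representation only) and BH-FDR is
computed jointly across the whole multi-source collection, the simplest
defensible treatment of a mixed BioCarta/KEGG/NCI/PANTHER/Reactome
report. Matching published pathway p-values from any specific enrichment
application is out of scope (backgrounds and list sizes of such apps are
not reproducible).

## qPCR quantification

ΔCt per sample = Ct_target − mean(reference Cts); averaging reference
Cts on the cycle (log2) scale equals normalizing expression by the
geometric mean of the references — the chosen combination rule when
several references (B2M + ACTB) are named without one. ΔΔCt = mean
ΔCt(treated) − mean ΔCt(control), fc = 2^−ΔΔCt, p from a two-sided
two-sample t-test on per-biological-replicate ΔCt values (PCR replicates
averaged first). The statistic is invariant to plate-wide Ct offsets and
label swap inverts the fold change. Amplification-efficiency correction
is out of scope.

Spearman validation pairs biological replicates by index across the
miRNA and mRNA series (the pairing is configurable since nothing pins it
down); ties get average ranks; a constant vector raises a distinct
`ConstantVectorError` rather than returning NaN. A pair validates when
ρ ≤ −0.5.

## Synthetic data: what it emulates, what it does not

The generator emulates a two-culture treated/control design with 3
biological × 2 technical replicates per cell (24 arrays), log2
intensities with uniform baselines in [6, 12], additive Gaussian noise —
biological (SD 0.25) shared by a bio-rep's technical replicates,
technical (SD 0.10) independent — treatment shifts of ±2.0 log2 units
for planted DE features, and planted repressive edges: the target mRNA
is a − x + ε of its miRNA with ε calibrated from the miRNA's total
cross-design variance so the population Pearson correlation equals the
requested value (default −0.8). Planted-edge miRNAs always receive the
treatment shift so that both endpoints are treatment-responsive and the
edge can traverse the DE filter; the shift magnitude matches the DE
power operating point (log2 shift 2 ≈ 4-fold, a typical strongly
validated microarray response) and the noise SDs are conventional
desk-scale microarray values — none of these are estimates from real
arrays, since no raw data is available to estimate from.

What a green test does *not* establish: the generator has no array
artifacts (spatial effects, background, probe saturation), no
probe-to-gene multiplicity, no correlated noise between features beyond
the planted edges, and Gaussian tails only. Recovery rates on real
arrays will be worse; the tests establish internal correctness and
calibration of the statistics, not field performance.

Calibration facts the suite checks (seeded Monte Carlo):

- planted-edge sample correlations average within 0.1 of the target;
- atanh(r) spread matches Fisher-z theory (SD within 20% of 1/√(n−3))
  in the bivariate-normal regime (edge shift 0 — the theory's own
  assumption; the default shifted regime is bimodal in the miRNA);
- under a pure null the pipeline's edge count matches the
  block-permutation null within a factor of 2 (the null-calibration
  check runs the network stage on all features, since a true null
  yields empty DE-significant sets and no network at all);
- DE type-I fraction ≤ 0.05 under the null, power ≥ 0.95 at the stated
  operating point, end-to-end planted-edge recall ≥ 0.8 (measured
  ≈ 0.84–0.95 depending on decoy load).

## Numerical choices

- BH adjustment delegates to statsmodels; tests verify against a
  hand-computed step-up oracle and permutation invariance.
- Fisher's exact test, hypergeometric tail and Spearman delegate to
  scipy; tests verify against enumeration over the hypergeometric
  support, exhaustive combinatorics (all N ≤ 25), and Pearson-on-ranks
  respectively.
- Correlation matrices are computed as z-scored matrix products and
  clipped to [−1, 1]; ties in top-k selection break lexicographically.
- TSV floats are written as shortest-round-trip reprs and read back with
  correctly-rounded parsing, so write∘read is the identity and artifact
  hashes are stable; every pipeline artifact carries a `# mirlink
  config=<hash> seed=<seed>` stamp (config hash excludes the output
  directory).
- All randomness flows through `numpy.random.default_rng(seed)`; the
  pipeline derives stage seeds as fixed small offsets of the run seed.

## Known limitations

- The moderated t uses a fixed prior (df 4, median variance), not an
  estimated hierarchy; p-values are mildly conservative in the tails
  relative to a full empirical-Bayes fit.
- The network FDR is a single network-level ratio, not per-edge; it says
  how much of the binary matrix chance would explain, nothing about any
  individual edge.
- Correlation at n = 12 is noisy (Fisher-z SD ≈ 0.33); edges near the
  −0.5 boundary are unstable across reseeds, which is inherent to the
  design size, not the implementation.
- The stylized regime "planted edges among many null features without a
  DE filter" cannot reach a network FDR below ~0.9 at n = 12, because
  ~5% of null pairs pass r ≤ −0.5 by chance; the FDR is informative only
  after the DE-significance restriction, where planted structure drives
  it well below 0.5.
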