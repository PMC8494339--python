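# Methods

## Model and statistical basis

All information quantities are in bits.  For discrete variables X (a
discretized gene) and C (the class), the empirical mutual information
estimated from N samples is biased upward under independence: the
statistic `G = 2N ln2 · I(X;C)` is asymptotically chi-square with
`(I−1)(K−1)` degrees of freedom, where `I` and `K` count the occupied
levels of X and C.  Two constructions follow:

* **Bias correction.**  Subtracting the chi-square mean on the bit
  scale, `df/(2N ln2)`, centres the score of an uninformative gene at
  zero.  The relevance score is `J_rel = I(X;C) − (I−1)(K−1)/(2N ln2)`;
  the complementary score applies the analogous correction
  `(I−1)(J−1)K/(2N ln2)` to the conditional MI `I(X;Y|C)`.
* **Significance threshold.**  A gene is "significant" when its
  corrected score exceeds `(χ²_{1−α}(df) − df)/(2N ln2)`.  Subtracting
  `df` from the quantile keeps the comparison algebraically identical to
  the ordinary raw-scale test `G > χ²_{1−α}(df)` (unit-tested as an
  equivalence).  A `literal` scale that skips the subtraction is
  available for comparison; it makes the test strictly more
  conservative.

Degrees of freedom use **occupied** level counts, not nominal bin
counts: empty bins contribute no cells to the contingency table and
hence no degrees of freedom to the null.

## Selection procedure

1. **Screening.**  Each gene is discretized at levels `d = 2..max_d`
   (equal-width over the observed range; equal-frequency available) and
   kept at the *first* level whose `J_rel` passes its chi-square test —
   the minimal granularity at which the gene shows significant class
   information.
2. **Greedy admission.**  Candidates are visited in decreasing-relevance
   order (ties: original gene order).  The top candidate seeds the
   selected set.  Every other candidate is re-scored by
   `J_MGS = J_rel + mean_s [I(g;g_s|C) − bias]` over levels
   `d−δ .. d+δ` (clamped to `[2, max_d]`) and admitted if the score
   passes for at least one level; the passing level with the highest
   score is stored.  The degrees of freedom of the composite test mirror
   its construction: `(I−1)(K−1) + mean_s (I−1)(J_s−1)K`.  Chi-square
   quantiles accept non-integer df, so the mean poses no difficulty.
3. **No redundancy penalty.**  An exact copy of a selected gene is
   retained — its conditional-MI term is non-negative — reflecting the
   biological argument that co-regulated genes can all be informative.

The published pseudocode for step 2 initializes its acceptance threshold
to zero, which admits any candidate whose (positive) screening relevance
survives even when the composite test never passed, and keeps the *last*
passing level rather than the best.  The default here is the strict
reading (admit only on a passed test, keep the best level);
`MiTestConfig(literal_algorithm1=True)` reproduces the pseudocode
verbatim, and a unit test pins the behavioral difference.

## Ranking and evaluation

Per-fold selections are unioned; **MGS_f** scores each gene by
`F_i / N_union`.  **MGS_rf** fits a random forest (entropy criterion,
bootstrap, √p features per split, 300 trees by default) on the union
genes and scores each gene by the mean weighted information gain
`(N_t/N)[H(parent) − (N_L/N_t)H(left) − (N_R/N_t)H(right)]` over the
internal nodes splitting on it; never-split genes score 0.
scikit-learn's entropy impurity is the node entropy in bits (verified
numerically), so node-level gains realize the formula exactly, with
bootstrap weights entering through the weighted node sample counts.
Ranking ties are broken by descending mean training-fold relevance, then
by natural gene-id order.

Evaluation uses leave-one-out when n < 100 and stratified 10-fold
otherwise.  Within each outer fold, an inner stratified cross-validation
(K = 5, capped by the smallest class) over the training split produces
the per-fold selections that feed the ranking; the top-η panel then
trains the classifier (linear-kernel SVM or the entropy random forest,
library defaults) on the training split only.  This keeps every test
sample out of screening, selection, ranking and fitting for its own
fold — a property enforced by a canary test that corrupts held-out
labels and checks the panel is unchanged.  AUROC is computed from pooled
test-split scores under leave-one-out (single-sample folds have no ROC
of their own) and averaged per fold under K-fold.  Accuracy is averaged
over folds.  The positive class is the lexicographically last class
name ("disease" under the default control/disease naming).

## Parameters

| parameter | default | meaning |
|---|---|---|
| `alpha` | 0.05 | significance level of every chi-square test |
| `max_d` | 10 | largest discretization level screened |
| `delta` | 2 | half-width of the level sweep at admission |
| `scheme` | equal-width | binning scheme (equal-frequency optional) |
| `eta` | 10 | biomarker panel size |
| `n_trees` | 300 | forest size for MGS_rf and the RF classifier |
| `inner_folds` | 5 | inner CV folds feeding the frequency ranking |

`max_d = 10` and `δ = 2` let the sweep span meaningful granularities at
the 20–250-sample scale typical of expression studies; both are
configurable.  `alpha = 0.05` is the conventional level.

## Synthetic data

The generator emulates a two-class expression study with known ground
truth: Bernoulli(0.5) labels over 60 samples; 10 informative genes
(standard normal + 1.5·label); 2 redundant copies per informative gene
(parent + N(0, 0.3)); 3 complementary pairs — jittered ±1 coins whose
XOR equals the label, so each gene is marginally label-independent but
the pair is jointly deterministic; and 2000 independent N(0,1) noise
genes.  XOR genes carry Gaussian jitter (SD 0.1) so they exercise the
real discretizer rather than arriving pre-binned.  The generator does
**not** model probe-level artifacts, batch effects, heteroskedastic
count noise, or gene–gene correlation beyond the planted structure, so
passing tests demonstrate correctness of the selection machinery on its
own statistical assumptions, not robustness to real microarray noise.
A `separable_dataset` fixture (5 genes at 2·label + N(0, 0.05), 25
noise genes, n = 40) provides a deterministic end-to-end sanity case.

Preprocessing mirrors the usual GEO-export convention: probes sharing a
gene symbol are collapsed by their unweighted per-sample mean over
observed values (raw scale), genes with no observed value are dropped,
and remaining missing cells are imputed at use time by the per-gene
median (deterministic, robust; can be disabled).

## Numerical choices

* `0·log 0 := 0` in all information sums; results are clamped at 0 to
  absorb −1e−16-scale float residue.
* Equal-width bin edges span the observed `[min, max]`; the maximum
  value belongs to the top bin; constant genes occupy a single bin and
  can never pass any test (zero df).
* Chi-square quantiles are cached; screening is vectorized across genes
  (per-level contingency tables via one-hot matrix products), which is
  what makes the 2000-gene studies and the null simulations fast.
* All randomness flows through explicit seeds; forest rankings and
  evaluation reports are bit-reproducible given (data, config, seed).

## Measured properties and known limitations

Two properties of the published procedure are measured by the
acceptance tests and reported rather than patched:

* **The screening sweep is not alpha-calibrated.**  Taking the first
  passing level among `d = 2..max_d` is a union of correlated tests
  with no multiplicity control: on independent N(0,1) genes the
  candidate rate is ≈0.15 (n = 100, levels 2–5) to ≈0.29 (n = 60,
  levels 2–10) at α = 0.05.  The *per-level* test is calibrated at the
  binary level (rejection rate within Monte-Carlo error of α, corrected
  score mean within 3 SE of 0) and drifts mildly anti-conservative at
  finer levels, the familiar small-sample behavior of the G statistic
  with sparse cells.  The downstream composite test prunes most false
  candidates (noise retention ≈6%), so the selected set, not the
  candidate pool, is the meaningful output.
* **Complementary rescue dilutes with selection size.**  The composite
  score averages the conditional-MI term over the whole selected set,
  so a single XOR mate's 1 bit contributes only `1/|G_S|` bits; with
  |G_S| ≈ 66 under the default study the planted XOR partners are not
  retained above the noise rate.  The rescue is real and tested when
  the mate anchors a small selected set; at scale, a max- or top-k-
  complementarity variant would be needed to preserve it (out of scope
  here).

Other limitations: binary classes are the tested regime (the formulas
support K > 2); LOOCV pooled-score AUROC carries the usual slight
pessimistic bias under the null (measured ≈0.43–0.47 on permuted
labels); and the method inherits the discretization's sensitivity to
extreme values, since equal-width edges depend on the observed range.
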