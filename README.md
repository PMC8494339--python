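# mgs — mutual-information based gene selection

Identifying the handful of genes whose expression discriminates two
biological states (control vs. disease, primary tumor vs. metastasis)
is hard when a study measures tens of thousands of genes on a few dozen
samples.  `mgs` implements a filter-style selector for exactly this
regime: it scores genes by **bias-corrected mutual information** with
the class, admits them through a **complementary-information**
chi-square test that deliberately has *no redundancy penalty*
(co-regulated genes are often individually informative and should all
be kept), ranks the selected genes across cross-validation folds, and
evaluates the resulting biomarker panels with standard classifiers.

## The method

Each gene `g_i` is discretized into `d` equal-width bins.  Its
*relevance* is

    J_rel(g_i) = I(g_i^d ; C) − (I−1)(K−1) / (2N ln2)

where `I` is the number of occupied bins, `K` the number of classes and
`N` the sample count; the subtracted term is the mean of the chi-square
distribution that `2N ln2 · I(g_i^d; C)` follows under independence, so
the corrected score is centred at zero for uninformative genes.  A gene
enters the candidate pool at the smallest `d ∈ {2..max_d}` for which
`J_rel` exceeds the chi-square critical value — a significance test,
not a hand-tuned cut-off.

Candidates are then admitted greedily by the composite score

    J_MGS(g_i) = J_rel(g_i) + mean over selected g_s of
                 [ I(g_i ; g_s | C) − (I−1)(J−1)K / (2N ln2) ]

whose second term rewards *complementary* information: conditional
dependence on already-selected genes given the class.  During this stage
each gene's discretization level is swept by ±δ and the best passing
level is kept.  Two rankings aggregate the per-fold selections:

* **MGS_f** — relative selection frequency `F_i / N_union`;
* **MGS_rf** — mean weighted information gain
  `(N_t/N)[H(parent) − (N_L/N_t)H(left) − (N_R/N_t)H(right)]`
  over the nodes of a 300-tree entropy random forest that split on the
  gene.

The top-η genes (η ≤ 10 by default) form the biomarker panel, evaluated
by accuracy and AUROC under leave-one-out (n < 100) or stratified
10-fold cross-validation, with selection and ranking confined to each
fold's training split.

## Worked example

```python
from mgs import rank_by_frequency, top_eta, union_selections

fold1 = ["g1", "g3", "g4", "g5", "g6"]
fold2 = ["g1", "g2", "g4", "g6"]
ranked = rank_by_frequency(union_selections([fold1, fold2]))
print(ranked.genes)     # ['g1', 'g4', 'g6', 'g2', 'g3', 'g5']
print(ranked.scores[0]) # 0.3333333333333333
```

Genes selected in both folds score 2/6 ≈ 0.333 and head the ranking;
single-fold genes follow at 1/6.  Running
`python examples/select_from_synthetic.py` prints a full selection round
on a generated 2036-gene × 60-sample study:

```
candidates after screening: 634  {'informative': 10, 'redundant': 20, 'complementary': 2, 'noise': 602}
selected subset:            75  {'informative': 10, 'redundant': 19, 'noise': 46}
informative genes missed: none
seed gene: inf8 (relevance 0.576 bits at 2 levels)
```

All ten planted class-shifted genes are recovered together with their
redundant copies (no redundancy penalty), while the composite test
prunes ~92% of the noise genes that slipped through screening.  The
other scripts in `examples/` demonstrate the complementary (XOR) pair
rescue and the cross-validated panel evaluation; a thin CLI (`mgs
simulate|preprocess|select|rank|evaluate|run-all`) wires the same stages
for shell use.

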