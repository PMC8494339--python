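"""Cross-validated end-to-end evaluation of selected biomarker panels.

Protocol: the samples are split into outer folds (leave-one-out when
n < 100, stratified 10-fold otherwise).  Within each outer fold the
selection pipeline sees *only* the training split: an inner
cross-validation over the training samples produces one selected subset
per inner fold, the subsets are unioned and ranked (by selection
frequency or by forest information gain), and the top-eta panel is used
to fit the classifier on the training split and score the held-out test
split.  No information from a fold's test samples can reach screening,
selection, ranking or classifier fitting for that fold.

Accuracy is averaged over folds.  AUROC is computed from the pooled
test-split scores under leave-one-out (single-sample test folds have no
ROC of their own) and averaged per fold under K-fold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .data_io import ExpressionDataset
from .mi_core import MiTestConfig
from .ranking import rank_by_frequency, rank_by_forest, top_eta, union_selections
from .selection import screen_candidates, select_subset


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def tpr_fpr(c: ConfusionCounts):
    """True- and false-positive rates; ``nan`` when a denominator is 0."""
    tpr = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else float("nan")
    fpr = c.fp / (c.fp + c.tn) if (c.fp + c.tn) else float("nan")
    return tpr, fpr


def auroc(scores, labels) -> float:
    """Area under the ROC curve (Mann-Whitney statistic, ties count 1/2)."""
    y = np.asarray(labels)
    if np.unique(y).size < 2:
        raise ValueError("AUROC needs both classes present")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def make_folds(n: int, labels=None, seed: int = 0, scheme: str = "auto",
               k: int = 10):
    """Outer fold plan: LOOCV when ``n < 100``, stratified K-fold otherwise.

    Returns ``(scheme_name, folds)`` where folds is a list of
    ``(train_idx, test_idx)`` arrays partitioning ``range(n)``.
    """
    if n < 2:
        raise ValueError("need at least 2 samples")
    if scheme == "auto":
        scheme = "loocv" if n < 100 else "kfcv"
    if scheme == "loocv":
        idx = np.arange(n)
        folds = [(np.delete(idx, i), np.array([i])) for i in range(n)]
        return "loocv", folds
    if scheme == "kfcv":
        if labels is None:
            raise ValueError("stratified K-fold needs labels")
        y = np.asarray(labels)
        k_eff = min(k, int(np.bincount(y).min()))
        skf = StratifiedKFold(n_splits=max(k_eff, 2), shuffle=True, random_state=seed)
        folds = [(tr, te) for tr, te in skf.split(np.zeros(n), y)]
        return f"kfcv-{max(k_eff, 2)}", folds
    raise ValueError(f"unknown fold scheme {scheme!r}")


def _make_classifier(name: str, n_trees: int, seed: int):
    if name == "svm":
        return SVC(kernel="linear")
    if name == "rf":
        return RandomForestClassifier(n_estimators=n_trees, criterion="entropy",
                                      random_state=seed)
    raise ValueError(f"unknown classifier {name!r} (expected 'svm' or 'rf')")


def _decision_scores(clf, X) -> np.ndarray:
    if hasattr(clf, "decision_function"):
        return np.asarray(clf.decision_function(X), dtype=float)
    proba = clf.predict_proba(X)
    return np.asarray(proba[:, list(clf.classes_).index(max(clf.classes_))])


@dataclass
class EvaluationReport:
    method: str
    classifier: str
    eta: int
    fold_scheme: str
    seed: int
    accuracy: float
    auroc: float
    fold_accuracies: list
    fold_panels: list
    skipped_folds: list
    positive_class: object
    config: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("fold\taccuracy\tpanel\n")
            for i, (acc, panel) in enumerate(zip(self.fold_accuracies, self.fold_panels)):
                fh.write(f"{i}\t{acc:.6g}\t{','.join(map(str, panel))}\n")
            fh.write(f"mean\t{self.accuracy:.6g}\t\n")
            fh.write(f"auroc\t{self.auroc:.6g}\t\n")


def _inner_selections(train: ExpressionDataset, cfg: MiTestConfig, seed: int,
                      inner_folds: int):
    """Per-inner-fold selection results on a training split.

    The training samples are split into stratified inner folds (capped
    by the smallest class) and selection runs on each inner training
    part; inner folds where screening finds nothing are skipped.  Falls
    back to a single selection on the whole split when stratification is
    impossible.
    """
    y = train.labels
    k_eff = min(inner_folds, int(np.bincount(y).min()))
    results = []
    if k_eff >= 2:
        skf = StratifiedKFold(n_splits=k_eff, shuffle=True, random_state=seed)
        splits = [tr for tr, _ in skf.split(np.zeros(train.n_samples), y)]
    else:
        splits = [np.arange(train.n_samples)]
    for fold_id, tr in enumerate(splits):
        sub = train.subset_samples(tr)
        if np.unique(sub.labels).size < 2:
            continue
        cands = screen_candidates(sub, cfg)
        if not cands:
            continue
        results.append(select_subset(cands, sub, cfg, fold_id=fold_id))
    return results


def _rank_training(train: ExpressionDataset, results, method: str, cfg: MiTestConfig,
                   n_trees: int, seed: int):
    counts = union_selections([r.gene_indices for r in results])
    relevances: dict = {}
    for r in results:
        for c in r.selected:
            relevances.setdefault(c.gene_index, []).append(c.relevance)
    tiebreak = {g: float(np.mean(v)) for g, v in relevances.items()}
    if method == "mgs_f":
        return rank_by_frequency(counts, tiebreak=tiebreak)
    if method == "mgs_rf":
        union = sorted(counts)
        X = train.values_imputed()[union, :].T
        return rank_by_forest(X, train.labels, union, n_trees=n_trees, seed=seed,
                              tiebreak=tiebreak)
    raise ValueError(f"unknown method {method!r} (expected 'mgs_f' or 'mgs_rf')")


def evaluate(ds: ExpressionDataset, method: str = "mgs_f", classifier: str = "svm",
             eta: int = 10, cfg: MiTestConfig | None = None, seed: int = 0,
             n_trees: int = 300, inner_folds: int = 5, fold_scheme: str = "auto",
             k_outer: int = 10) -> EvaluationReport:
    """Run the full selection -> ranking -> classification pipeline.

    Returns per-fold and aggregate accuracy plus AUROC for the chosen
    ranking method (``mgs_f`` or ``mgs_rf``) and classifier (``svm``
    linear kernel or ``rf`` with ``n_trees`` entropy trees).  Outer
    folds whose training split yields no selected genes are skipped and
    listed in the report.
    """
    cfg = cfg or MiTestConfig()
    scheme_name, folds = make_folds(ds.n_samples, ds.labels, seed=seed,
                                    scheme=fold_scheme, k=k_outer)
    positive = int(np.max(np.unique(ds.labels)))
    fold_accs: list = []
    fold_panels: list = []
    fold_aurocs: list = []
    skipped: list = []
    pooled_scores: list = []
    pooled_labels: list = []
    for fold_id, (tr, te) in enumerate(folds):
        train = ds.subset_samples(tr)
        test = ds.subset_samples(te)
        results = _inner_selections(train, cfg, seed, inner_folds)
        if not results:
            skipped.append(fold_id)
            continue
        ranked = _rank_training(train, results, method, cfg, n_trees, seed)
        panel = top_eta(ranked, eta)
        Xtr = train.values_imputed()[panel, :].T
        Xte = test.values_imputed()[panel, :].T
        clf = _make_classifier(classifier, n_trees, seed)
        clf.fit(Xtr, train.labels)
        pred = clf.predict(Xte)
        fold_accs.append(float(np.mean(pred == test.labels)))
        fold_panels.append([ds.gene_ids[g] for g in panel])
        scores = _decision_scores(clf, Xte)
        pooled_scores.extend(scores.tolist())
        pooled_labels.extend((test.labels == positive).astype(int).tolist())
        if scheme_name != "loocv" and np.unique(test.labels).size == 2:
            fold_aurocs.append(auroc(scores, (test.labels == positive).astype(int)))
    if not fold_accs:
        raise ValueError("selection produced no genes in any fold")
    if scheme_name == "loocv":
        roc = auroc(pooled_scores, pooled_labels) if len(set(pooled_labels)) == 2 else float("nan")
    else:
        roc = float(np.mean(fold_aurocs)) if fold_aurocs else float("nan")
    names = ds.label_names or sorted(map(str, np.unique(ds.labels)))
    return EvaluationReport(
        method=method,
        classifier=classifier,
        eta=eta,
        fold_scheme=scheme_name,
        seed=seed,
        accuracy=float(np.mean(fold_accs)),
        auroc=roc,
        fold_accuracies=fold_accs,
        fold_panels=fold_panels,
        skipped_folds=skipped,
        positive_class=names[positive] if positive < len(names) else positive,
        config={
            "alpha": cfg.alpha, "max_d": cfg.max_d, "delta": cfg.delta,
            "scheme": cfg.scheme, "critical_scale": cfg.critical_scale,
            "literal_algorithm1": cfg.literal_algorithm1,
            "n_trees": n_trees, "inner_folds": inner_folds,
        },
    )
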