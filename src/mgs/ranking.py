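"""Ranking of the selected genes and biomarker panel extraction.

Two rank scores are supported for the union of the per-fold selections:

* frequency ranking: a gene's score is its relative selection frequency,
  ``F_i / N_union`` — genes selected in every fold are presumed the most
  stable biomarkers;
* forest ranking: an entropy-criterion random forest is fitted on the
  union genes and every internal node contributes its *weighted*
  information gain ``(N_t/N) [H(parent) - (N_L/N_t) H(left)
  - (N_R/N_t) H(right)]`` (bits) to the gene it splits on; a gene's
  score is the mean over the nodes that split on it, and genes never
  split on score 0.

Ties are broken by descending tie-break score (typically the mean
training-fold relevance) and then by natural gene-id order.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier


@dataclass(frozen=True)
class ForestNodeRecord:
    """One internal forest node: the splitting gene and its weighted IG."""

    gene_id: object
    weighted_ig: float


@dataclass
class RankedGeneList:
    """Genes in rank order (best first) with their aligned scores."""

    genes: list
    scores: list
    method: str

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.scores):
            raise ValueError("genes and scores must be aligned")
        if any(b > a + 1e-12 for a, b in zip(self.scores, self.scores[1:])):
            raise ValueError("scores must be non-increasing along the rank order")

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("rank\tgene_id\tscore\tmethod\n")
            for r, (g, s) in enumerate(zip(self.genes, self.scores), start=1):
                fh.write(f"{r}\t{g}\t{s:.10g}\t{self.method}\n")


def _nat_key(gene_id):
    parts = re.split(r"(\d+)", str(gene_id))
    return tuple((0, int(p)) if p.isdigit() else (1, p) for p in parts if p != "")


def _sorted_ranking(scores: dict, method: str, tiebreak: dict | None) -> RankedGeneList:
    tb = tiebreak or {}
    genes = sorted(scores, key=lambda g: (-scores[g], -tb.get(g, 0.0), _nat_key(g)))
    return RankedGeneList(genes=genes,
                          scores=[float(scores[g]) for g in genes],
                          method=method)


def union_selections(per_fold) -> Counter:
    """Union the per-fold gene lists into per-gene selection counts.

    Accepts either plain iterables of gene identifiers or objects with a
    ``gene_indices`` attribute (per-fold selection results).  Raises if
    every fold is empty.
    """
    counts: Counter = Counter()
    n_folds = 0
    for fold in per_fold:
        genes = getattr(fold, "gene_indices", fold)
        genes = list(genes)
        n_folds += 1
        counts.update(set(genes))
    if n_folds == 0 or not counts:
        raise ValueError("no selections to aggregate: all folds are empty")
    return counts


def rank_by_frequency(counts, n_union: int | None = None,
                      tiebreak: dict | None = None) -> RankedGeneList:
    """Relative-frequency ranking: score ``F_i / N_union``.

    ``N_union`` defaults to the number of distinct selected genes.  The
    scores generally do not sum to 1 (they are per-gene frequencies over
    the union size, not a distribution).
    """
    if not counts:
        raise ValueError("empty selection counts")
    if n_union is None:
        n_union = len(counts)
    if n_union <= 0:
        raise ValueError("union size must be positive")
    scores = {g: f / n_union for g, f in dict(counts).items()}
    return _sorted_ranking(scores, "MGS_f", tiebreak)


def rank_from_scores(scores: dict, method: str,
                     tiebreak: dict | None = None) -> RankedGeneList:
    """Sort externally supplied per-gene scores into a ranked list."""
    if not scores:
        raise ValueError("empty score table")
    return _sorted_ranking({g: float(s) for g, s in scores.items()}, method, tiebreak)


def _entropy_bits(labels) -> float:
    _, counts = np.unique(np.asarray(labels), return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def weighted_information_gain(parent_labels, left_labels, right_labels,
                              n_total: int) -> float:
    """Weighted IG of one split, in bits.

    ``(N_t/N) [H(parent) - (N_L/N_t) H(left) - (N_R/N_t) H(right)]``
    where ``N_t`` is the parent size and ``N`` the total sample count.
    The two children must partition the parent.
    """
    parent = np.asarray(parent_labels)
    left = np.asarray(left_labels)
    right = np.asarray(right_labels)
    if parent.size == 0:
        raise ValueError("empty parent node")
    if left.size + right.size != parent.size:
        raise ValueError("children must partition the parent")
    if n_total < parent.size:
        raise ValueError("n_total smaller than the parent node")
    nt = parent.size
    gain = _entropy_bits(parent)
    if left.size:
        gain -= left.size / nt * _entropy_bits(left)
    if right.size:
        gain -= right.size / nt * _entropy_bits(right)
    return nt / n_total * gain


def forest_node_records(forest: RandomForestClassifier, gene_ids) -> list:
    """Collect every internal node of a fitted forest as a record.

    Relies on the entropy split criterion, whose node impurity is the
    class entropy in bits, so the per-node weighted IG realizes the
    formula above with bootstrap sample weights.
    """
    records = []
    for est in forest.estimators_:
        t = est.tree_
        n_root = t.weighted_n_node_samples[0]
        for node in range(t.node_count):
            left, right = t.children_left[node], t.children_right[node]
            if left == -1:
                continue
            nt = t.weighted_n_node_samples[node]
            gain = t.impurity[node]
            gain -= t.weighted_n_node_samples[left] / nt * t.impurity[left]
            gain -= t.weighted_n_node_samples[right] / nt * t.impurity[right]
            wig = max(nt / n_root * gain, 0.0)
            records.append(ForestNodeRecord(gene_ids[t.feature[node]], float(wig)))
    return records


def rank_by_forest(X, labels, gene_ids, n_trees: int = 300, seed: int = 0,
                   tiebreak: dict | None = None,
                   max_features="sqrt") -> RankedGeneList:
    """Mean-weighted-IG ranking from an entropy random forest.

    ``X`` is samples x genes restricted to the union of selections.  A
    gene's score is the mean weighted IG over the forest nodes that
    split on it (0 if it is never split on).
    """
    y = np.asarray(labels)
    if np.unique(y).size < 2:
        raise ValueError("forest ranking needs at least two classes")
    if len(gene_ids) == 0:
        raise ValueError("empty gene set")
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        criterion="entropy",
        bootstrap=True,
        max_features=max_features,
        random_state=seed,
    )
    forest.fit(np.asarray(X, dtype=float), y)
    records = forest_node_records(forest, list(gene_ids))
    totals: dict = {g: 0.0 for g in gene_ids}
    hits: dict = {g: 0 for g in gene_ids}
    for rec in records:
        totals[rec.gene_id] += rec.weighted_ig
        hits[rec.gene_id] += 1
    scores = {g: (totals[g] / hits[g] if hits[g] else 0.0) for g in gene_ids}
    return _sorted_ranking(scores, "MGS_rf", tiebreak)


def top_eta(ranked: RankedGeneList, eta: int) -> list:
    """The top ``eta`` genes of a ranking (all of them if fewer exist)."""
    if eta < 1:
        raise ValueError(f"eta must be >= 1, got {eta}")
    return list(ranked.genes[:eta])
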