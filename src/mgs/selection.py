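"""Incremental gene selection by relevance and complementary information.

The procedure has two stages.

Screening: every gene is discretized at levels ``2 .. max_d`` in order
and kept as a candidate at the *first* level whose bias-corrected
relevance exceeds its chi-square critical value (the minimal significant
granularity).  Genes that never pass are excluded.

Selection: candidates are sorted by decreasing relevance; the top one
seeds the selected set.  Each remaining candidate is re-scored by the
composite criterion (relevance plus mean bias-corrected conditional MI
with the already-selected genes, given the class) over a small sweep of
levels around its screening level, and admitted when the score clears
the chi-square threshold for at least one level in the sweep.  There is
no redundancy penalty: an exact copy of an already-selected gene is
retained, because its conditional-MI term can only help.

The published pseudocode for the second stage contains an accept-always
quirk (a candidate whose test never passes is still admitted because its
positive relevance beats the zero-initialized threshold); the default
here is the strict reading (admit only on a passed test), with
``literal_algorithm1`` reproducing the pseudocode verbatim.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .data_io import ExpressionDataset
from .mi_core import (
    LN2,
    DiscretizedGene,
    MiTestConfig,
    _chi2_ppf,
    _cmi_from_counts,
    _mi_from_counts,
    chi2_critical_mi,
    discretize,
    discretize_matrix,
    mi_profile,
    relevance_bias,
)


@dataclass(frozen=True)
class CandidateGene:
    """A gene that passed screening (or was selected).

    ``score`` is the bias-corrected relevance at screening time and the
    composite selection score after admission; ``relevance`` always
    keeps the screening-stage relevance (used later for rank
    tie-breaking).
    """

    gene_index: int
    d: int
    score: float
    relevance: float = float("nan")


@dataclass
class SelectionResult:
    """The ordered selected subset of one (cross-validation) fold."""

    selected: list
    fold_id: int = 0
    n_candidates: int = 0
    config: MiTestConfig = field(default_factory=MiTestConfig)

    @property
    def gene_indices(self) -> list:
        return [c.gene_index for c in self.selected]

    def gene_ids(self, ds: ExpressionDataset) -> list:
        return [ds.gene_ids[c.gene_index] for c in self.selected]

    def to_dict(self, ds: ExpressionDataset | None = None) -> dict:
        out = {
            "fold_id": self.fold_id,
            "n_candidates": self.n_candidates,
            "config": asdict(self.config),
            "selected": [asdict(c) for c in self.selected],
        }
        if ds is not None:
            for entry, c in zip(out["selected"], self.selected):
                entry["gene_id"] = ds.gene_ids[c.gene_index]
        return out

    def to_json(self, path, ds: ExpressionDataset | None = None) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(ds), fh, indent=2)


def _fast_mi(xb: np.ndarray, dx: int, yi: np.ndarray, k: int) -> float:
    counts = np.bincount(xb * k + yi, minlength=dx * k).reshape(dx, k).astype(float)
    return _mi_from_counts(counts)


def _fast_cmi(xb, dx, sb, ds_, yi, k) -> float:
    counts = (
        np.bincount((xb * ds_ + sb) * k + yi, minlength=dx * ds_ * k)
        .reshape(dx, ds_, k)
        .astype(float)
    )
    return _cmi_from_counts(counts)


def screen_candidates(ds: ExpressionDataset, cfg: MiTestConfig | None = None) -> list:
    """Relevance screening at the minimal significant discretization level.

    Returns one :class:`CandidateGene` per passing gene, in original
    gene order.  Genes whose relevance never clears the chi-square
    threshold at any level ``2 .. max_d`` are excluded; constant genes
    can never pass (zero degrees of freedom).
    """
    cfg = cfg or MiTestConfig()
    X = ds.values_imputed()
    y = ds.labels
    n = ds.n_samples
    k = ds.n_classes
    g = ds.n_genes
    chosen_d = np.full(g, -1, dtype=int)
    chosen_score = np.zeros(g)
    undecided = np.ones(g, dtype=bool)
    for d in range(2, cfg.max_d + 1):
        if not undecided.any():
            break
        idx = np.where(undecided)[0]
        if cfg.scheme == "equal-width":
            bins = discretize_matrix(X[idx], d)
        else:
            bins = np.vstack([discretize(X[i], d, cfg.scheme).bins for i in idx])
        mi, occ = mi_profile(bins, y, d)
        df = (occ - 1) * (k - 1)
        bias = df / (2.0 * n * LN2)
        score = mi - bias
        crit = np.array([
            chi2_critical_mi(f, cfg.alpha, n, cfg.critical_scale) if f > 0 else np.inf
            for f in df
        ])
        passed = score > crit
        hit = idx[passed]
        chosen_d[hit] = d
        chosen_score[hit] = score[passed]
        undecided[hit] = False
    return [
        CandidateGene(gene_index=int(i), d=int(chosen_d[i]),
                      score=float(chosen_score[i]), relevance=float(chosen_score[i]))
        for i in np.where(chosen_d > 0)[0]
    ]


def select_subset(candidates: list, ds: ExpressionDataset,
                  cfg: MiTestConfig | None = None, fold_id: int = 0) -> SelectionResult:
    """Greedy complementary-information selection over screened candidates.

    Candidates are visited in decreasing-relevance order (ties broken by
    original gene index); the top one seeds the selected set.  For every
    other candidate the composite score is evaluated at levels
    ``d - delta .. d + delta`` (clamped to ``[2, max_d]``); the gene is
    admitted when the score exceeds its chi-square critical value for at
    least one level, storing the score-maximizing passing level.  In
    ``literal_algorithm1`` mode the last passing level is kept and a
    candidate with no passing level is still admitted when its screening
    relevance is positive, matching the published pseudocode verbatim.
    """
    cfg = cfg or MiTestConfig()
    if not candidates:
        raise ValueError("no significant genes: candidate list is empty")
    order = sorted(candidates, key=lambda c: (-c.score, c.gene_index))
    X = ds.values_imputed()
    y = ds.labels
    _, yi = np.unique(y, return_inverse=True)
    n = ds.n_samples
    k = ds.n_classes

    seed = order[0]
    seed_disc = discretize(X[seed.gene_index], seed.d, cfg.scheme)
    selected = [CandidateGene(seed.gene_index, seed.d, seed.score, seed.relevance)]
    partners = [(seed_disc.bins, seed.d, seed_disc.occupied)]

    for cand in order[1:]:
        lo = max(2, cand.d - cfg.delta)
        hi = min(cfg.max_d, cand.d + cfg.delta)
        best_level, best_score = -1, -np.inf
        last_level, last_score, last_crit = -1, -np.inf, 0.0
        any_passed = False
        for level in range(lo, hi + 1):
            dg = discretize(X[cand.gene_index], level, cfg.scheme)
            i_occ = dg.occupied
            df = (i_occ - 1) * (k - 1)
            if df <= 0:
                continue
            score = _fast_mi(dg.bins, level, yi, k) - relevance_bias(i_occ, k, n)
            df_comp = 0.0
            comp = 0.0
            for sb, sd, s_occ in partners:
                comp += _fast_cmi(dg.bins, level, sb, sd, yi, k)
                comp -= (i_occ - 1) * (s_occ - 1) * k / (2.0 * n * LN2)
                df_comp += (i_occ - 1) * (s_occ - 1) * k
            m = len(partners)
            score += comp / m
            df_total = df + df_comp / m
            q = _chi2_ppf(cfg.alpha, float(df_total))
            if cfg.critical_scale == "corrected":
                q = q - df_total
            crit = q / (2.0 * n * LN2)
            if score > crit:
                any_passed = True
                last_level, last_score, last_crit = level, score, crit
                if score > best_score:
                    best_level, best_score = level, score
        if cfg.literal_algorithm1:
            admit = (last_score if any_passed else cand.score) > (last_crit if any_passed else 0.0)
            level, score = (last_level, last_score) if any_passed else (cand.d, cand.score)
        else:
            admit = any_passed
            level, score = best_level, best_score
        if admit:
            dg = discretize(X[cand.gene_index], level, cfg.scheme)
            selected.append(CandidateGene(cand.gene_index, level, float(score),
                                          cand.relevance))
            partners.append((dg.bins, level, dg.occupied))
    return SelectionResult(selected=selected, fold_id=fold_id,
                           n_candidates=len(candidates), config=cfg)


def select_genes(ds: ExpressionDataset, cfg: MiTestConfig | None = None,
                 fold_id: int = 0) -> SelectionResult:
    """Screening followed by selection in one call."""
    cfg = cfg or MiTestConfig()
    candidates = screen_candidates(ds, cfg)
    return select_subset(candidates, ds, cfg, fold_id=fold_id)
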