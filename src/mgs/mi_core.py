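"""Discretization, information measures, and finite-sample significance thresholds.

All information quantities are expressed in **bits** (base-2 logarithms).
The central statistical fact used throughout: for two discrete variables
that are actually independent, the statistic ``2 N ln2 * MI`` (the
likelihood-ratio / G statistic) is asymptotically chi-square distributed
with ``(I - 1)(K - 1)`` degrees of freedom, where ``I`` and ``K`` are the
numbers of occupied levels.  Two consequences drive the design:

* the empirical MI of independent variables is biased upward by the
  chi-square mean, ``df / (2 N ln 2)`` bits — subtracting it centres the
  null ("bias correction");
* a chi-square quantile converted to the same bit scale gives a
  significance threshold that needs no hand-tuned cut-off.

Relevance of a gene to the class is its bias-corrected MI after
discretization; complementary information of a gene with respect to an
already-selected gene is their bias-corrected conditional MI given the
class.  The composite selection score adds the relevance and the mean
complementary term over the selected set — deliberately with no
redundancy penalty, since co-regulated genes may be both correlated and
individually informative.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.stats import chi2 as _chi2

LN2 = float(np.log(2.0))

_SCHEMES = ("equal-width", "equal-frequency")
_SCALES = ("corrected", "literal")


@dataclass(frozen=True)
class MiTestConfig:
    """Knobs of the information-theoretic selection machinery.

    alpha
        Significance level of every chi-square test (both the relevance
        screen and the composite selection test).
    max_d
        Largest discretization level tried when screening a gene.
    delta
        Half-width of the level sweep around a gene's screening level
        during the selection stage (levels ``d - delta .. d + delta``,
        clamped to ``[2, max_d]``).
    scheme
        Binning scheme: ``equal-width`` (default) or ``equal-frequency``.
    critical_scale
        ``corrected`` compares the bias-corrected statistic against
        ``(chi2_q - df) / (2 N ln 2)``, which is algebraically the
        standard raw-scale chi-square test; ``literal`` compares against
        ``chi2_q / (2 N ln 2)`` (no null-mean subtraction).
    literal_algorithm1
        Reproduce the published pseudocode verbatim in the selection
        stage, including its always-accept quirk (see ``selection``).
    """

    alpha: float = 0.05
    max_d: int = 10
    delta: int = 2
    scheme: str = "equal-width"
    critical_scale: str = "corrected"
    literal_algorithm1: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.max_d < 2:
            raise ValueError(f"max_d must be >= 2, got {self.max_d}")
        if self.delta < 0:
            raise ValueError(f"delta must be >= 0, got {self.delta}")
        if self.scheme not in _SCHEMES:
            raise ValueError(f"scheme must be one of {_SCHEMES}")
        if self.critical_scale not in _SCALES:
            raise ValueError(f"critical_scale must be one of {_SCALES}")


@dataclass(frozen=True)
class DiscretizedGene:
    """A gene's expression mapped to integer bins.

    ``bins`` holds one bin index in ``0..d-1`` per sample, ``edges`` the
    ``d + 1`` strictly increasing bin boundaries.  ``occupied`` counts
    the levels that actually received samples; it is what enters the
    degrees of freedom of every chi-square null.
    """

    bins: np.ndarray
    d: int
    edges: np.ndarray

    @property
    def occupied(self) -> int:
        return int(np.unique(self.bins).size)


def _as_bins(x) -> np.ndarray:
    if isinstance(x, DiscretizedGene):
        return x.bins
    return np.asarray(x)


def discretize(values, d: int, scheme: str = "equal-width") -> DiscretizedGene:
    """Map a real vector to ``d`` bins.

    Equal-width bins span the observed ``[min, max]``; the maximum value
    is assigned to the top bin.  A constant vector maps every sample to
    bin 0.  Equal-frequency places edges at empirical quantiles (edges
    are deduplicated, so heavily tied data may occupy fewer levels).
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot discretize an empty vector")
    if not np.all(np.isfinite(v)):
        raise ValueError("discretize requires finite values (impute missing data first)")
    if d < 2:
        raise ValueError(f"discretization level must be >= 2, got {d}")
    lo, hi = float(v.min()), float(v.max())
    if scheme == "equal-width":
        width = (hi - lo) / d if hi > lo else 1.0
        edges = lo + width * np.arange(d + 1)
        bins = np.clip(np.floor((v - lo) / width).astype(np.int64), 0, d - 1)
    elif scheme == "equal-frequency":
        qs = np.quantile(v, np.linspace(0.0, 1.0, d + 1))
        inner = np.unique(qs[1:-1])
        span = hi - lo if hi > lo else 1.0
        edges = np.concatenate(([lo], inner, [hi if hi > lo else lo + span]))
        if edges.size < 2:
            edges = np.array([lo, lo + span])
        bins = np.searchsorted(edges[1:-1], v, side="right").astype(np.int64)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    return DiscretizedGene(bins=bins, d=d, edges=edges)


def discretize_matrix(X: np.ndarray, d: int) -> np.ndarray:
    """Row-wise equal-width binning of a genes x samples matrix."""
    X = np.asarray(X, dtype=float)
    lo = X.min(axis=1, keepdims=True)
    hi = X.max(axis=1, keepdims=True)
    width = (hi - lo) / d
    width[width == 0.0] = 1.0
    return np.clip(np.floor((X - lo) / width).astype(np.int64), 0, d - 1)


def entropy_bits(labels) -> float:
    """Shannon entropy of a discrete vector, in bits."""
    y = np.asarray(labels)
    if y.size == 0:
        raise ValueError("entropy of an empty vector is undefined")
    _, counts = np.unique(y, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _mi_from_counts(counts: np.ndarray) -> float:
    """MI in bits from a 2-D contingency table of counts."""
    n = counts.sum()
    pxy = counts / n
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    nz = pxy > 0
    val = float((pxy[nz] * np.log2(pxy[nz] / (px * py)[nz])).sum())
    return max(val, 0.0)


def _cmi_from_counts(counts: np.ndarray) -> float:
    """Conditional MI in bits from a 3-D (x, y, z) contingency table."""
    n = counts.sum()
    p = counts / n
    pz = p.sum(axis=(0, 1))
    pxz = p.sum(axis=1)
    pyz = p.sum(axis=0)
    denom = pxz[:, None, :] * pyz[None, :, :]
    nz = p > 0
    val = float((p[nz] * np.log2((p * pz[None, None, :])[nz] / denom[nz])).sum())
    return max(val, 0.0)


def mutual_information(x, y) -> float:
    """Empirical MI between two discrete vectors, in bits.

    Accepts raw integer vectors or :class:`DiscretizedGene` on either
    side.  Computed from the joint histogram; always non-negative and
    bounded by ``min(H(X), H(Y))``.
    """
    xb, yb = _as_bins(x), _as_bins(y)
    if xb.shape != yb.shape:
        raise ValueError(f"length mismatch: {xb.shape} vs {yb.shape}")
    _, xi = np.unique(xb, return_inverse=True)
    _, yi = np.unique(yb, return_inverse=True)
    nx, ny = int(xi.max()) + 1, int(yi.max()) + 1
    counts = np.bincount(xi * ny + yi, minlength=nx * ny).reshape(nx, ny).astype(float)
    return _mi_from_counts(counts)


def conditional_mutual_information(x, y, z) -> float:
    """Empirical conditional MI ``I(X; Y | Z)`` in bits."""
    xb, yb, zb = _as_bins(x), _as_bins(y), np.asarray(z)
    if not (xb.shape == yb.shape == zb.shape):
        raise ValueError("length mismatch among x, y, z")
    _, xi = np.unique(xb, return_inverse=True)
    _, yi = np.unique(yb, return_inverse=True)
    _, zi = np.unique(zb, return_inverse=True)
    nx, ny, nz = int(xi.max()) + 1, int(yi.max()) + 1, int(zi.max()) + 1
    counts = (
        np.bincount((xi * ny + yi) * nz + zi, minlength=nx * ny * nz)
        .reshape(nx, ny, nz)
        .astype(float)
    )
    return _cmi_from_counts(counts)


def relevance_bias(i_levels: int, k_classes: int, n: int) -> float:
    """Null mean of the relevance MI: ``(I-1)(K-1) / (2 N ln 2)`` bits."""
    if i_levels < 1 or k_classes < 1 or n < 1:
        raise ValueError("level/class counts and N must be >= 1")
    return (i_levels - 1) * (k_classes - 1) / (2.0 * n * LN2)


def complementary_bias(i_levels: int, j_levels: int, k_classes: int, n: int) -> float:
    """Null mean of the conditional MI: ``(I-1)(J-1)K / (2 N ln 2)`` bits."""
    if i_levels < 1 or j_levels < 1 or k_classes < 1 or n < 1:
        raise ValueError("level/class counts and N must be >= 1")
    return (i_levels - 1) * (j_levels - 1) * k_classes / (2.0 * n * LN2)


def j_rel(gene, labels, d: int, scheme: str = "equal-width") -> float:
    """Bias-corrected relevance of a gene at discretization level ``d``.

    ``I(g^d; C) - (I-1)(K-1)/(2 N ln 2)`` with ``I`` the occupied level
    count of the discretized gene.
    """
    y = np.asarray(labels)
    dg = discretize(gene, d, scheme)
    n = y.size
    k = int(np.unique(y).size)
    return mutual_information(dg, y) - relevance_bias(dg.occupied, k, n)


@lru_cache(maxsize=4096)
def _chi2_ppf(alpha: float, df: float) -> float:
    return float(_chi2.ppf(1.0 - alpha, df))


def chi2_critical_mi(df: float, alpha: float, n: int, scale: str = "corrected") -> float:
    """Chi-square critical value converted to the bit scale of the scores.

    On the default ``corrected`` scale the null mean ``df`` is subtracted
    from the chi-square quantile so that comparing a *bias-corrected*
    score against the returned threshold is algebraically identical to
    the ordinary raw-scale test ``2 N ln2 * MI > chi2_q``.  The
    ``literal`` scale omits the subtraction.
    """
    if df <= 0:
        raise ValueError(f"degrees of freedom must be > 0, got {df}")
    if scale not in _SCALES:
        raise ValueError(f"scale must be one of {_SCALES}")
    q = _chi2_ppf(alpha, float(df))
    if scale == "corrected":
        q = q - df
    return q / (2.0 * n * LN2)


def j_mgs_with_df(gene, labels, d: int, selected, scheme: str = "equal-width"):
    """Composite selection score and its degrees of freedom.

    The score is the bias-corrected relevance plus the mean, over the
    already-selected genes, of the bias-corrected conditional MI given
    the class.  The df mirrors the construction: relevance df plus the
    mean of the per-partner complementary dfs.
    """
    if not selected:
        raise ValueError("selected set must be non-empty (seed genes use j_rel alone)")
    y = np.asarray(labels)
    n = y.size
    k = int(np.unique(y).size)
    dg = discretize(gene, d, scheme)
    i = dg.occupied
    score = mutual_information(dg, y) - relevance_bias(i, k, n)
    comp = 0.0
    df_comp = 0.0
    for s in selected:
        j = s.occupied
        comp += conditional_mutual_information(dg, s, y) - complementary_bias(i, j, k, n)
        df_comp += (i - 1) * (j - 1) * k
    m = len(selected)
    score += comp / m
    df = (i - 1) * (k - 1) + df_comp / m
    return score, df


def j_mgs(gene, labels, d: int, selected, scheme: str = "equal-width") -> float:
    """Composite selection score (relevance + mean complementary term)."""
    score, _ = j_mgs_with_df(gene, labels, d, selected, scheme)
    return score


def mi_profile(bins: np.ndarray, labels: np.ndarray, d: int):
    """Vectorized per-row MI with the labels plus occupied level counts.

    ``bins`` is a genes x samples integer matrix with values in
    ``0..d-1``.  Returns ``(mi_bits, occupied)`` arrays of length
    ``n_genes``.  Used by the screening stage, where thousands of genes
    are tested at once.
    """
    y = np.asarray(labels)
    classes, yi = np.unique(y, return_inverse=True)
    k = classes.size
    n = y.size
    onehot = np.zeros((n, k))
    onehot[np.arange(n), yi] = 1.0
    counts = np.stack([(bins == b).astype(float) @ onehot for b in range(d)], axis=1)
    pxy = counts / n
    px = pxy.sum(axis=2, keepdims=True)
    py = pxy.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = pxy * np.log2(pxy / (px * py))
    mi = np.nansum(terms, axis=(1, 2))
    occupied = (counts.sum(axis=2) > 0).sum(axis=1)
    return np.maximum(mi, 0.0), occupied.astype(int)
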