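"""Synthetic expression data with known ground truth.

The generator caricatures a two-class expression study: thousands of
genes, tens of samples, and four gene roles —

* **informative** genes whose mean shifts with the class label;
* **redundant** genes, noisy copies of an informative parent (they carry
  real class signal despite being correlated with their parent, and a
  sound selector must keep them);
* **complementary** pairs: two coin-like genes individually independent
  of the label but jointly determining it (the label is their XOR), which
  only a conditional-information criterion can reward;
* pure **noise** genes independent of everything.

Every gene's role is recorded, so selection power, false-positive rates
and the retention of complementary partners are all directly measurable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field

import numpy as np

from .data_io import ExpressionDataset


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator parameters.

    Defaults describe a desk-scale two-class study: 60 samples, balanced
    classes, 10 informative genes with a 1.5-SD class shift, 2 redundant
    copies per informative gene (additive noise SD 0.3), 3 complementary
    (XOR) pairs, and 2000 noise genes.
    """

    n_samples: int = 60
    class_balance: float = 0.5
    n_informative: int = 10
    effect_size: float = 1.5
    n_redundant_per_informative: int = 2
    redundancy_noise: float = 0.3
    n_complementary_pairs: int = 3
    n_noise: int = 2000
    xor_jitter: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("need at least 2 samples")
        if not 0.0 < self.class_balance < 1.0:
            raise ValueError("class_balance must be in (0, 1)")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if min(self.n_informative, self.n_redundant_per_informative,
               self.n_complementary_pairs, self.n_noise) < 0:
            raise ValueError("gene counts must be >= 0")


@dataclass
class GroundTruth:
    """Which synthetic gene plays which role."""

    informative: list = field(default_factory=list)
    redundant: list = field(default_factory=list)
    complementary: list = field(default_factory=list)
    noise: list = field(default_factory=list)
    parent_of: dict = field(default_factory=dict)
    pairs: list = field(default_factory=list)

    def role_of(self, gene_id) -> str:
        for role in ("informative", "redundant", "complementary", "noise"):
            if gene_id in set(getattr(self, role)):
                return role
        raise KeyError(gene_id)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def generate(spec: SyntheticSpec | None = None):
    """Generate an :class:`ExpressionDataset` plus its ground truth.

    Labels are Bernoulli(class_balance) (redrawn, deterministically from
    the same stream, in the degenerate case of a single observed class).
    Informative genes are standard normal plus ``effect_size * label``;
    redundant genes add ``N(0, redundancy_noise)`` to their parent;
    complementary pairs are jittered +-1 coins whose XOR equals the
    label; noise genes are standard normal.
    """
    spec = spec or SyntheticSpec()
    total = (spec.n_informative * (1 + spec.n_redundant_per_informative)
             + 2 * spec.n_complementary_pairs + spec.n_noise)
    if total == 0:
        raise ValueError("the spec describes zero genes")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    labels = (rng.random(n) < spec.class_balance).astype(int)
    while np.unique(labels).size < 2:
        labels = (rng.random(n) < spec.class_balance).astype(int)

    rows = []
    gene_ids: list = []
    truth = GroundTruth()
    for i in range(spec.n_informative):
        gid = f"inf{i + 1}"
        base = rng.normal(size=n) + spec.effect_size * labels
        rows.append(base)
        gene_ids.append(gid)
        truth.informative.append(gid)
        for r in range(spec.n_redundant_per_informative):
            rid = f"red{i + 1}_{r + 1}"
            rows.append(base + rng.normal(scale=spec.redundancy_noise, size=n))
            gene_ids.append(rid)
            truth.redundant.append(rid)
            truth.parent_of[rid] = gid
    for p in range(spec.n_complementary_pairs):
        a = rng.integers(0, 2, size=n)
        b = a ^ labels  # XOR(a, b) == label by construction
        ida, idb = f"xor{p + 1}a", f"xor{p + 1}b"
        jitter = spec.xor_jitter
        rows.append((2 * a - 1) + rng.normal(scale=jitter, size=n))
        rows.append((2 * b - 1) + rng.normal(scale=jitter, size=n))
        gene_ids.extend([ida, idb])
        truth.complementary.extend([ida, idb])
        truth.pairs.append([ida, idb])
    for j in range(spec.n_noise):
        gid = f"noise{j + 1}"
        rows.append(rng.normal(size=n))
        gene_ids.append(gid)
        truth.noise.append(gid)

    ds = ExpressionDataset.from_arrays(
        np.vstack(rows), labels, gene_ids=gene_ids,
        label_names=["control", "disease"],
    )
    return ds, truth


def separable_dataset(n_samples: int = 40, n_signal: int = 5, n_noise: int = 25,
                      signal_noise: float = 0.05, seed: int = 0):
    """A trivially separable fixture: ``n_signal`` genes track the label.

    Each signal gene is ``2 * label + N(0, signal_noise)`` — the classes
    are linearly separable by any single signal gene — plus independent
    standard-normal noise genes.  Returns (dataset, signal gene ids).
    """
    rng = np.random.default_rng(seed)
    labels = np.array([0, 1] * (n_samples // 2) + [0] * (n_samples % 2))
    rows = [2.0 * labels + rng.normal(scale=signal_noise, size=n_samples)
            for _ in range(n_signal)]
    rows += [rng.normal(size=n_samples) for _ in range(n_noise)]
    gene_ids = [f"sig{i + 1}" for i in range(n_signal)]
    gene_ids += [f"noise{j + 1}" for j in range(n_noise)]
    ds = ExpressionDataset.from_arrays(np.vstack(rows), labels, gene_ids=gene_ids,
                                       label_names=["control", "disease"])
    return ds, gene_ids[:n_signal]
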