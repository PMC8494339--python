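"""Reading, writing and preprocessing of expression matrices.

The on-disk layout mirrors the usual CSV export of a GEO-style series:
genes as rows with a probe-id column and a gene-symbol column followed
by one column per sample, plus a small companion labels CSV mapping
``sample_id -> class``.  A transposed (samples-as-rows) orientation is
also accepted.

Preprocessing follows the common microarray convention: probes mapping
to the same gene symbol are collapsed by their per-sample arithmetic
mean, and genes with no expression value in any sample are dropped.
Class strings are mapped to integer codes in sorted order, so the
mapping is deterministic regardless of row order in the labels file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd


@dataclass
class ExpressionDataset:
    """A genes x samples expression matrix with per-sample class labels.

    ``expression`` may contain NaN for missing cells; ``labels`` holds
    integer class codes ``0..K-1`` and ``label_names`` the class string
    for each code.
    """

    expression: np.ndarray
    gene_ids: list
    sample_ids: list
    labels: np.ndarray
    probe_ids: list | None = None
    label_names: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.expression = np.asarray(self.expression, dtype=float)
        self.labels = np.asarray(self.labels)
        g, n = self.expression.shape
        if len(self.gene_ids) != g:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {g} expression rows")
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} columns")
        if self.labels.size != n:
            raise ValueError(f"{self.labels.size} labels for {n} samples")

    @property
    def n_genes(self) -> int:
        return self.expression.shape[0]

    @property
    def n_samples(self) -> int:
        return self.expression.shape[1]

    @property
    def n_classes(self) -> int:
        return int(np.unique(self.labels).size)

    @classmethod
    def from_arrays(cls, expression, labels, gene_ids=None, sample_ids=None,
                    label_names=None) -> "ExpressionDataset":
        expression = np.asarray(expression, dtype=float)
        g, n = expression.shape
        if gene_ids is None:
            gene_ids = [f"g{i + 1}" for i in range(g)]
        if sample_ids is None:
            sample_ids = [f"s{j + 1}" for j in range(n)]
        labels = np.asarray(labels)
        if label_names is None:
            label_names = [str(c) for c in np.unique(labels)]
        return cls(expression=expression, gene_ids=list(gene_ids),
                   sample_ids=list(sample_ids), labels=labels,
                   label_names=list(label_names))

    def values_imputed(self, impute: bool = True) -> np.ndarray:
        """Expression matrix with missing cells filled by per-gene medians.

        Median over the observed values of each gene; deterministic and
        robust to outliers.  With ``impute=False`` the raw matrix (NaN
        included) is returned.
        """
        X = self.expression
        if not impute or not np.isnan(X).any():
            return X.copy()
        X = X.copy()
        nan_rows = np.where(np.isnan(X).any(axis=1))[0]
        for i in nan_rows:
            row = X[i]
            obs = row[~np.isnan(row)]
            if obs.size == 0:
                raise ValueError(
                    f"gene {self.gene_ids[i]!r} has no observed values; "
                    "run drop_empty_genes first"
                )
            row[np.isnan(row)] = np.median(obs)
        return X

    def subset_samples(self, idx) -> "ExpressionDataset":
        idx = np.asarray(idx)
        return replace(
            self,
            expression=self.expression[:, idx],
            sample_ids=[self.sample_ids[i] for i in idx],
            labels=self.labels[idx],
        )

    def subset_genes(self, idx) -> "ExpressionDataset":
        idx = np.asarray(idx)
        return replace(
            self,
            expression=self.expression[idx, :],
            gene_ids=[self.gene_ids[i] for i in idx],
            probe_ids=None if self.probe_ids is None
            else [self.probe_ids[i] for i in idx],
        )


def _parse_numeric(frame: pd.DataFrame, path) -> np.ndarray:
    """Convert a string-valued expression block to float, NaN for blanks.

    A non-empty cell that fails numeric conversion raises with its
    (row-label, column) coordinates.
    """
    raw = frame.to_numpy(dtype=object)
    out = np.empty(raw.shape, dtype=float)
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            cell = raw[i, j]
            if cell is None or (isinstance(cell, float) and np.isnan(cell)):
                out[i, j] = np.nan
                continue
            s = str(cell).strip()
            if s == "" or s.lower() in ("na", "nan", "null"):
                out[i, j] = np.nan
                continue
            try:
                out[i, j] = float(s)
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric expression value {s!r} at "
                    f"row {frame.index[i]!r}, column {frame.columns[j]!r}"
                ) from None
    return out


def read_labels_csv(path) -> dict:
    """Read a companion labels CSV with columns ``sample_id, class``."""
    df = pd.read_csv(path, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: labels file needs columns (sample_id, class)")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


def _encode_labels(class_of: dict, sample_ids: list):
    missing = [s for s in sample_ids if str(s) not in class_of]
    if missing:
        raise ValueError(f"missing labels for samples: {missing[:5]}")
    names = sorted(set(class_of[str(s)] for s in sample_ids))
    code = {c: i for i, c in enumerate(names)}
    labels = np.array([code[class_of[str(s)]] for s in sample_ids])
    return labels, names


def read_expression_csv(path, labels_path=None,
                        orientation: str = "genes-as-rows") -> ExpressionDataset:
    """Read an expression CSV plus its labels.

    ``genes-as-rows``: columns ``probe_id, gene_symbol, <sample...>``.
    ``samples-as-rows``: first column ``sample_id``, remaining column
    headers ``probe_id|gene_symbol`` (or a bare symbol).  Labels come
    from a companion CSV (``sample_id, class``) or, for genes-as-rows,
    from a reserved row whose probe id is ``class``.  Blank cells are
    recorded as missing, never as zero; the dataset is returned before
    any probe collapsing.
    """
    try:
        df = pd.read_csv(path, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas names the row itself
        raise ValueError(f"{path}: malformed CSV ({exc})") from exc
    if orientation == "genes-as-rows":
        if df.shape[1] < 3:
            raise ValueError(f"{path}: expected columns probe_id, gene_symbol, samples...")
        probe_col = df.iloc[:, 0].astype(str)
        class_row = probe_col.str.lower() == "class"
        inline = None
        if class_row.any():
            row = df.loc[class_row].iloc[0]
            inline = {str(c): str(row[c]) for c in df.columns[2:]}
            df = df.loc[~class_row]
        probes = df.iloc[:, 0].astype(str).tolist()
        symbols = df.iloc[:, 1].astype(str).tolist()
        sample_ids = [str(c) for c in df.columns[2:]]
        X = _parse_numeric(df.iloc[:, 2:], path)
        class_of = read_labels_csv(labels_path) if labels_path is not None else inline
    elif orientation == "samples-as-rows":
        sample_ids = df.iloc[:, 0].astype(str).tolist()
        cols = [str(c) for c in df.columns[1:]]
        probes = [c.split("|", 1)[0] for c in cols]
        symbols = [c.split("|", 1)[1] if "|" in c else c for c in cols]
        X = _parse_numeric(df.iloc[:, 1:], path).T
        class_of = read_labels_csv(labels_path) if labels_path is not None else None
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    if class_of is None:
        raise ValueError(f"{path}: no labels supplied (companion file or class row)")
    labels, names = _encode_labels(class_of, sample_ids)
    if len(names) < 2:
        raise ValueError(f"{path}: need at least 2 distinct class labels")
    return ExpressionDataset(
        expression=X,
        gene_ids=symbols,
        sample_ids=sample_ids,
        labels=labels,
        probe_ids=[[p] for p in probes],
        label_names=names,
    )


def write_expression_csv(ds: ExpressionDataset, path, labels_path=None) -> None:
    """Write the genes-as-rows CSV (and optionally the labels CSV).

    Values are printed with 17 significant digits so a write -> read
    round trip reproduces the matrix exactly.
    """
    probes = (
        [";".join(p) for p in ds.probe_ids]
        if ds.probe_ids is not None
        else list(ds.gene_ids)
    )
    out = pd.DataFrame(ds.expression, columns=ds.sample_ids)
    out.insert(0, "gene_symbol", ds.gene_ids)
    out.insert(0, "probe_id", probes)
    out.to_csv(path, index=False, float_format="%.17g")
    if labels_path is not None:
        names = ds.label_names or [str(c) for c in np.unique(ds.labels)]
        pd.DataFrame(
            {"sample_id": ds.sample_ids,
             "class": [names[c] for c in ds.labels]}
        ).to_csv(labels_path, index=False)


def collapse_probes(ds: ExpressionDataset) -> ExpressionDataset:
    """Merge probes sharing a gene symbol by their per-sample mean.

    The mean is unweighted across probes and computed over observed
    (non-missing) values only; a cell missing in every probe stays
    missing.  Symbols keep their first-occurrence order.  With no
    duplicate symbols this is the identity (probe provenance is still
    recorded).
    """
    order: list = []
    groups: dict = {}
    for i, sym in enumerate(ds.gene_ids):
        if sym not in groups:
            groups[sym] = []
            order.append(sym)
        groups[sym].append(i)
    rows = []
    provenance = []
    for sym in order:
        idx = groups[sym]
        block = ds.expression[idx, :]
        with np.errstate(invalid="ignore"):
            obs = (~np.isnan(block)).sum(axis=0)
            summed = np.nansum(block, axis=0)
        merged = np.where(obs > 0, summed / np.maximum(obs, 1), np.nan)
        rows.append(merged)
        if ds.probe_ids is not None:
            provenance.append([p for i in idx for p in ds.probe_ids[i]])
        else:
            provenance.append([sym])
    return replace(
        ds,
        expression=np.vstack(rows),
        gene_ids=order,
        probe_ids=provenance,
    )


def drop_empty_genes(ds: ExpressionDataset) -> ExpressionDataset:
    """Remove genes with no observed value in any sample.

    Genes with partial missingness are kept.  Raises if nothing
    survives.
    """
    keep = np.where(~np.isnan(ds.expression).all(axis=1))[0]
    if keep.size == 0:
        raise ValueError("no usable genes: every gene is entirely missing")
    return ds.subset_genes(keep)


def preprocess(ds: ExpressionDataset):
    """Collapse probes, then drop empty genes; returns (dataset, provenance).

    The provenance dict lists the probes merged into each symbol and the
    symbols dropped for having no expression values, and is meant to be
    written as a JSON sidecar next to the collapsed matrix.
    """
    collapsed = collapse_probes(ds)
    cleaned = drop_empty_genes(collapsed)
    dropped = sorted(set(collapsed.gene_ids) - set(cleaned.gene_ids))
    merged = {
        sym: probes
        for sym, probes in zip(collapsed.gene_ids, collapsed.probe_ids or [])
        if len(probes) > 1
    }
    provenance = {"merged_probes": merged, "dropped_genes": dropped}
    return cleaned, provenance


def write_provenance(provenance: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)
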