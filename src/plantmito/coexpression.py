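"""Gene co-expression features.

The working hypothesis: mitochondrial genes co-express with other
mitochondrial genes across many expression experiments.  Pearson
correlation matrices from individual datasets are combined meta-analytically
(Fisher z transform, inverse-variance weights n - 3) into meta-Pearson
correlation coefficients (meta-PCCs); a query gene is then summarized by the
fraction of positively labeled training genes among its top-K% most
co-expressed training genes, at K in {0.25, 0.5, 1, 2, 4}% — five KNN scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .seqdata import ProteinRecord

_CLAMP = 1.0 - 1e-6
DEFAULT_K_PERCENTS = (0.25, 0.5, 1.0, 2.0, 4.0)


class ExpressionError(ValueError):
    """Invalid expression data (negative values, bad shapes, bad manifest)."""


class MappingError(ValueError):
    """Conflicting protein-to-gene mapping rows."""


@dataclass
class ExpressionDataset:
    """One genes x samples expression matrix (log2 scale after transform)."""

    dataset_id: str
    genes: list[str]
    matrix: np.ndarray
    n_samples: int
    already_logged: bool = False

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.genes), self.n_samples):
            raise ExpressionError(
                f"{self.dataset_id}: matrix shape {self.matrix.shape} != "
                f"({len(self.genes)}, {self.n_samples})"
            )
        if self.n_samples < 2:
            raise ExpressionError(f"{self.dataset_id}: need at least 2 samples")
        if len(set(self.genes)) != len(self.genes):
            raise ExpressionError(f"{self.dataset_id}: duplicate gene identifiers")


@dataclass
class MetaCorrelationMatrix:
    """Symmetric meta-PCC matrix with per-pair dataset coverage counts.

    Entries for gene pairs covered by zero datasets are NaN; such pairs rank
    below all covered pairs during neighbor search rather than being imputed.
    """

    genes: list[str]
    values: np.ndarray  # symmetric, NaN where uncovered
    coverage: np.ndarray  # int counts, same shape

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.coverage = np.asarray(self.coverage, dtype=int)
        n = len(self.genes)
        if self.values.shape != (n, n) or self.coverage.shape != (n, n):
            raise ExpressionError("meta matrix shapes inconsistent with gene list")
        with np.errstate(invalid="ignore"):
            if np.nanmax(np.abs(self.values), initial=0.0) > 1 + 1e-9:
                raise ExpressionError("meta-PCC magnitudes exceed 1")

    def index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}


@dataclass
class KNNConfig:
    """Training gene labels and the neighborhood sizes for KNN scoring.

    ``k_percents`` are percentages of the training-set size; the neighbor
    count at each K is max(1, round-half-up(K/100 * N_train)).
    """

    training_genes: list[str]
    training_labels: list[str]  # "positive" / "negative", parallel to genes
    k_percents: tuple[float, ...] = DEFAULT_K_PERCENTS

    def __post_init__(self) -> None:
        if not self.training_genes:
            raise ExpressionError("empty training gene set")
        if len(self.training_genes) != len(self.training_labels):
            raise ExpressionError("training genes and labels differ in length")
        if any(not (0 < k < 100) for k in self.k_percents):
            raise ExpressionError("each K percent must be in (0, 100)")

    def neighbor_counts(self) -> list[int]:
        n = len(self.training_genes)
        return [max(1, math.floor(k / 100.0 * n + 0.5)) for k in self.k_percents]


def log2_transform(dataset: ExpressionDataset, pseudocount: float = 1.0) -> ExpressionDataset:
    """x -> log2(x + pseudocount); identity if the dataset is already logged."""
    if dataset.already_logged:
        return dataset
    if (dataset.matrix < 0).any():
        raise ExpressionError(
            f"{dataset.dataset_id}: negative values but already_logged is not set"
        )
    return replace(dataset, matrix=np.log2(dataset.matrix + pseudocount),
                   already_logged=True)


def pearson_matrix(dataset: ExpressionDataset) -> np.ndarray:
    """Pearson correlation per gene pair over samples.

    Zero-variance gene profiles yield NaN rows/columns (excluded pairs)
    rather than raising; the diagonal stays defined only for varying genes.
    """
    x = dataset.matrix
    sd = x.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x)
    r = np.atleast_2d(r)
    bad = sd == 0
    r[bad, :] = np.nan
    r[:, bad] = np.nan
    return np.clip(r, -1.0, 1.0)


def meta_combine(
    correlations: Sequence[np.ndarray],
    n_samples: Sequence[int],
    genes: Sequence[str],
) -> MetaCorrelationMatrix:
    """Combine per-dataset correlation matrices into meta-PCCs.

    Each r is Fisher z-transformed (|r| clamped at 1 - 1e-6 to avoid
    infinities), averaged with inverse-variance weights (n - 3), and mapped
    back with tanh.  Pairs covered by no dataset stay NaN.  All matrices must
    share the same gene order; datasets not covering a gene mark its
    rows/columns NaN.
    """
    if len(correlations) != len(n_samples):
        raise ExpressionError("one sample count per correlation matrix required")
    if not correlations:
        raise ExpressionError("no correlation matrices to combine")
    if all(n <= 3 for n in n_samples):
        raise ExpressionError("all datasets have n <= 3; inverse-variance weights vanish")
    g = len(genes)
    zsum = np.zeros((g, g))
    wsum = np.zeros((g, g))
    cover = np.zeros((g, g), dtype=int)
    for r, n in zip(correlations, n_samples):
        r = np.asarray(r, dtype=float)
        if r.shape != (g, g):
            raise ExpressionError("correlation matrix shape mismatch with gene list")
        if n <= 3:
            continue
        ok = np.isfinite(r)
        z = np.arctanh(np.clip(np.where(ok, r, 0.0), -_CLAMP, _CLAMP))
        w = float(n - 3)
        zsum += np.where(ok, w * z, 0.0)
        wsum += np.where(ok, w, 0.0)
        cover += ok.astype(int)
    with np.errstate(invalid="ignore", divide="ignore"):
        meta = np.tanh(zsum / wsum)
    meta[wsum == 0] = np.nan
    return MetaCorrelationMatrix(list(genes), meta, cover)


def build_meta_matrix(datasets: Sequence[ExpressionDataset]) -> MetaCorrelationMatrix:
    """Convenience pipeline: log2-transform, per-dataset Pearson, meta-combine.

    The gene universe is the union over datasets (sorted); genes absent from
    a dataset contribute nothing to its correlation matrix.
    """
    genes = sorted({g for d in datasets for g in d.genes})
    idx = {g: i for i, g in enumerate(genes)}
    corrs, ns = [], []
    for d in datasets:
        d = log2_transform(d)
        r_local = pearson_matrix(d)
        r_full = np.full((len(genes), len(genes)), np.nan)
        rows = np.array([idx[g] for g in d.genes])
        r_full[np.ix_(rows, rows)] = r_local
        corrs.append(r_full)
        ns.append(d.n_samples)
    return meta_combine(corrs, ns, genes)


def knn_scores(
    query_gene: str,
    meta: MetaCorrelationMatrix,
    config: KNNConfig,
) -> np.ndarray:
    """Five KNN co-expression scores for one query gene.

    Training genes are ranked by meta-PCC with the query (descending,
    correlation ties broken lexicographically by gene id, uncovered pairs
    below all covered ones, the query's own gene excluded); the score at each
    K is the positive fraction among the top k = max(1, round(K/100 * N))
    neighbors.  Callers substitute five zeros for queries absent from the
    meta matrix.
    """
    gidx = meta.index()
    if query_gene not in gidx:
        raise KeyError(f"query gene {query_gene!r} not in meta matrix")
    qi = gidx[query_gene]
    candidates = []
    for gene, label in zip(config.training_genes, config.training_labels):
        if gene == query_gene:
            continue  # never count the query itself
        ti = gidx.get(gene)
        r = meta.values[qi, ti] if ti is not None else np.nan
        covered = ti is not None and np.isfinite(r)
        candidates.append((0 if covered else 1, -(r if covered else 0.0), gene, label))
    if not candidates:
        raise ExpressionError("no training genes other than the query")
    candidates.sort()
    labels = np.array([c[3] == "positive" for c in candidates])
    scores = []
    for k in config.neighbor_counts():
        top = labels[: min(k, len(labels))]
        scores.append(top.mean())
    return np.array(scores)


def knn_score_table(
    records: Sequence[ProteinRecord],
    meta: MetaCorrelationMatrix,
    config: KNNConfig,
) -> dict[str, np.ndarray | None]:
    """KNN scores per record; None for records without a mapped/covered gene."""
    gidx = meta.index()
    out: dict[str, np.ndarray | None] = {}
    for r in records:
        if r.gene_id is None or r.gene_id not in gidx:
            out[r.id] = None
        else:
            out[r.id] = knn_scores(r.gene_id, meta, config)
    return out


def read_mapping_table(path: str | Path) -> dict[str, str]:
    """Read a 2-column (protein_id, gene_id) best-hit mapping table."""
    mapping: dict[str, str] = {}
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise MappingError(f"{path}:{i}: expected two columns")
        pid, gid = parts
        if pid in mapping and mapping[pid] != gid:
            raise MappingError(f"{path}:{i}: conflicting gene ids for {pid!r}")
        mapping[pid] = gid
    return mapping


def map_to_reference(
    records: Sequence[ProteinRecord],
    mapping: Mapping[str, str] | str | Path,
) -> list[ProteinRecord]:
    """Attach reference gene ids from a best-hit mapping table.

    Records without an entry keep ``gene_id`` absent; their co-expression
    block becomes five zeros downstream.
    """
    if not isinstance(mapping, Mapping):
        mapping = read_mapping_table(mapping)
    return [replace(r, gene_id=mapping.get(r.id, r.gene_id)) for r in records]


# --- delimited-text IO ------------------------------------------------------

def write_expression(path: str | Path, dataset: ExpressionDataset) -> None:
    df = pd.DataFrame(dataset.matrix, index=dataset.genes,
                      columns=[f"s{i+1}" for i in range(dataset.n_samples)])
    df.to_csv(path, sep="\t", index_label="gene")


def read_expression(path: str | Path, dataset_id: str,
                    already_logged: bool = False) -> ExpressionDataset:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionDataset(dataset_id, [str(g) for g in df.index],
                             df.to_numpy(float), df.shape[1],
                             already_logged=already_logged)


def read_manifest(path: str | Path) -> list[ExpressionDataset]:
    """Load datasets listed in a YAML manifest (dataset_id, path, n_samples,
    already_logged); paths are resolved relative to the manifest."""
    path = Path(path)
    entries = yaml.safe_load(path.read_text())
    datasets = []
    for e in entries:
        d = read_expression(path.parent / e["path"], e["dataset_id"],
                            already_logged=bool(e.get("already_logged", False)))
        if d.n_samples != int(e["n_samples"]):
            raise ExpressionError(
                f"{e['dataset_id']}: manifest says {e['n_samples']} samples, "
                f"file has {d.n_samples}"
            )
        datasets.append(d)
    return datasets


def write_meta_matrix(path: str | Path, meta: MetaCorrelationMatrix) -> None:
    df = pd.DataFrame(meta.values, index=meta.genes, columns=meta.genes)
    df.to_csv(path, sep="\t", index_label="gene")


def read_meta_matrix(path: str | Path) -> MetaCorrelationMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    values = df.to_numpy(float)
    coverage = np.isfinite(values).astype(int)
    return MetaCorrelationMatrix([str(g) for g in df.index], values, coverage)
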