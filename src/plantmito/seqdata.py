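"""Labeled protein sequence sets: reading, validation, filtering, redundancy
reduction and train/specificity/test partitioning.

The prediction task is binary: is a plant protein imported into mitochondria
or not.  Datasets are lists of :class:`ProteinRecord`; labels live either in
the FASTA-adjacent label table or are attached programmatically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
AMBIGUOUS_AA = "XBZUO"
VALID_AA = set(STANDARD_AA) | set(AMBIGUOUS_AA)

LABELS = ("positive", "negative", "unknown")


class SequenceError(ValueError):
    """Malformed sequence input (bad residues, empty sequence, bad FASTA)."""


class SizingError(ValueError):
    """A partition request exceeds the available records."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein with its localization label.

    ``gene_id`` is the best-hit reference gene used to look the protein up in
    the co-expression matrix; it stays ``None`` for unmapped proteins, whose
    co-expression feature block becomes five zeros downstream.
    """

    id: str
    sequence: str
    label: str = "unknown"
    species: str | None = None
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceError("record id must be non-empty")
        if not self.sequence:
            raise SequenceError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - VALID_AA
        if bad:
            raise SequenceError(
                f"record {self.id!r}: invalid residues {sorted(bad)}"
            )
        if self.label not in LABELS:
            raise SequenceError(
                f"record {self.id!r}: label must be one of {LABELS}"
            )


@dataclass
class DatasetPartition:
    """Training / specificity-estimation / independent-test split.

    The specificity set holds negatives only; its score distribution under a
    trained model converts raw scores into estimated-specificity thresholds.
    """

    training: list[ProteinRecord]
    specificity_set: list[ProteinRecord]
    test: list[ProteinRecord]

    def __post_init__(self) -> None:
        ids = [r.id for part in (self.training, self.specificity_set, self.test) for r in part]
        if len(ids) != len(set(ids)):
            raise SizingError("partition parts are not disjoint by id")
        if any(r.label != "negative" for r in self.specificity_set):
            raise SizingError("specificity set must contain negatives only")


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into records with label ``unknown``.

    Sequences are uppercased.  A sequence line before any header, an empty
    sequence, or residues outside the 20 standard amino acids plus X/B/Z/U/O
    raise :class:`SequenceError` naming the offending entry.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if first and not first.startswith((">", ";")) and first.strip():
            raise SequenceError(
                f"{path}: sequence data before the first FASTA header"
            )
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise SequenceError(f"{path}: duplicate id {entry.id!r}")
        seen.add(entry.id)
        records.append(ProteinRecord(id=entry.id, sequence=str(entry.seq).upper()))
    return records


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a 2-column delimited text file (id, label) -> mapping."""
    labels: dict[str, str] = {}
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise SequenceError(f"{path}:{i}: expected two columns, got {len(parts)}")
        pid, lab = parts
        if lab not in LABELS:
            raise SequenceError(f"{path}:{i}: unknown label {lab!r}")
        if pid in labels and labels[pid] != lab:
            raise SequenceError(f"{path}:{i}: conflicting labels for {pid!r}")
        labels[pid] = lab
    return labels


def attach_labels(records: Sequence[ProteinRecord], labels: Mapping[str, str]) -> list[ProteinRecord]:
    """Return records with labels looked up by id (unlisted ids stay unknown)."""
    return [replace(r, label=labels.get(r.id, r.label)) for r in records]


def filter_min_length(records: Sequence[ProteinRecord], min_len: int = 50) -> list[ProteinRecord]:
    """Drop records shorter than ``min_len`` residues (default 50), keeping order.

    Very short chains cannot carry an informative N-terminal targeting signal
    and are excluded from training and evaluation.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    return [r for r in records if len(r.sequence) >= min_len]


def _kmer_set(seq: str, k: int) -> set[str]:
    if len(seq) < k:
        return {seq}
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def kmer_identity(a: str, b: str, k: int = 5) -> float:
    """Containment estimate of pairwise sequence identity.

    Shared k-mer fraction relative to the smaller k-mer set.  This is a fast
    proxy for alignment identity, adequate for leakage control; it is not
    bit-compatible with alignment-based clustering tools.
    """
    ka, kb = _kmer_set(a, k), _kmer_set(b, k)
    denom = min(len(ka), len(kb))
    if denom == 0:
        return 0.0
    return len(ka & kb) / denom


def reduce_redundancy(
    records: Sequence[ProteinRecord],
    identity_threshold: float = 0.40,
    k: int = 5,
    cluster_table: Mapping[str, str] | None = None,
) -> list[ProteinRecord]:
    """Collapse similar sequences, keeping one representative per cluster.

    Greedy longest-first clustering: each sequence joins the first existing
    cluster whose seed it matches at >= ``identity_threshold`` estimated
    identity (k-mer containment), else seeds a new cluster.  The longest
    member (the seed) represents each cluster.  Alternatively a precomputed
    cluster-membership table (id -> cluster_id), e.g. from an external
    clustering tool, can be supplied, in which case only representative
    selection (longest per cluster) is performed.
    """
    if not records:
        raise ValueError("records must be non-empty")
    if not (0 < identity_threshold <= 1):
        raise ValueError("identity_threshold must be in (0, 1]")
    if cluster_table is not None:
        best: dict[str, ProteinRecord] = {}
        order: list[str] = []
        for r in records:
            cid = cluster_table.get(r.id)
            if cid is None:
                raise KeyError(f"record {r.id!r} missing from cluster table")
            if cid not in best:
                order.append(cid)
                best[cid] = r
            elif len(r.sequence) > len(best[cid].sequence):
                best[cid] = r
        return [best[cid] for cid in order]

    ranked = sorted(records, key=lambda r: (-len(r.sequence), r.id))
    seeds: list[ProteinRecord] = []
    for r in ranked:
        for s in seeds:
            if kmer_identity(r.sequence, s.sequence, k) >= identity_threshold:
                break
        else:
            seeds.append(r)
    keep = {s.id for s in seeds}
    return [r for r in records if r.id in keep]


def partition(
    records: Sequence[ProteinRecord],
    n_train_per_class: int,
    n_spec_neg: int,
    n_test_per_class: int,
    seed: int,
) -> DatasetPartition:
    """Random class-balanced split into training, specificity and test sets.

    Deterministic for a fixed seed.  The specificity set draws negatives only.
    """
    pos = [r for r in records if r.label == "positive"]
    neg = [r for r in records if r.label == "negative"]
    need_pos = n_train_per_class + n_test_per_class
    need_neg = n_train_per_class + n_spec_neg + n_test_per_class
    if len(pos) < need_pos:
        raise SizingError(
            f"need {need_pos} positives, have {len(pos)} (short by {need_pos - len(pos)})"
        )
    if len(neg) < need_neg:
        raise SizingError(
            f"need {need_neg} negatives, have {len(neg)} (short by {need_neg - len(neg)})"
        )
    rng = np.random.default_rng(seed)
    pos_idx = rng.permutation(len(pos))
    neg_idx = rng.permutation(len(neg))
    pos_sh = [pos[i] for i in pos_idx]
    neg_sh = [neg[i] for i in neg_idx]
    training = pos_sh[:n_train_per_class] + neg_sh[:n_train_per_class]
    spec = neg_sh[n_train_per_class : n_train_per_class + n_spec_neg]
    test = (
        pos_sh[n_train_per_class : n_train_per_class + n_test_per_class]
        + neg_sh[n_train_per_class + n_spec_neg : n_train_per_class + n_spec_neg + n_test_per_class]
    )
    return DatasetPartition(training=training, specificity_set=spec, test=test)
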