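"""End-to-end feature assembly: records + profiles + co-expression -> matrix.

Glue used by the command-line workflows, the evaluation experiments and the
acceptance checks.  Fallbacks are applied here: a missing profile becomes a
substitution-matrix profile (flagged), an unmapped or uncovered gene
becomes five zeros in the co-expression block.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import coexpression as cx
from .features import (FeatureConfig, FeatureVector, ProfileMatrix,
                       assemble_features, layout_fingerprint, parse_profile,
                       scale_profile, substitution_fallback_profile)
from .seqdata import ProteinRecord


@dataclass
class FeatureSet:
    """Assembled design matrix with provenance flags per protein."""

    records: list[ProteinRecord]
    vectors: list[FeatureVector]
    config: FeatureConfig
    fallback_profile_ids: list[str] = field(default_factory=list)
    unmapped_ids: list[str] = field(default_factory=list)

    @property
    def X(self) -> np.ndarray:
        return np.vstack([v.values for v in self.vectors])

    @property
    def y(self) -> np.ndarray:
        return np.array([1 if r.label == "positive" else 0 for r in self.records])

    @property
    def fingerprint(self) -> str:
        return layout_fingerprint(self.config.layout())


def load_profiles(pssm_dir: str | Path, records: Sequence[ProteinRecord],
                  suffix: str = ".pssm") -> dict[str, ProfileMatrix]:
    """Parse per-protein ASCII PSSM files matched by filename stem."""
    pssm_dir = Path(pssm_dir)
    out: dict[str, ProfileMatrix] = {}
    for r in records:
        path = pssm_dir / f"{r.id}{suffix}"
        if path.exists():
            out[r.id] = parse_profile(path, r.sequence)
    return out


def build_feature_set(
    records: Sequence[ProteinRecord],
    profiles: Mapping[str, ProfileMatrix] | None = None,
    meta: cx.MetaCorrelationMatrix | None = None,
    knn_config: cx.KNNConfig | None = None,
    config: FeatureConfig | None = None,
) -> FeatureSet:
    """Assemble the enabled feature blocks for every record.

    Records lacking a profile get the substitution fallback; records without
    a mapped, covered gene get a five-zero co-expression block.  Both
    conditions are recorded so downstream outputs can flag them.
    """
    config = config or FeatureConfig()
    profiles = profiles or {}
    knn_table: Mapping[str, np.ndarray | None] = {}
    if meta is not None and knn_config is not None and "Coexpr" in config.blocks_enabled:
        knn_table = cx.knn_score_table(records, meta, knn_config)
    vectors, fallback_ids, unmapped_ids = [], [], []
    for r in records:
        prof = profiles.get(r.id)
        if prof is None and {"PSSM.NT", "PSSM"} & set(config.blocks_enabled):
            prof = substitution_fallback_profile(r.sequence, r.id)
        if prof is not None:
            if prof.source == "substitution_fallback":
                fallback_ids.append(r.id)
            if not prof.scaled:
                prof = scale_profile(prof)
        knn = knn_table.get(r.id)
        if "Coexpr" in config.blocks_enabled and knn is None:
            unmapped_ids.append(r.id)
        vectors.append(assemble_features(r, prof, knn, config))
    return FeatureSet(list(records), vectors, config,
                      fallback_profile_ids=fallback_ids, unmapped_ids=unmapped_ids)


def cross_validate(
    records: Sequence[ProteinRecord],
    profiles: Mapping[str, ProfileMatrix] | None = None,
    meta: cx.MetaCorrelationMatrix | None = None,
    config: FeatureConfig | None = None,
    kind: str = "svm",
    svm_config=None,
    dnn_config=None,
    k: int = 10,
    seed: int = 0,
):
    """Stratified k-fold CV with fold-safe co-expression features.

    The label-dependent KNN co-expression block is recomputed in every
    rotation from the labels of the training folds only, so no test-fold
    label can reach a test-fold feature even through shared neighbors.  The
    label-free sequence blocks are assembled once.  Protocols per rotation
    match :func:`plantmito.models.run_cv` (svm: 9 train / 1 test; dnn: 8
    train / 1 validation / 1 test).
    """
    from dataclasses import replace as dc_replace

    from . import models as md

    config = config or FeatureConfig()
    labeled = [r for r in records if r.label in ("positive", "negative")]
    y = np.array([1 if r.label == "positive" else 0 for r in labeled])
    seq_config = FeatureConfig(
        nterm_window=config.nterm_window,
        blocks_enabled=tuple(b for b in config.blocks_enabled if b != "Coexpr"),
    ) if set(config.blocks_enabled) != {"Coexpr"} else None
    X_seq = None
    if seq_config is not None and seq_config.blocks_enabled:
        X_seq = build_feature_set(labeled, profiles, config=seq_config).X
    use_coexpr = "Coexpr" in config.blocks_enabled and meta is not None
    folds = md.stratified_kfold(y, k=k, seed=seed)
    seeds = np.random.SeedSequence(seed).generate_state(k) % (2**31)
    fold_scores, fold_labels, fold_aucs = [], [], []
    for i, test in enumerate(folds):
        if kind == "dnn":
            val = folds[(i + 1) % k]
            train = np.concatenate(
                [f for j, f in enumerate(folds) if j != i and j != (i + 1) % k])
        else:
            val = None
            train = np.concatenate([f for j, f in enumerate(folds) if j != i])
        if use_coexpr:
            knn_cfg = training_knn_config([labeled[j] for j in train])
            knn_tab = cx.knn_score_table(labeled, meta, knn_cfg)
            X_cx = np.vstack([
                knn_tab[r.id] if knn_tab[r.id] is not None else np.zeros(5)
                for r in labeled
            ])
            X = X_cx if X_seq is None else np.hstack([X_seq, X_cx])
        else:
            X = X_seq
        if kind == "svm":
            cfg = svm_config or md.SVMConfig()
            clf = md.train_svm(X[train], y[train], cfg.cost, cfg.gamma)
            s = clf.decision_function(X[test])
        elif kind == "dnn":
            cfg = dc_replace(dnn_config or md.DNNConfig(), seed=int(seeds[i]))
            net = md.train_dnn(X[train], y[train], X[val], y[val], cfg)
            s = net.predict_proba(X[test])
        else:
            raise ValueError(f"unknown model kind {kind!r}")
        fold_scores.append(s)
        fold_labels.append(y[test])
        from sklearn.metrics import roc_auc_score
        fold_aucs.append(float(roc_auc_score(y[test], s)))
    return md.CVResult(fold_scores, fold_labels, fold_aucs)


def training_knn_config(records: Sequence[ProteinRecord],
                        k_percents: tuple[float, ...] = cx.DEFAULT_K_PERCENTS) -> cx.KNNConfig:
    """KNN config from the mapped training records (gene ids + labels)."""
    genes, labels = [], []
    for r in records:
        if r.gene_id is not None and r.label in ("positive", "negative"):
            genes.append(r.gene_id)
            labels.append(r.label)
    return cx.KNNConfig(genes, labels, k_percents)
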