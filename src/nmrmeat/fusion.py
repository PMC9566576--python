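"""Mid-level data fusion of polar and non-polar blocks.

Each block is reduced separately by PCA; the score matrices are concatenated
column-wise after aligning rows by sample id, and a single LDA/NCM classifier
is fitted on the joint score space.  Inside cross-validation the per-block
PCAs are refit on the training rows of each fold before fusing, so held-out
samples never influence either block's reduction (no leakage).

No rescaling is applied to the blocks before concatenation by default; an
optional per-block scaling to unit total score variance is available for
blocks with very different score magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .chemometrics import (
    ClassifierModel,
    LDAModel,
    PCAModel,
    PCAPolicy,
    fit_lda,
    ncm_classify,
    project,
)
from .preprocess import FeatureMatrix
from .validation import CVPlan, MCCVResult, _mccv_engine, report_from_ld


@dataclass
class ScoreBlock:
    """One block's PCA scores with sample identity."""

    values: np.ndarray
    sample_ids: list[str]
    name: str = "block"

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] != len(self.sample_ids):
            raise ValueError("scores and sample_ids must align")


@dataclass
class FusedScores:
    """Joint score matrix; columns carry their block of origin."""

    values: np.ndarray
    sample_ids: list[str]
    block_boundary: int  # first column of the second block
    column_provenance: list[str]
    labels: list[str] | None = None

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.sample_ids, name="sample_id"),
            columns=self.column_provenance,
        )

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.to_dataframe().to_csv(path)
        return path

    @classmethod
    def load(cls, path: str | Path) -> "FusedScores":
        df = pd.read_csv(path, index_col=0)
        prov = list(df.columns)
        prefixes = [c.rsplit("_", 1)[0] for c in prov]
        boundary = len(prov)
        for i in range(1, len(prefixes)):
            if prefixes[i] != prefixes[0]:
                boundary = i
                break
        return cls(
            values=df.to_numpy(),
            sample_ids=[str(i) for i in df.index],
            block_boundary=boundary,
            column_provenance=prov,
        )


def midlevel_fuse(
    block_a: ScoreBlock,
    block_b: ScoreBlock,
    labels: Sequence[str] | None = None,
) -> FusedScores:
    """Column-wise concatenation of two score blocks after id alignment.

    Row order follows ``block_a``; ``block_b`` rows are matched by sample id.
    Any id present in one block but not the other is an error.
    """
    ids_a, ids_b = set(block_a.sample_ids), set(block_b.sample_ids)
    if ids_a != ids_b:
        missing_in_b = sorted(ids_a - ids_b)
        missing_in_a = sorted(ids_b - ids_a)
        raise ValueError(
            f"sample id mismatch between blocks: missing in {block_b.name!r}: "
            f"{missing_in_b}; missing in {block_a.name!r}: {missing_in_a}"
        )
    pos_b = {sid: i for i, sid in enumerate(block_b.sample_ids)}
    order_b = [pos_b[sid] for sid in block_a.sample_ids]
    values = np.hstack([block_a.values, block_b.values[order_b]])
    provenance = [f"{block_a.name}_PC{i + 1}" for i in range(block_a.values.shape[1])] + [
        f"{block_b.name}_PC{i + 1}" for i in range(block_b.values.shape[1])
    ]
    return FusedScores(
        values=values,
        sample_ids=list(block_a.sample_ids),
        block_boundary=block_a.values.shape[1],
        column_provenance=provenance,
        labels=list(labels) if labels is not None else None,
    )


def fit_fused_model(
    fused: FusedScores,
    labels: Sequence[str] | None = None,
) -> ClassifierModel:
    """LDA + NCM directly on the fused score columns (no second PCA)."""
    y = fused.labels if labels is None else list(labels)
    if y is None:
        raise ValueError("labels required")
    lda = fit_lda(fused.values, y)
    return ClassifierModel(pca=None, lda=lda, pretreatment=None)


@dataclass
class FusedClassifier:
    """Per-block PCA models plus an LDA/NCM on the fused score space."""

    pca_a: PCAModel
    pca_b: PCAModel
    lda: LDAModel
    name_a: str = "polar"
    name_b: str = "nonpolar"
    pretreatment_a: dict | None = None
    pretreatment_b: dict | None = None
    scale_blocks: bool = False
    _scale_factors: tuple[float, float] = (1.0, 1.0)

    @property
    def classes(self) -> tuple[str, ...]:
        return self.lda.class_labels

    def transform_pair(self, X_a: np.ndarray, X_b: np.ndarray) -> np.ndarray:
        sa, sb = self._scale_factors
        scores = np.hstack([project(self.pca_a, X_a) * sa, project(self.pca_b, X_b) * sb])
        return self.lda.transform(scores)

    def classify_pair(self, X_a: np.ndarray, X_b: np.ndarray):
        return ncm_classify(self.lda, self.transform_pair(X_a, X_b))


def _align_b_to_a(fm_a: FeatureMatrix, fm_b: FeatureMatrix) -> FeatureMatrix:
    if set(fm_a.sample_ids) != set(fm_b.sample_ids):
        raise ValueError("blocks do not share the same sample ids")
    pos = {sid: i for i, sid in enumerate(fm_b.sample_ids)}
    return fm_b.subset([pos[sid] for sid in fm_a.sample_ids])


def fit_fused_classifier(
    fm_a: FeatureMatrix,
    fm_b: FeatureMatrix,
    labels: Sequence[str] | None = None,
    policy_a: PCAPolicy | None = None,
    policy_b: PCAPolicy | None = None,
    scale_blocks: bool = False,
) -> FusedClassifier:
    """Fit per-block PCAs, fuse the training scores, fit the joint LDA."""
    fm_b = _align_b_to_a(fm_a, fm_b)
    y = fm_a.labels if labels is None else np.asarray(labels, dtype=object)
    policy_a = policy_a or PCAPolicy()
    policy_b = policy_b or PCAPolicy()
    pca_a = policy_a.fit(fm_a.values)
    pca_b = policy_b.fit(fm_b.values)
    T_a = project(pca_a, fm_a.values)
    T_b = project(pca_b, fm_b.values)
    factors = (1.0, 1.0)
    if scale_blocks:
        factors = (1.0 / np.sqrt(T_a.var(axis=0).sum()), 1.0 / np.sqrt(T_b.var(axis=0).sum()))
        T_a, T_b = T_a * factors[0], T_b * factors[1]
    lda = fit_lda(np.hstack([T_a, T_b]), y)
    block_a = fm_a.pretreatment.get("block", "a") if fm_a.pretreatment else "a"
    block_b = fm_b.pretreatment.get("block", "b") if fm_b.pretreatment else "b"
    return FusedClassifier(
        pca_a=pca_a,
        pca_b=pca_b,
        lda=lda,
        name_a=block_a,
        name_b=block_b,
        pretreatment_a=dict(fm_a.pretreatment) if fm_a.pretreatment else None,
        pretreatment_b=dict(fm_b.pretreatment) if fm_b.pretreatment else None,
        scale_blocks=scale_blocks,
        _scale_factors=factors,
    )


def run_fused_mccv(
    fm_a: FeatureMatrix,
    fm_b: FeatureMatrix,
    labels: Sequence[str] | None = None,
    policy_a: PCAPolicy | None = None,
    policy_b: PCAPolicy | None = None,
    plan: CVPlan | None = None,
    scale_blocks: bool = False,
) -> MCCVResult:
    """MC-embedded CV of the fused classifier.

    Fusion happens inside each training fold: both blocks' PCAs see training
    rows only, then the fused LDA is fitted and the held-out pairs classified.
    """
    fm_b = _align_b_to_a(fm_a, fm_b)
    y = fm_a.labels if labels is None else np.asarray(labels, dtype=object)
    plan = plan or CVPlan()

    def fit_predict(train: np.ndarray, test: np.ndarray) -> np.ndarray:
        fc = fit_fused_classifier(
            fm_a.subset(train),
            fm_b.subset(train),
            policy_a=policy_a,
            policy_b=policy_b,
            scale_blocks=scale_blocks,
        )
        return fc.classify_pair(fm_a.values[test], fm_b.values[test]).labels

    return _mccv_engine(y, plan, fit_predict)


def external_validate_fused(
    fc: FusedClassifier,
    fm_a: FeatureMatrix,
    fm_b: FeatureMatrix,
) -> pd.DataFrame:
    """External validation of paired new samples against the fused model."""
    if fc.pretreatment_a is not None and fm_a.pretreatment:
        if fc.pretreatment_a != fm_a.pretreatment:
            raise ValueError("block-A pretreatment record does not match the model")
    if fc.pretreatment_b is not None and fm_b.pretreatment:
        if fc.pretreatment_b != fm_b.pretreatment:
            raise ValueError("block-B pretreatment record does not match the model")
    fm_b = _align_b_to_a(fm_a, fm_b)
    Z = fc.transform_pair(fm_a.values, fm_b.values)
    shim = ClassifierModel(pca=None, lda=fc.lda, pretreatment=None)
    return report_from_ld(shim, Z, fm_a.sample_ids)


def fused_membership_pvalues(
    fc: FusedClassifier, fm_a: FeatureMatrix, fm_b: FeatureMatrix
) -> pd.DataFrame:
    """Per-class chi-square membership p-values for paired new samples."""
    from .validation import membership_pvalues

    fm_b = _align_b_to_a(fm_a, fm_b)
    Z = fc.transform_pair(fm_a.values, fm_b.values)
    shim = ClassifierModel(pca=None, lda=fc.lda, pretreatment=None)
    out = membership_pvalues(shim, Z)
    out.index = pd.Index(fm_a.sample_ids, name="sample_id")
    return out
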