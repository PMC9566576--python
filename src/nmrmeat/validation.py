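"""Monte-Carlo-embedded cross-validation and external validation.

Internal validation is a 10-fold CV repeated under Monte-Carlo resampling of
the fold segmentation (default 10 repeats): each repeat reshuffles the
samples, splits them into folds, refits the *entire* model chain (centering,
PCA, LDA) on the training folds only, and classifies the held-out fold by the
nearest-class-mean rule.  The resulting n_mc x n_folds confusion matrices are
summed into one aggregated matrix whose diagonal percentages are the
per-class accuracies.

External validation applies a fitted model to new samples and reports, per
sample, the assigned class, the squared Mahalanobis distance to the assigned
class mean (using that class's LD-space covariance), and a p-value from the
upper tail of the chi-square distribution with as many degrees of freedom as
LD dimensions.  A sample lies inside the 95% region of its class when
p >= 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .chemometrics import ClassifierModel, LDAModel, PCAPolicy, fit_classifier
from .preprocess import FeatureMatrix


@dataclass(frozen=True)
class CVPlan:
    """Cross-validation layout: folds, Monte-Carlo repeats, master seed."""

    n_folds: int = 10
    n_mc: int = 10
    seed: int = 0
    stratified: bool = False

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.n_mc < 1:
            raise ValueError("n_mc must be >= 1")


def make_folds(
    n_samples: int,
    plan: CVPlan,
    seed: int | None = None,
    labels: Sequence[str] | None = None,
) -> list[np.ndarray]:
    """Random disjoint test folds covering all indices; sizes differ by <= 1.

    Unstratified (default): a seeded permutation split into contiguous blocks.
    Stratified: per-class permutations dealt round-robin across folds.
    """
    if n_samples < plan.n_folds:
        raise ValueError(f"cannot split {n_samples} samples into {plan.n_folds} folds")
    rng = np.random.default_rng(plan.seed if seed is None else seed)
    if plan.stratified:
        if labels is None:
            raise ValueError("stratified folds require labels")
        y = np.asarray(labels, dtype=object)
        dealt: list[int] = []
        for c in sorted(set(y)):
            idx = np.flatnonzero(y == c)
            dealt.extend(rng.permutation(idx).tolist())
        return [np.asarray(dealt[f :: plan.n_folds]) for f in range(plan.n_folds)]
    perm = rng.permutation(n_samples)
    return list(np.array_split(perm, plan.n_folds))


@dataclass
class ConfusionMatrix:
    """True-class x assigned-class counts with accuracy summaries."""

    counts: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        g = len(self.labels)
        if self.counts.shape != (g, g):
            raise ValueError("counts must be square over the label set")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @classmethod
    def from_predictions(
        cls, y_true: Sequence[str], y_pred: Sequence[str], labels: Sequence[str]
    ) -> "ConfusionMatrix":
        labels = tuple(labels)
        index = {c: i for i, c in enumerate(labels)}
        counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
        for t, p in zip(y_true, y_pred):
            counts[index[t], index[p]] += 1
        return cls(counts=counts, labels=labels)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def per_class_accuracy(self) -> np.ndarray:
        """Percent correct per true class (100 * diagonal / row total)."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return 100.0 * np.diag(self.counts) / self.row_totals

    @property
    def overall_accuracy(self) -> float:
        """Percent correct overall (100 * trace / total)."""
        return 100.0 * np.trace(self.counts) / self.total if self.total else float("nan")

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if self.labels != other.labels:
            raise ValueError("confusion matrices have different label sets")
        return ConfusionMatrix(counts=self.counts + other.counts, labels=self.labels)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=pd.Index(self.labels, name="true"),
            columns=pd.Index(self.labels, name="assigned"),
        )

    def to_csv(self, path: str | Path) -> Path:
        """Counts block followed by a row-normalized percentage block."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        counts = self.to_dataframe()
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = counts.div(counts.sum(axis=1), axis=0) * 100.0
        with open(path, "w") as fh:
            fh.write("# counts\n")
            counts.to_csv(fh)
            fh.write("# row percent\n")
            pct.round(2).to_csv(fh)
            fh.write(f"# overall_accuracy_percent,{self.overall_accuracy:.4f}\n")
        return path


def aggregate_confusions(matrices: Sequence[ConfusionMatrix]) -> ConfusionMatrix:
    """Elementwise sum; accuracies are recomputed on the aggregate."""
    if not matrices:
        raise ValueError("nothing to aggregate")
    out = matrices[0]
    for m in matrices[1:]:
        out = out + m
    return out


@dataclass
class MCCVResult:
    aggregate: ConfusionMatrix
    per_model: list[ConfusionMatrix] = field(repr=False)
    plan: CVPlan | None = None

    @property
    def per_run(self) -> list[ConfusionMatrix]:
        """One aggregated matrix per Monte-Carlo run."""
        if self.plan is None:
            return [self.aggregate]
        k = self.plan.n_folds
        return [
            aggregate_confusions(self.per_model[i : i + k])
            for i in range(0, len(self.per_model), k)
        ]


def _mccv_engine(
    labels: np.ndarray,
    plan: CVPlan,
    fit_predict: Callable[[np.ndarray, np.ndarray], np.ndarray],
) -> MCCVResult:
    """Generic MC-embedded CV: one model per (run, fold), all matrices summed."""
    n = labels.size
    classes = tuple(sorted(set(labels)))
    mats = []
    for r in range(plan.n_mc):
        folds = make_folds(n, plan, seed=plan.seed + r, labels=labels)
        for fold in folds:
            train = np.setdiff1d(np.arange(n), fold)
            train_counts = pd.Series(labels[train]).value_counts()
            thin = [c for c in classes if train_counts.get(c, 0) < 2]
            if thin:
                raise ValueError(
                    f"classes {thin} have fewer than 2 training samples in a fold; "
                    "use stratified folds or fewer folds"
                )
            pred = fit_predict(train, fold)
            mats.append(ConfusionMatrix.from_predictions(labels[fold], pred, classes))
    return MCCVResult(aggregate=aggregate_confusions(mats), per_model=mats, plan=plan)


def run_mccv(
    data: FeatureMatrix | np.ndarray,
    labels: Sequence[str] | None = None,
    model_config: PCAPolicy | None = None,
    plan: CVPlan | None = None,
) -> MCCVResult:
    """MC-embedded CV of the PCA/LDA/NCM chain on a feature matrix.

    The full chain is refit per fold on the training rows only — there is no
    information leakage from held-out samples into centering, PCA or LDA.
    Passing a prefit model as ``model_config`` is rejected.
    """
    if isinstance(model_config, ClassifierModel):
        raise TypeError(
            "model_config must be a PCAPolicy; refusing a prefit model (leakage)"
        )
    plan = plan or CVPlan()
    policy = model_config or PCAPolicy()
    if isinstance(data, FeatureMatrix):
        X = data.values
        y = data.labels if labels is None else np.asarray(labels, dtype=object)
    else:
        X = np.asarray(data, dtype=float)
        if labels is None:
            raise ValueError("labels required when passing a bare array")
        y = np.asarray(labels, dtype=object)

    def fit_predict(train: np.ndarray, test: np.ndarray) -> np.ndarray:
        model = fit_classifier(X[train], y[train], policy=policy)
        return model.classify(X[test]).labels

    return _mccv_engine(y, plan, fit_predict)


# ------------------------------------------------------ external validation


def _class_mahalanobis(lda: LDAModel, Z: np.ndarray, class_index: int) -> np.ndarray:
    """Squared Mahalanobis distances to one class mean (own covariance,
    pooled fallback if singular)."""
    delta = Z - lda.class_means_ld[class_index]
    cov = lda.class_cov_ld[class_index]
    try:
        cond = np.linalg.cond(cov)
        if not np.isfinite(cond) or cond > 1e12:
            raise np.linalg.LinAlgError("ill-conditioned")
        sol = np.linalg.solve(cov, delta.T)
    except np.linalg.LinAlgError:
        warnings.warn(
            f"singular covariance for class {lda.class_labels[class_index]!r}; "
            "falling back to the pooled covariance",
            RuntimeWarning,
        )
        sol = np.linalg.solve(lda.pooled_cov_ld, delta.T)
    return np.einsum("nd,dn->n", delta, sol)


def membership_pvalues(model: ClassifierModel, Z: np.ndarray) -> pd.DataFrame:
    """Chi-square upper-tail p-value of membership in every class (LD scores in)."""
    Z = np.atleast_2d(Z)
    df = model.lda.n_ld
    cols = {}
    for i, c in enumerate(model.lda.class_labels):
        cols[c] = chi2.sf(_class_mahalanobis(model.lda, Z, i), df=df)
    return pd.DataFrame(cols)


def external_validate(
    model: ClassifierModel,
    new_samples: FeatureMatrix | np.ndarray,
    sample_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Assign new samples and score how well they fit the assigned class.

    Returns one row per sample: assigned label, Euclidean LD distance to each
    class mean, squared Mahalanobis distance ``d2`` to the assigned class,
    ``p_value`` = chi-square upper tail at d2 with df = LD dimensions, and
    ``inside_95`` (p >= 0.05).  The samples' pretreatment record must match
    the model's.
    """
    if isinstance(new_samples, FeatureMatrix):
        model.check_pretreatment(new_samples.pretreatment)
        X = new_samples.values
        ids = new_samples.sample_ids if sample_ids is None else list(sample_ids)
    else:
        X = np.atleast_2d(np.asarray(new_samples, dtype=float))
        ids = list(sample_ids) if sample_ids is not None else [str(i) for i in range(len(X))]
    Z = model.transform(X)
    return report_from_ld(model, Z, ids)


def report_from_ld(model: ClassifierModel, Z: np.ndarray, ids: Sequence[str]) -> pd.DataFrame:
    """External-validation report from already-computed LD scores."""
    from .chemometrics import ncm_classify

    Z = np.atleast_2d(Z)
    ncm = ncm_classify(model.lda, Z)
    df_dims = model.lda.n_ld
    d2 = np.empty(len(Z))
    for i, c in enumerate(model.lda.class_labels):
        rows = np.flatnonzero(ncm.labels == c)
        if rows.size:
            d2[rows] = _class_mahalanobis(model.lda, Z[rows], i)
    p = chi2.sf(d2, df=df_dims)
    out = pd.DataFrame(
        {
            "sample_id": list(ids),
            "assigned": ncm.labels,
            "d2": d2,
            "p_value": p,
            "inside_95": p >= 0.05,
        }
    )
    for c in model.lda.class_labels:
        out[f"dist_{c}"] = ncm.distances[c].to_numpy()
    return out
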