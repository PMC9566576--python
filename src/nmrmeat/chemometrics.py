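"""PCA/LDA chemometrics with nearest-class-mean classification.

The model chain is the standard fingerprinting one: mean-centre the
log-transformed bucket matrix (no unit-variance scaling — the log transform
already acts as a pseudo-scaling), reduce dimension by PCA, then find the
linear discriminants maximising between-class over within-class scatter, and
classify by Euclidean distance to the class means in discriminant space.

PCA is computed from the SVD of the centred matrix; LDA solves the
generalised symmetric eigenproblem on (S_b, S_w) with a small ridge added to
S_w for numerical stability.  Up to g-1 discriminants are retained for g
classes.  Class means and covariances are stored in discriminant (LD) space
for the nearest-class-mean rule, confidence ellipses and external validation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.stats import chi2

from .preprocess import FeatureMatrix

#: relative ridge added to S_w, as a fraction of trace(S_w)/dim
LDA_RIDGE = 1e-8


# --------------------------------------------------------------------- PCA


@dataclass
class PCAModel:
    center: np.ndarray
    loadings: np.ndarray  # (n_features, n_components), orthonormal columns
    explained_variance_ratio: np.ndarray
    n_components: int


def _fix_signs(basis: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-|entry| element positive."""
    flip = np.sign(basis[np.argmax(np.abs(basis), axis=0), np.arange(basis.shape[1])])
    flip[flip == 0] = 1.0
    return basis * flip


def fit_pca(
    X: np.ndarray,
    n_components: int | None = None,
    variance_target: float | None = None,
    max_components: int | None = None,
) -> PCAModel:
    """PCA of the mean-centred matrix via SVD.

    If ``variance_target`` is given, the smallest component count reaching
    that cumulative explained-variance fraction is used, optionally capped by
    ``max_components``.  An explicit ``n_components`` above the matrix rank is
    an error.
    """
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    if n < 2:
        raise ValueError("PCA requires at least 2 samples")
    center = X.mean(axis=0)
    Xc = X - center
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2 / (n - 1)
    total = var.sum()
    if total <= 0:
        raise ValueError("matrix has zero variance")
    evr = var / total
    rank = int(np.sum(s > s[0] * 1e-12))
    if n_components is not None:
        if n_components > rank:
            raise ValueError(f"n_components={n_components} exceeds rank {rank}")
        m = n_components
    elif variance_target is not None:
        cum = np.cumsum(evr)
        m = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
        m = min(m, rank)
    else:
        m = rank
    if max_components is not None:
        m = min(m, max_components)
    return PCAModel(
        center=center,
        loadings=_fix_signs(Vt[:m].T),
        explained_variance_ratio=evr[:m],
        n_components=m,
    )


def project(pca: PCAModel, X: np.ndarray) -> np.ndarray:
    """Scores: (x - center) . loadings."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != pca.center.size:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match model ({pca.center.size})"
        )
    return (X - pca.center) @ pca.loadings


def inverse_project(pca: PCAModel, scores: np.ndarray) -> np.ndarray:
    return np.atleast_2d(scores) @ pca.loadings.T + pca.center


@dataclass(frozen=True)
class PCAPolicy:
    """Dimension policy: explicit count, or variance target with a hard cap.

    The default keeps the smallest number of components explaining 98.9% of
    the variance, never more than 16.
    """

    n_components: int | None = None
    variance_target: float | None = 0.989
    max_components: int | None = 16

    def fit(self, X: np.ndarray) -> PCAModel:
        return fit_pca(
            X,
            n_components=self.n_components,
            variance_target=self.variance_target,
            max_components=self.max_components,
        )


# --------------------------------------------------------------------- LDA


@dataclass
class LDAModel:
    discriminants: np.ndarray  # (n_score_dims, n_ld)
    class_labels: tuple[str, ...]  # sorted
    class_means_ld: np.ndarray  # (g, n_ld)
    class_cov_ld: np.ndarray  # (g, n_ld, n_ld)
    pooled_cov_ld: np.ndarray  # (n_ld, n_ld)
    eigenvalues: np.ndarray

    @property
    def n_ld(self) -> int:
        return self.discriminants.shape[1]

    def transform(self, scores: np.ndarray) -> np.ndarray:
        scores = np.atleast_2d(np.asarray(scores, dtype=float))
        if scores.shape[1] != self.discriminants.shape[0]:
            raise ValueError("score dimension does not match LDA model")
        return scores @ self.discriminants


def fit_lda(scores: np.ndarray, labels: Sequence[str], ridge: float = LDA_RIDGE) -> LDAModel:
    """Linear discriminants from the generalised eigenproblem on (S_b, S_w).

    Requires >= 2 classes with >= 2 samples each.  Retains
    min(g-1, n_score_dims) discriminants, S_w-whitened and sign-fixed for
    determinism.  Identical class means yield a degenerate-separation warning
    but still return discriminants.
    """
    X = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=object)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("scores and labels must align")
    classes = tuple(sorted(set(y)))
    if len(classes) < 2:
        raise ValueError("LDA requires at least 2 classes")
    n, p = X.shape
    mu = X.mean(axis=0)
    Sw = np.zeros((p, p))
    Sb = np.zeros((p, p))
    class_means = {}
    for c in classes:
        Xc = X[y == c]
        if Xc.shape[0] < 2:
            raise ValueError(f"class {c!r} has fewer than 2 samples")
        mc = Xc.mean(axis=0)
        class_means[c] = mc
        R = Xc - mc
        Sw += R.T @ R
        dm = (mc - mu)[:, None]
        Sb += Xc.shape[0] * (dm @ dm.T)
    tr = np.trace(Sw)
    Sw_r = Sw + (ridge * tr / p if tr > 0 else ridge) * np.eye(p)
    evals, evecs = scipy.linalg.eigh(Sb, Sw_r)
    order = np.argsort(evals)[::-1]
    m = min(len(classes) - 1, p)
    W = _fix_signs(evecs[:, order[:m]])
    evals = evals[order[:m]]
    if evals[0] <= 1e-12:
        warnings.warn("degenerate LDA: all class means coincide", RuntimeWarning)
    Z = X @ W
    g = len(classes)
    means_ld = np.vstack([class_means[c] @ W for c in classes])
    covs_ld = np.stack(
        [np.cov(Z[y == c], rowvar=False, ddof=1).reshape(m, m) for c in classes]
    )
    counts = np.array([np.sum(y == c) for c in classes])
    pooled = np.einsum("g,gij->ij", counts - 1, covs_ld) / (n - g)
    return LDAModel(
        discriminants=W,
        class_labels=classes,
        class_means_ld=means_ld,
        class_cov_ld=covs_ld,
        pooled_cov_ld=pooled,
        eigenvalues=evals,
    )


class NCMResult(NamedTuple):
    labels: np.ndarray  # assigned label per sample
    distances: pd.DataFrame  # samples x classes Euclidean LD distances
    tied: np.ndarray  # True where the minimum distance was not unique


def ncm_classify(lda: LDAModel, ld_scores: np.ndarray) -> NCMResult:
    """Nearest-class-mean rule in LD space.

    Ties are broken toward the lexicographically smallest label (class labels
    are stored sorted) and flagged in the result.
    """
    Z = np.atleast_2d(np.asarray(ld_scores, dtype=float))
    if Z.shape[1] != lda.n_ld:
        raise ValueError("LD dimension mismatch")
    diffs = Z[:, None, :] - lda.class_means_ld[None, :, :]
    D = np.sqrt(np.einsum("ngd,ngd->ng", diffs, diffs))
    idx = np.argmin(D, axis=1)  # first minimum = lexicographically smallest
    tied = (D == D[np.arange(len(idx)), idx][:, None]).sum(axis=1) > 1
    labels = np.asarray([lda.class_labels[i] for i in idx], dtype=object)
    return NCMResult(
        labels=labels,
        distances=pd.DataFrame(D, columns=list(lda.class_labels)),
        tied=tied,
    )


# ------------------------------------------------------------- classifier


@dataclass
class ClassifierModel:
    """Composite PCA -> LDA -> NCM classifier.

    ``pca`` may be None for models fitted directly on score-level features
    (e.g. fused score matrices).
    """

    pca: PCAModel | None
    lda: LDAModel
    pretreatment: dict | None = None

    @property
    def classes(self) -> tuple[str, ...]:
        return self.lda.class_labels

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Bucket (or score) space -> LD space."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        scores = project(self.pca, X) if self.pca is not None else X
        return self.lda.transform(scores)

    def classify(self, X: np.ndarray) -> NCMResult:
        return ncm_classify(self.lda, self.transform(X))

    def check_pretreatment(self, record: dict | None) -> None:
        if self.pretreatment is not None and record is not None:
            if self.pretreatment != record:
                raise ValueError(
                    "pretreatment record of the samples does not match the model"
                )

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        arrays = {
            "lda_discriminants": self.lda.discriminants,
            "lda_class_means": self.lda.class_means_ld,
            "lda_class_cov": self.lda.class_cov_ld,
            "lda_pooled_cov": self.lda.pooled_cov_ld,
            "lda_eigenvalues": self.lda.eigenvalues,
        }
        if self.pca is not None:
            arrays["pca_center"] = self.pca.center
            arrays["pca_loadings"] = self.pca.loadings
            arrays["pca_evr"] = self.pca.explained_variance_ratio
        meta = {
            "class_labels": list(self.lda.class_labels),
            "pretreatment": self.pretreatment,
            "has_pca": self.pca is not None,
        }
        np.savez(path, _meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)
        return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")

    @classmethod
    def load(cls, path: str | Path) -> "ClassifierModel":
        with np.load(path) as z:
            meta = json.loads(bytes(z["_meta"]).decode())
            pca = None
            if meta["has_pca"]:
                pca = PCAModel(
                    center=z["pca_center"],
                    loadings=z["pca_loadings"],
                    explained_variance_ratio=z["pca_evr"],
                    n_components=int(z["pca_loadings"].shape[1]),
                )
            lda = LDAModel(
                discriminants=z["lda_discriminants"],
                class_labels=tuple(meta["class_labels"]),
                class_means_ld=z["lda_class_means"],
                class_cov_ld=z["lda_class_cov"],
                pooled_cov_ld=z["lda_pooled_cov"],
                eigenvalues=z["lda_eigenvalues"],
            )
        return cls(pca=pca, lda=lda, pretreatment=meta["pretreatment"])


def fit_classifier(
    data: FeatureMatrix | np.ndarray,
    labels: Sequence[str] | None = None,
    policy: PCAPolicy | None = None,
) -> ClassifierModel:
    """Fit the PCA/LDA/NCM chain on a feature matrix."""
    policy = policy or PCAPolicy()
    if isinstance(data, FeatureMatrix):
        X = data.values
        y = data.labels if labels is None else np.asarray(labels, dtype=object)
        record = dict(data.pretreatment)
    else:
        if labels is None:
            raise ValueError("labels required when passing a bare array")
        X = np.asarray(data, dtype=float)
        y = np.asarray(labels, dtype=object)
        record = None
    pca = policy.fit(X)
    lda = fit_lda(project(pca, X), y)
    return ClassifierModel(pca=pca, lda=lda, pretreatment=record)


# ----------------------------------------------------------- diagnostics


@dataclass(frozen=True)
class Ellipse95:
    """Confidence ellipse of a 2-D class cloud in LD units."""

    center: tuple[float, float]
    semi_axes: tuple[float, float]  # major, minor
    orientation: float  # radians of major axis vs first coordinate


def confidence_ellipse(points_2d: np.ndarray, level: float = 0.95) -> Ellipse95:
    """Ellipse from the class covariance; semi-axes sqrt(eigval * chi2_2(level))."""
    P = np.asarray(points_2d, dtype=float)
    if P.ndim != 2 or P.shape[1] != 2 or P.shape[0] < 3:
        raise ValueError("need >= 3 two-dimensional points")
    if not 0.0 <= level < 1.0:
        raise ValueError("level must be in [0, 1)")
    center = P.mean(axis=0)
    S = np.cov(P, rowvar=False, ddof=1)
    evals, evecs = np.linalg.eigh(S)
    if evals[0] <= np.finfo(float).eps * max(evals[-1], 1.0):
        raise ValueError("singular class covariance")
    r2 = chi2.ppf(level, df=2)
    semi = np.sqrt(evals[::-1] * r2)  # major first
    major = evecs[:, -1]
    return Ellipse95(
        center=(float(center[0]), float(center[1])),
        semi_axes=(float(semi[0]), float(semi[1])),
        orientation=float(np.arctan2(major[1], major[0])),
    )


def ld_loadings_in_bucket_space(model: ClassifierModel) -> np.ndarray:
    """Per-bucket weight of each LD axis: PCA loadings composed with LDA.

    Returns an (n_buckets, n_ld) array; large |weight| marks buckets that
    drive the separation along that discriminant.
    """
    if model.pca is None:
        return model.lda.discriminants
    return model.pca.loadings @ model.lda.discriminants


def two_class_marker_report(
    fm: FeatureMatrix,
    labels: Sequence[str] | None = None,
    classes: tuple[str, str] | None = None,
    one_vs_rest: str | None = None,
    top_k: int = 10,
    policy: PCAPolicy | None = None,
) -> pd.DataFrame:
    """Rank buckets by |LD1 loading| of a two-class model.

    ``classes=(a, b)`` restricts to those two classes; ``one_vs_rest``
    contrasts one class against everything else (e.g. poultry vs non-poultry).
    For each top bucket the report gives the LD1 loading, which group the
    bucket elevates (by comparing group means), and per-group five-number
    summaries (min, Q1, median, Q3, max; quartiles by linear interpolation)
    for box-whisker output.
    """
    if (classes is None) == (one_vs_rest is None):
        raise ValueError("give exactly one of classes=(a, b) or one_vs_rest")
    y_all = fm.labels if labels is None else np.asarray(labels, dtype=object)
    if one_vs_rest is not None:
        y = np.where(y_all == one_vs_rest, one_vs_rest, f"non-{one_vs_rest}")
        mask = np.ones(len(y_all), dtype=bool)
        group_names = (one_vs_rest, f"non-{one_vs_rest}")
    else:
        a, b = classes
        mask = (y_all == a) | (y_all == b)
        y = y_all[mask]
        group_names = (a, b)
    y = np.asarray(y, dtype=object)
    for g in group_names:
        if not np.any(y == g):
            raise ValueError(f"group {g!r} is empty")
    if top_k > fm.n_buckets:
        raise ValueError(f"top_k={top_k} exceeds bucket count {fm.n_buckets}")
    X = fm.values[mask]
    model = fit_classifier(X, y, policy=policy or PCAPolicy())
    w = ld_loadings_in_bucket_space(model)[:, 0]
    order = np.argsort(-np.abs(w))[:top_k]
    rows = []
    for j in order:
        col = X[:, j]
        means = {g: float(col[np.asarray(y) == g].mean()) for g in group_names}
        direction = max(means, key=means.get)
        row = {
            "bucket_center": float(fm.bucket_centers[j]),
            "ld1_loading": float(w[j]),
            "direction_class": direction,
        }
        for g in group_names:
            vals = col[np.asarray(y) == g]
            q = np.percentile(vals, [0, 25, 50, 75, 100])
            row.update(
                {
                    f"{g}_min": q[0],
                    f"{g}_q1": q[1],
                    f"{g}_median": q[2],
                    f"{g}_q3": q[3],
                    f"{g}_max": q[4],
                }
            )
        rows.append(row)
    return pd.DataFrame(rows)
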