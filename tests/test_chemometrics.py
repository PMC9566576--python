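"""PCA, LDA, nearest-class-mean rule, ellipses and marker extraction."""

import numpy as np
import pytest
from scipy.stats import chi2

import nmrmeat as nm
from nmrmeat.chemometrics import (
    PCAPolicy,
    confidence_ellipse,
    fit_classifier,
    fit_lda,
    fit_pca,
    inverse_project,
    ld_loadings_in_bucket_space,
    ncm_classify,
    project,
    two_class_marker_report,
)


# ------------------------------------------------------------------- PCA


def test_pca_rank1_data_first_ratio_one():
    t = np.linspace(0, 1, 20)
    X = np.column_stack([t, 2 * t])  # points on a line
    pca = fit_pca(X)
    assert pca.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-10)


def test_pca_square_toy_equal_ratios():
    X = np.array([[0.0, 0.0], [2.0, 0.0], [0.0, 2.0], [2.0, 2.0]])
    pca = fit_pca(X)
    np.testing.assert_allclose(pca.explained_variance_ratio, [0.5, 0.5], atol=1e-12)


def test_pca_variance_target_selects_smallest_count():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(60, 8)) * np.array([5, 3, 2, 1, 0.5, 0.3, 0.2, 0.1])
    full = fit_pca(X)
    cum = np.cumsum(full.explained_variance_ratio)
    target = 0.9
    expected = int(np.searchsorted(cum, target) + 1)
    pca = fit_pca(X, variance_target=target)
    assert pca.n_components == expected
    capped = fit_pca(X, variance_target=target, max_components=2)
    assert capped.n_components == min(expected, 2)


def test_pca_dims_above_rank_error():
    X = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])  # rank 1
    with pytest.raises(ValueError, match="rank"):
        fit_pca(X, n_components=2)


def test_pca_matches_sklearn_oracle():
    from sklearn.decomposition import PCA as SkPCA

    rng = np.random.default_rng(1)
    X = rng.normal(size=(40, 12)) @ rng.normal(size=(12, 12))
    ours = fit_pca(X, n_components=5)
    ref = SkPCA(n_components=5).fit(X)
    np.testing.assert_allclose(
        ours.explained_variance_ratio, ref.explained_variance_ratio_, rtol=1e-9
    )
    # loadings agree column-wise up to sign
    dots = np.abs(np.sum(ours.loadings * ref.components_.T, axis=0))
    np.testing.assert_allclose(dots, 1.0, atol=1e-8)


def test_pca_loadings_orthonormal(raw_features):
    pca = PCAPolicy().fit(raw_features.values)
    G = pca.loadings.T @ pca.loadings
    np.testing.assert_allclose(G, np.eye(pca.n_components), atol=1e-8)
    assert np.all(np.diff(pca.explained_variance_ratio) <= 1e-12)
    assert pca.explained_variance_ratio.sum() <= 1 + 1e-12


def test_projection_centering_and_reconstruction():
    rng = np.random.default_rng(2)
    X = rng.normal(size=(30, 6))
    pca = fit_pca(X)  # full rank
    T = project(pca, X)
    np.testing.assert_allclose(T.mean(axis=0), 0.0, atol=1e-8)
    np.testing.assert_allclose(project(pca, pca.center)[0], 0.0, atol=1e-10)
    np.testing.assert_allclose(inverse_project(pca, T), X, atol=1e-6)
    with pytest.raises(ValueError, match="dimension"):
        project(pca, X[:, :4])


def test_pca_reconstruction_error_monotone():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(25, 10)) * np.linspace(3, 0.1, 10)
    errors = []
    for m in range(1, 9):
        pca = fit_pca(X, n_components=m)
        err = np.linalg.norm(X - inverse_project(pca, project(pca, X)))
        errors.append(err)
    assert all(a >= b - 1e-9 for a, b in zip(errors, errors[1:]))


# ------------------------------------------------------------------- LDA


def _blobs(rng, centers, n_per=20, sd=0.5):
    X, y = [], []
    for label, c in centers.items():
        X.append(rng.normal(size=(n_per, len(c))) * sd + np.asarray(c))
        y += [label] * n_per
    return np.vstack(X), np.array(y, dtype=object)


def test_lda_returns_g_minus_1_discriminants():
    rng = np.random.default_rng(4)
    X, y = _blobs(rng, {"a": (0, 0, 0), "b": (5, 0, 0), "c": (0, 5, 0), "d": (0, 0, 5)})
    lda = fit_lda(X, y)
    assert lda.n_ld == 3
    assert lda.class_labels == ("a", "b", "c", "d")


def test_lda_separated_classes_perfect_training_ncm():
    rng = np.random.default_rng(5)
    X, y = _blobs(rng, {"a": (0, 0), "b": (10, 0)}, sd=0.5)  # ratio ~ 20
    lda = fit_lda(X, y)
    res = ncm_classify(lda, lda.transform(X))
    assert np.all(res.labels == y)


def test_lda_permutation_invariance():
    rng = np.random.default_rng(6)
    X, y = _blobs(rng, {"a": (0, 0), "b": (3, 1), "c": (1, 3)})
    perm = rng.permutation(len(y))
    lda1 = fit_lda(X, y)
    lda2 = fit_lda(X[perm], y[perm])
    np.testing.assert_allclose(lda1.discriminants, lda2.discriminants, atol=1e-8)
    np.testing.assert_allclose(lda1.class_means_ld, lda2.class_means_ld, atol=1e-8)


def test_lda_small_class_error():
    X = np.array([[0.0, 0], [1, 0], [5, 5]])
    with pytest.raises(ValueError, match="fewer than 2"):
        fit_lda(X, ["a", "a", "b"])


def test_lda_identical_means_warns_but_returns():
    rng = np.random.default_rng(7)
    X = rng.normal(size=(40, 3))
    y = np.array(["a", "b"] * 20, dtype=object)
    X[1::2] = X[::2]  # classes literally identical
    with pytest.warns(RuntimeWarning, match="degenerate"):
        lda = fit_lda(X, y)
    assert lda.n_ld == 1


def test_two_class_ld1_matches_closed_form():
    """LD1 is collinear with S_w^-1 (mu_1 - mu_2) for two classes."""
    for seed in range(5):
        rng = np.random.default_rng(100 + seed)
        A = rng.normal(size=(15, 4)) @ rng.normal(size=(4, 4)) + rng.normal(size=4)
        B = rng.normal(size=(12, 4)) @ rng.normal(size=(4, 4)) + rng.normal(size=4)
        X = np.vstack([A, B])
        y = np.array(["a"] * 15 + ["b"] * 12, dtype=object)
        lda = fit_lda(X, y)
        Sw = np.zeros((4, 4))
        for G in (A, B):
            R = G - G.mean(axis=0)
            Sw += R.T @ R
        w_ref = np.linalg.solve(Sw, A.mean(axis=0) - B.mean(axis=0))
        w = lda.discriminants[:, 0]
        cos = abs(w @ w_ref) / (np.linalg.norm(w) * np.linalg.norm(w_ref))
        assert cos == pytest.approx(1.0, abs=1e-6)


def test_lda_subspace_matches_sklearn_oracle():
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

    rng = np.random.default_rng(8)
    X, y = _blobs(rng, {"a": (0, 0, 0), "b": (4, 1, 0), "c": (1, 4, 2)}, n_per=30)
    lda = fit_lda(X, y)
    ref = LinearDiscriminantAnalysis(solver="eigen").fit(X, y.astype(str))
    W_ours = lda.discriminants
    W_ref = ref.scalings_[:, :2]
    # identical 2-D subspaces: projecting one basis onto the other loses nothing
    Q, _ = np.linalg.qr(W_ref)
    proj = Q @ (Q.T @ W_ours)
    np.testing.assert_allclose(
        np.linalg.norm(proj, axis=0), np.linalg.norm(W_ours, axis=0), rtol=1e-6
    )


# ------------------------------------------------------------------- NCM


def test_ncm_at_class_mean_and_geometry():
    rng = np.random.default_rng(9)
    X, y = _blobs(rng, {"a": (-1.0,), "b": (1.0,)}, sd=0.1)
    lda = fit_lda(X, y)
    res = ncm_classify(lda, lda.class_means_ld[0][None, :])
    assert res.labels[0] == "a"
    assert res.distances.iloc[0]["a"] == pytest.approx(0.0, abs=1e-12)
    # sample at +0.2 between means at -1 / +1 goes to the +1 class
    z_plus = lda.transform(np.array([[0.2]]))
    m_a, m_b = lda.class_means_ld[:, 0]
    closer = "a" if abs(z_plus[0, 0] - m_a) < abs(z_plus[0, 0] - m_b) else "b"
    assert ncm_classify(lda, z_plus).labels[0] == closer


def test_ncm_tie_breaks_lexicographically_and_flags():
    lda = fit_lda(
        np.array([[-1.0], [-1.1], [1.0], [1.1]]), np.array(["b", "b", "z", "z"], dtype=object)
    )
    mid = lda.class_means_ld.mean(axis=0)[None, :]
    res = ncm_classify(lda, mid)
    assert res.labels[0] == "b"  # smallest label wins the tie
    assert bool(res.tied[0])


def test_ncm_dimension_mismatch_error():
    lda = fit_lda(np.array([[0.0], [0.1], [5.0], [5.1]]), ["a", "a", "b", "b"])
    with pytest.raises(ValueError, match="dimension"):
        ncm_classify(lda, np.zeros((1, 3)))


# -------------------------------------------------------------- ellipses


def test_confidence_ellipse_isotropic_radius():
    rng = np.random.default_rng(10)
    P = rng.normal(size=(200, 2))
    # whiten to exactly unit sample covariance
    P = P - P.mean(axis=0)
    L = np.linalg.cholesky(np.cov(P, rowvar=False, ddof=1))
    P = P @ np.linalg.inv(L).T
    ell = confidence_ellipse(P, level=0.95)
    expected = np.sqrt(chi2.ppf(0.95, 2))  # ~ 2.4477
    assert ell.semi_axes[0] == pytest.approx(expected, abs=1e-6)
    assert ell.semi_axes[1] == pytest.approx(expected, abs=1e-6)


def test_confidence_ellipse_level_zero_degenerate():
    rng = np.random.default_rng(11)
    ell = confidence_ellipse(rng.normal(size=(50, 2)), level=0.0)
    assert ell.semi_axes == (0.0, 0.0)


def test_confidence_ellipse_rotation_equivariance():
    rng = np.random.default_rng(12)
    P = rng.normal(size=(100, 2)) * np.array([3.0, 0.5])
    theta = 0.7
    R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    e1 = confidence_ellipse(P)
    e2 = confidence_ellipse(P @ R.T)
    d = (e2.orientation - e1.orientation - theta) % np.pi
    assert min(d, np.pi - d) == pytest.approx(0.0, abs=1e-6)
    np.testing.assert_allclose(e2.semi_axes, e1.semi_axes, rtol=1e-9)


def test_confidence_ellipse_singular_error():
    P = np.column_stack([np.arange(5.0), np.arange(5.0)])  # perfectly collinear
    with pytest.raises(ValueError, match="singular"):
        confidence_ellipse(P)


# ---------------------------------------------------------- marker tools


def test_ld_loading_vector_dimensions(raw_features):
    model = fit_classifier(raw_features)
    W = ld_loadings_in_bucket_space(model)
    assert W.shape == (raw_features.n_buckets, 3)  # 970 buckets, 4 classes


def test_carnosine_only_contrast_top_loading(carnosine_only_features, carnosine_peak_shifts):
    """When only carnosine differs, the strongest LD1 bucket is a carnosine bucket."""
    fm = carnosine_only_features
    model = fit_classifier(fm)
    w = np.abs(ld_loadings_in_bucket_space(model)[:, 0])
    top_center = fm.bucket_centers[np.argmax(w)]
    assert min(abs(top_center - s) for s in carnosine_peak_shifts) < 0.009


def test_null_contrast_has_much_weaker_separation(carnosine_only_features):
    """Identical profiles: LD1 separates the (arbitrary) groups far less than
    a real contrast does."""
    fm = carnosine_only_features
    rng = np.random.default_rng(13)
    y_null = np.array(rng.permutation(fm.labels), dtype=object)

    def separation(labels):
        model = fit_classifier(fm, labels=labels)
        z = model.transform(fm.values)[:, 0]
        g1, g2 = (z[labels == c] for c in model.classes)
        pooled = np.sqrt(0.5 * (g1.var(ddof=1) + g2.var(ddof=1)))
        return abs(g1.mean() - g2.mean()) / pooled

    assert separation(y_null) < separation(fm.labels) / 3


def test_two_class_marker_report_directions(raw_features):
    report = two_class_marker_report(raw_features, classes=("pork", "lamb"), top_k=40)
    near = lambda c, s: abs(c - s) < 0.01
    carno = report[[any(near(c, s) for s in (8.500, 7.239, 2.67)) for c in report.bucket_center]]
    anser = report[[any(near(c, s) for s in (8.536, 3.842)) for c in report.bucket_center]]
    assert len(carno) > 0 and (carno.direction_class == "pork").all()
    assert len(anser) > 0 and (anser.direction_class == "lamb").all()


def test_marker_report_one_vs_rest_groups(raw_features):
    report = two_class_marker_report(raw_features, one_vs_rest="poultry", top_k=5)
    assert set(report.direction_class) <= {"poultry", "non-poultry"}
    assert "poultry_median" in report.columns and "non-poultry_median" in report.columns


def test_marker_report_quartile_oracle_and_constant_bucket():
    # two classes, 11 samples each; bucket 0 holds fixed values, bucket 1 constant
    vals = np.array([1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 100.0])
    X = np.zeros((22, 3))
    X[:11, 0] = vals
    X[11:, 0] = vals + 50
    X[:, 1] = 7.7  # constant across all samples
    X[:, 2] = np.linspace(0, 1, 22)
    fm = nm.FeatureMatrix(
        values=X,
        bucket_centers=np.array([1.0, 2.0, 3.0]),
        bucket_edges=np.array([[0.9, 1.1], [1.9, 2.1], [2.9, 3.1]]),
        sample_ids=[f"s{i}" for i in range(22)],
        class_labels=["a"] * 11 + ["b"] * 11,
    )
    report = two_class_marker_report(fm, classes=("a", "b"), top_k=3).set_index("bucket_center")
    row = report.loc[1.0]
    # order-statistics oracle for n=11 with linear interpolation
    assert row["a_min"] == 1.0 and row["a_max"] == 100.0
    assert row["a_q1"] == pytest.approx(3.5)
    assert row["a_median"] == pytest.approx(6.0)
    assert row["a_q3"] == pytest.approx(8.5)
    const = report.loc[2.0]
    assert const["a_q3"] - const["a_q1"] == 0.0  # zero IQR
    with pytest.raises(ValueError, match="top_k"):
        two_class_marker_report(fm, classes=("a", "b"), top_k=99)


def test_relabeling_classes_relabels_outputs(carnosine_only_features):
    fm = carnosine_only_features
    mapping = {"pork": "A", "lamb": "B"}
    y2 = np.array([mapping[c] for c in fm.labels], dtype=object)
    m1 = fit_classifier(fm)
    m2 = fit_classifier(fm, labels=y2)
    p1 = m1.classify(fm.values).labels
    p2 = m2.classify(fm.values).labels
    np.testing.assert_array_equal(np.array([mapping[c] for c in p1], dtype=object), p2)


def test_model_save_load_roundtrip(tmp_path, carnosine_only_features):
    fm = carnosine_only_features
    model = fit_classifier(fm)
    path = model.save(tmp_path / "model.npz")
    back = nm.ClassifierModel.load(path)
    np.testing.assert_array_equal(
        model.classify(fm.values).labels, back.classify(fm.values).labels
    )
    assert back.pretreatment == model.pretreatment
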