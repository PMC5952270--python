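"""OPLS-DA: NIPALS oracle equivalence, orthogonality, S-plot, trajectories."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import urinmr as u
from urinmr.preprocess import BinnedMatrix


def nipals_pls1(X, y):
    """Independent textbook one-component NIPALS PLS1 oracle."""
    w = X.T @ y
    w = w / np.sqrt((w * w).sum())
    t = X @ w
    p = X.T @ t / (t @ t)
    c = (y @ t) / (t @ t)
    return {"w": w, "t": t, "p": p, "c": c}


def scaled_matrix(data, sample_ids=None, rng=None):
    """Wrap a raw matrix as a centered/Pareto-scaled BinnedMatrix."""
    data = np.atleast_2d(data)
    n, p = data.shape
    ids = sample_ids or [f"s{i}" for i in range(n)]
    edges = np.column_stack([np.arange(p, dtype=float),
                             np.arange(p, dtype=float) + 1])
    B = BinnedMatrix(edges=edges, centers=edges.mean(axis=1), data=data,
                     sample_ids=ids, normalized=True)
    return u.center_and_pareto_scale(B)


def balanced_cv(n, ids=None):
    labels = ["A"] * (n // 2) + ["B"] * (n - n // 2)
    ids = ids or [f"s{i}" for i in range(n)]
    return u.ClassVector.from_labels(ids, labels, positive_label="A")


def test_zero_ortho_equals_nipals_pls1():
    rng = np.random.default_rng(10)
    B = scaled_matrix(rng.normal(size=(20, 40)))
    cv = balanced_cv(20)
    model = u.fit_oplsda(B, cv, n_ortho=0)
    oracle = nipals_pls1(B.data, cv.y)
    sign = np.sign(model.weights @ oracle["w"])
    assert np.allclose(model.weights, sign * oracle["w"], atol=1e-8)
    assert np.allclose(model.scores, sign * oracle["t"], atol=1e-8)
    assert np.allclose(model.loadings, sign * oracle["p"], atol=1e-8)


def test_informative_column_has_top_correlation():
    rng = np.random.default_rng(11)
    cv = balanced_cv(30)
    X = rng.normal(size=(30, 25))
    X[:, 7] = cv.y + 0.05 * rng.normal(size=30)
    model = u.fit_oplsda(scaled_matrix(X), cv, n_ortho=1)
    assert int(np.argmax(np.abs(model.correlation))) == 7


@pytest.mark.parametrize("n_ortho", [1, 2, 3])
def test_score_orthogonality(n_ortho):
    rng = np.random.default_rng(12 + n_ortho)
    B = scaled_matrix(rng.normal(size=(25, 30)))
    cv = balanced_cv(25)
    model = u.fit_oplsda(B, cv, n_ortho=n_ortho)
    for k in range(n_ortho):
        assert abs(model.scores @ model.ortho_scores[k]) < 1e-8
        assert abs(cv.y @ model.ortho_scores[k]) < 1e-8
        assert np.linalg.norm(model.ortho_weights[k]) == pytest.approx(1.0)
    assert np.linalg.norm(model.weights) == pytest.approx(1.0)
    assert np.all(np.abs(model.correlation) <= 1 + 1e-12)


def test_r2y_never_decreases_with_more_ortho_components():
    rng = np.random.default_rng(14)
    B = scaled_matrix(rng.normal(size=(20, 30)))
    cv = balanced_cv(20)
    r2 = [u.fit_oplsda(B, cv, k).r2y for k in range(4)]
    assert np.all(np.diff(r2) >= -1e-12)


def test_predict_reproduces_training_fit():
    rng = np.random.default_rng(15)
    B = scaled_matrix(rng.normal(size=(16, 20)))
    cv = balanced_cv(16)
    model = u.fit_oplsda(B, cv, n_ortho=1)
    pred = u.predict(model, B)
    assert np.allclose(pred["y_score"], model.fitted_values, atol=1e-10)
    assert np.allclose(pred["t"], model.scores, atol=1e-10)
    # duplicated rows give duplicated predictions
    dup = u.predict(model, np.vstack([B.data[3], B.data[3]]))
    assert dup["t"].iloc[0] == dup["t"].iloc[1]


def test_predict_column_mismatch_raises():
    rng = np.random.default_rng(16)
    model = u.fit_oplsda(scaled_matrix(rng.normal(size=(12, 10))),
                         balanced_cv(12), 0)
    with pytest.raises(ValueError, match="column count"):
        u.predict(model, np.ones((2, 7)))


def test_splot_against_pearson_oracle():
    rng = np.random.default_rng(17)
    B = scaled_matrix(rng.normal(size=(24, 15)))
    cv = balanced_cv(24)
    model = u.fit_oplsda(B, cv, n_ortho=1)
    table = u.splot(model)
    for j in range(15):
        r = stats.pearsonr(model.scores, B.data[:, j]).statistic
        assert table["correlation"].iloc[j] == pytest.approx(r, abs=1e-10)


def test_splot_rank_one_matrix_gives_unit_correlations():
    rng = np.random.default_rng(18)
    cv = balanced_cv(14)
    d = rng.uniform(0.5, 2.0, size=8) * np.sign(rng.normal(size=8))
    X = np.outer(cv.y, d)
    model = u.fit_oplsda(scaled_matrix(X), cv, n_ortho=0)
    table = u.splot(model)
    assert np.allclose(np.abs(table["correlation"]), 1.0, atol=1e-8)
    assert np.array_equal(np.sign(table["correlation"]),
                          np.sign(d) * np.sign(table["correlation"].iloc[0]
                                               * np.sign(d[0])))


def test_splot_zero_variance_bin_flagged():
    rng = np.random.default_rng(19)
    X = rng.normal(size=(12, 6))
    X[:, 2] = 3.14  # constant column
    model = u.fit_oplsda(scaled_matrix(X), balanced_cv(12), 0)
    table = u.splot(model)
    assert table["degenerate"].iloc[2]
    assert table["correlation"].iloc[2] == 0.0
    assert table["covariance"].iloc[2] == pytest.approx(0.0, abs=1e-12)


def test_scores_invariant_to_column_permutation():
    rng = np.random.default_rng(20)
    X = rng.normal(size=(18, 22))
    cv = balanced_cv(18)
    perm = rng.permutation(22)
    m1 = u.fit_oplsda(scaled_matrix(X), cv, n_ortho=1)
    m2 = u.fit_oplsda(scaled_matrix(X[:, perm]), cv, n_ortho=1)
    assert np.allclose(m1.scores, m2.scores, atol=1e-8)
    assert np.allclose(m1.weights[perm], m2.weights, atol=1e-8)


def test_planted_direction_recovered():
    """One discriminant direction plus stronger orthogonal structure:
    the predictive weight recovers the planted direction."""
    rng = np.random.default_rng(21)
    n, p = 40, 50
    cv = balanced_cv(n)
    d = rng.normal(size=p)
    d /= np.linalg.norm(d)
    e = rng.normal(size=p)
    e -= (e @ d) * d
    e /= np.linalg.norm(e)
    z = rng.normal(size=n)  # orthogonal structured noise
    X = 2.0 * np.outer(cv.y, d) + 4.0 * np.outer(z, e) \
        + 0.05 * rng.normal(size=(n, p))
    model = u.fit_oplsda(scaled_matrix(X), cv, n_ortho=1)
    cos = abs(model.weights @ d)
    assert cos > 0.95


def test_fit_requires_scaled_matrix_and_matching_ids():
    rng = np.random.default_rng(22)
    B = scaled_matrix(rng.normal(size=(10, 8)))
    cv = balanced_cv(10, ids=[f"x{i}" for i in range(10)])
    with pytest.raises(ValueError, match="ids"):
        u.fit_oplsda(B, cv, 0)
    with pytest.raises(ValueError, match="rank"):
        u.fit_oplsda(B, balanced_cv(10), n_ortho=9)


def test_class_vector_requires_two_levels():
    with pytest.raises(ValueError, match="two class levels"):
        u.ClassVector.from_labels(["a", "b"], ["A", "A"])


# ---------------------------------------------------------------- trajectory


def _scores_frame(ids, t, to):
    return pd.DataFrame({"sample_id": ids, "t": t, "t_ortho1": to})


def test_trajectory_single_sample_cells_equal_scores():
    meta = pd.DataFrame({"sample_id": ["a", "b"], "group": ["NC", "NC"],
                         "period": ["T1", "T2"]})
    traj = u.trajectory(_scores_frame(["a", "b"], [1.5, -2.0], [0.3, 0.4]),
                        meta, ["NC"], ["T1", "T2"])
    assert traj["mean_t"].tolist() == [1.5, -2.0]
    assert traj["period"].tolist() == ["T1", "T2"]


def test_trajectory_symmetric_scores_average_to_zero():
    meta = pd.DataFrame({"sample_id": ["a", "b"], "group": ["NC", "NC"],
                         "period": ["T1", "T1"]})
    traj = u.trajectory(_scores_frame(["a", "b"], [2.0, -2.0], [1.0, -1.0]),
                        meta, ["NC"], ["T1"])
    assert traj["mean_t"].iloc[0] == 0.0
    assert traj["mean_t_ortho1"].iloc[0] == 0.0


def test_trajectory_empty_cell_warns_and_is_omitted():
    meta = pd.DataFrame({"sample_id": ["a"], "group": ["NC"],
                         "period": ["T1"]})
    with pytest.warns(UserWarning, match="omitted"):
        traj = u.trajectory(_scores_frame(["a"], [1.0], [0.0]), meta,
                            ["NC"], ["T1", "T2"])
    assert len(traj) == 1


def test_trajectory_decaying_effect_approaches_control(library):
    """A planted effect that decays over periods pulls the affected
    group's trajectory back toward the control centroid."""
    decay = {"T1": 3.0, "T4": 1.7, "T8": 1.05}
    effects = [u.EffectSpec("glutamate", ("TAA",), decay),
               u.EffectSpec("citrate", ("TAA",),
                            {p: 1 / f for p, f in decay.items()})]
    design = u.CohortDesign(groups=("NC", "TAA"), n_subjects=8,
                            periods=("T1", "T4", "T8"))
    X, meta, _ = u.generate_cohort(design, library, effects,
                                   u.NoiseModel(seed=23), ppm_step=0.002)
    norm, scaled = u.standard_preprocess(X)
    cv = u.ClassVector.from_labels(
        scaled.sample_ids,
        meta.set_index("sample_id").loc[scaled.sample_ids, "group"], "TAA")
    model = u.fit_oplsda(scaled, cv, n_ortho=1)
    traj = u.trajectory(u.training_scores(model), meta, ["NC", "TAA"],
                        ["T1", "T4", "T8"])
    nc = traj[traj["group"] == "NC"][["mean_t", "mean_t_ortho1"]].mean()
    taa = traj[traj["group"] == "TAA"].set_index("period")
    dist = {p: np.hypot(taa.loc[p, "mean_t"] - nc["mean_t"],
                        taa.loc[p, "mean_t_ortho1"] - nc["mean_t_ortho1"])
            for p in ("T1", "T4", "T8")}
    assert dist["T1"] > dist["T4"] > dist["T8"]
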