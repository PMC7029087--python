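"""GPA, shape PCA, permutational GLMs, DFA and genital classification."""

import numpy as np
import pandas as pd
import pytest

from hybridscan.core_data import LandmarkSet, default_slider_spec
from hybridscan.morphometrics import (
    align_to_reference,
    centroid_size,
    concordance_report,
    genitalia_dfa,
    genitalia_visual_classify,
    gpa_align,
    predict_shape_dfa,
    procrustes_glm,
    shape_pca,
    train_shape_dfa,
)
from hybridscan.synthetic_data import mean_shapes


def _noisy_set(n, shape, noise, rng, sliders=True):
    X = np.stack([shape + rng.normal(0, noise, shape.shape) for _ in range(n)])
    return LandmarkSet(
        sample_ids=[f"s{i}" for i in range(n)],
        configurations=X,
        slider_spec=default_slider_spec() if sliders else [],
    )


def test_centroid_size_hand_computed():
    square = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
    # each corner is sqrt(0.5) from the centroid: CS = sqrt(4 * 0.5) = sqrt(2)
    assert centroid_size(square) == pytest.approx(np.sqrt(2.0))


def test_gpa_similarity_invariance():
    rng = np.random.default_rng(0)
    base = mean_shapes(0.06)["fabalis"] + rng.normal(0, 0.01, (28, 2))
    configs = [base]
    for _ in range(4):
        a = rng.uniform(0, 2 * np.pi)
        R = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
        configs.append(base @ R * rng.uniform(0.5, 3.0) + rng.uniform(-4, 4, 2))
    lms = LandmarkSet(
        sample_ids=[f"s{i}" for i in range(5)],
        configurations=np.stack(configs),
        slider_spec=default_slider_spec(),
    )
    al = gpa_align(lms)
    assert np.abs(al.aligned - al.aligned[0]).max() < 1e-9
    assert np.abs(al.shape_variables).max() < 1e-9
    # centroid sizes recorded before scaling
    assert al.centroid_sizes[0] == pytest.approx(centroid_size(base))


def test_gpa_matches_plain_procrustes_oracle():
    """With sliding off, the alignment equals an independent plain GPA."""
    rng = np.random.default_rng(1)
    shape = mean_shapes(0.06)["obtusata"]
    lms = _noisy_set(5, shape, 0.02, rng, sliders=False)
    al = gpa_align(lms, slide=False, max_iter=200, tol=1e-12)

    # oracle: naive iterative GPA written independently of the implementation
    X = lms.configurations.copy()
    for i in range(5):
        X[i] -= X[i].mean(0)
        X[i] /= np.sqrt((X[i] ** 2).sum())
    cons = X[0].copy()
    for _ in range(200):
        for i in range(5):
            u, _, vt = np.linalg.svd(X[i].T @ cons)
            if np.linalg.det(u @ vt) < 0:
                u[:, -1] *= -1
            X[i] = X[i] @ (u @ vt)
        new = X.mean(0)
        new -= new.mean(0)
        new /= np.sqrt((new ** 2).sum())
        if np.abs(new - cons).max() < 1e-12:
            break
        cons = new
    for i in range(5):
        u, _, vt = np.linalg.svd(X[i].T @ cons)
        if np.linalg.det(u @ vt) < 0:
            u[:, -1] *= -1
        X[i] = X[i] @ (u @ vt)
    assert np.abs(al.aligned - X).max() < 1e-6


def test_gpa_degenerate_configuration_errors():
    lms = LandmarkSet(
        sample_ids=["ok", "bad"],
        configurations=np.stack(
            [mean_shapes(0.06)["fabalis"], np.zeros((28, 2))]
        ),
        slider_spec=[],
    )
    with pytest.raises(ValueError, match="bad"):
        gpa_align(lms)


def test_effective_shape_dimensionality_at_most_52():
    rng = np.random.default_rng(2)
    lms = _noisy_set(60, mean_shapes(0.06)["fabalis"], 0.01, rng)
    al = gpa_align(lms)
    sv = al.shape_variables
    assert np.linalg.matrix_rank(sv - sv.mean(0), tol=1e-8) <= 52


def test_shape_pca_conservation_and_separation():
    rng = np.random.default_rng(3)
    ms = mean_shapes(0.2)
    lms_f = _noisy_set(30, ms["fabalis"], 0.005, rng)
    lms_o = _noisy_set(30, ms["obtusata"], 0.005, rng)
    both = LandmarkSet(
        sample_ids=lms_f.sample_ids + [s + "o" for s in lms_o.sample_ids],
        configurations=np.vstack([lms_f.configurations, lms_o.configurations]),
        slider_spec=default_slider_spec(),
    )
    al = gpa_align(both)
    p = shape_pca(al)
    total = ((al.shape_variables - al.shape_variables.mean(0)) ** 2).sum() / 59
    assert p["eigenvalues"].sum() == pytest.approx(total)
    pc1 = p["scores"][:, 0]
    assert abs(pc1[:30].mean() - pc1[30:].mean()) > 3 * (pc1[:30].std() + pc1[30:].std())


def test_glm_determinism_and_saturation():
    rng = np.random.default_rng(4)
    Y = np.vstack([rng.normal(0, 0.05, (20, 6)), rng.normal(2, 0.05, (20, 6))])
    data = pd.DataFrame({"g": ["a"] * 20 + ["b"] * 20})
    r1 = procrustes_glm(Y, data, ["g"], nperm=499, seed=7)
    r2 = procrustes_glm(Y, data, ["g"], nperm=499, seed=7)
    pd.testing.assert_frame_equal(r1.table, r2.table)
    assert r1.term("g")["p"] == pytest.approx(1 / 500)
    assert r1.term("g")["Z"] > 1  # log-scale standardized effect, positive
    # df bookkeeping: term dfs + residual df = total df
    t = r1.table.set_index("term")
    assert t.loc["g", "df"] + t.loc["Residuals", "df"] == t.loc["Total", "df"]


def test_glm_sequential_terms_and_covariate():
    rng = np.random.default_rng(5)
    n = 60
    size = rng.normal(2, 0.3, n)
    grp = np.repeat(["a", "b", "c"], n // 3)
    Y = size[:, None] * 0.5 + rng.normal(0, 0.2, (n, 4))
    data = pd.DataFrame({"cs": size, "g": grp})
    res = procrustes_glm(Y, data, ["cs", "g"], nperm=199, seed=8)
    assert res.term("cs")["p"] <= 0.05  # injected allometry detected
    assert res.term("g")["df"] == 2


def test_glm_degenerate_level_errors():
    Y = np.random.default_rng(6).normal(size=(5, 3))
    data = pd.DataFrame({"g": ["a", "a", "a", "a", "b"]})
    with pytest.raises(ValueError, match="b"):
        procrustes_glm(Y, data, ["g"], nperm=19, seed=0)


def test_dfa_posteriors_and_boundary():
    rng = np.random.default_rng(7)
    X = np.vstack([rng.normal(0, 1, (60, 5)), rng.normal([6, 0, 0, 0, 0], 1, (60, 5))])
    y = ["fabalis"] * 60 + ["obtusata"] * 60
    model = train_shape_dfa(X, y)
    assert np.allclose(model.loocv_posteriors.sum(axis=1), 1.0)
    acc = (
        np.array(y)
        == np.array([model.classes[i] for i in model.loocv_posteriors.argmax(1)])
    ).mean()
    assert acc >= 0.97
    pred = predict_shape_dfa(model, X[:5])
    assert set(pred.columns) >= {"sample_id", "fabalis", "obtusata", "label"}
    # exactly-at-cutoff posteriors are assigned (inclusive rule)
    from hybridscan.morphometrics.dfa import _labels_from_pp

    assert _labels_from_pp(np.array([[0.90, 0.10]]), ["fabalis", "obtusata"], 0.90) == ["fabalis"]
    assert _labels_from_pp(np.array([[0.6, 0.4]]), ["fabalis", "obtusata"], 0.90) == ["intermediate"]


def test_dfa_chance_level_when_identical():
    rng = np.random.default_rng(8)
    X = rng.normal(size=(120, 5))
    y = ["fabalis"] * 60 + ["obtusata"] * 60
    model = train_shape_dfa(X, y)
    acc = (
        np.array(y)
        == np.array([model.classes[i] for i in model.loocv_posteriors.argmax(1)])
    ).mean()
    assert 0.30 <= acc <= 0.70  # binomial band around chance


def test_align_to_reference_frames():
    rng = np.random.default_rng(9)
    ms = mean_shapes(0.1)
    train = _noisy_set(20, ms["fabalis"], 0.01, rng)
    ref = gpa_align(train)
    new = _noisy_set(5, ms["fabalis"], 0.01, rng)
    al = align_to_reference(new, ref)
    assert np.allclose(al.consensus, ref.consensus)
    assert np.abs(al.shape_variables).max() < 0.2


def test_genitalia_visual_bands():
    assert genitalia_visual_classify(2.0, 10.0) == "obtusata"  # ratio 0.20
    assert genitalia_visual_classify(4.5, 10.0) == "fabalis"  # ratio 0.45
    assert genitalia_visual_classify(0.5, 10.0) == "unknown"  # ratio 0.05
    assert genitalia_visual_classify(2.7, 10.0) == "intermediate"
    assert genitalia_visual_classify(2.5, 10.0) == "obtusata"  # inclusive edge
    assert genitalia_visual_classify(3.0, 10.0) == "fabalis"
    with pytest.raises(ValueError):
        genitalia_visual_classify(-1.0, 10.0)


def test_genitalia_dfa_priors_and_separation():
    rng = np.random.default_rng(10)
    mf = np.array([2.0, 4.5, 1.0, 3.0, 15.0, 0.8, 0.3])
    mo = np.array([0.9, 5.0, 2.0, 6.0, 40.0, 1.0, 0.35])
    sd = np.array([0.1, 0.2, 0.1, 0.4, 1.5, 0.05, 0.03])
    rows, ids, labels = [], [], []
    for i in range(24):
        rows.append(rng.normal(mf, sd)); ids.append(f"f{i}"); labels.append("fabalis")
    for i in range(44):
        rows.append(rng.normal(mo, sd)); ids.append(f"o{i}"); labels.append("obtusata")
    df = pd.DataFrame(rows, columns=[f"v{i}" for i in range(7)])
    df.insert(0, "sample_id", ids)
    df.loc[len(df)] = ["missing"] + [1.0] * 6 + [np.nan]
    res = genitalia_dfa(df, ids, labels, cutoff=0.99)
    assert res["priors"]["fabalis"] == pytest.approx(24 / 68)
    assert res["priors"]["obtusata"] == pytest.approx(44 / 68)
    assert res["excluded"] == ["missing"]
    frac_assigned = (res["loocv"]["label"] != "intermediate").mean()
    assert frac_assigned >= 0.95


def test_concordance_report_identical_and_disjoint():
    meta = pd.DataFrame(
        {"sample_id": ["a", "b", "c"], "location": ["X"] * 3, "context": ["sympatric"] * 3}
    )
    labels = {"a": "fabalis", "b": "obtusata", "c": "fabalis"}
    rep = concordance_report({"genetic": labels, "shape": dict(labels)}, meta)
    assert rep[("genetic", "shape")]["concordance"] == 1.0
    with pytest.warns(UserWarning, match="no samples shared"):
        rep2 = concordance_report(
            {"genetic": {"a": "fabalis"}, "shape": {"z": "fabalis"}}, meta
        )
    assert rep2[("genetic", "shape")]["n"] == 0


from hypothesis import given, settings as hyp_settings
from hypothesis import strategies as st


@given(
    fil=st.floats(min_value=0.0, max_value=100.0, allow_nan=False),
    tot=st.floats(min_value=0.01, max_value=100.0, allow_nan=False),
)
@hyp_settings(max_examples=200, derandomize=True)
def test_visual_classifier_is_total_and_band_consistent(fil, tot):
    """Every non-negative ratio maps to exactly one label, consistent with
    the published bands."""
    label = genitalia_visual_classify(fil, tot)
    r = fil / tot
    if 0.10 <= r <= 0.25:
        assert label == "obtusata"
    elif 0.25 < r < 0.30:
        assert label == "intermediate"
    elif 0.30 <= r <= 0.60:
        assert label == "fabalis"
    else:
        assert label == "unknown"
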