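"""Regression-concept-vector interpretability: measures, RCV fits, sensitivities, Br."""

import numpy as np
import pytest

from semipatch.errors import (
    ConfigurationError,
    DataError,
    DegenerateError,
    UndefinedMeasureError,
)
from semipatch.interpret import (
    ConceptMeasure,
    br_score,
    br_significance,
    concept_measures,
    cross_val_r2,
    finite_difference_sensitivity,
    fit_rcv,
    layer_r2_profile,
    pearson_screen,
    pooled_activations,
    scale_br,
    sensitivity_scores,
)
from semipatch.nn import Dense, Reshape, Sequential, Sigmoid, Softmax
from semipatch.synthio import ConceptPatch, SynthConfig, generate_concept_dataset


def _concept(image, mask=None):
    if mask is None:
        mask = np.ones(image.shape[:2], dtype=np.uint8)
    return ConceptPatch(image=image, mask=mask, planted={})


def _linear_model(w, b=0.0):
    """f_c(x) = x @ w[:, c] + b, probed at its own input layer."""
    d, c = w.shape
    rng = np.random.default_rng(0)
    dense = Dense(d, c, rng, name="lin")
    dense.params["w"] = np.asarray(w, dtype=float)
    dense.params["b"] = np.full(c, float(b))
    return Sequential([Reshape((d,), name="input"), dense], name="linear")


# -- Haralick and morphology oracles ---------------------------------------

def test_constant_image_has_asm_one_and_contrast_zero():
    img = np.full((16, 16, 3), 0.5)
    [asm, contrast] = concept_measures([_concept(img)], measures=("asm", "contrast"))
    assert asm.values[0] == pytest.approx(1.0, abs=1e-12)
    assert contrast.values[0] == pytest.approx(0.0, abs=1e-12)


def test_constant_image_correlation_is_undefined():
    img = np.full((16, 16, 3), 0.5)
    with pytest.raises(UndefinedMeasureError, match="correlation"):
        concept_measures([_concept(img)], measures=("correlation",))


def test_checkerboard_contrast_equals_squared_level_difference():
    """Hand-enumerated horizontal-offset GLCM of a two-level checkerboard:
    every co-occurring pair differs by delta, so contrast = delta^2."""
    lo, hi = 8, 20  # quantised grey levels out of 32
    board = np.indices((16, 16)).sum(axis=0) % 2
    gray = np.where(board == 1, (hi + 0.5) / 32, (lo + 0.5) / 32)
    img = np.repeat(gray[:, :, None], 3, axis=2)
    [contrast] = concept_measures(
        [_concept(img)], measures=("contrast",), glcm_params={"angles": (0.0,)}
    )
    assert contrast.values[0] == pytest.approx((hi - lo) ** 2, abs=1e-9)


def test_filled_disk_morphology():
    patches = generate_concept_dataset(
        SynthConfig(seed=5), 3, n_nuclei_range=(1, 1), radius_range=(10.0, 10.0), ecc_range=(0.0, 0.0)
    )
    area, euler, ecc = concept_measures(patches, measures=("area", "euler", "eccentricity"))
    for a in area.values:
        assert abs(a - np.pi * 100) <= 0.05 * np.pi * 100
    assert (euler.values == 1).all()
    assert (ecc.values <= 0.15).all()


def test_empty_mask_morphology_is_undefined():
    img = np.random.default_rng(0).random((16, 16, 3))
    patch = _concept(img, mask=np.zeros((16, 16), dtype=np.uint8))
    with pytest.raises(UndefinedMeasureError, match="empty mask"):
        concept_measures([patch], measures=("area",))


# -- Pearson screening ------------------------------------------------------

def test_pearson_perfect_correlations():
    x = np.linspace(0, 1, 20)
    assert pearson_screen(x, x)[0] == pytest.approx(1.0)
    assert pearson_screen(x, -x)[0] == pytest.approx(-1.0)


def test_pearson_attenuation_matches_closed_form():
    """y = x + noise(sd 0.5) attenuates rho to 1/sqrt(1 + 0.25/var(x))."""
    rng = np.random.default_rng(7)
    x = rng.normal(0.0, 1.0, 200)
    y = x + rng.normal(0.0, 0.5, 200)
    rho, p = pearson_screen(x, y)
    expected = 1.0 / np.sqrt(1.0 + 0.25 / x.var())
    assert rho == pytest.approx(expected, abs=0.1)
    assert p < 1e-6


def test_pearson_constant_input_is_degenerate():
    with pytest.raises(DegenerateError):
        pearson_screen(np.ones(10), np.arange(10.0))


# -- RCV fitting ------------------------------------------------------------

def test_exact_linear_concept_is_recovered_perfectly():
    rng = np.random.default_rng(1)
    A = rng.normal(size=(60, 10))
    w = rng.normal(size=10)
    cv = fit_rcv(A, A @ w + 2.0)
    assert cv.r_squared == pytest.approx(1.0, abs=1e-9)
    cos = abs(cv.v @ (w / np.linalg.norm(w)))
    assert cos >= 1.0 - 1e-9
    assert np.linalg.norm(cv.v) == pytest.approx(1.0, abs=1e-9)


def test_pure_noise_concept_has_low_cross_validated_r2():
    rng = np.random.default_rng(2)
    A = rng.normal(size=(500, 10))
    noise = rng.normal(size=500)
    assert cross_val_r2(A, noise, folds=10, seed=0) <= 0.1


def test_rank_deficient_design_requires_ridge_fallback():
    rng = np.random.default_rng(3)
    A = rng.normal(size=(5, 10))  # n < dim
    c = rng.normal(size=5)
    with pytest.raises(DataError, match="rank-deficient"):
        fit_rcv(A, c, ridge_fallback=False)
    cv = fit_rcv(A, c, ridge_fallback=True)
    assert np.linalg.norm(cv.v) == pytest.approx(1.0, abs=1e-9)


# -- layer profiling --------------------------------------------------------

def test_planted_concept_is_located_at_the_last_pooling_layer(tiny_cnn, small_patches):
    images = small_patches.images[:30]
    acts = pooled_activations(tiny_cnn, images, "pool3")
    u = np.random.default_rng(4).normal(size=acts.shape[1])
    concept = acts @ u
    frame, best = layer_r2_profile(
        tiny_cnn, images, concept, ["relu1", "relu2", "pool3"], folds=5, reps=3, seed=0
    )
    assert best == "pool3"
    assert len(frame) == 3


def test_minimal_profile_runs(tiny_cnn, small_patches):
    images = small_patches.images[:4]
    vals = np.arange(4.0)
    frame, _ = layer_r2_profile(tiny_cnn, images, vals, ["pool3"], folds=2, reps=1)
    assert len(frame) == 1


def test_profile_needs_enough_patches(tiny_cnn, small_patches):
    with pytest.raises(ConfigurationError):
        layer_r2_profile(tiny_cnn, small_patches.images[:4], np.arange(4.0), ["pool3"], folds=10)


# -- sensitivities ----------------------------------------------------------

def test_linear_model_sensitivity_has_closed_form():
    rng = np.random.default_rng(5)
    w = rng.normal(size=(6, 2))
    model = _linear_model(w)
    X = rng.normal(size=(8, 6))
    v = rng.normal(size=6)
    v /= np.linalg.norm(v)
    S = sensitivity_scores(model, "input", X, v, class_index=1)
    assert np.allclose(S, w[:, 1] @ v, atol=1e-6)


def test_orthogonal_direction_has_zero_sensitivity():
    rng = np.random.default_rng(6)
    w = rng.normal(size=(6, 2))
    model = _linear_model(w)
    # Gram-Schmidt: v orthogonal to the class-1 weight column
    u = w[:, 1] / np.linalg.norm(w[:, 1])
    r = rng.normal(size=6)
    v_orth = r - (r @ u) * u
    v_orth /= np.linalg.norm(v_orth)
    S = sensitivity_scores(model, "input", rng.normal(size=(5, 6)), v_orth, class_index=1)
    assert np.allclose(S, 0.0, atol=1e-8)


@pytest.mark.parametrize("layer,eps", [("pool3", 1e-3), ("gap", 1e-3), ("relu2", 1e-4)])
def test_autodiff_sensitivity_matches_finite_differences(tiny_cnn, small_patches, layer, eps):
    images = small_patches.images[:10]
    acts = pooled_activations(tiny_cnn, images, layer)
    rng = np.random.default_rng(8)
    v = rng.normal(size=acts.shape[1])
    v /= np.linalg.norm(v)
    S = sensitivity_scores(tiny_cnn, layer, images, v)
    S_fd = finite_difference_sensitivity(tiny_cnn, layer, images, v, eps=eps)
    rel = np.abs(S - S_fd).max() / (np.abs(S_fd).max() + 1e-12)
    assert rel <= 1e-3


# -- Br score ---------------------------------------------------------------

def test_br_arithmetic_on_hand_computable_inputs():
    # sample SD of (1, 2, 3) is 1, mean 2 -> Br = 0.5 * 1/2 = 0.25
    assert br_score(0.5, np.array([1.0, 2.0, 3.0])) == pytest.approx(0.25, abs=1e-12)
    assert br_score(0.7, np.array([2.0, 2.0, 2.0])) == 0.0  # zero spread
    assert br_score(0.0, np.array([1.0, 5.0, 9.0])) == 0.0  # zero fit quality


def test_br_degenerate_inputs():
    with pytest.raises(DegenerateError):
        br_score(0.5, np.array([1.0, -1.0]))  # zero mean
    with pytest.raises(DataError):
        br_score(0.5, np.array([1.0]))


def test_br_sign_matches_mean_sensitivity_sign():
    rng = np.random.default_rng(9)
    for _ in range(20):
        s = rng.normal(rng.choice([-2.0, 2.0]), 1.0, 30)
        if s.mean() == 0 or s.std(ddof=1) == 0:
            continue
        assert np.sign(br_score(0.4, s)) == np.sign(s.mean())


def test_scale_br_affine_map_and_endpoints():
    scaled = scale_br(np.array([-0.4, 0.1, 0.9]))
    assert np.allclose(scaled, [-1.0, -0.2308, 1.0], atol=1e-4)
    assert np.allclose(scale_br(np.array([0.3, 0.8])), [-1.0, 1.0])
    # idempotence: rescaling a scaled vector changes nothing
    assert np.allclose(scale_br(scaled), scaled)
    with pytest.raises(DegenerateError):
        scale_br(np.array([0.5, 0.5]))


def test_br_significance_behaviour():
    rng = np.random.default_rng(10)
    strong = 1.0 + rng.normal(0, 0.01, 50)
    _, p = br_significance(strong)
    assert p < 1e-6
    null = rng.normal(0, 1.0, 50)
    null = null - null.mean() + rng.normal(0, 0.01)  # symmetric around ~0
    _, p = br_significance(null)
    assert p > 0.05
    with pytest.raises(DataError):
        br_significance(np.array([1.0]))
    with pytest.raises(DegenerateError):
        br_significance(np.full(10, 3.0))


# -- planted-direction recovery ---------------------------------------------

def test_planted_driving_direction_gets_the_maximal_scaled_br():
    """When the model output increases along direction u in activation space,
    the concept measured along u recovers v ~ u and receives the top scaled
    Br; the concept along -u receives the bottom one."""
    rng = np.random.default_rng(11)
    d, n = 8, 300
    A = rng.normal(size=(n, d))
    u = rng.normal(size=d)
    u /= np.linalg.norm(u)
    w = np.column_stack([-u, u])  # class-1 score increases along u
    dense = Dense(d, 2, rng, name="lin")
    dense.params["w"] = w
    dense.params["b"] = np.zeros(2)
    model = Sequential([Reshape((d,), name="feat"), dense, Softmax(name="sm")], name="driven")

    noise = 0.1 * rng.normal(size=n)
    concepts = {
        "planted": A @ u + noise,
        "anti": A @ (-u) + noise,
        "weak": A @ u + 3.0 * rng.normal(size=n),
    }
    raws, cosines = {}, {}
    for name, c in concepts.items():
        cv = fit_rcv(A, c, concept=name)
        sens = sensitivity_scores(model, "feat", A, cv, class_index=1)
        raws[name] = br_score(cv.r_squared, sens)
        cosines[name] = cv.v @ u
    assert cosines["planted"] >= 0.9
    assert cosines["anti"] <= -0.9
    names = list(concepts)
    scaled = dict(zip(names, scale_br(np.array([raws[k] for k in names]))))
    assert scaled["planted"] == 1.0
    assert scaled["anti"] == -1.0
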