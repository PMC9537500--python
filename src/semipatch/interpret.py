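"""Global interpretability via regression concept vectors (RCVs).

Human-interpretable concept measures — nuclei morphology (mean area,
perimeter, Euler number, major-axis length, eccentricity) and Haralick
texture statistics (angular second moment, contrast, correlation) — are
computed on an annotated nuclei dataset. A concept's direction in a chosen
layer's activation space is the unit vector of a least-squares regression of
the concept measure on the (channel-wise pooled) activations; its quality is
the regression R^2, cross-validated per layer to locate where the network
learns the concept. The relevance of a concept to the IDC prediction is
quantified by the sensitivity of the class score along the concept vector
(a directional derivative) over the test set, summarised by the
bidirectional relevance score

    Br = R^2 * (sigma / mu)

with the sample standard deviation and mean of the per-patch sensitivities,
min-max scaled across concepts to [-1, 1], plus a two-tailed one-sample
t-test of the sensitivities against the zero-mean null of a random
direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from skimage.color import rgb2gray
from skimage.feature import graycomatrix, graycoprops
from skimage.measure import euler_number as _euler_number
from skimage.measure import label as _label
from skimage.measure import regionprops

from .errors import ConfigurationError, DataError, DegenerateError, DimensionError, UndefinedMeasureError
from .nn import Sequential
from .synthio import ConceptPatch

__all__ = [
    "MORPHOLOGY_CONCEPTS",
    "TEXTURE_CONCEPTS",
    "ConceptMeasure",
    "ConceptVector",
    "BrReport",
    "concept_measures",
    "pearson_screen",
    "fit_rcv",
    "cross_val_r2",
    "pooled_activations",
    "layer_r2_profile",
    "sensitivity_scores",
    "finite_difference_sensitivity",
    "br_score",
    "scale_br",
    "br_significance",
    "global_interpretability",
]

MORPHOLOGY_CONCEPTS = ("area", "perimeter", "euler", "axis_length", "eccentricity")
TEXTURE_CONCEPTS = ("asm", "contrast", "correlation")
ALL_CONCEPTS = MORPHOLOGY_CONCEPTS + TEXTURE_CONCEPTS

DEFAULT_GLCM = {
    "levels": 32,
    "distances": (1,),
    "angles": (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4),
    "symmetric": True,
    "normed": True,
}


@dataclass
class ConceptMeasure:
    name: str
    values: np.ndarray
    source: str = "concept_dataset"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise DataError(f"concept measure {self.name!r} contains non-finite values")


@dataclass
class ConceptVector:
    """Unit direction of increasing concept value in a layer's pooled activation space."""

    v: np.ndarray
    layer: str
    r_squared: float
    concept: str = ""

    def __post_init__(self):
        self.v = np.asarray(self.v, dtype=float)
        norm = np.linalg.norm(self.v)
        if abs(norm - 1.0) > 1e-9:
            raise DegenerateError(f"concept vector must be unit length, got ||v|| = {norm}")


@dataclass
class BrReport:
    """Per-concept relevance table.

    Columns: concept, rho, rho_p, r2, mu, sigma, br_raw, br_scaled, t, t_p.
    """

    frame: pd.DataFrame
    layer: str = ""
    sensitivities: dict[str, np.ndarray] = field(default_factory=dict)

    def to_json(self) -> str:
        return self.frame.to_json(orient="records")


# ---------------------------------------------------------------------------
# Concept measures
# ---------------------------------------------------------------------------

def _texture_features(gray: np.ndarray, glcm_params: dict) -> dict[str, float]:
    levels = glcm_params["levels"]
    q = np.clip((gray * levels).astype(int), 0, levels - 1).astype(np.uint8)
    glcm = graycomatrix(
        q,
        distances=list(glcm_params["distances"]),
        angles=list(glcm_params["angles"]),
        levels=levels,
        symmetric=glcm_params["symmetric"],
        normed=glcm_params["normed"],
    )
    return {
        "asm": float(graycoprops(glcm, "ASM").mean()),
        "contrast": float(graycoprops(glcm, "contrast").mean()),
        "correlation": float(graycoprops(glcm, "correlation").mean()),
        "_constant": bool(q.min() == q.max()),
    }


def concept_measures(
    patches: list[ConceptPatch],
    measures: tuple[str, ...] = ALL_CONCEPTS,
    glcm_params: dict | None = None,
) -> list[ConceptMeasure]:
    """Compute per-patch concept measures.

    Morphology measures are averaged over the mask's connected components
    (area in px^2, perimeter in px, major-axis length in px, eccentricity in
    [0, 1]); the Euler number is that of the whole mask. Texture measures
    come from a symmetric normalised grey-level co-occurrence matrix of the
    grayscale image (quantised to ``levels`` grey levels), averaged over the
    configured offsets.
    """
    unknown = set(measures) - set(ALL_CONCEPTS)
    if unknown:
        raise ConfigurationError(f"unknown concept measures {sorted(unknown)}")
    params = {**DEFAULT_GLCM, **(glcm_params or {})}
    need_morph = bool(set(measures) & set(MORPHOLOGY_CONCEPTS))
    need_texture = bool(set(measures) & set(TEXTURE_CONCEPTS))
    columns: dict[str, list[float]] = {m: [] for m in measures}
    for i, cp in enumerate(patches):
        if need_morph:
            if cp.mask.sum() == 0:
                raise UndefinedMeasureError(f"patch {i}: empty mask, morphology measures undefined")
            props = regionprops(_label(cp.mask, connectivity=2))
            morph = {
                "area": float(np.mean([p.area for p in props])),
                "perimeter": float(np.mean([p.perimeter for p in props])),
                "euler": float(_euler_number(cp.mask, connectivity=2)),
                "axis_length": float(np.mean([p.axis_major_length for p in props])),
                "eccentricity": float(np.mean([p.eccentricity for p in props])),
            }
            for m in MORPHOLOGY_CONCEPTS:
                if m in columns:
                    columns[m].append(morph[m])
        if need_texture:
            gray = rgb2gray(cp.image) if cp.image.ndim == 3 else cp.image
            tex = _texture_features(gray, params)
            if tex["_constant"] and "correlation" in measures:
                raise UndefinedMeasureError(f"patch {i}: constant grayscale image, correlation undefined")
            for m in TEXTURE_CONCEPTS:
                if m in columns:
                    columns[m].append(tex[m])
    return [ConceptMeasure(name=m, values=np.array(columns[m])) for m in measures]


# ---------------------------------------------------------------------------
# Screening and regression
# ---------------------------------------------------------------------------

def pearson_screen(measure: ConceptMeasure | np.ndarray, predictions: np.ndarray) -> tuple[float, float]:
    """Pearson product-moment correlation between a concept measure and the
    per-patch network prediction, with its two-sided p-value."""
    x = measure.values if isinstance(measure, ConceptMeasure) else np.asarray(measure, dtype=float)
    y = np.asarray(predictions, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise DataError("pearson_screen needs >= 3 aligned pairs")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise DataError("pearson_screen requires finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateError("correlation undefined for a constant input")
    rho, p = stats.pearsonr(x, y)
    return float(rho), float(p)


def fit_rcv(
    activations: np.ndarray,
    measure: ConceptMeasure | np.ndarray,
    layer: str = "",
    concept: str = "",
    ridge_fallback: bool = True,
) -> ConceptVector:
    """Least-squares regression of the concept measure on the activations.

    The concept vector is the coefficient vector normalised to unit length;
    R^2 is that of the same fit. Rank-deficient designs (including n <= dim)
    fall back to a tiny ridge penalty (1e-6) unless disabled, in which case
    they raise.
    """
    A = np.asarray(activations, dtype=float)
    c = measure.values if isinstance(measure, ConceptMeasure) else np.asarray(measure, dtype=float)
    if A.ndim != 2 or len(A) != len(c):
        raise DimensionError("activations must be (n, dim) aligned with the measure")
    n, d = A.shape
    centered = A - A.mean(axis=0)
    deficient = n < d + 1 or np.linalg.matrix_rank(centered) < d
    if deficient and not ridge_fallback:
        raise DataError(f"rank-deficient design (n={n}, dim={d}) and ridge fallback disabled")
    X = centered
    y = c - c.mean()
    if deficient:
        coef = np.linalg.solve(X.T @ X + 1e-6 * np.eye(d), X.T @ y)
    else:
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    pred = X @ coef
    ss_res = float(((y - pred) ** 2).sum())
    ss_tot = float((y**2).sum())
    if ss_tot == 0:
        raise DegenerateError("constant concept measure; R^2 undefined")
    r2 = 1.0 - ss_res / ss_tot
    norm = np.linalg.norm(coef)
    if norm == 0:
        raise DegenerateError("zero regression coefficients; concept direction undefined")
    return ConceptVector(v=coef / norm, layer=layer, r_squared=float(r2), concept=concept)


def cross_val_r2(
    activations: np.ndarray,
    values: np.ndarray,
    folds: int = 10,
    seed: int = 0,
) -> float:
    """Mean out-of-fold R^2 of the RCV regression under shuffled k-fold CV."""
    from sklearn.model_selection import KFold

    A = np.asarray(activations, dtype=float)
    y = np.asarray(values, dtype=float)
    if len(A) < folds:
        raise ConfigurationError(f"need at least {folds} patches for {folds}-fold CV, got {len(A)}")
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = []
    for train_idx, test_idx in kf.split(A):
        mu_a = A[train_idx].mean(axis=0)
        mu_y = y[train_idx].mean()
        Xtr = A[train_idx] - mu_a
        d = Xtr.shape[1]
        coef = np.linalg.solve(Xtr.T @ Xtr + 1e-6 * np.eye(d), Xtr.T @ (y[train_idx] - mu_y))
        pred = (A[test_idx] - mu_a) @ coef + mu_y
        ss_res = float(((y[test_idx] - pred) ** 2).sum())
        ss_tot = float(((y[test_idx] - y[test_idx].mean()) ** 2).sum())
        scores.append(1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0)
    return float(np.mean(scores))


def pooled_activations(model: Sequential, images: np.ndarray, layer: str) -> np.ndarray:
    """Channel-wise globally averaged activations at a named layer.

    ``images`` is (N, H, W, 3) in [0, 1]; 4-D activations are pooled over
    space, vector activations pass through.
    """
    x = _as_model_input(images)
    model.forward(x, training=False, record=True)
    act = model.activation(layer)
    return act.mean(axis=(2, 3)) if act.ndim == 4 else act


def layer_r2_profile(
    model: Sequential,
    concept_images: np.ndarray,
    measure: ConceptMeasure | np.ndarray,
    layers: list[str],
    folds: int = 10,
    reps: int = 50,
    seed: int = 0,
) -> tuple[pd.DataFrame, str]:
    """Cross-validated R^2 of the concept regression at each layer.

    For each layer the k-fold CV R^2 is recomputed ``reps`` times with
    re-shuffled folds; returns the per-layer mean/sd table and the arg-max
    layer.
    """
    values = measure.values if isinstance(measure, ConceptMeasure) else np.asarray(measure, dtype=float)
    if len(concept_images) < folds:
        raise ConfigurationError(f"need at least {folds} patches for {folds}-fold CV")
    rows = []
    for layer in layers:
        acts = pooled_activations(model, concept_images, layer)
        scores = [cross_val_r2(acts, values, folds=folds, seed=seed + r) for r in range(reps)]
        rows.append({"layer": layer, "r2_mean": float(np.mean(scores)), "r2_sd": float(np.std(scores, ddof=1)) if reps > 1 else 0.0})
    frame = pd.DataFrame(rows)
    best = str(frame.loc[frame["r2_mean"].idxmax(), "layer"])
    return frame, best


# ---------------------------------------------------------------------------
# Sensitivities and Br
# ---------------------------------------------------------------------------

def _as_model_input(test_inputs: np.ndarray) -> np.ndarray:
    """(N, H, W, 3) images become NCHW; 2-D feature matrices pass through."""
    x = np.asarray(test_inputs, dtype=float)
    if x.ndim == 4:
        return np.ascontiguousarray(x.transpose(0, 3, 1, 2))
    if x.ndim == 2:
        return x
    raise DimensionError(f"model inputs must be 2-D or 4-D, got {x.ndim}-D")


def _class_readout_grad(n: int, class_index: int, n_out: int) -> np.ndarray:
    g = np.zeros((n, n_out))
    g[:, class_index] = 1.0
    return g


def sensitivity_scores(
    model: Sequential,
    layer: str,
    test_images: np.ndarray,
    v: ConceptVector | np.ndarray,
    class_index: int = 1,
    batch_size: int = 64,
) -> np.ndarray:
    """Directional derivative of the class membership along the concept vector.

    The gradient of the class score with respect to the layer's activation
    is averaged over spatial positions per channel (matching the pooled
    space the concept vector lives in) and dotted with v.
    """
    vec = v.v if isinstance(v, ConceptVector) else np.asarray(v, dtype=float)
    X = _as_model_input(test_images)
    n_out = model.forward(X[:1], training=False).shape[1]
    out = []
    for start in range(0, len(X), batch_size):
        xb = X[start : start + batch_size]
        grad = model.gradient_at(xb, layer, _class_readout_grad(len(xb), class_index, n_out))
        g = grad.mean(axis=(2, 3)) if grad.ndim == 4 else grad
        if g.shape[1] != len(vec):
            raise DimensionError(
                f"concept vector length {len(vec)} does not match layer {layer!r} channels {g.shape[1]}"
            )
        out.append(g @ vec)
    return np.concatenate(out)


def finite_difference_sensitivity(
    model: Sequential,
    layer: str,
    test_images: np.ndarray,
    v: ConceptVector | np.ndarray,
    class_index: int = 1,
    eps: float = 1e-3,
) -> np.ndarray:
    """Independent central-difference estimate of ``sensitivity_scores``.

    Perturbs the layer activation uniformly over space by +/- eps * v (per
    channel) and re-runs only the layers above; the derivative is divided by
    the spatial extent to express it in the pooled space. Uses no gradient
    machinery.
    """
    vec = v.v if isinstance(v, ConceptVector) else np.asarray(v, dtype=float)
    X = _as_model_input(test_images)
    model.forward(X, training=False, record=True)
    act = model.activation(layer)
    if act.ndim == 4:
        spatial = act.shape[2] * act.shape[3]
        pert = vec[None, :, None, None]
    else:
        spatial = 1
        pert = vec[None, :]
    f_plus = model.forward_from(layer, act + eps * pert)[:, class_index]
    f_minus = model.forward_from(layer, act - eps * pert)[:, class_index]
    return (f_plus - f_minus) / (2.0 * eps) / spatial


def br_score(r_squared: float, sensitivities: np.ndarray) -> float:
    """Bidirectional relevance: Br = R^2 * (sigma / mu), sample-sd convention."""
    s = np.asarray(sensitivities, dtype=float)
    if len(s) < 2:
        raise DataError(f"need at least 2 sensitivity scores, got {len(s)}")
    mu = float(s.mean())
    if mu == 0.0:
        raise DegenerateError("mean sensitivity is zero; Br undefined")
    sigma = float(s.std(ddof=1))
    return float(r_squared) * (sigma / mu)


def scale_br(raw_scores: np.ndarray) -> np.ndarray:
    """Affine min-max map of the per-concept raw Br scores onto [-1, 1]."""
    raw = np.asarray(raw_scores, dtype=float)
    if len(raw) < 2 or np.ptp(raw) == 0:
        raise DegenerateError("scaling needs >= 2 distinct raw Br scores")
    return -1.0 + 2.0 * (raw - raw.min()) / (raw.max() - raw.min())


def br_significance(sensitivities: np.ndarray) -> tuple[float, float]:
    """Two-tailed one-sample t-test of the sensitivities against mean 0
    (the null of a randomly oriented concept direction)."""
    s = np.asarray(sensitivities, dtype=float)
    if len(s) < 2:
        raise DataError(f"need at least 2 sensitivity scores, got {len(s)}")
    if s.std(ddof=1) == 0:
        raise DegenerateError("zero-variance sensitivities; t-test undefined")
    t, p = stats.ttest_1samp(s, popmean=0.0)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# End-to-end report
# ---------------------------------------------------------------------------

def global_interpretability(
    model: Sequential,
    concept_patches: list[ConceptPatch],
    test_images: np.ndarray,
    layer: str,
    concepts: tuple[str, ...] = TEXTURE_CONCEPTS,
    glcm_params: dict | None = None,
    class_index: int = 1,
) -> BrReport:
    """Full concept pipeline: measures -> Pearson screen -> RCV fit at the
    chosen layer -> sensitivities on the test set -> Br, scaled Br and
    significance, one row per concept."""
    from .classifier import predict_proba

    measures = concept_measures(concept_patches, measures=concepts, glcm_params=glcm_params)
    concept_imgs = np.stack([cp.image for cp in concept_patches])
    predictions = predict_proba(model, concept_imgs)[:, class_index]
    acts = pooled_activations(model, concept_imgs, layer)
    rows, sens_store, raws = [], {}, []
    for m in measures:
        rho, rho_p = pearson_screen(m, predictions)
        cv = fit_rcv(acts, m, layer=layer, concept=m.name)
        sens = sensitivity_scores(model, layer, test_images, cv, class_index=class_index)
        raw = br_score(cv.r_squared, sens)
        t, t_p = br_significance(sens)
        rows.append(
            {
                "concept": m.name,
                "rho": rho,
                "rho_p": rho_p,
                "r2": cv.r_squared,
                "mu": float(sens.mean()),
                "sigma": float(sens.std(ddof=1)),
                "br_raw": raw,
                "t": t,
                "t_p": t_p,
            }
        )
        raws.append(raw)
        sens_store[m.name] = sens
    frame = pd.DataFrame(rows)
    frame["br_scaled"] = scale_br(np.array(raws))
    frame = frame[["concept", "rho", "rho_p", "r2", "mu", "sigma", "br_raw", "br_scaled", "t", "t_p"]]
    return BrReport(frame=frame, layer=layer, sensitivities=sens_store)
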