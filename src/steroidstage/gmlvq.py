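"""Generalised Matrix Learning Vector Quantisation (GMLVQ), from scratch.

GMLVQ represents each class by one (or more) prototype vector(s) w in
feature space and measures dissimilarity with a *learned* quadratic metric

    d(w, x) = (x − w)ᵀ Λ (x − w),    Λ = Ωᵀ Ω,

where Ω is an unrestricted d×d matrix adapted jointly with the prototypes.
Λ is symmetric positive semi-definite by construction and is kept at
trace(Λ) = 1 throughout, so its diagonal is a normalised measure of how much
each feature contributes to the classification — the basis of the steroid
relevance ranking.

Training minimises the relative-distance cost Σᵢ φ(μᵢ) with

    μᵢ = (d_J − d_K) / (d_J + d_K),

d_J the distance to the closest prototype of the sample's own class and d_K
the closest wrong-class prototype; μ < 0 iff the sample is classified
correctly, and each term is bounded in [−1, 1] for φ = identity.  Gradients
are analytic; batch mode uses step-halving so the cost never increases
across epochs.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .preprocessing import FeatureMatrix

__all__ = [
    "GMLVQModel",
    "TrainConfig",
    "init_model",
    "squared_distance",
    "cost",
    "cost_gradients",
    "train",
    "predict",
    "predict_batch",
    "decision_score",
    "decision_scores",
    "relevances",
    "project_2d",
    "model_to_json",
    "model_from_json",
]

log = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    """Gradient-descent hyperparameters.

    The original analysis does not publish its training schedule; these
    defaults are the package's own and are deliberately conservative: batch
    descent with per-epoch step-halving whenever a step would increase the
    cost, which makes the training loss non-increasing and every run
    reproducible from the seed.  The metric learning rate defaults to a
    small fraction of the prototype rate: slow metric adaptation keeps the
    relevance estimates stable across validation splits.
    """

    epochs: int = 80
    lr_prototype: float = 0.5
    lr_omega: float | None = None  # default: lr_prototype / 50
    schedule: float = 1.0  # multiplicative decay per epoch
    mode: str = "batch"  # "batch" | "stochastic"
    seed: int = 0
    phi: str = "identity"  # "identity" | "sigmoid"
    sigmoid_slope: float = 1.0
    step_halving: bool = True
    max_halvings: int = 30

    def validate(self) -> None:
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.lr_prototype <= 0:
            raise ValueError("lr_prototype must be > 0")
        if self.lr_omega is not None and self.lr_omega <= 0:
            raise ValueError("lr_omega must be > 0")
        if not (0 < self.schedule <= 1):
            raise ValueError("schedule decay must be in (0, 1]")
        if self.mode not in ("batch", "stochastic"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.phi not in ("identity", "sigmoid"):
            raise ValueError(f"unknown phi {self.phi!r}")


@dataclass
class GMLVQModel:
    """Prototypes + metric matrix Ω (relevance Λ = ΩᵀΩ)."""

    prototypes: np.ndarray  # (P, d)
    prototype_labels: tuple[str, ...]
    omega: np.ndarray  # (d, d)
    feature_names: tuple[str, ...]
    trained: bool = False
    training_log: list = field(default_factory=list)  # cost per epoch
    trace_log: list = field(default_factory=list)  # trace(Λ) after each epoch

    def __post_init__(self):
        self.prototypes = np.asarray(self.prototypes, dtype=float)
        self.omega = np.asarray(self.omega, dtype=float)
        d = len(self.feature_names)
        if self.prototypes.shape != (len(self.prototype_labels), d):
            raise ValueError("prototype array shape inconsistent with labels/features")
        if self.omega.shape != (d, d):
            raise ValueError("omega must be d×d")

    @property
    def d(self) -> int:
        return self.omega.shape[0]

    @property
    def classes(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.prototype_labels)))

    def lambda_matrix(self) -> np.ndarray:
        return self.omega.T @ self.omega

    def copy(self) -> "GMLVQModel":
        return GMLVQModel(
            prototypes=self.prototypes.copy(),
            prototype_labels=self.prototype_labels,
            omega=self.omega.copy(),
            feature_names=self.feature_names,
            trained=self.trained,
            training_log=list(self.training_log),
            trace_log=list(self.trace_log),
        )


def _normalise_omega(omega: np.ndarray) -> np.ndarray:
    """Rescale so trace(ΩᵀΩ) = Σ Ωᵢⱼ² = 1."""
    nrm = np.sqrt(np.sum(omega * omega))
    if nrm == 0:
        raise FloatingPointError("omega collapsed to zero")
    return omega / nrm


def init_model(fm: FeatureMatrix, prototypes_per_class: int = 1, seed: int = 0) -> GMLVQModel:
    """Prototypes at class-conditional means plus small seeded jitter
    (σ = 0.01 in z-units); Ω = I/√d so trace(Λ) = 1 exactly."""
    classes = sorted(set(fm.labels))
    if len(classes) < 2:
        raise ValueError("at least two classes are required")
    labels = np.asarray(fm.labels)
    rng = np.random.default_rng(seed)
    protos, proto_labels = [], []
    for c in classes:
        idx = np.where(labels == c)[0]
        if idx.size < 2:
            raise ValueError(f"class {c!r} has fewer than 2 samples")
        mean = fm.values[idx].mean(axis=0)
        for _ in range(prototypes_per_class):
            protos.append(mean + rng.normal(0.0, 0.01, size=fm.d))
            proto_labels.append(c)
    omega = np.eye(fm.d) / np.sqrt(fm.d)
    return GMLVQModel(
        prototypes=np.vstack(protos),
        prototype_labels=tuple(proto_labels),
        omega=omega,
        feature_names=fm.feature_names,
    )


def squared_distance(model: GMLVQModel, x: np.ndarray) -> np.ndarray:
    """d(w, x) = ‖Ω(x − w)‖² for every prototype; ≥ 0 each."""
    x = np.asarray(x, dtype=float)
    if x.shape != (model.d,):
        raise ValueError(f"expected vector of length {model.d}, got shape {x.shape}")
    diff = x[None, :] - model.prototypes  # (P, d)
    od = diff @ model.omega.T
    return np.einsum("pj,pj->p", od, od)


def _pairwise_sq(model: GMLVQModel, X: np.ndarray) -> np.ndarray:
    """(n, P) matrix of metric squared distances."""
    ox = X @ model.omega.T
    ow = model.prototypes @ model.omega.T
    diff = ox[:, None, :] - ow[None, :, :]
    return np.einsum("npj,npj->np", diff, diff)


def _mu_terms(model: GMLVQModel, X: np.ndarray, y: np.ndarray):
    """Per-sample μ plus the winning correct/wrong prototype indices.

    Samples equidistant from coinciding correct and wrong prototypes
    (d_J + d_K = 0) contribute μ = 0 with a logged warning.
    """
    proto_labels = np.asarray(model.prototype_labels)
    D = _pairwise_sq(model, X)
    correct = proto_labels[None, :] == y[:, None]
    if not correct.any(axis=1).all():
        missing = sorted(set(y) - set(proto_labels))
        raise ValueError(f"no prototype for class(es) {missing}")
    inf = np.inf
    dj_all = np.where(correct, D, inf)
    dk_all = np.where(~correct, D, inf)
    j_idx = np.argmin(dj_all, axis=1)
    k_idx = np.argmin(dk_all, axis=1)
    dj = dj_all[np.arange(len(X)), j_idx]
    dk = dk_all[np.arange(len(X)), k_idx]
    denom = dj + dk
    degenerate = denom == 0
    if degenerate.any():
        log.warning("%d sample(s) coincide with prototypes of both classes; μ set to 0",
                    int(degenerate.sum()))
    mu = np.zeros(len(X))
    ok = ~degenerate
    mu[ok] = (dj[ok] - dk[ok]) / denom[ok]
    return mu, j_idx, k_idx, dj, dk, degenerate


def _phi(config: TrainConfig, mu: np.ndarray):
    if config.phi == "identity":
        return mu, np.ones_like(mu)
    s = config.sigmoid_slope
    f = 1.0 / (1.0 + np.exp(-s * mu))
    return f, s * f * (1.0 - f)


def _labels_array(fm: FeatureMatrix) -> np.ndarray:
    return np.asarray(fm.labels)


def cost(model: GMLVQModel, fm: FeatureMatrix, config: TrainConfig | None = None) -> float:
    """Σ φ(μᵢ) over the samples; finite, and in [−n, n] for φ = identity."""
    config = config or TrainConfig()
    mu, *_ = _mu_terms(model, fm.values, _labels_array(fm))
    f, _ = _phi(config, mu)
    return float(np.sum(f))


def cost_gradients(model: GMLVQModel, fm: FeatureMatrix, config: TrainConfig | None = None):
    """Analytic gradients of the cost.

    Returns ``(cost, grad_prototypes (P,d), grad_omega (d,d))`` at the
    current parameters, without any renormalisation applied.
    """
    config = config or TrainConfig()
    X = fm.values
    y = _labels_array(fm)
    mu, j_idx, k_idx, dj, dk, degenerate = _mu_terms(model, X, y)
    f, fprime = _phi(config, mu)
    n = len(X)

    denom2 = np.where(degenerate, 1.0, (dj + dk) ** 2)
    gamma_j = np.where(degenerate, 0.0, 2.0 * dk / denom2)  # ∂μ/∂d_J
    gamma_k = np.where(degenerate, 0.0, -2.0 * dj / denom2)  # ∂μ/∂d_K

    uj = X - model.prototypes[j_idx]  # (n, d)
    uk = X - model.prototypes[k_idx]
    lam = model.lambda_matrix()

    # ∂d/∂w = −2 Λ (x − w)
    aj = fprime * gamma_j
    ak = fprime * gamma_k
    grad_w = np.zeros_like(model.prototypes)
    np.add.at(grad_w, j_idx, (-2.0 * aj)[:, None] * (uj @ lam))
    np.add.at(grad_w, k_idx, (-2.0 * ak)[:, None] * (uk @ lam))

    # ∂d/∂Ω = 2 Ω u uᵀ
    M = (uj * aj[:, None]).T @ uj + (uk * ak[:, None]).T @ uk
    grad_omega = 2.0 * model.omega @ M

    return float(np.sum(f)), grad_w, grad_omega


def _check_finite(epoch: int, *arrays):
    for a in arrays:
        if not np.all(np.isfinite(a)):
            raise FloatingPointError(f"non-finite cost or gradient at epoch {epoch}")


def train(model: GMLVQModel, fm: FeatureMatrix, config: TrainConfig | None = None) -> GMLVQModel:
    """Gradient descent on the relative-distance cost.

    Batch mode (default) takes one step per epoch over the mean gradient;
    when step-halving is on, a step that would increase the cost is undone
    and retried with halved rates, so the recorded cost sequence is
    non-increasing.  Ω is renormalised to trace(Λ) = 1 after every update.
    Stochastic mode visits samples in a seeded shuffle, one update each.
    The input model is not modified; a trained copy is returned.
    """
    config = config or TrainConfig()
    config.validate()
    if fm.feature_names != model.feature_names:
        raise ValueError("feature names of model and data differ")
    model = model.copy()
    lr_w = config.lr_prototype
    lr_o = config.lr_omega if config.lr_omega is not None else config.lr_prototype / 50.0
    n = fm.n
    rng = np.random.default_rng(config.seed)

    if config.mode == "batch":
        c_cur = cost(model, fm, config)
        for epoch in range(config.epochs):
            c0, grad_w, grad_o = cost_gradients(model, fm, config)
            _check_finite(epoch, np.array([c0]), grad_w, grad_o)
            w_old, o_old = model.prototypes.copy(), model.omega.copy()
            step_w, step_o = lr_w, lr_o
            accepted = False
            for _ in range(config.max_halvings + 1):
                model.prototypes = w_old - step_w * grad_w / n
                model.omega = _normalise_omega(o_old - step_o * grad_o / n)
                c_new = cost(model, fm, config)
                if not config.step_halving or c_new <= c0:
                    accepted = True
                    break
                step_w *= 0.5
                step_o *= 0.5
            if not accepted:
                # No decreasing step found at any rate: keep the old state.
                model.prototypes, model.omega = w_old, o_old
                c_new = c0
            c_cur = c_new
            model.training_log.append(c_cur)
            tr = float(np.sum(model.omega * model.omega))
            model.trace_log.append(tr)
            assert abs(tr - 1.0) < 1e-10, "trace(Λ) drifted from 1"
            lr_w *= config.schedule
            lr_o *= config.schedule
    else:  # stochastic
        y = _labels_array(fm)
        for epoch in range(config.epochs):
            order = rng.permutation(n)
            for i in order:
                xi = fm.values[i : i + 1]
                yi = y[i : i + 1]
                sub = replace(fm, values=xi, labels=(fm.labels[i],), normalisation=None)
                _c, grad_w, grad_o = cost_gradients(model, sub, config)
                _check_finite(epoch, grad_w, grad_o)
                model.prototypes = model.prototypes - lr_w * grad_w
                model.omega = _normalise_omega(model.omega - lr_o * grad_o)
            c_ep = cost(model, fm, config)
            _check_finite(epoch, np.array([c_ep]))
            model.training_log.append(c_ep)
            model.trace_log.append(float(np.sum(model.omega * model.omega)))
            lr_w *= config.schedule
            lr_o *= config.schedule

    model.trained = True
    return model


def predict(model: GMLVQModel, x: np.ndarray) -> str:
    """Class of the nearest prototype under the learned metric; exact ties go
    to the lowest class label in sort order (deterministic)."""
    dist = squared_distance(model, x)
    winners = np.where(dist == dist.min())[0]
    labels = sorted(model.prototype_labels[i] for i in winners)
    if len(set(labels)) > 1:
        log.info("tie between classes %s; returning %s", sorted(set(labels)), labels[0])
    return labels[0]


def predict_batch(model: GMLVQModel, X: np.ndarray) -> list[str]:
    D = _pairwise_sq(model, np.asarray(X, dtype=float))
    out = []
    for row in D:
        winners = np.where(row == row.min())[0]
        out.append(min(model.prototype_labels[i] for i in winners))
    return out


def _binary_arms(model: GMLVQModel, positive_class: str):
    classes = model.classes
    if len(classes) != 2:
        raise ValueError(f"decision scores require a binary model, got classes {classes}")
    if positive_class not in classes:
        raise ValueError(f"{positive_class!r} is not a model class {classes}")
    negative_class = classes[0] if classes[1] == positive_class else classes[1]
    return negative_class, positive_class


def decision_score(model: GMLVQModel, x: np.ndarray, positive_class: str) -> float:
    """Signed relative distance μ̂(x) = (d₋ − d₊)/(d₋ + d₊) ∈ [−1, 1].

    Larger is more positive-class-like; thresholding at 0 reproduces
    :func:`predict`, and swapping the arms flips the sign.
    """
    return float(decision_scores(model, np.asarray(x)[None, :], positive_class)[0])


def decision_scores(model: GMLVQModel, X: np.ndarray, positive_class: str) -> np.ndarray:
    neg, pos = _binary_arms(model, positive_class)
    labels = np.asarray(model.prototype_labels)
    D = _pairwise_sq(model, np.asarray(X, dtype=float))
    d_pos = D[:, labels == pos].min(axis=1)
    d_neg = D[:, labels == neg].min(axis=1)
    denom = d_neg + d_pos
    out = np.zeros(len(D))
    ok = denom > 0
    out[ok] = (d_neg[ok] - d_pos[ok]) / denom[ok]
    return out


def relevances(model: GMLVQModel) -> dict[str, float]:
    """diag(ΩᵀΩ) keyed by feature: each ≥ 0, summing to 1."""
    diag = np.einsum("ij,ij->j", model.omega, model.omega)
    return {name: float(v) for name, v in zip(model.feature_names, diag)}


def project_2d(model: GMLVQModel, fm_or_values) -> np.ndarray:
    """Project data onto the two leading eigenvectors of Λ, each scaled by
    the square root of its eigenvalue.

    The projection distance ‖p(x) − p(y)‖² never exceeds the full metric
    distance and equals it when rank(Λ) ≤ 2.  For a rank-deficient metric
    the second coordinate is zero-filled with a warning.  Eigenvector sign
    is fixed (largest-magnitude component positive) so output is
    deterministic.
    """
    X = fm_or_values.values if isinstance(fm_or_values, FeatureMatrix) else np.asarray(fm_or_values, dtype=float)
    lam = model.lambda_matrix()
    evals, evecs = np.linalg.eigh(lam)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    evals = np.clip(evals, 0.0, None)
    coords = np.zeros((X.shape[0], 2))
    tol = 1e-12
    for k in range(2):
        if evals[k] <= tol:
            warnings.warn("relevance matrix has rank < 2; coordinate zero-filled")
            continue
        v = evecs[:, k]
        imax = np.argmax(np.abs(v))
        if v[imax] < 0:
            v = -v
        coords[:, k] = np.sqrt(evals[k]) * (X @ v)
    return coords


# ---------------------------------------------------------------------------
# Serialisation: JSON round trip reproducing predictions bit-identically
# (floats stored via repr-exact JSON encoding).

def model_to_json(model: GMLVQModel, path=None) -> str:
    doc = {
        "feature_names": list(model.feature_names),
        "prototype_labels": list(model.prototype_labels),
        "prototypes": model.prototypes.tolist(),
        "omega": [x for row in model.omega.tolist() for x in row],  # row-major
        "trained": model.trained,
        "training_log": list(map(float, model.training_log)),
        "trace_log": list(map(float, model.trace_log)),
    }
    text = json.dumps(doc, indent=1)
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
    return text


def model_from_json(source) -> GMLVQModel:
    if isinstance(source, str) and source.lstrip().startswith("{"):
        doc = json.loads(source)
    else:
        with open(source, "r", encoding="utf-8") as fh:
            doc = json.load(fh)
    d = len(doc["feature_names"])
    return GMLVQModel(
        prototypes=np.asarray(doc["prototypes"], dtype=float),
        prototype_labels=tuple(doc["prototype_labels"]),
        omega=np.asarray(doc["omega"], dtype=float).reshape(d, d),
        feature_names=tuple(doc["feature_names"]),
        trained=bool(doc["trained"]),
        training_log=list(doc["training_log"]),
        trace_log=list(doc.get("trace_log", [])),
    )
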