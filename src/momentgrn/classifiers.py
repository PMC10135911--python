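"""Kernel classifiers for gene-pair labels.

The centerpiece is rare-event weighted kernel logistic regression (REWKLR):
logistic regression on an RBF kernel expansion whose log-likelihood terms
are weighted to correct for event rarity.  With training prevalence ȳ and
population prevalence τ, class weights are w₁ = τ/ȳ and w₀ = (1−τ)/(1−ȳ)
— the weighted-likelihood prior correction for case–control style sampling.
The penalized objective

    J(α, b) = Σᵢ w_{yᵢ} [yᵢ ln pᵢ + (1−yᵢ) ln(1−pᵢ)] − (λ/2) αᵀKα,
    pᵢ = logistic((Kα)ᵢ + b),

is concave in (α, b) and maximized by damped Newton iterations with an
unpenalized intercept.  Two-class SVM and one-class SVM are provided at
contract level over scikit-learn.

Kernel parameterization note: REWKLR uses the bandwidth form
K(u,v) = exp(−‖u−v‖²/(2σ²)); the SVMs use the coefficient form
K(u,v) = exp(−γ‖u−v‖²).  Both are available from :func:`rbf_kernel`.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.spatial.distance import cdist
from scipy.special import expit, log_expit
from sklearn.svm import SVC, OneClassSVM

from .labeling import LabeledTrainingSet

logger = logging.getLogger(__name__)


class ClassifierError(ValueError):
    """Invalid classifier configuration or training input."""


class ConvergenceError(RuntimeError):
    """Solver failed to reach the gradient tolerance."""

    def __init__(self, message: str, gradient_norm: float):
        super().__init__(message)
        self.gradient_norm = gradient_norm


def rbf_kernel(
    U: np.ndarray,
    V: np.ndarray,
    bandwidth: float,
    parameterization: Literal["sigma", "gamma"] = "sigma",
) -> np.ndarray:
    """Gaussian RBF kernel matrix between the rows of U and V.

    ``sigma`` form: exp(−‖u−v‖² / (2σ²)); ``gamma`` form: exp(−γ‖u−v‖²).
    """
    if bandwidth <= 0:
        raise ClassifierError(f"bandwidth must be positive, got {bandwidth}")
    U = np.atleast_2d(np.asarray(U, dtype=float))
    V = np.atleast_2d(np.asarray(V, dtype=float))
    if U.shape[1] != V.shape[1]:
        raise ClassifierError(
            f"feature widths differ: {U.shape[1]} vs {V.shape[1]}"
        )
    sq = cdist(U, V, "sqeuclidean")
    if parameterization == "sigma":
        return np.exp(-sq / (2.0 * bandwidth**2))
    if parameterization == "gamma":
        return np.exp(-bandwidth * sq)
    raise ClassifierError(f"unknown parameterization {parameterization!r}")


# ---------------------------------------------------------------------------
# REWKLR
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class REWKLRConfig:
    """Hyperparameters for rare-event weighted kernel logistic regression.

    ``lam`` is the dual regularization weight λ; ``sigma`` the RBF
    bandwidth; ``tau`` the population event prevalence used for the
    rare-event weight correction, or ``"sample"`` to use the training
    prevalence (which makes the weights 1, i.e. unweighted).
    """

    lam: float = 1.0
    sigma: float = 1.0
    tau: float | str = "sample"
    max_iter: int = 100
    tol: float = 1e-6
    jitter: float = 1e-8

    def __post_init__(self) -> None:
        if self.lam <= 0 or self.sigma <= 0:
            raise ClassifierError("lam and sigma must be positive")
        if self.tol <= 0:
            raise ClassifierError("tol must be positive")
        if self.tau != "sample" and not (0.0 < float(self.tau) < 1.0):
            raise ClassifierError("tau must be in (0,1) or 'sample'")


@dataclass
class REWKLRModel:
    """Fitted REWKLR: support points, dual coefficients, intercept."""

    support_points: np.ndarray
    alpha: np.ndarray
    intercept: float
    config: REWKLRConfig
    class_weights: tuple[float, float]  # (w0, w1)
    gradient_norm: float
    n_iter: int
    objective: float


def _class_weights(y: np.ndarray, tau: float | str) -> tuple[float, float]:
    ybar = float(np.mean(y))
    if tau == "sample":
        return 1.0, 1.0
    tau = float(tau)
    if not (0.0 < ybar < 1.0):
        raise ClassifierError("both classes must be present")
    return (1.0 - tau) / (1.0 - ybar), tau / ybar


def rewklr_objective(
    K: np.ndarray,
    y: np.ndarray,
    alpha: np.ndarray,
    b: float,
    lam: float,
    weights: np.ndarray,
) -> float:
    """Penalized weighted log-likelihood J(α, b)."""
    eta = K @ alpha + b
    # y·ln p + (1−y)·ln(1−p), computed stably via log_expit
    loglik = np.sum(weights * (y * log_expit(eta) + (1 - y) * log_expit(-eta)))
    return float(loglik - 0.5 * lam * (alpha @ (K @ alpha)))


def rewklr_gradient(
    K: np.ndarray,
    y: np.ndarray,
    alpha: np.ndarray,
    b: float,
    lam: float,
    weights: np.ndarray,
) -> np.ndarray:
    """Gradient of J over (α, b), length n+1."""
    p = expit(K @ alpha + b)
    r = weights * (y - p)
    g_alpha = K @ r - lam * (K @ alpha)
    g_b = float(np.sum(r))
    return np.concatenate([g_alpha, [g_b]])


def train_rewklr(
    train: LabeledTrainingSet | tuple[np.ndarray, np.ndarray],
    config: REWKLRConfig = REWKLRConfig(),
) -> REWKLRModel:
    """Fit REWKLR by damped Newton on the concave objective.

    Accepts a :class:`LabeledTrainingSet` or a plain ``(features, labels)``
    tuple.  Iterates Newton steps with backtracking line search (J never
    decreases) until the gradient norm over (α, b) falls below ``tol``.

    Raises
    ------
    ConvergenceError
        If ``max_iter`` damped steps do not reach the tolerance; the final
        gradient norm is attached.
    """
    if isinstance(train, LabeledTrainingSet):
        X, y = train.features, train.labels.astype(float)
    else:
        X, y = train
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ClassifierError("features contain non-finite values")
    classes = set(np.unique(y))
    if classes != {0.0, 1.0}:
        raise ClassifierError(f"need both classes 0 and 1, got {sorted(classes)}")

    w0, w1 = _class_weights(y, config.tau)
    weights = np.where(y == 1, w1, w0)
    n = len(y)
    K = rbf_kernel(X, X, config.sigma, "sigma")
    K[np.diag_indices(n)] += config.jitter

    alpha = np.zeros(n)
    b = 0.0
    J = rewklr_objective(K, y, alpha, b, config.lam, weights)
    grad = rewklr_gradient(K, y, alpha, b, config.lam, weights)
    gnorm = float(np.linalg.norm(grad))
    n_iter = 0
    for n_iter in range(1, config.max_iter + 1):
        if gnorm <= config.tol:
            break
        p = expit(K @ alpha + b)
        d = weights * p * (1.0 - p)
        # Newton system: H s = grad with H = -(∂²J); H is PSD + jitter
        KD = K * d  # K @ diag(d)
        H = np.empty((n + 1, n + 1))
        H[:n, :n] = KD @ K + config.lam * K
        H[:n, n] = K @ d
        H[n, :n] = H[:n, n]
        H[n, n] = float(np.sum(d))
        step = _solve_spd(H, grad, config.jitter)
        # backtracking: accept only non-decreasing J
        scale = 1.0
        for _ in range(60):
            new_alpha = alpha + scale * step[:n]
            new_b = b + scale * step[n]
            new_J = rewklr_objective(K, y, new_alpha, new_b, config.lam, weights)
            if new_J >= J - 1e-12 * max(1.0, abs(J)):
                break
            scale *= 0.5
        alpha, b, J = new_alpha, new_b, new_J
        grad = rewklr_gradient(K, y, alpha, b, config.lam, weights)
        gnorm = float(np.linalg.norm(grad))
    if gnorm > config.tol:
        raise ConvergenceError(
            f"REWKLR did not converge in {config.max_iter} iterations "
            f"(gradient norm {gnorm:.3e} > tol {config.tol:.1e})",
            gradient_norm=gnorm,
        )
    return REWKLRModel(
        support_points=X.copy(),
        alpha=alpha,
        intercept=float(b),
        config=config,
        class_weights=(w0, w1),
        gradient_norm=gnorm,
        n_iter=n_iter,
        objective=J,
    )


def _solve_spd(H: np.ndarray, g: np.ndarray, jitter: float) -> np.ndarray:
    """Solve H s = g for SPD-up-to-rounding H, escalating the jitter."""
    current = jitter
    for _ in range(6):
        try:
            return np.linalg.solve(
                H + current * np.eye(H.shape[0]), g
            )
        except np.linalg.LinAlgError:
            current = max(current * 100.0, 1e-10)
    raise ClassifierError("Newton system is singular even after jitter escalation")


def predict_rewklr(
    model: REWKLRModel, X: np.ndarray, threshold: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior probabilities and thresholded labels for new points."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.support_points.shape[1]:
        raise ClassifierError(
            f"feature width {X.shape[1]} does not match model "
            f"({model.support_points.shape[1]})"
        )
    Kx = rbf_kernel(X, model.support_points, model.config.sigma, "sigma")
    prob = expit(Kx @ model.alpha + model.intercept)
    return prob, (prob >= threshold).astype(int)


# ---------------------------------------------------------------------------
# Two-class and one-class SVM (library-backed)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SVMConfig:
    """RBF soft-margin SVM hyperparameters (γ coefficient form)."""

    C: float = 1.0
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if self.C <= 0 or self.gamma <= 0:
            raise ClassifierError("C and gamma must be positive")


@dataclass
class SVMModel:
    estimator: SVC
    config: SVMConfig


def train_svm(
    train: LabeledTrainingSet | tuple[np.ndarray, np.ndarray],
    config: SVMConfig = SVMConfig(),
) -> SVMModel:
    """Soft-margin RBF SVM (scikit-learn SVC) with the config echoed back."""
    if isinstance(train, LabeledTrainingSet):
        X, y = train.features, train.labels
    else:
        X, y = train
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ClassifierError("SVM training needs both classes")
    est = SVC(C=config.C, gamma=config.gamma, kernel="rbf")
    est.fit(X, y)
    return SVMModel(estimator=est, config=config)


def predict_svm(model: SVMModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Continuous decision scores (for ROC) and hard labels."""
    scores = model.estimator.decision_function(X)
    labels = (scores >= 0).astype(int)
    return scores, labels


@dataclass(frozen=True)
class OneClassConfig:
    """One-class SVM hyperparameters; ν bounds the training rejection rate."""

    nu: float = 0.05
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.nu <= 1.0):
            raise ClassifierError("nu must be in (0, 1]")
        if self.gamma <= 0:
            raise ClassifierError("gamma must be positive")


@dataclass
class OneClassModel:
    estimator: OneClassSVM
    config: OneClassConfig


def train_ocsvm(
    positives: np.ndarray, config: OneClassConfig = OneClassConfig()
) -> OneClassModel:
    """ν-parameterized one-class boundary around the positive class."""
    positives = np.atleast_2d(np.asarray(positives, dtype=float))
    if positives.shape[0] < 2:
        raise ClassifierError("one-class SVM needs at least 2 positive points")
    est = OneClassSVM(nu=config.nu, gamma=config.gamma, kernel="rbf")
    est.fit(positives)
    return OneClassModel(estimator=est, config=config)


def predict_ocsvm(model: OneClassModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Signed boundary scores and inlier flags (1 = inlier, 0 = outlier)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    scores = model.estimator.decision_function(X)
    inlier = (model.estimator.predict(X) == 1).astype(int)
    return scores, inlier


# ---------------------------------------------------------------------------
# Bootstrap hyperparameter tuning
# ---------------------------------------------------------------------------

def make_grid(**axes: Sequence[float]) -> list[dict[str, float]]:
    """Cartesian parameter lattice, in the axes' given order."""
    names = list(axes)
    return [
        dict(zip(names, combo))
        for combo in itertools.product(*(axes[n] for n in names))
    ]


def _fit_predict(
    classifier: str,
    params: dict,
    X_tr: np.ndarray,
    y_tr: np.ndarray,
    X_te: np.ndarray,
) -> np.ndarray:
    if classifier == "rewklr":
        cfg = REWKLRConfig(
            lam=params["lam"], sigma=params["sigma"], tau=params.get("tau", "sample")
        )
        model = train_rewklr((X_tr, y_tr), cfg)
        _, labels = predict_rewklr(model, X_te)
        return labels
    if classifier == "svm":
        model = train_svm((X_tr, y_tr), SVMConfig(C=params["C"], gamma=params["gamma"]))
        _, labels = predict_svm(model, X_te)
        return labels
    if classifier == "ocsvm":
        model = train_ocsvm(
            X_tr[y_tr == 1], OneClassConfig(nu=params["nu"], gamma=params["gamma"])
        )
        _, inlier = predict_ocsvm(model, X_te)
        return inlier
    raise ClassifierError(f"unknown classifier tag {classifier!r}")


def bootstrap_tune(
    train: LabeledTrainingSet | tuple[np.ndarray, np.ndarray],
    classifier: Literal["rewklr", "svm", "ocsvm"],
    grid: Sequence[dict[str, float]],
    n_boot: int = 10,
    seed: int = 0,
    max_redraws: int = 20,
) -> tuple[dict[str, float], "pd.DataFrame"]:
    """Select hyperparameters by bootstrap out-of-bag accuracy.

    For each grid point, ``n_boot`` bootstrap resamples define train /
    out-of-bag splits.  The score is the mean over resamples of the average
    of the two per-class accuracies (binary classifiers) or the
    positive-class accuracy (one-class).  Ties take the first grid point in
    order, so put preferred (e.g. smoother) settings first.  A resample
    missing a class in-bag or out-of-bag is redrawn, up to ``max_redraws``.
    """
    import pandas as pd

    if not grid:
        raise ClassifierError("empty parameter grid")
    if isinstance(train, LabeledTrainingSet):
        X, y = train.features, train.labels
    else:
        X, y = train
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n = len(y)

    rng = np.random.default_rng(seed)
    splits: list[tuple[np.ndarray, np.ndarray]] = []
    draws = 0
    while len(splits) < n_boot:
        if draws > n_boot * max_redraws:
            raise ClassifierError("could not draw class-complete bootstrap splits")
        draws += 1
        in_bag = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), in_bag)
        if oob.size == 0:
            continue
        if len(np.unique(y[in_bag])) < 2 or len(np.unique(y[oob])) < 2:
            logger.debug("redrawing bootstrap split missing a class")
            continue
        splits.append((in_bag, oob))

    records = []
    best_score, best_params = -np.inf, None
    for params in grid:
        scores = []
        for in_bag, oob in splits:
            pred = _fit_predict(classifier, params, X[in_bag], y[in_bag], X[oob])
            y_oob = y[oob]
            if classifier == "ocsvm":
                score = float(np.mean(pred[y_oob == 1] == 1))
            else:
                acc1 = float(np.mean(pred[y_oob == 1] == 1))
                acc0 = float(np.mean(pred[y_oob == 0] == 0))
                score = 0.5 * (acc0 + acc1)
            scores.append(score)
        mean_score = float(np.mean(scores))
        records.append({**params, "score": mean_score, "score_sd": float(np.std(scores))})
        if mean_score > best_score:  # strict: ties keep the earlier grid point
            best_score, best_params = mean_score, dict(params)
    return best_params, pd.DataFrame.from_records(records)
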