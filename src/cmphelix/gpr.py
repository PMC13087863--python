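"""Gaussian-process surrogate mapping embedding coordinates to Tm.

The surrogate is an exact GP with an anisotropic (ARD) RBF kernel: one
length scale per embedding dimension plus a signal variance, all optimized
by marginal log-likelihood maximization with a fixed restart schedule.
Replicate-derived measurement noise enters as a fixed heteroscedastic
diagonal (the squared standard error of each training Tm) added to the
kernel matrix.  Targets are standardized to zero mean / unit variance and
inputs are scaled per dimension before optimization; reported
hyperparameters are converted back to natural units, so the model is

    Tm(x) ~ GP(mean = ybar,  k(x, x') = s2 * exp(-sum_d (x_d - x'_d)^2 / (2 l_d^2)))

with observation noise se_i^2 on training point i.  The numerical fit is
delegated to scikit-learn's ``GaussianProcessRegressor`` (L-BFGS with
restarts); a jitter-escalation guard retries a failed Cholesky with an
inflated diagonal before giving up.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_solve
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel

from .errors import DimensionMismatch, NonFiniteInput, SingularKernel

LENGTH_SCALE_BOUNDS = (5e-2, 5e1)   # in input-standardized units
SIGNAL_BOUNDS = (1e-8, 1e4)         # in target-standardized units
N_RESTARTS = 5
JITTER_LADDER = (0.0, 1e-8, 1e-6, 1e-4)


@dataclass
class GPRState:
    """A fitted surrogate plus the standardization constants."""

    model: GaussianProcessRegressor
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    y_scale: float
    train_inputs: np.ndarray
    train_targets: np.ndarray
    train_noise: np.ndarray  # variances, K^2

    @property
    def length_scales(self) -> np.ndarray:
        """ARD length scales in natural (embedding) units."""
        ls = np.atleast_1d(self.model.kernel_.k2.length_scale)
        if ls.size == 1:
            ls = np.full(self.x_scale.size, float(ls[0]))
        return ls * self.x_scale

    @property
    def signal_variance(self) -> float:
        """Kernel signal variance in K^2."""
        return float(self.model.kernel_.k1.constant_value) * self.y_scale**2

    def log_marginal_likelihood(self, theta=None) -> float:
        """MLL of the standardized-target model (at ``theta`` if given)."""
        if theta is None:
            return float(self.model.log_marginal_likelihood_value_)
        return float(self.model.log_marginal_likelihood(theta))

    def _xs(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.x_mean.size:
            raise DimensionMismatch(
                f"expected {self.x_mean.size}-D inputs, got {X.shape[1]}-D"
            )
        return (X - self.x_mean) / self.x_scale


def _make_kernel(n_dims: int, length_scales=None, signal_variance=None,
                 fixed: bool = False):
    ls = np.ones(n_dims) if length_scales is None else np.asarray(length_scales, float)
    sv = 1.0 if signal_variance is None else float(signal_variance)
    if fixed:
        return ConstantKernel(sv, "fixed") * RBF(ls, "fixed")
    return ConstantKernel(sv, SIGNAL_BOUNDS) * RBF(ls, LENGTH_SCALE_BOUNDS)


def fit_gpr(
    X: np.ndarray,
    y: np.ndarray,
    noise_se: np.ndarray | float = 0.0,
    seed: int = 0,
    optimize: bool = True,
    length_scales: np.ndarray | None = None,
    signal_variance: float | None = None,
    n_restarts: int = N_RESTARTS,
) -> GPRState:
    """Fit the ARD-RBF surrogate.

    ``noise_se`` is the per-point standard error of the Tm estimate (K),
    entered into the GP as the fixed variance ``se^2``.  With
    ``optimize=False`` the supplied ``length_scales`` (natural units) and
    ``signal_variance`` (K^2) are used as-is, which is the path exercised by
    closed-form oracles.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise NonFiniteInput("training data contain non-finite values")
    if X.shape[0] != y.size or X.shape[0] < 2:
        raise NonFiniteInput("need n >= 2 matched inputs and targets")
    noise = np.broadcast_to(np.asarray(noise_se, dtype=float), y.shape).copy()
    if not np.isfinite(noise).all() or (noise < 0).any():
        raise NonFiniteInput("noise standard errors must be finite and >= 0")

    x_mean = X.mean(axis=0)
    x_scale = X.std(axis=0)
    x_scale[x_scale == 0] = 1.0
    y_mean = float(y.mean())
    y_scale = float(y.std())
    if y_scale == 0:
        y_scale = 1.0
    if not optimize:
        # fixed hyperparameters given in natural units: convert
        if length_scales is None or signal_variance is None:
            raise NonFiniteInput("fixed fit requires length_scales and signal_variance")
        ls_std = np.asarray(length_scales, float) / x_scale
        sv_std = float(signal_variance) / y_scale**2
        kernel = _make_kernel(X.shape[1], ls_std, sv_std, fixed=True)
        optimizer = None
    else:
        kernel = _make_kernel(X.shape[1], length_scales, signal_variance)
        optimizer = "fmin_l_bfgs_b"

    Xs = (X - x_mean) / x_scale
    ys = (y - y_mean) / y_scale
    alpha0 = (noise / y_scale) ** 2 + 1e-10
    last_err = None
    for jitter in JITTER_LADDER:
        gp = GaussianProcessRegressor(
            kernel=kernel,
            alpha=alpha0 + jitter,
            optimizer=optimizer,
            n_restarts_optimizer=n_restarts if optimizer else 0,
            normalize_y=False,
            random_state=seed,
        )
        try:
            with warnings.catch_warnings():
                # ARD length scales of uninformative dimensions legitimately
                # saturate their bounds; not an error for this model
                warnings.simplefilter("ignore")
                gp.fit(Xs, ys)
            return GPRState(
                model=gp,
                x_mean=x_mean,
                x_scale=x_scale,
                y_mean=y_mean,
                y_scale=y_scale,
                train_inputs=X,
                train_targets=y,
                train_noise=noise**2,
            )
        except np.linalg.LinAlgError as err:  # Cholesky failure -> escalate
            last_err = err
    raise SingularKernel(f"kernel not positive definite after jitter: {last_err}")


def predict(state: GPRState, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mean and standard deviation (both in K) at ``X``."""
    mu, sd = state.model.predict(state._xs(X), return_std=True)
    return state.y_mean + state.y_scale * mu, state.y_scale * sd


def predict_cov(state: GPRState, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mean (K) and joint covariance (K^2) over a batch."""
    mu, cov = state.model.predict(state._xs(X), return_cov=True)
    return state.y_mean + state.y_scale * mu, state.y_scale**2 * cov


def posterior_cross_cov(state: GPRState, A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Posterior covariance between two point sets, shape (len(A), len(B)).

    cov(f(A), f(B)) = k(A, B) - k(A, X) (K + D)^-1 k(X, B), in K^2.
    """
    gp = state.model
    As, Bs = state._xs(A), state._xs(B)
    kab = gp.kernel_(As, Bs)
    kax = gp.kernel_(As, gp.X_train_)
    kxb = gp.kernel_(gp.X_train_, Bs)
    v = cho_solve((gp.L_, True), kxb, check_finite=False)
    return state.y_scale**2 * (kab - kax @ v)
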