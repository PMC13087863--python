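"""Equilibrium stability estimation along a learned reaction coordinate.

Workflow mirrored here: (i) learn the slowest collective coordinate (TIC0)
of a denaturation trajectory by time-lagged independent component analysis
of per-frame feature vectors (pairwise alpha-carbon distances in the
original protocol); (ii) umbrella-sample along TIC0 with harmonic biases;
(iii) reconstruct the unbiased potential of mean force (PMF) with the
weighted histogram analysis method (WHAM); (iv) report the free-energy
difference between the low-TIC0 (triple helix) and high-TIC0 (denatured)
basins, with bootstrap uncertainties from resampled window data.

Units: window force constants are kJ/mol per coordinate-unit^2, PMFs are
reported in kcal/mol referenced to the helix basin, temperatures in K
(320 K default, the sampling temperature of the underlying protocol).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy.special import logsumexp

from .errors import (
    LagTooLarge,
    NoOverlap,
    NotConverged,
    RankDeficientCovariance,
    SingleBasin,
)

KB_KJ_PER_MOL_K = 0.008314462618
KJ_PER_KCAL = 4.184
DEFAULT_TEMPERATURE_K = 320.0
DEFAULT_N_BINS = 100
DEFAULT_FORCE_CONSTANT = 1000.0  # kJ/mol per unit^2
WHAM_TOL_KT = 1e-7
WHAM_MAX_ITER = 100_000
BASIN_BARRIER_KCAL = 0.5
SMOOTH_BINS = 5


# ---------------------------------------------------------------------------
# TICA
# ---------------------------------------------------------------------------

@dataclass
class TICAModel:
    lag: int
    feature_means: np.ndarray
    eigenvectors: np.ndarray   # columns, ordered by decreasing eigenvalue
    eigenvalues: np.ndarray    # in (0, 1] after symmetrization/clipping

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X - self.feature_means) @ self.eigenvectors

    def tic0(self, X: np.ndarray) -> np.ndarray:
        return self.transform(X)[:, 0]


def fit_tica(feature_series: np.ndarray, lag: int, reg: float = 1e-10) -> TICAModel:
    """Solve the symmetrized generalized eigenproblem C(tau) v = lam C(0) v.

    Covariances are estimated from mean-free features with the reversible
    (symmetrized) estimator; C(0) is regularized by ``reg * tr(C0)/d`` on
    the diagonal.  Eigenvalues are clipped into (0, 1], eigenvectors are
    C(0)-orthogonal and the projection of the training mean is zero.
    """
    X = np.atleast_2d(np.asarray(feature_series, dtype=float))
    T, d = X.shape
    if lag < 1 or lag >= T:
        raise LagTooLarge(f"lag must satisfy 1 <= lag < {T}, got {lag}")
    mean = X.mean(axis=0)
    X0 = X[:-lag] - mean
    Xt = X[lag:] - mean
    n = T - lag
    C0 = (X0.T @ X0 + Xt.T @ Xt) / (2.0 * n)
    Ct = (X0.T @ Xt + Xt.T @ X0) / (2.0 * n)
    C0 = C0 + reg * (np.trace(C0) / d + 1e-300) * np.eye(d)
    try:
        w, V = scipy.linalg.eigh(Ct, C0)
    except scipy.linalg.LinAlgError as err:
        raise RankDeficientCovariance(str(err)) from err
    if not np.isfinite(w).all():
        raise RankDeficientCovariance("non-finite TICA eigenvalues")
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    w = np.clip(w, np.finfo(float).tiny, 1.0)
    return TICAModel(lag=lag, feature_means=mean, eigenvectors=V, eigenvalues=w)


# ---------------------------------------------------------------------------
# WHAM
# ---------------------------------------------------------------------------

@dataclass
class UmbrellaWindow:
    center: float
    force_constant: float  # kJ/mol per unit^2
    samples: np.ndarray

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.force_constant <= 0:
            raise NoOverlap("force constant must be positive")
        if self.samples.size < 1:
            raise NoOverlap("window has no samples")


@dataclass
class PMFEstimate:
    grid: np.ndarray               # bin centers along the coordinate
    F: np.ndarray                  # kcal/mol, min-referenced; NaN on empty bins
    temperature: float = DEFAULT_TEMPERATURE_K
    F_se: np.ndarray | None = None
    deltaF: float | None = None
    deltaF_se: float | None = None
    window_free_energies: np.ndarray | None = None
    basins: tuple | None = None    # (helix bin index, denatured bin index)


def _window_overlap_check(counts: np.ndarray) -> None:
    # counts: (n_windows, n_bins) histograms
    occupied = counts > 0
    n_win = counts.shape[0]
    if n_win == 1:
        return
    for i in range(n_win):
        others = occupied[np.arange(n_win) != i].any(axis=0)
        if not (occupied[i] & others).any():
            raise NoOverlap(
                f"umbrella window {i} shares no occupied bin with any other; "
                "add intermediate windows and resample"
            )


def wham(
    windows: list[UmbrellaWindow],
    n_bins: int = DEFAULT_N_BINS,
    temperature: float = DEFAULT_TEMPERATURE_K,
    tol: float = WHAM_TOL_KT,
    max_iter: int = WHAM_MAX_ITER,
) -> PMFEstimate:
    """Self-consistent WHAM reconstruction of the unbiased PMF.

    Iterates the standard coupled equations for the unbiased bin
    probabilities and the per-window free energies until the largest change
    in any window free energy is below ``tol`` (in kT).  Bins never visited
    by any window are masked (NaN), not interpolated.  The returned profile
    is ``-kT ln p`` converted to kcal/mol and shifted so the occupied
    minimum is zero.
    """
    if not windows:
        raise NoOverlap("need at least one umbrella window")
    kT = KB_KJ_PER_MOL_K * temperature  # kJ/mol
    all_samples = np.concatenate([w.samples for w in windows])
    if not np.isfinite(all_samples).all():
        raise NotConverged("non-finite reaction-coordinate samples")
    lo, hi = all_samples.min(), all_samples.max()
    if hi == lo:
        hi = lo + 1e-9
    edges = np.linspace(lo, hi, n_bins + 1)
    grid = 0.5 * (edges[:-1] + edges[1:])

    counts = np.array([np.histogram(w.samples, bins=edges)[0] for w in windows])
    _window_overlap_check(counts)
    N_i = counts.sum(axis=1).astype(float)     # samples per window
    M_k = counts.sum(axis=0).astype(float)     # total counts per bin
    occupied = M_k > 0

    # reduced bias energies c_ik / kT
    centers = np.array([w.center for w in windows])
    ks = np.array([w.force_constant for w in windows])
    bias = 0.5 * ks[:, None] * (grid[None, :] - centers[:, None]) ** 2 / kT

    f = np.zeros(len(windows))  # window free energies in kT
    log_Ni = np.log(N_i)
    with np.errstate(divide="ignore"):
        log_Mk = np.where(occupied, np.log(M_k), -np.inf)
    for _ in range(max_iter):
        # log p_k = log M_k - logsumexp_i(log N_i + f_i - bias_ik)
        denom = logsumexp(log_Ni[:, None] + f[:, None] - bias, axis=0)
        log_p = log_Mk - denom
        f_new = -logsumexp(log_p[None, :] - bias, axis=1)
        f_new -= f_new[0]
        delta = np.abs(f_new - f).max()
        f = f_new
        if delta < tol:
            break
    else:
        raise NotConverged(f"WHAM did not converge within {max_iter} iterations")

    denom = logsumexp(log_Ni[:, None] + f[:, None] - bias, axis=0)
    log_p = log_Mk - denom
    F_kcal = np.full(n_bins, np.nan)
    F_kcal[occupied] = (-kT * log_p[occupied]) / KJ_PER_KCAL
    F_kcal -= np.nanmin(F_kcal)
    return PMFEstimate(
        grid=grid, F=F_kcal, temperature=temperature,
        window_free_energies=f * kT / KJ_PER_KCAL,
    )


# ---------------------------------------------------------------------------
# basin extraction and bootstrap
# ---------------------------------------------------------------------------

def _moving_average(y: np.ndarray, width: int) -> np.ndarray:
    """NaN-aware centered moving average."""
    half = width // 2
    out = np.full_like(y, np.nan)
    for i in range(y.size):
        seg = y[max(0, i - half): i + half + 1]
        if np.isfinite(seg).any():
            out[i] = np.nanmean(seg)
    return out


def _local_minima(y: np.ndarray) -> list[int]:
    idx = []
    finite = np.isfinite(y)
    for i in range(y.size):
        if not finite[i]:
            continue
        left = y[i - 1] if i > 0 and finite[i - 1] else np.inf
        right = y[i + 1] if i < y.size - 1 and finite[i + 1] else np.inf
        if y[i] <= left and y[i] <= right and (y[i] < left or y[i] < right):
            idx.append(i)
    return idx


def _barrier_between(y: np.ndarray, i: int, j: int) -> float:
    seg = y[min(i, j): max(i, j) + 1]
    return float(np.nanmax(seg) - max(y[i], y[j]))


def extract_deltaF(pmf: PMFEstimate,
                   barrier: float = BASIN_BARRIER_KCAL,
                   smooth_bins: int = SMOOTH_BINS) -> PMFEstimate:
    """Locate the helix and denatured basins and report their gap.

    The PMF is smoothed with a ``smooth_bins`` moving average; local minima
    separated by a barrier of at least ``barrier`` kcal/mol qualify as
    basins.  The helix basin is the lowest-coordinate qualifying minimum
    and the denatured basin the highest-coordinate one;
    ``deltaF = F(denatured) - F(helix)``, so positive values mean the helix
    is the more stable state.  Basin free energies are read from the
    unsmoothed profile at the local minimum within +-2 bins of the smoothed
    location.
    """
    smooth = _moving_average(pmf.F, smooth_bins)
    minima = _local_minima(smooth)
    # prune minima not separated from a deeper neighbor by the barrier
    pruned = list(minima)
    changed = True
    while changed and len(pruned) > 1:
        changed = False
        for a, b in zip(pruned[:-1], pruned[1:]):
            if _barrier_between(smooth, a, b) < barrier:
                pruned.remove(a if smooth[a] >= smooth[b] else b)
                changed = True
                break
    if len(pruned) < 2:
        raise SingleBasin("PMF exposes fewer than two separated minima")

    def refine(i: int) -> int:
        lo = max(0, i - 2)
        seg = pmf.F[lo: i + 3]
        if not np.isfinite(seg).any():
            return i
        return lo + int(np.nanargmin(seg))

    helix = refine(pruned[0])
    denat = refine(pruned[-1])
    pmf.basins = (helix, denat)
    pmf.deltaF = float(pmf.F[denat] - pmf.F[helix])
    return pmf


def bootstrap_pmf(
    windows: list[UmbrellaWindow],
    n_boot: int = 5,
    seed: int = 0,
    n_bins: int = DEFAULT_N_BINS,
    temperature: float = DEFAULT_TEMPERATURE_K,
    barrier: float = BASIN_BARRIER_KCAL,
) -> PMFEstimate:
    """PMF with bootstrap uncertainties on each bin and on deltaF.

    Each replicate resamples every window's reaction-coordinate values with
    replacement, reruns WHAM and the basin extraction, and the reported
    uncertainties are the standard deviations across replicates.  The point
    estimate itself comes from the unresampled data.
    """
    point = extract_deltaF(
        wham(windows, n_bins=n_bins, temperature=temperature), barrier=barrier
    )
    rng = np.random.default_rng(seed)
    profiles, deltas = [], []
    for _ in range(n_boot):
        resampled = [
            UmbrellaWindow(
                w.center, w.force_constant,
                rng.choice(w.samples, size=w.samples.size, replace=True),
            )
            for w in windows
        ]
        rep = wham(resampled, n_bins=n_bins, temperature=temperature)
        # evaluate replicate on the point-estimate grid by interpolation
        F_rep = np.interp(point.grid, rep.grid, rep.F,
                          left=np.nan, right=np.nan)
        profiles.append(F_rep)
        try:
            deltas.append(extract_deltaF(rep, barrier=barrier).deltaF)
        except SingleBasin:
            continue
    profiles = np.array(profiles)
    with warnings.catch_warnings():
        # bins unoccupied in every replicate legitimately yield NaN spread
        warnings.simplefilter("ignore", RuntimeWarning)
        point.F_se = np.nanstd(profiles, axis=0, ddof=0)
    if deltas:
        point.deltaF_se = float(np.std(deltas, ddof=0))
    return point
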