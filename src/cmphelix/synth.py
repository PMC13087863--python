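"""Synthetic stand-ins for the molecular-dynamics engine.

Desk-scale emulators of the three simulation stages the design loop
consumes, so the whole pipeline runs end-to-end without MD:

* :func:`oracle_tm` -- a composition-driven melting-temperature landscape
  over the sequence library with replicate noise.  Charged NLys/NGlu
  residues stabilize, light hydrophobes mildly stabilize, bulky
  hydrophobes and the short Nae side chain destabilize, and co-occurring
  NLys with NGlu/NAsp earns a salt-bridge-like pairing bonus.  Defaults
  are calibrated so latent Tm spans roughly 330-435 K with replicate
  standard errors of a few K, matching the dispersion the temperature-ramp
  protocol produces.
* :func:`generate_trajectory` -- ramped denaturation observables: per-strand
  radii of gyration and inter-strand distances follow stationary
  Ornstein-Uhlenbeck noise around helix-like baselines until an assigned
  event temperature, then relax to collapsed or dissociated values.
* :func:`sample_umbrella_windows` -- overdamped Langevin (Euler-Maruyama)
  sampling of an analytic 1-D potential under harmonic biases, mirroring
  the 42-window umbrella protocol so WHAM can be validated against a known
  free-energy surface.

These generators reproduce the statistical features the detectors and
estimators consume, not the physics that produces them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InconsistentParams, StepSizeUnstable
from .fingerprint import fnv1a64
from .melt import TmEstimate, TrajectoryObservables
from .palette import composition_vector
from .fes import KB_KJ_PER_MOL_K, KJ_PER_KCAL, UmbrellaWindow

DEFAULT_EFFECTS_K = {
    "K": 12.0, "E": 12.0,           # long charged residues stabilize
    "F": 6.0, "L": 6.0, "Y": 6.0, "I": 6.0,  # light hydrophobes
    "1": -10.0, "W": -10.0, "3": -10.0, "4": -10.0,  # bulky hydrophobes
    "X": -8.0,                       # short cationic side chain
}


@dataclass
class OracleParams:
    intercept: float = 370.0           # K
    effects: dict = field(default_factory=lambda: dict(DEFAULT_EFFECTS_K))
    pair_bonus: float = 6.0            # K per co-occurring (NLys, NGlu/NAsp) pair
    noise_sd: float = 8.0              # K, replicate-to-replicate
    n_replicates: int = 6
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise InconsistentParams("replicate noise sd must be >= 0")


def latent_tm(code: str, params: OracleParams | None = None) -> float:
    """Noise-free landscape value for a hexamer code."""
    params = params or OracleParams()
    cv = composition_vector(code)
    tm = params.intercept
    for r, c in cv.counts.items():
        tm += params.effects.get(r, 0.0) * c
    n_k = cv.counts.get("K", 0)
    n_eD = cv.counts.get("E", 0) + cv.counts.get("D", 0)
    tm += params.pair_bonus * min(n_k, n_eD)
    return tm


def oracle_tm(seq, params: OracleParams | None = None) -> TmEstimate:
    """Replicate Tm draws for a sequence; deterministic per (sequence, seed)."""
    params = params or OracleParams()
    code = seq if isinstance(seq, str) else seq.hexamer_code
    base = latent_tm(code, params)
    ss = np.random.SeedSequence([params.seed, fnv1a64(code.encode()) % 2**31])
    rng = np.random.default_rng(ss)
    reps = base + params.noise_sd * rng.standard_normal(params.n_replicates)
    se = float(reps.std(ddof=1) / np.sqrt(reps.size)) if reps.size > 1 else 0.0
    return TmEstimate(
        mean_Tm=float(reps.mean()),
        se_Tm=se,
        n_replicates=reps.size,
        n_censored=0,
        replicate_Tms=tuple(float(t) for t in reps),
    )


# ---------------------------------------------------------------------------
# ramped denaturation trajectories
# ---------------------------------------------------------------------------

@dataclass
class TrajectoryParams:
    T_star: float = 400.0            # assigned melt temperature, K
    mode: str = "collapse"           # collapse | dissociation | none
    T0: float = 320.0
    ramp_rate: float = 1.0           # K/ns
    frame_spacing_ps: float = 20.0
    duration_ns: float | None = None  # default: event time + 10 ns
    ou_tau_ns: float = 1.0
    ou_sigma_nm: float = 0.04
    relax_ns: float = 0.3            # post-event relaxation time
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("collapse", "dissociation", "none"):
            raise InconsistentParams(f"unknown event mode {self.mode!r}")
        if self.mode != "none" and self.T_star < self.T0:
            raise InconsistentParams("assigned T* below the ramp start")


RG_HELIX_NM = 1.6
RG_COLLAPSED_NM = 1.0
DIST_HELIX_NM = 1.2
DIST_DISSOCIATED_NM = 2.8


def _ou(rng, n, dt, tau, sigma):
    a = np.exp(-dt / tau)
    noise = sigma * np.sqrt(1 - a * a) * rng.standard_normal(n)
    x = np.empty(n)
    x[0] = sigma * rng.standard_normal()
    for k in range(1, n):
        x[k] = a * x[k - 1] + noise[k]
    return x


def generate_trajectory(params: TrajectoryParams) -> TrajectoryObservables:
    """Synthesize one temperature-ramp replicate.

    Before the assigned event time ``t* = (T* - T0)/rate`` every observable
    is a stationary OU process around its helix baseline; afterwards the
    first strand's Rg (collapse mode) or the first pair distance
    (dissociation mode) relaxes exponentially to its post-event value, so
    the detector's threshold crossing lags t* by a fraction of
    ``relax_ns``.  Mode ``none`` never crosses a threshold.
    """
    dt = params.frame_spacing_ps / 1000.0
    t_event = (params.T_star - params.T0) / params.ramp_rate
    duration = params.duration_ns
    if duration is None:
        duration = (t_event if params.mode != "none" else 0.0) + 10.0
    if params.mode != "none" and duration < t_event:
        raise InconsistentParams("duration shorter than the assigned event time")
    times = np.arange(0.0, duration + dt / 2, dt)
    n = times.size
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 0xD1A7]))

    rg = np.array([RG_HELIX_NM + _ou(rng, n, dt, params.ou_tau_ns,
                                     params.ou_sigma_nm) for _ in range(3)])
    dist = np.array([DIST_HELIX_NM + _ou(rng, n, dt, params.ou_tau_ns,
                                         params.ou_sigma_nm) for _ in range(3)])
    if params.mode != "none":
        after = times >= t_event
        decay = np.exp(-(times[after] - t_event) / params.relax_ns)
        if params.mode == "collapse":
            rg[0, after] = RG_COLLAPSED_NM + (RG_HELIX_NM - RG_COLLAPSED_NM) * decay \
                + 0.02 * rng.standard_normal(after.sum())
        else:
            dist[0, after] = DIST_DISSOCIATED_NM \
                - (DIST_DISSOCIATED_NM - DIST_HELIX_NM) * decay \
                + 0.02 * rng.standard_normal(after.sum())
    np.clip(rg, 0.05, None, out=rg)
    np.clip(dist, 0.05, None, out=dist)
    return TrajectoryObservables(
        frame_times=times,
        rg_per_strand=rg,
        pair_distances=dist,
        T0=params.T0,
        ramp_rate=params.ramp_rate,
        replicate_id=params.seed,
    )


# ---------------------------------------------------------------------------
# biased Langevin sampling of analytic potentials
# ---------------------------------------------------------------------------

def double_well(x, barrier_kcal: float = 2.0, tilt_kcal: float = 0.8):
    """Tilted double well ``(b (x^2-1)^2 + t x)`` in kJ/mol (minima near +-1)."""
    x = np.asarray(x, dtype=float)
    return (barrier_kcal * (x * x - 1.0) ** 2 + tilt_kcal * x) * KJ_PER_KCAL


def harmonic(x, k_kJ: float = 4.184):
    return 0.5 * k_kJ * np.asarray(x, dtype=float) ** 2


def sample_umbrella_windows(
    potential,
    span: tuple[float, float] = (-1.6, 1.6),
    n_windows: int = 42,
    force_constant: float = 1000.0,
    n_steps: int = 2500,
    dt: float = 2e-5,
    thin: int = 60,
    temperature: float = 320.0,
    burn_in: int = 2000,
    seed: int = 0,
    grad=None,
) -> list[UmbrellaWindow]:
    """Euler-Maruyama sampling under ``potential`` + harmonic window biases.

    ``potential`` maps coordinate to energy in kJ/mol; its gradient is taken
    by central differences unless ``grad`` is supplied.  Window centers are
    uniformly spaced across ``span``.  All windows are integrated in
    lockstep (one coupled vector update per step) with unit mobility, a
    step of ``dt`` reduced time units and thermal noise ``sqrt(2 kT dt)``.
    ``n_steps`` samples per window are recorded every ``thin`` integration
    steps after a ``burn_in``-step equilibration is discarded.

    The defaults keep the integrator well inside its accuracy regime for
    stiff biases: the Euler-Maruyama stationary variance of a harmonic
    degree of freedom with total curvature kappa is inflated by roughly
    kappa*dt/2, so with the 1000 kJ/mol default bias and dt = 2e-5 the
    systematic error is ~1%, and thinning by about one bias relaxation
    time (1/(kappa*dt) steps) makes recorded samples nearly independent so
    that bootstrap uncertainties are honest.  A window wandering beyond
    1e3 coordinate units or producing non-finite values raises
    :class:`StepSizeUnstable`.
    """
    if grad is None:
        h = 1e-6
        def grad(x):  # noqa: ANN001 - simple closure
            return (potential(x + h) - potential(x - h)) / (2 * h)
    kT = KB_KJ_PER_MOL_K * temperature
    centers = np.linspace(span[0], span[1], n_windows)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x0B1A]))
    x = centers.copy()
    sigma = np.sqrt(2.0 * kT * dt)
    samples = np.empty((n_steps, n_windows))
    recorded = 0
    total = burn_in + n_steps * thin
    for step in range(total):
        force = -grad(x) - force_constant * (x - centers)
        x = x + force * dt + sigma * rng.standard_normal(n_windows)
        if not np.isfinite(x).all() or np.abs(x).max() > 1e3:
            raise StepSizeUnstable(f"divergent samples at step {step}; reduce dt")
        if step >= burn_in and (step - burn_in) % thin == thin - 1:
            samples[recorded] = x
            recorded += 1
    return [
        UmbrellaWindow(center=float(c), force_constant=force_constant,
                       samples=samples[:, i])
        for i, c in enumerate(centers)
    ]
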