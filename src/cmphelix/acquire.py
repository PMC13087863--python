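"""Batched q-Expected-Improvement selection and the active-learning driver.

Candidate selection is batched Bayesian optimization over the *discrete*
embedded library: the acquisition value of a batch is the Monte-Carlo
estimate of

    qEI(B) = E[ max( max_{x in B} f(x) - (f* + beta), 0 ) ]

under the joint GP posterior over the batch, where ``f*`` is the incumbent
(best observed mean Tm) and ``beta`` shifts the improvement threshold:
``beta = 0`` is the balanced explore/exploit setting and ``beta = -f*``
moves the threshold to zero, a pure exploitation strategy that ranks
candidates essentially by posterior mean.  Batches are built greedily --
each step adds the pool candidate that maximizes the qEI of the partial
batch -- using common random numbers so that successive evaluations are
comparable.

The campaign driver reproduces the published protocol: 26 random seed
candidates in Round 0, then up to 24 rounds of 8 selections each, balanced
acquisition for the first 18 rounds and pure exploitation afterwards,
terminating early only if the exploitation phase fails to improve the
top-8 mean Tm for 4 consecutive rounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    EmptyBatch,
    LibraryTooSmall,
    OracleFailure,
    PoolTooSmall,
)
from .gpr import GPRState, fit_gpr, posterior_cross_cov, predict, predict_cov
from .melt import TmEstimate

_VAR_FLOOR = 1e-12


@dataclass
class AcquisitionConfig:
    q: int = 8
    beta: float = 0.0
    n_mc: int = 512
    seed: int = 0

    def __post_init__(self):
        if self.q < 1 or self.n_mc < 1:
            raise EmptyBatch("q and n_mc must be >= 1")


def _sqrt_factor(cov: np.ndarray) -> np.ndarray:
    """Symmetric PSD square root via eigendecomposition (robust to rank loss)."""
    w, V = np.linalg.eigh((cov + cov.T) / 2.0)
    return V * np.sqrt(np.clip(w, 0.0, None))


def qei(
    state: GPRState,
    batch: np.ndarray,
    incumbent: float,
    cfg: AcquisitionConfig,
) -> float:
    """Monte-Carlo qEI of a batch of coordinates (common random numbers).

    For a single point this converges to the closed-form expected
    improvement; for batches the joint posterior correlation is respected,
    so duplicating a candidate does not inflate the value.
    """
    batch = np.atleast_2d(np.asarray(batch, dtype=float))
    if batch.shape[0] == 0:
        raise EmptyBatch("batch must contain at least one candidate")
    mu, cov = predict_cov(state, batch)
    rng = np.random.default_rng(cfg.seed)
    Z = rng.standard_normal((cfg.n_mc, batch.shape[0]))
    samples = mu + Z @ _sqrt_factor(cov).T
    improvement = samples.max(axis=1) - (incumbent + cfg.beta)
    return float(np.mean(np.clip(improvement, 0.0, None)))


def select_batch(
    state: GPRState,
    pool: np.ndarray,
    cfg: AcquisitionConfig,
    incumbent: float,
    pool_codes: list[str] | None = None,
) -> list[int]:
    """Greedy sequential qEI maximization over the discrete pool.

    Returns ``cfg.q`` distinct pool indices.  One matrix of standard
    normals, drawn once from ``cfg.seed``, supplies the common random
    numbers: column ``j`` drives the j-th batch slot, so every candidate is
    scored against identical posterior draws of the partial batch.  Exact
    value ties are broken lexicographically by candidate code (by pool
    index when codes are not supplied).
    """
    pool = np.atleast_2d(np.asarray(pool, dtype=float))
    n = pool.shape[0]
    if n < cfg.q:
        raise PoolTooSmall(f"pool of {n} cannot fill a batch of {cfg.q}")
    codes = pool_codes if pool_codes is not None else [f"{i:09d}" for i in range(n)]
    threshold = incumbent + cfg.beta

    mu, sd = predict(state, pool)
    var = np.clip(sd**2, _VAR_FLOOR, None)
    rng = np.random.default_rng(cfg.seed)
    Z = rng.standard_normal((cfg.n_mc, cfg.q))

    selected: list[int] = []
    for j in range(cfg.q):
        if not selected:
            f_x = mu[:, None] + np.sqrt(var)[:, None] * Z[None, :, 0]
            vals = np.clip(f_x - threshold, 0.0, None).mean(axis=1)
        else:
            B = pool[selected]
            mu_B, cov_B = predict_cov(state, B)
            L_B = _sqrt_factor(cov_B)
            f_B = mu_B + Z[:, : len(selected)] @ L_B.T      # (n_mc, m)
            best_B = f_B.max(axis=1)                        # (n_mc,)
            C_xB = posterior_cross_cov(state, pool, B)      # (n, m)
            A = C_xB @ np.linalg.pinv(cov_B)                # (n, m)
            cond_var = np.clip(var - np.sum(A * C_xB, axis=1), _VAR_FLOOR, None)
            cond_mean = mu[:, None] + (A @ L_B) @ Z[:, : len(selected)].T
            f_x = cond_mean + np.sqrt(cond_var)[:, None] * Z[None, :, j]
            vals = np.clip(
                np.maximum(best_B[None, :], f_x) - threshold, 0.0, None
            ).mean(axis=1)
        vals[selected] = -np.inf
        best = np.flatnonzero(vals == vals.max())
        pick = min(best, key=lambda i: codes[i])
        selected.append(int(pick))
    return selected


# ---------------------------------------------------------------------------
# campaign driver
# ---------------------------------------------------------------------------

@dataclass
class CampaignState:
    """Bookkeeping of one active-learning campaign."""

    codes: list[str]
    coords: np.ndarray
    evaluated: dict = field(default_factory=dict)   # code -> TmEstimate
    rounds: dict = field(default_factory=dict)      # code -> selection round
    round_index: int = 0
    top8_history: list = field(default_factory=list)
    audit_rows: list = field(default_factory=list)
    terminated_by: str = "max_rounds"

    @property
    def Tm_max(self) -> float:
        return max(est.mean_Tm for est in self.evaluated.values())

    def top_mean(self, k: int = 8) -> float:
        means = sorted((e.mean_Tm for e in self.evaluated.values()), reverse=True)
        return float(np.mean(means[:k]))

    def remaining_indices(self) -> np.ndarray:
        return np.array(
            [i for i, c in enumerate(self.codes) if c not in self.evaluated],
            dtype=int,
        )

    def audit_log(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.audit_rows,
            columns=[
                "round", "sequence", "replicate_Tms", "mean_Tm_K", "se_Tm_K",
                "beta_K", "cumulative_best_K", "top8_mean_K", "top16_mean_K",
            ],
        )


def _evaluate(state: CampaignState, code: str, rnd: int, beta, oracle) -> None:
    try:
        est: TmEstimate = oracle(code)
    except Exception as err:  # noqa: BLE001 - reported as a campaign failure
        raise OracleFailure(f"oracle failed on {code!r}: {err}") from err
    state.evaluated[code] = est
    state.rounds[code] = rnd
    state.audit_rows.append(
        {
            "round": rnd,
            "sequence": code,
            "replicate_Tms": ";".join(f"{t:.3f}" for t in est.replicate_Tms),
            "mean_Tm_K": round(est.mean_Tm, 6),
            "se_Tm_K": round(est.se_Tm, 6),
            "beta_K": "" if beta is None else round(beta, 6),
            "cumulative_best_K": None,
            "top8_mean_K": None,
            "top16_mean_K": None,
        }
    )


def _close_round(state: CampaignState) -> None:
    best, t8, t16 = state.Tm_max, state.top_mean(8), state.top_mean(16)
    for row in state.audit_rows:
        if row["cumulative_best_K"] is None:
            row["cumulative_best_K"] = round(best, 6)
            row["top8_mean_K"] = round(t8, 6)
            row["top16_mean_K"] = round(t16, 6)
    state.top8_history.append(t8)


def run_campaign(
    codes: list[str],
    coords: np.ndarray,
    oracle,
    n_init: int = 26,
    q: int = 8,
    max_rounds: int = 24,
    balanced_rounds: int = 18,
    stagnation_window: int = 4,
    n_mc: int = 512,
    noise_floor: float = 1.0,
    seed: int = 0,
) -> CampaignState:
    """Run the full active-learning campaign against a Tm oracle.

    ``oracle`` maps a hexamer code to a :class:`~cmphelix.melt.TmEstimate`.
    Round 0 draws ``n_init`` candidates uniformly without replacement; each
    later round refits the surrogate on everything evaluated so far and
    selects a fresh batch of ``q``.  ``beta = 0`` through ``balanced_rounds``
    and ``beta = -Tm_max`` afterwards.  The stagnation stopping rule is
    armed in the exploitation phase only: the campaign terminates once the
    top-8 mean Tm has failed to (strictly) improve for
    ``stagnation_window`` consecutive exploitation rounds.  All randomness
    descends from ``seed``, so a rerun reproduces the audit log exactly.
    """
    coords = np.asarray(coords, dtype=float)
    if len(codes) < n_init + q * max_rounds:
        raise LibraryTooSmall(
            f"library of {len(codes)} cannot support {n_init} + {q}x{max_rounds}"
        )
    state = CampaignState(codes=list(codes), coords=coords)
    index_of = {c: i for i, c in enumerate(state.codes)}
    root = np.random.SeedSequence(seed)
    init_seed, *round_seeds = root.spawn(1 + max_rounds)

    rng = np.random.default_rng(init_seed)
    first = rng.choice(len(codes), size=n_init, replace=False)
    for i in sorted(first):
        _evaluate(state, codes[i], 0, None, oracle)
    _close_round(state)

    stagnant = 0
    for rnd in range(1, max_rounds + 1):
        state.round_index = rnd
        means = np.array([state.evaluated[c].mean_Tm for c in state.evaluated])
        ses = np.array([state.evaluated[c].se_Tm for c in state.evaluated])
        Xtr = coords[[index_of[c] for c in state.evaluated]]
        sub = round_seeds[rnd - 1].generate_state(2)
        surrogate = fit_gpr(
            Xtr, means, np.maximum(ses, noise_floor),
            seed=int(sub[0] % (2**31)),
        )
        incumbent = state.Tm_max
        beta = 0.0 if rnd <= balanced_rounds else -incumbent
        cfg = AcquisitionConfig(q=q, beta=beta, n_mc=n_mc,
                                seed=int(sub[1] % (2**31)))
        rem = state.remaining_indices()
        picks = select_batch(
            surrogate, coords[rem], cfg, incumbent,
            pool_codes=[codes[i] for i in rem],
        )
        prev_top8 = state.top8_history[-1]
        for i in picks:
            _evaluate(state, codes[rem[i]], rnd, beta, oracle)
        _close_round(state)

        if rnd > balanced_rounds:
            stagnant = stagnant + 1 if state.top8_history[-1] <= prev_top8 else 0
            if stagnant >= stagnation_window:
                state.terminated_by = "stagnation"
                break
    return state
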