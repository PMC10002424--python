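"""DREAM-ZS multi-chain MCMC with an optional Kalman-inspired proposal.

DREAM-ZS runs a small number of chains whose jump proposals are built
from differences of states in an archive of past samples Z: parallel-
direction moves (scaled difference of archive pairs on a random
coordinate subset) and snooker moves (a jump along the line through the
current state and an archive point, with the standard Metropolis
correction (|th_p - z| / |th - z|)^(d-1)).

The KZS variant adds a third move built from the Kalman gain estimated
on the archive's parameter/prediction pairs:

    th_p = th + K (d - f(th)) + K eps,   K = C_td (C_dd + R)^{-1}

with eps drawn from the measurement-error distribution N(0, R).  The
move drags chains toward the data and dramatically shortens burn-in,
but it is not symmetric; rather than pay for a proposal-density
correction it is only offered during the first T_k generations, and all
samples up to T_k are discarded as burn-in.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .evaluation import CalibrationResult, rmse
from .smoothers import kalman_gain, reflect_into_bounds

__all__ = [
    "ProposalMixture",
    "log_likelihood",
    "parallel_direction_proposal",
    "snooker_proposal",
    "kalman_proposal",
    "dream_run",
    "gelman_rubin",
]

Model = Callable[[np.ndarray], np.ndarray]

_CR_VALUES = (1 / 3, 2 / 3, 1.0)
_ARCHIVE_STRIDE = 10
_ARCHIVE_INIT_PER_DIM = 10
_MOVE_NAMES = ("parallel", "snooker", "kalman")


@dataclass(frozen=True)
class ProposalMixture:
    """Move-selection probabilities and the Kalman cutoff fraction."""

    p_parallel: float = 0.7
    p_snooker: float = 0.1
    p_kalman: float = 0.2
    t_kalman_frac: float = 0.2  # T_k = frac * T

    def __post_init__(self):
        probs = (self.p_parallel, self.p_snooker, self.p_kalman)
        if any(p < 0 for p in probs) or not np.isclose(sum(probs), 1.0):
            raise ValueError("move probabilities must be >= 0 and sum to 1")
        if not 0 <= self.t_kalman_frac <= 1:
            raise ValueError("t_kalman_frac must be in [0, 1]")

    def probs(self, kalman_active: bool) -> np.ndarray:
        if kalman_active:
            return np.array([self.p_parallel, self.p_snooker, self.p_kalman])
        p = np.array([self.p_parallel, self.p_snooker, 0.0])
        return p / p.sum()


def log_likelihood(theta: np.ndarray, prediction: np.ndarray,
                   d_obs: np.ndarray, R: np.ndarray,
                   bounds: np.ndarray | None = None) -> float:
    """Gaussian log density of the residual d - f(theta) under N(0, R),
    with a uniform-prior box indicator (-inf outside the bounds)."""
    if bounds is not None and (np.any(theta < bounds[:, 0])
                               or np.any(theta > bounds[:, 1])):
        return -np.inf
    resid = np.asarray(d_obs, float) - np.asarray(prediction, float)
    if not np.isfinite(resid).all():
        return -np.inf
    cf = cho_factor(R, lower=True)
    logdet = 2.0 * np.log(np.diag(cf[0])).sum()
    quad = float(resid @ cho_solve(cf, resid))
    return -0.5 * (len(resid) * np.log(2 * np.pi) + logdet + quad)


def parallel_direction_proposal(theta: np.ndarray, archive: np.ndarray,
                                rng: np.random.Generator, delta: int = 1,
                                cr: float = 1.0,
                                gamma: float | None = None,
                                noise_scale: np.ndarray | float = 0.0,
                                jitter: float = 0.05) -> np.ndarray:
    """Differential-evolution jump from ``delta`` archive pairs.

    th_p = th + (1+e) * gamma(delta, d') * sum(z_a - z_b) + eps on the
    CR-selected coordinate subset, gamma = 2.38 / sqrt(2 delta d') unless
    overridden (unit jumps every fifth generation are the caller's
    responsibility); e ~ U(-jitter, jitter) and eps ~ N(0, noise_scale^2)
    are small perturbations.
    """
    n = len(archive)
    if n < 2 * delta:
        raise ValueError("archive too small for the requested pairs")
    d = len(theta)
    idx = rng.choice(n, size=2 * delta, replace=False)
    diff = archive[idx[:delta]].sum(axis=0) - archive[idx[delta:]].sum(axis=0)
    mask = rng.random(d) < cr
    if not mask.any():
        mask[rng.integers(d)] = True
    d_eff = int(mask.sum())
    g = 2.38 / np.sqrt(2 * delta * d_eff) if gamma is None else gamma
    e = rng.uniform(-jitter, jitter, size=d)
    eps = rng.standard_normal(d) * noise_scale
    theta_p = theta.copy()
    theta_p[mask] += ((1 + e[mask]) * g * diff[mask] + eps[mask])
    return theta_p


def snooker_proposal(theta: np.ndarray, archive: np.ndarray,
                     rng: np.random.Generator
                     ) -> tuple[np.ndarray, float]:
    """Snooker jump along the line through theta and an archive point z.

    Returns the candidate and the Metropolis correction
    (|th_p - z| / |th - z|)^(d-1).
    """
    n = len(archive)
    if n < 3:
        raise ValueError("archive too small for a snooker move")
    d = len(theta)
    for _ in range(16):
        z = archive[rng.integers(n)]
        u = theta - z
        norm2 = float(u @ u)
        if norm2 > 0:
            break
    else:  # archive collapsed onto the current state
        return theta.copy(), 1.0
    ia, ib = rng.choice(n, size=2, replace=False)
    za, zb = archive[ia], archive[ib]
    gamma_s = rng.uniform(1.2, 2.2)
    jump = gamma_s * (float((za - zb) @ u) / norm2) * u
    theta_p = theta + jump
    num = float(np.linalg.norm(theta_p - z))
    den = float(np.sqrt(norm2))
    correction = (num / den) ** (d - 1) if den > 0 else 1.0
    return theta_p, correction


def kalman_proposal(theta: np.ndarray, prediction: np.ndarray,
                    archive: np.ndarray, archive_pred: np.ndarray,
                    d_obs: np.ndarray, R: np.ndarray,
                    rng: np.random.Generator) -> np.ndarray:
    """Kalman-gain jump toward the data, using archive covariances."""
    if len(archive) < 2:
        raise ValueError("archive too small for a Kalman move")
    K = kalman_gain(archive, archive_pred, R)
    resid = d_obs - prediction
    eps = rng.multivariate_normal(np.zeros(len(d_obs)), R,
                                  method="cholesky")
    return theta + K @ (resid + eps)


def gelman_rubin(chains: np.ndarray) -> np.ndarray:
    """Split-free potential scale reduction factor R-hat per parameter.

    ``chains`` has shape (n_chains, n_samples, d).
    """
    m, n, _ = chains.shape
    if m < 2 or n < 2:
        raise ValueError("need at least 2 chains and 2 samples")
    means = chains.mean(axis=1)
    w = chains.var(axis=1, ddof=1).mean(axis=0)
    b = n * means.var(axis=0, ddof=1)
    var_hat = (n - 1) / n * w + b / n
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.sqrt(var_hat / w)


def dream_run(model: Model, d_obs: np.ndarray, R: np.ndarray,
              bounds: np.ndarray, mixture: ProposalMixture | None = None,
              n_chains: int = 3, n_generations: int = 1000,
              seed: int = 0, variant: str = "zs",
              param_names: Sequence[str] | None = None,
              burn_in: int | None = None,
              archive_stride: int = _ARCHIVE_STRIDE) -> CalibrationResult:
    """Run DREAM-ZS (``variant='zs'``) or DREAM-KZS (``variant='kzs'``).

    The archive is seeded with 10*d uniform prior draws and appended
    with all chains' states every ``archive_stride`` generations.
    Posterior summaries use generations after ``burn_in`` (default: half
    the run, and never earlier than the Kalman cutoff T_k for the KZS
    variant, whose early samples are biased by the asymmetric move).
    """
    if variant not in ("zs", "kzs"):
        raise ValueError("variant must be 'zs' or 'kzs'")
    if n_chains < 2:
        raise ValueError("need at least 2 chains")
    mixture = mixture or ProposalMixture()
    bounds = np.asarray(bounds, float)
    d = bounds.shape[0]
    T = n_generations
    t_k = int(round(mixture.t_kalman_frac * T)) if variant == "kzs" else 0
    if burn_in is None:
        burn_in = max(T // 2, t_k)

    ss = np.random.SeedSequence(seed)
    chain_rngs = [np.random.default_rng(c) for c in ss.spawn(n_chains)]
    init_rng = np.random.default_rng(ss.spawn(1)[0])

    lo, hi = bounds[:, 0], bounds[:, 1]
    n_init = _ARCHIVE_INIT_PER_DIM * d
    init = lo + (hi - lo) * init_rng.random((n_init + n_chains, d))
    init_pred = model(init)
    archive = list(init[:n_init])
    archive_pred = list(init_pred[:n_init])
    theta = init[n_init:].copy()
    pred = init_pred[n_init:].copy()

    cf = cho_factor(R, lower=True)
    logdet = 2.0 * np.log(np.diag(cf[0])).sum()
    cho_L = np.linalg.cholesky(R)  # for measurement-noise draws
    m_obs = len(d_obs)

    def loglik(p: np.ndarray) -> float:
        resid = d_obs - p
        if not np.isfinite(resid).all():
            return -np.inf
        return -0.5 * (m_obs * np.log(2 * np.pi) + logdet
                       + float(resid @ cho_solve(cf, resid)))

    ll = np.array([loglik(p) for p in pred])
    noise_scale = 1e-6 * (hi - lo)

    chains_hist = np.empty((n_chains, T, d))
    preds_hist = np.empty((n_chains, T, m_obs))
    ll_hist = np.empty((n_chains, T))
    rmse_hist = np.empty((n_chains, T))
    move_hist = np.empty((n_chains, T), dtype=np.int8)
    acc_hist = np.zeros((n_chains, T), dtype=bool)
    move_counts = np.zeros(3, dtype=int)
    acc_counts = np.zeros(3, dtype=int)

    arc = np.asarray(archive)
    arc_pred = np.asarray(archive_pred)
    kalman_K: np.ndarray | None = None  # gain cached per archive version

    for t in range(T):
        kalman_active = variant == "kzs" and t < t_k
        probs = mixture.probs(kalman_active)
        proposals = np.empty((n_chains, d))
        corrections = np.ones(n_chains)
        moves = np.empty(n_chains, dtype=int)
        for i in range(n_chains):
            rng = chain_rngs[i]
            move = int(rng.choice(3, p=probs))
            moves[i] = move
            if move == 0:
                delta = int(rng.integers(1, 4))
                cr = _CR_VALUES[rng.integers(len(_CR_VALUES))]
                gamma = 1.0 if (t + 1) % 5 == 0 else None
                theta_p = parallel_direction_proposal(
                    theta[i], arc, rng, delta=delta, cr=cr, gamma=gamma,
                    noise_scale=noise_scale)
            elif move == 1:
                theta_p, corrections[i] = snooker_proposal(theta[i], arc,
                                                           rng)
            else:
                if kalman_K is None:
                    kalman_K = kalman_gain(arc, arc_pred, R)
                eps = cho_L @ rng.standard_normal(m_obs)
                theta_p = theta[i] + kalman_K @ (d_obs - pred[i] + eps)
            proposals[i] = reflect_into_bounds(theta_p, bounds)
        pred_p = model(proposals)
        for i in range(n_chains):
            rng = chain_rngs[i]
            ll_p = loglik(pred_p[i])
            ratio = np.exp(min(ll_p - ll[i], 0.0)) * corrections[i]
            move_counts[moves[i]] += 1
            if rng.random() < min(ratio, 1.0):
                theta[i], pred[i], ll[i] = proposals[i], pred_p[i], ll_p
                acc_counts[moves[i]] += 1
                acc_hist[i, t] = True
            chains_hist[i, t] = theta[i]
            preds_hist[i, t] = pred[i]
            ll_hist[i, t] = ll[i]
            rmse_hist[i, t] = rmse(pred[i], d_obs)
            move_hist[i, t] = moves[i]
        if (t + 1) % archive_stride == 0:
            archive.extend(theta.copy())
            archive_pred.extend(pred.copy())
            arc = np.asarray(archive)
            arc_pred = np.asarray(archive_pred)
            kalman_K = None

    samples = chains_hist[:, burn_in:, :].reshape(-1, d)
    sample_preds = preds_hist[:, burn_in:, :].reshape(-1, m_obs)
    sample_ll = ll_hist[:, burn_in:].reshape(-1)
    map_index = int(np.argmax(sample_ll))

    names = list(param_names) if param_names is not None else \
        [f"p{i}" for i in range(d)]
    with np.errstate(invalid="ignore"):
        rhat = gelman_rubin(chains_hist[:, burn_in:, :]) if T - burn_in >= 2 \
            else np.full(d, np.nan)
    result = CalibrationResult(
        method=f"dream_{variant}", param_names=names, samples=samples,
        predictions=sample_preds, map_index=map_index,
        log_likelihoods=sample_ll,
        history={
            "chains": chains_hist, "loglik": ll_hist,
            "rmse_series": rmse_hist, "move_type": move_hist,
            "accepted": acc_hist, "burn_in": burn_in, "t_kalman": t_k,
        },
        config={
            "variant": variant, "n_chains": n_chains, "n_generations": T,
            "mixture": [mixture.p_parallel, mixture.p_snooker,
                        mixture.p_kalman],
            "t_kalman": t_k, "archive_stride": archive_stride,
        },
        seed=seed,
    )
    by_move = {}
    for k, name in enumerate(_MOVE_NAMES):
        by_move[name] = {
            "proposed": int(move_counts[k]),
            "accepted": int(acc_counts[k]),
            "rate": float(acc_counts[k] / move_counts[k])
            if move_counts[k] else None,
        }
    result.stats["acceptance"] = by_move
    result.stats["rhat"] = [float(v) for v in rhat]
    result.stats["rmse_map"] = rmse(result.map_prediction, d_obs)
    return result
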