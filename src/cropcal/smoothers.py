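"""Ensemble smoother machinery: ES update, ES-MDA and ILUES.

All three rest on the Kalman update applied to an ensemble of parameter
vectors m with paired forward-model predictions f(m):

    m_a = m_f + C_MD (C_DD + CD)^{-1} [d_j - f(m_f)]

with C_MD the parameter/prediction cross-covariance, C_DD the
prediction auto-covariance (both 1/(Ne-1) sample estimates), CD the
measurement-error covariance and d_j an observation vector perturbed
independently per member.

ES-MDA assimilates the same data n times with the error covariance
inflated by factors alpha_i; the consistency condition implemented here
is sum(1/alpha_i) = 1 (a constant schedule alpha_i = n).  A variant
normalization sum(1/alpha_i^2) = 1 is available behind a flag.

ILUES replaces the global update by per-member local updates: each
member ranks the whole ensemble by a blended objective

    J(m) = a * J1(m)/J1max + b * J2(m)/J2max

where J1 is the normalized data misfit and J2 the Mahalanobis distance
to that member under the ensemble parameter covariance, updates its
NL = alpha_frac * Ne nearest members with local covariances, and adopts
one updated local member at random.  The randomness of that adoption is
what lets ILUES hold several posterior modes at once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.spatial.distance import cdist

from .evaluation import CalibrationResult, rmse

__all__ = [
    "MDASchedule",
    "ILUESConfig",
    "kalman_gain",
    "es_update",
    "esmda_run",
    "ilues_objective",
    "ilues_run",
    "reflect_into_bounds",
]

_RIDGE = 1e-10  # trace-scaled ridge added before factorizing covariances

Model = Callable[[np.ndarray], np.ndarray]


@dataclass(frozen=True)
class MDASchedule:
    """Inflation factors alpha_i for multiple data assimilation."""

    factors: tuple[float, ...]
    squared_constraint: bool = False  # enforce sum 1/alpha^2 = 1 instead

    def __post_init__(self):
        f = np.asarray(self.factors, float)
        if (f < 1).any():
            raise ValueError("inflation factors must be >= 1")
        total = (1.0 / f**2).sum() if self.squared_constraint \
            else (1.0 / f).sum()
        if not np.isclose(total, 1.0, atol=1e-8):
            kind = "sum 1/alpha^2" if self.squared_constraint else \
                "sum 1/alpha"
            raise ValueError(f"schedule must satisfy {kind} = 1, got {total}")

    @classmethod
    def constant(cls, n: int, squared_constraint: bool = False
                 ) -> "MDASchedule":
        """n equal factors: alpha = n (or sqrt(n) under the squared
        normalization)."""
        a = float(np.sqrt(n)) if squared_constraint else float(n)
        return cls(tuple([a] * n), squared_constraint=squared_constraint)


@dataclass(frozen=True)
class ILUESConfig:
    ensemble_size: int = 500
    n_iterations: int = 3
    local_fraction: float = 0.1  # alpha: local set NL = alpha * Ne
    a: float = 1.0  # weight on the data-misfit term J1
    b: float = 1.0  # weight on the parameter-distance term J2
    inflate: bool = False  # inflate CD by n_iterations per update (MDA-style)
    seed: int | None = None

    def __post_init__(self):
        if not 0 < self.local_fraction <= 1:
            raise ValueError("local_fraction must be in (0, 1]")
        if self.n_local < 2:
            raise ValueError("local ensemble needs at least 2 members")

    @property
    def n_local(self) -> int:
        return int(round(self.local_fraction * self.ensemble_size))


def _ridged_cho(C: np.ndarray):
    m = C.shape[0]
    ridge = _RIDGE * max(np.trace(C) / m, 1.0)
    try:
        return cho_factor(C + ridge * np.eye(m), lower=True)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "covariance singular even after regularization") from exc


def kalman_gain(M: np.ndarray, D: np.ndarray, CD: np.ndarray) -> np.ndarray:
    """K = C_MD (C_DD + CD)^{-1} via Cholesky solve, never inversion.

    Sample covariances use the 1/(Ne-1) normalization.
    """
    M, D = np.asarray(M, float), np.asarray(D, float)
    ne = M.shape[0]
    if ne < 2:
        raise ValueError("need at least 2 ensemble members")
    A = M - M.mean(axis=0)
    B = D - D.mean(axis=0)
    c_md = A.T @ B / (ne - 1)
    c_dd = B.T @ B / (ne - 1)
    cf = _ridged_cho(c_dd + CD)
    return cho_solve(cf, c_md.T).T


def reflect_into_bounds(M: np.ndarray, bounds: np.ndarray) -> np.ndarray:
    """Fold out-of-box coordinates back inside by reflection at the walls.

    Reflection (rather than clipping) keeps updated ensembles from
    piling probability mass onto the bound itself.
    """
    lo, hi = bounds[:, 0], bounds[:, 1]
    span = hi - lo
    y = np.mod(M - lo, 2 * span)
    return lo + np.minimum(y, 2 * span - y)


def _perturb_obs(d_obs: np.ndarray, CD: np.ndarray, n: int,
                 rng: np.random.Generator,
                 inflation: float = 1.0) -> np.ndarray:
    L = np.linalg.cholesky(inflation * CD + _RIDGE * np.eye(len(d_obs)))
    return d_obs + rng.standard_normal((n, len(d_obs))) @ L.T


def es_update(model: Model, M: np.ndarray, D: np.ndarray, d_obs: np.ndarray,
              CD: np.ndarray, rng: int | np.random.Generator,
              bounds: np.ndarray | None = None,
              inflation: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """One global ensemble-smoother update followed by re-simulation.

    Each member assimilates its own perturbed observation drawn from
    N(d, inflation*CD).  Returns the updated parameter matrix and fresh
    predictions ``model(M_new)``.
    """
    rng = np.random.default_rng(rng) if not isinstance(
        rng, np.random.Generator) else rng
    K = kalman_gain(M, D, inflation * CD)
    d_pert = _perturb_obs(d_obs, CD, M.shape[0], rng, inflation)
    M_new = M + (d_pert - D) @ K.T
    if bounds is not None:
        M_new = reflect_into_bounds(M_new, bounds)
    return M_new, model(M_new)


def _misfit_j1(D: np.ndarray, d_obs: np.ndarray,
               CD: np.ndarray) -> np.ndarray:
    """J1 = (d - f)^T CD^{-1} (d - f) per row; NaN rows map to +inf."""
    resid = d_obs - D
    cf = _ridged_cho(CD)
    bad = ~np.isfinite(resid).all(axis=1)
    resid = np.where(np.isfinite(resid), resid, 0.0)
    j1 = np.einsum("ij,ij->i", resid, cho_solve(cf, resid.T).T)
    j1[bad] = np.inf
    return j1


def _gaussian_loglik(D: np.ndarray, d_obs: np.ndarray,
                     CD: np.ndarray) -> np.ndarray:
    m = len(d_obs)
    cf = _ridged_cho(CD)
    logdet = 2.0 * np.log(np.diag(cf[0])).sum()
    j1 = _misfit_j1(D, d_obs, CD)
    return -0.5 * (m * np.log(2 * np.pi) + logdet + j1)


def _result(method: str, M: np.ndarray, D: np.ndarray, d_obs: np.ndarray,
            CD: np.ndarray, history: dict, config: dict, seed,
            param_names: Sequence[str] | None) -> CalibrationResult:
    ll = _gaussian_loglik(D, d_obs, CD)
    map_index = int(np.argmax(ll))
    names = list(param_names) if param_names is not None else \
        [f"p{i}" for i in range(M.shape[1])]
    res = CalibrationResult(method=method, param_names=names, samples=M,
                            predictions=D, map_index=map_index,
                            log_likelihoods=ll, history=history,
                            config=config, seed=seed)
    res.stats["rmse_map"] = rmse(res.map_prediction, d_obs)
    return res


def esmda_run(model: Model, M0: np.ndarray, d_obs: np.ndarray,
              CD: np.ndarray, schedule: MDASchedule | None = None,
              seed: int | np.random.Generator = 0,
              bounds: np.ndarray | None = None,
              param_names: Sequence[str] | None = None,
              D0: np.ndarray | None = None) -> CalibrationResult:
    """ES with multiple data assimilation over an inflation schedule.

    Defaults to three assimilations with constant factors alpha_i = 3.
    The per-iteration ensembles are retained in ``history`` for trace
    plots.
    """
    schedule = schedule or MDASchedule.constant(3)
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    M = np.array(M0, float)
    D = model(M) if D0 is None else np.array(D0, float)
    hist_M, hist_D = [M.copy()], [D.copy()]
    for alpha in schedule.factors:
        M, D = es_update(model, M, D, d_obs, CD, rng, bounds=bounds,
                         inflation=alpha)
        hist_M.append(M.copy())
        hist_D.append(D.copy())
    history = {"iterations": hist_M, "predictions": hist_D}
    config = {"schedule": list(schedule.factors),
              "squared_constraint": schedule.squared_constraint,
              "ensemble_size": M.shape[0]}
    return _result("esmda", M, D, d_obs, CD, history, config,
                   seed if isinstance(seed, int) else None, param_names)


def ilues_objective(M_cand: np.ndarray, D_cand: np.ndarray,
                    d_obs: np.ndarray, CD: np.ndarray, m_ref: np.ndarray,
                    CMM: np.ndarray, a: float = 1.0,
                    b: float = 1.0) -> np.ndarray:
    """Blended local-selection objective J over a candidate set.

    J1 is the CD-weighted data misfit, J2 the CMM-weighted distance to
    the reference member ``m_ref``; each is normalized by its maximum
    over the candidate set before weighting.
    """
    j1 = _misfit_j1(D_cand, d_obs, CD)
    diff = M_cand - m_ref
    cf = _ridged_cho(CMM)
    j2 = np.einsum("ij,ij->i", diff, cho_solve(cf, diff.T).T)
    j1max = np.max(j1[np.isfinite(j1)], initial=0.0)
    finite_j1 = np.where(np.isfinite(j1), j1, np.inf)
    j1n = np.divide(finite_j1, j1max, out=np.where(
        np.isfinite(finite_j1), 0.0, np.inf), where=j1max > 0)
    j2max = j2.max()
    j2n = j2 / j2max if j2max > 0 else np.zeros_like(j2)
    return a * j1n + b * j2n


def ilues_run(model: Model, M0: np.ndarray, d_obs: np.ndarray,
              CD: np.ndarray, config: ILUESConfig | None = None,
              bounds: np.ndarray | None = None,
              param_names: Sequence[str] | None = None,
              D0: np.ndarray | None = None) -> CalibrationResult:
    """Iterative local updating ensemble smoother.

    Per iteration and per member j: rank the whole ensemble by
    :func:`ilues_objective` anchored at member j, Kalman-update the NL
    best-ranked members with covariances estimated from that local set,
    and replace member j with a uniformly random member of the updated
    local set.  All members are then re-simulated together.
    """
    config = config or ILUESConfig(ensemble_size=len(M0))
    rng = np.random.default_rng(config.seed)
    M = np.array(M0, float)
    ne, d = M.shape
    nl = config.n_local
    if nl > ne:
        raise ValueError("local ensemble larger than the ensemble itself")
    D = model(M) if D0 is None else np.array(D0, float)
    inflation = float(config.n_iterations) if config.inflate else 1.0
    hist_M, hist_D = [M.copy()], [D.copy()]

    for _ in range(config.n_iterations):
        j1 = _misfit_j1(D, d_obs, CD)
        j1max = np.max(j1[np.isfinite(j1)], initial=0.0)
        j1n = np.where(np.isfinite(j1),
                       j1 / j1max if j1max > 0 else 0.0, np.inf)
        cmm = np.atleast_2d(np.cov(M, rowvar=False))
        cmm = cmm + _RIDGE * np.eye(d) * max(float(np.trace(cmm)) / d, 1.0)
        # pairwise Mahalanobis distances under the ensemble covariance
        L = np.linalg.cholesky(cmm)
        Y = solve_triangular(L, M.T, lower=True).T
        j2_all = cdist(Y, Y, "sqeuclidean")

        M_next = np.empty_like(M)
        for j in range(ne):
            j2 = j2_all[j]
            j2max = j2.max()
            j2n = j2 / j2max if j2max > 0 else np.zeros_like(j2)
            J = config.a * j1n + config.b * j2n
            local = np.argpartition(J, nl - 1)[:nl]
            M_loc, D_loc = M[local], D[local]
            K = kalman_gain(M_loc, D_loc, inflation * CD)
            d_pert = _perturb_obs(d_obs, CD, nl, rng, inflation)
            M_upd = M_loc + (d_pert - D_loc) @ K.T
            if bounds is not None:
                M_upd = reflect_into_bounds(M_upd, bounds)
            M_next[j] = M_upd[rng.integers(nl)]
        M = M_next
        D = model(M)
        hist_M.append(M.copy())
        hist_D.append(D.copy())

    history = {"iterations": hist_M, "predictions": hist_D}
    cfg = {"ensemble_size": config.ensemble_size,
           "n_iterations": config.n_iterations,
           "local_fraction": config.local_fraction,
           "a": config.a, "b": config.b, "inflate": config.inflate}
    return _result("ilues", M, D, d_obs, CD, history, cfg, config.seed,
                   param_names)
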