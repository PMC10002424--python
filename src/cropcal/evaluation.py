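"""Fit statistics, calibration-result container and posterior summaries.

Three classical agreement statistics evaluate simulated (S) against
observed (O) series of length n:

    ME   = sum(S_i - O_i) / n                       (mean bias error)
    RMSE = sqrt(sum((S_i - O_i)^2) / n)
    IA   = 1 - sum((S_i - O_i)^2)
             / sum((|S_i - Obar| + |O_i - Obar|)^2)  (index of agreement)

IA is bounded in [0, 1]; 1 means perfect agreement.  Its denominator is
zero only when every S_i and O_i equals the observed mean, in which case
the statistic is undefined and reported as ``None``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

__all__ = [
    "FitStats",
    "CalibrationResult",
    "fit_stats",
    "rmse",
    "rmse_map",
    "uncertainty_bands",
    "summarize_marginals",
    "rmse_evolution",
]


@dataclass(frozen=True)
class FitStats:
    me: float
    rmse: float
    ia: float | None
    n: int

    def to_dict(self) -> dict[str, Any]:
        return {"me": self.me, "rmse": self.rmse, "ia": self.ia, "n": self.n}


def rmse(simulated: np.ndarray, observed: np.ndarray) -> float:
    s, o = np.asarray(simulated, float), np.asarray(observed, float)
    if s.shape != o.shape:
        raise ValueError("length mismatch between simulated and observed")
    return float(np.sqrt(np.mean((s - o) ** 2)))


def fit_stats(simulated: np.ndarray, observed: np.ndarray) -> FitStats:
    """ME, RMSE and index of agreement for paired series."""
    s, o = np.asarray(simulated, float), np.asarray(observed, float)
    if s.shape != o.shape or s.ndim != 1:
        raise ValueError("simulated and observed must be 1-d of equal length")
    if len(s) < 1:
        raise ValueError("need at least one observation")
    diff = s - o
    me = float(diff.mean())
    rm = float(np.sqrt(np.mean(diff**2)))
    obar = o.mean()
    denom = float(((np.abs(s - obar) + np.abs(o - obar)) ** 2).sum())
    if denom == 0:
        ia = None
    else:
        # the triangle inequality bounds IA in [0,1] exactly; clip the
        # one-ulp float excursions so the bound holds numerically too
        ia = float(min(max(1.0 - (diff**2).sum() / denom, 0.0), 1.0))
    return FitStats(me=me, rmse=rm, ia=ia, n=len(s))


@dataclass
class CalibrationResult:
    """Posterior samples, MAP member and run history of one calibration.

    ``samples``/``predictions`` are the posterior parameter matrix and
    the paired forward-model outputs; ``map_index`` points at the member
    with the highest Gaussian log-likelihood (equivalently the smallest
    normalized data misfit J1).  ``history`` carries per-iteration
    ensembles for the smoothers or per-generation chain state for MCMC.
    """

    method: str
    param_names: list[str]
    samples: np.ndarray  # (n, d)
    predictions: np.ndarray  # (n, m)
    map_index: int
    log_likelihoods: np.ndarray | None = None
    history: dict[str, Any] = field(default_factory=dict)
    stats: dict[str, Any] = field(default_factory=dict)
    config: dict[str, Any] = field(default_factory=dict)
    seed: int | None = None

    @property
    def map_params(self) -> np.ndarray:
        return self.samples[self.map_index]

    @property
    def map_prediction(self) -> np.ndarray:
        return self.predictions[self.map_index]

    def save(self, outdir) -> None:
        """Serialize: JSON summary plus CSV matrices (samples, predictions,
        per-iteration parameter traces when present)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(self.samples, columns=self.param_names).to_csv(
            outdir / "samples.csv", index=False)
        pd.DataFrame(self.predictions).to_csv(
            outdir / "predictions.csv", index=False)
        meta = {
            "method": self.method,
            "param_names": self.param_names,
            "map_index": int(self.map_index),
            "stats": self.stats,
            "config": self.config,
            "seed": self.seed,
        }
        if self.log_likelihoods is not None:
            meta["log_likelihoods"] = [float(v) for v in self.log_likelihoods]
        (outdir / "result.json").write_text(json.dumps(meta, indent=1))
        if "iterations" in self.history:
            rows = []
            for it, M in enumerate(self.history["iterations"]):
                df = pd.DataFrame(M, columns=self.param_names)
                df.insert(0, "iteration", it)
                rows.append(df)
            pd.concat(rows).to_csv(outdir / "trace.csv", index=False)
        if "rmse_series" in self.history:
            arr = np.asarray(self.history["rmse_series"])
            df = pd.DataFrame(arr.T, columns=[f"chain_{c}"
                                              for c in range(arr.shape[0])])
            df.insert(0, "generation", np.arange(arr.shape[1]))
            df.to_csv(outdir / "rmse_evolution.csv", index=False)

    @classmethod
    def load(cls, outdir) -> "CalibrationResult":
        outdir = Path(outdir)
        meta = json.loads((outdir / "result.json").read_text())
        samples = pd.read_csv(outdir / "samples.csv").to_numpy(float)
        preds = pd.read_csv(outdir / "predictions.csv").to_numpy(float)
        ll = meta.get("log_likelihoods")
        return cls(method=meta["method"], param_names=meta["param_names"],
                   samples=samples, predictions=preds,
                   map_index=meta["map_index"],
                   log_likelihoods=None if ll is None else np.array(ll),
                   stats=meta["stats"], config=meta["config"],
                   seed=meta["seed"])


def rmse_map(result: CalibrationResult, observed: np.ndarray) -> float:
    """RMSE between the MAP member's prediction and the observations."""
    if len(result.samples) == 0:
        raise ValueError("empty calibration result")
    return rmse(result.map_prediction, np.asarray(observed, float))


def uncertainty_bands(result: CalibrationResult, noise_sd: float,
                      level: float = 0.95,
                      seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Pointwise central predictive intervals at ``level``.

    The parameter band is the central quantile range of the posterior
    predictions; the total band adds one fresh measurement-noise draw to
    each posterior prediction before taking quantiles, so it reflects
    parameter plus observation uncertainty.
    """
    preds = result.predictions
    if len(preds) < 20:
        raise ValueError("need at least 20 posterior samples for bands")
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
    noisy = preds + rng.normal(0.0, noise_sd, size=preds.shape)
    param_lo = np.quantile(preds, lo_q, axis=0)
    param_hi = np.quantile(preds, hi_q, axis=0)
    # total uncertainty nests parameter uncertainty by definition; take
    # the union so finite-sample quantile noise cannot invert the nesting
    total_lo = np.minimum(np.quantile(noisy, lo_q, axis=0), param_lo)
    total_hi = np.maximum(np.quantile(noisy, hi_q, axis=0), param_hi)
    return pd.DataFrame({
        "point": np.arange(preds.shape[1]),
        "param_lower": param_lo,
        "param_upper": param_hi,
        "total_lower": total_lo,
        "total_upper": total_hi,
    })


def summarize_marginals(samples: np.ndarray,
                        names: list[str] | None = None) -> pd.DataFrame:
    """Per-parameter histogram table with Freedman-Diaconis binning.

    Returns long format (parameter, bin_left, bin_right, count, density);
    constant samples occupy a single degenerate bin.
    """
    samples = np.atleast_2d(np.asarray(samples, float))
    if samples.size == 0:
        raise ValueError("empty sample matrix")
    if names is None:
        names = [f"p{i}" for i in range(samples.shape[1])]
    frames = []
    for i, name in enumerate(names):
        col = samples[:, i]
        if np.ptp(col) == 0:
            frames.append(pd.DataFrame({
                "parameter": [name], "bin_left": [col[0]],
                "bin_right": [col[0]], "count": [len(col)],
                "density": [np.inf]}))
            continue
        counts, edges = np.histogram(col, bins="fd")
        widths = np.diff(edges)
        frames.append(pd.DataFrame({
            "parameter": name, "bin_left": edges[:-1], "bin_right": edges[1:],
            "count": counts, "density": counts / (counts.sum() * widths)}))
    return pd.concat(frames, ignore_index=True)


def rmse_evolution(predictions: np.ndarray,
                   observed: np.ndarray) -> np.ndarray:
    """RMSE of each step's prediction against the observations.

    ``predictions`` has shape (..., n_obs); RMSE is taken over the last
    axis, so chain stacks (n_chains, T, n_obs) yield (n_chains, T).
    """
    preds = np.asarray(predictions, float)
    if preds.size == 0:
        raise ValueError("empty prediction history")
    diff = preds - np.asarray(observed, float)
    return np.sqrt(np.mean(diff**2, axis=-1))
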