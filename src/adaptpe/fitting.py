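"""Maximum-likelihood fitting and information-criterion comparison.

Predictions y_m are modelled as Gaussian around the model-predicted means,
p(y_m | Phi) = N(mu_m, sigma^2).  The noise variance has a closed-form MLE
(the mean squared residual), so it is profiled out analytically and the
numerical search runs over the learning parameters only, by bounded
multi-start local optimisation (L-BFGS-B from Latin-hypercube starts).  A
brute-force grid evaluator is provided as an independent oracle for the
optimiser.  Model comparison uses AIC/BIC with sigma counted among the free
parameters.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import qmc

from .models import FREE_PARAMS, MODEL_IDS, PARAM_BOUNDS, ModelParams

__all__ = [
    "SIGMA2_FLOOR",
    "FitResult",
    "gaussian_loglik",
    "profile_sigma",
    "profiled_loglik",
    "fit_model",
    "grid_oracle",
    "fit_all_models",
    "compare_models",
    "fits_to_frame",
]

#: Floor on the profiled noise variance, guarding degenerate (noise-free)
#: synthetic input where the MLE of sigma^2 would be zero.
SIGMA2_FLOOR = 1e-4

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass
class FitResult:
    """Outcome of fitting one model to one agent's prediction sequence."""

    agent_id: str
    model_id: str
    params: ModelParams
    loglik: float
    n_free: int
    n_obs: int
    aic: float
    bic: float
    n_restarts: int
    converged: bool
    best_start: np.ndarray

    def to_dict(self) -> dict:
        d = {
            "agent_id": self.agent_id,
            "model_id": self.model_id,
            "loglik": self.loglik,
            "n_free": self.n_free,
            "n_obs": self.n_obs,
            "aic": self.aic,
            "bic": self.bic,
            "n_restarts": self.n_restarts,
            "converged": self.converged,
            "sigma": self.params.sigma,
        }
        for name in FREE_PARAMS[self.model_id]:
            d[name] = getattr(self.params, name)
        return d


def gaussian_loglik(y, mu, sigma2: float) -> float:
    """Sum of Gaussian log-densities of ``y`` around ``mu`` with variance sigma2."""
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if y.shape != mu.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {mu.shape}")
    if sigma2 <= 0:
        raise ValueError(f"sigma2 must be positive, got {sigma2}")
    resid = y - mu
    m = y.size
    return -0.5 * (m * (_LOG_2PI + math.log(sigma2))
                   + float(resid @ resid) / sigma2)


def profile_sigma(y, mu, floor: float = SIGMA2_FLOOR) -> float:
    """Gaussian MLE of the noise variance: the mean squared residual.

    Floored at ``floor`` so that noiseless input yields a finite likelihood.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if y.size < 2:
        raise ValueError("need at least two observations to profile sigma")
    if np.isnan(y).all():
        raise ValueError("all observations missing")
    resid = y - mu
    return max(float(resid @ resid) / y.size, floor)


def profiled_loglik(y, mu, floor: float = SIGMA2_FLOOR) -> tuple[float, float]:
    """Log-likelihood at the profiled (MLE) noise variance.

    Returns (loglik, sigma2_hat).  Maximising this over the learning
    parameters is equivalent to the joint maximisation over (theta, sigma).
    """
    sigma2 = profile_sigma(y, mu, floor=floor)
    return gaussian_loglik(y, mu, sigma2), sigma2


# ---------------------------------------------------------------------------
# Fast prepared likelihood: trials are decomposed once into per-pot streams
# so that each objective evaluation is a plain loop over ~31 floats per pot.
# ---------------------------------------------------------------------------

class _PreparedData:
    def __init__(self, trials: pd.DataFrame, mu_init: float | str):
        ordered = trials.sort_values(["session", "trial"], kind="stable")
        ordered = ordered[~ordered["missed"].astype(bool)]
        y_all = ordered["prediction"].to_numpy(dtype=float)
        if np.isnan(y_all).any():
            raise ValueError("non-missed trials must have predictions to fit")
        self.pots = []
        self.y = y_all
        pos = 0
        for dist_id in ordered["dist_id"].unique():
            sub = ordered[ordered["dist_id"] == dist_id]
            r = sub["reward"].to_numpy(dtype=float)
            y = sub["prediction"].to_numpy(dtype=float)
            sd = float(sub["sd"].iloc[0])
            mu0 = float(np.clip(y[0], 0.0, 100.0)) \
                if mu_init == "first_prediction" else float(mu_init)
            self.pots.append((r, y, sd, mu0))
            pos += len(sub)
        self.n_obs = int(y_all.size)


def _pot_mus(model_id: str, theta, r: np.ndarray, sd: float, mu0: float,
             C: float = 1.0, D: float = 1.0) -> np.ndarray:
    """Model-predicted means along one pot's reward stream (fast path)."""
    n = r.size
    mus = np.empty(n)
    mu = mu0
    if model_id == "RW1":
        k = theta[0]
        for i in range(n):
            mus[i] = mu
            mu += k * (r[i] - mu)
            mu = 0.0 if mu < 0.0 else (100.0 if mu > 100.0 else mu)
    elif model_id == "RW2":
        kp, kn = theta[0], theta[1]
        for i in range(n):
            mus[i] = mu
            d = r[i] - mu
            mu += (kp if d >= 0 else kn) * d
            mu = 0.0 if mu < 0.0 else (100.0 if mu > 100.0 else mu)
    elif model_id in ("PH1", "PH2"):
        k1, gamma = theta[0], theta[1]
        denom = 1.0
        if model_id == "PH2":
            nu = theta[2]
            denom = (D * math.log(sd)) ** nu
        k = k1
        for i in range(n):
            mus[i] = mu
            d = r[i] - mu
            k = (1.0 - gamma) * k + gamma * C * abs(d) / 100.0
            mu += k * d / denom
            mu = 0.0 if mu < 0.0 else (100.0 if mu > 100.0 else mu)
    else:
        raise ValueError(f"unknown model_id {model_id!r}")
    return mus


def _objective(model_id: str, theta, data: _PreparedData,
               floor: float = SIGMA2_FLOOR) -> float:
    """Negative profiled log-likelihood of theta on prepared data."""
    sse = 0.0
    for r, y, sd, mu0 in data.pots:
        resid = y - _pot_mus(model_id, theta, r, sd, mu0)
        sse += float(resid @ resid)
    m = data.n_obs
    sigma2 = max(sse / m, floor)
    return 0.5 * m * (_LOG_2PI + math.log(sigma2) + sse / (m * sigma2))


def _bounds(model_id: str) -> list[tuple[float, float]]:
    return [PARAM_BOUNDS[n] for n in FREE_PARAMS[model_id]]


def fit_model(
    model_id: str,
    trials: pd.DataFrame,
    n_restarts: int = 20,
    seed: int | np.random.SeedSequence | None = None,
    mu_init: float | str = "first_prediction",
    agent_id: str | None = None,
    convergence_tol: float = 1e-4,
) -> FitResult:
    """Fit one learning model to one agent's trials by profiled ML.

    Runs ``n_restarts`` bounded L-BFGS-B searches from a seeded
    Latin-hypercube over the parameter box and keeps the best; the fit is
    flagged converged when at least two restarts agree within
    ``convergence_tol`` nats of the best.  Deterministic given the seed.
    """
    if model_id not in MODEL_IDS:
        raise ValueError(f"unknown model_id {model_id!r}")
    data = _PreparedData(trials, mu_init)
    if data.n_obs < 30:
        raise ValueError(
            f"need >= 30 non-missed trials to fit, got {data.n_obs}"
        )
    bounds = _bounds(model_id)
    dim = len(bounds)
    sampler = qmc.LatinHypercube(d=dim, seed=np.random.default_rng(seed))
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    starts = lo + sampler.random(n_restarts) * (hi - lo)

    finals = []
    results = []
    for start in starts:
        res = minimize(
            lambda th: _objective(model_id, th, data),
            x0=start, method="L-BFGS-B", bounds=bounds,
        )
        results.append((float(res.fun), res.x, start))
        finals.append(float(res.fun))
    if not results:
        raise RuntimeError("no restarts executed")
    best_fun, best_x, best_start = min(results, key=lambda t: t[0])
    if not math.isfinite(best_fun):
        raise RuntimeError(f"optimizer failed on all restarts for {model_id}")
    agree = sum(1 for f in finals if f - best_fun <= convergence_tol)
    converged = agree >= 2 if n_restarts >= 2 else True

    # Recover the profiled noise variance at the optimum.
    sse = 0.0
    mus_all = []
    for r, y, sd, mu0 in data.pots:
        mus = _pot_mus(model_id, best_x, r, sd, mu0)
        mus_all.append(mus)
        resid = y - mus
        sse += float(resid @ resid)
    sigma2 = max(sse / data.n_obs, SIGMA2_FLOOR)
    loglik = -best_fun
    n_free = dim + 1  # learning parameters + sigma
    m = data.n_obs
    return FitResult(
        agent_id=agent_id or str(trials["agent_id"].iloc[0]),
        model_id=model_id,
        params=ModelParams.from_vector(model_id, best_x,
                                       sigma=math.sqrt(sigma2)),
        loglik=loglik,
        n_free=n_free,
        n_obs=m,
        aic=2 * n_free - 2 * loglik,
        bic=n_free * math.log(m) - 2 * loglik,
        n_restarts=n_restarts,
        converged=converged,
        best_start=np.asarray(best_start),
    )


def grid_oracle(
    model_id: str,
    trials: pd.DataFrame,
    grid_spec: dict[str, np.ndarray],
    mu_init: float | str = "first_prediction",
    max_points: int = 100_000,
) -> tuple[dict[str, float], float]:
    """Exhaustive profiled-likelihood evaluation over a parameter grid.

    An independent check on the optimiser: the optimiser's log-likelihood
    must be at least the grid's best minus a small slack.  Returns the best
    grid point (by name) and its log-likelihood.
    """
    names = FREE_PARAMS[model_id]
    if set(grid_spec) != set(names):
        raise ValueError(f"grid must cover exactly {names}, got {set(grid_spec)}")
    axes = [np.asarray(grid_spec[n], dtype=float) for n in names]
    n_points = int(np.prod([a.size for a in axes]))
    if n_points > max_points:
        raise ValueError(f"grid of {n_points} points exceeds cap {max_points}")
    data = _PreparedData(trials, mu_init)
    best_fun, best_theta = math.inf, None
    for theta in itertools.product(*axes):
        fun = _objective(model_id, theta, data)
        if fun < best_fun:
            best_fun, best_theta = fun, theta
    return dict(zip(names, best_theta)), -best_fun


def fit_all_models(
    trials: pd.DataFrame,
    models: tuple[str, ...] = MODEL_IDS,
    n_restarts: int = 20,
    seed: int | np.random.SeedSequence | None = None,
    **kwargs,
) -> list[FitResult]:
    """Fit several models to one agent, with independent seeded restarts."""
    ss = np.random.SeedSequence(seed) if not isinstance(
        seed, np.random.SeedSequence) else seed
    children = ss.spawn(len(models))
    return [
        fit_model(mid, trials, n_restarts=n_restarts, seed=child, **kwargs)
        for mid, child in zip(models, children)
    ]


def fits_to_frame(fits: list[FitResult]) -> pd.DataFrame:
    """Long-format table of fit results, one row per agent x model."""
    return pd.DataFrame([f.to_dict() for f in fits])


def compare_models(
    fits: pd.DataFrame | list[FitResult],
    models: tuple[str, ...] = MODEL_IDS,
) -> dict:
    """Pairwise information-criterion comparison across agents.

    For every ordered model pair, the mean across agents of
    (criterion_row - criterion_col); negative entries favour the row model.
    Rows are each model after the first, columns every earlier model, one row
    per criterion (AIC and BIC) - the standard lower-triangular layout for
    nested model sets.  Also reports each agent's best model by BIC, ties
    broken toward fewer parameters.
    """
    frame = fits if isinstance(fits, pd.DataFrame) else fits_to_frame(fits)
    missing = [m for m in models if m not in set(frame["model_id"])]
    if missing:
        raise ValueError(f"missing fits for models: {missing}")
    wide = {
        crit: frame.pivot(index="agent_id", columns="model_id", values=crit)
        for crit in ("aic", "bic")
    }
    for crit, w in wide.items():
        if w.isna().any().any():
            bad = w.index[w.isna().any(axis=1)].tolist()
            raise ValueError(f"agents missing {crit} fits: {bad}")

    rows = []
    for row_model in models[1:]:
        for crit in ("aic", "bic"):
            entry = {"model": row_model, "criterion": f"d{crit.upper()}"}
            for col_model in models[: models.index(row_model)]:
                d = (wide[crit][row_model] - wide[crit][col_model]).mean()
                entry[col_model] = float(d)
            rows.append(entry)
    table = pd.DataFrame(rows).set_index(["model", "criterion"])

    nf = frame.pivot(index="agent_id", columns="model_id", values="n_free")
    bic = wide["bic"]

    def _best(agent):
        vals = bic.loc[agent]
        best_val = vals.min()
        tied = [m for m in models if math.isclose(vals[m], best_val,
                                                  abs_tol=1e-9)]
        return min(tied, key=lambda m: nf.loc[agent, m])

    best = pd.Series({a: _best(a) for a in bic.index}, name="best_model")
    return {"table": table, "best_by_bic": best}
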