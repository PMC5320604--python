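"""Trial-by-trial reinforcement-learning models of reward-magnitude prediction.

Four generative models of the prediction sequence, all of the delta-rule
family mu' = mu + k * delta with delta = reward - prediction:

* ``RW1`` - Rescorla-Wagner with a single constant learning rate k.
* ``RW2`` - Rescorla-Wagner with separate rates k+ / k- for positive and
  negative prediction errors.
* ``PH1`` - Pearce-Hall: a dynamic learning rate driven by the recent
  absolute prediction error, k_n = (1 - gamma) * k_{n-1} +
  gamma * C * |delta_n| / 100, which lets predictions stabilise in the face
  of continuing errors.
* ``PH2`` - adaptive Pearce-Hall: as PH1, but the error that updates the
  prediction is first scaled relative to the variability of the reward
  distribution, delta / (D * ln SD)**nu.  nu = 0 means no scaling; nu = 1
  full scaling.  This is the mechanism that restrains learning when
  prediction errors fluctuate more.

The models nest exactly: RW2 with k+ = k- is RW1, and PH2 with nu = 0 is
PH1.  Predictions live on the £0-£100 response scale and are clipped to it
after every update.  Scaling coefficients C and D are fixed at 1 (with
|delta| normalised by the 100-point scale inside the Pearce-Hall rate),
leaving k (or k+/k-), k1, gamma and nu as the learnable parameters, plus a
Gaussian response-noise SD sigma shared by all models.

State is kept separately per reward distribution ("pot"): the cue identifies
the pot, so an agent tracks the two interleaved distributions of a session
independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "MODEL_IDS",
    "FREE_PARAMS",
    "PARAM_BOUNDS",
    "ModelParams",
    "ModelState",
    "prediction_error",
    "scale_pe",
    "model_step",
    "predict_series",
    "simulate_agent",
    "running_mean_agent",
]

MODEL_IDS = ("RW1", "RW2", "PH1", "PH2")

#: Learning parameters fitted per model (response noise sigma is profiled
#: separately and shared by all models).
FREE_PARAMS: dict[str, tuple[str, ...]] = {
    "RW1": ("k",),
    "RW2": ("k_pos", "k_neg"),
    "PH1": ("k1", "gamma"),
    "PH2": ("k1", "gamma", "nu"),
}

#: Box bounds of every learnable parameter (all are rates/extents on [0, 1]).
PARAM_BOUNDS: dict[str, tuple[float, float]] = {
    "k": (0.0, 1.0),
    "k_pos": (0.0, 1.0),
    "k_neg": (0.0, 1.0),
    "k1": (0.0, 1.0),
    "gamma": (0.0, 1.0),
    "nu": (0.0, 1.0),
}

_SCALE = 100.0  # response-scale span used to normalise |delta| in the PH rate


@dataclass(frozen=True)
class ModelParams:
    """Parameter vector for one learning model.

    Only the fields listed in ``FREE_PARAMS[model_id]`` are meaningful for a
    given model; the rest are ignored.  ``sigma`` is the SD (in GBP) of the
    Gaussian response noise in the observation model.
    """

    model_id: str
    k: float = 0.0
    k_pos: float = 0.0
    k_neg: float = 0.0
    k1: float = 0.0
    gamma: float = 0.0
    nu: float = 0.0
    sigma: float = 1.0
    C: float = 1.0
    D: float = 1.0

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_IDS:
            raise ValueError(f"unknown model_id {self.model_id!r}")
        for name in FREE_PARAMS[self.model_id]:
            lo, hi = PARAM_BOUNDS[name]
            value = getattr(self, name)
            if not lo <= value <= hi:
                raise ValueError(f"{name}={value} outside [{lo}, {hi}]")
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")

    @classmethod
    def from_vector(
        cls, model_id: str, theta, sigma: float = 1.0
    ) -> "ModelParams":
        """Build params from the fitting-order vector ``FREE_PARAMS[model_id]``."""
        names = FREE_PARAMS[model_id]
        if len(theta) != len(names):
            raise ValueError(
                f"{model_id} expects {len(names)} parameters, got {len(theta)}"
            )
        return cls(model_id=model_id, sigma=sigma,
                   **dict(zip(names, map(float, theta))))

    def to_vector(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FREE_PARAMS[self.model_id]])


@dataclass
class ModelState:
    """Per-pot learner state: current predicted mean and learning rate."""

    mu: float
    k_current: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mu <= _SCALE:
            raise ValueError(f"mu must lie in [0, {_SCALE:g}], got {self.mu}")


def prediction_error(y: float, r: float) -> float:
    """delta = reward - prediction; missing if either input is missing."""
    if y is None or r is None or math.isnan(y) or math.isnan(r):
        return math.nan
    return r - y


def scale_pe(delta: float, sd: float, nu: float, D: float = 1.0) -> float:
    """Scale a prediction error relative to reward variability.

    Returns delta / (D * ln sd)**nu (natural log).  nu = 0 is the identity.
    With D = 1 and the task's SDs (>= 5), ln(sd) > 1 so scaling always
    shrinks the error.
    """
    if not 0.0 <= nu <= 1.0:
        raise ValueError(f"nu must lie in [0, 1], got {nu}")
    if nu == 0.0:
        return delta
    if sd <= 1.0:
        raise ValueError(f"sd must exceed 1 for log-SD scaling, got {sd}")
    return delta / (D * math.log(sd)) ** nu


def _update(
    params: ModelParams, state: ModelState, delta: float, sd: float
) -> ModelState:
    """Advance one learner state by one observed prediction error."""
    mid = params.model_id
    if mid == "RW1":
        k = params.k
        effective = delta
    elif mid == "RW2":
        k = params.k_pos if delta >= 0 else params.k_neg
        effective = delta
    elif mid in ("PH1", "PH2"):
        k = (1.0 - params.gamma) * state.k_current \
            + params.gamma * params.C * abs(delta) / _SCALE
        effective = delta if mid == "PH1" else scale_pe(
            delta, sd, params.nu, params.D
        )
    else:  # pragma: no cover - guarded in ModelParams
        raise ValueError(f"unknown model_id {mid!r}")
    mu_next = min(max(state.mu + k * effective, 0.0), _SCALE)
    return ModelState(mu=mu_next, k_current=k)


def model_step(
    params: ModelParams, state: ModelState, r: float, sd: float
) -> tuple[ModelState, float]:
    """One model-internal update: delta = r - mu, then the model's rule.

    Returns the new state and the next predicted mean.
    """
    if not 0.0 <= r <= _SCALE:
        raise ValueError(f"reward must lie in [0, {_SCALE:g}], got {r}")
    new = _update(params, state, r - state.mu, sd)
    return new, new.mu


def _initial_state(params: ModelParams, mu: float) -> ModelState:
    k0 = params.k1 if params.model_id in ("PH1", "PH2") else 0.0
    return ModelState(mu=mu, k_current=k0)


def predict_series(
    params: ModelParams,
    trials: pd.DataFrame,
    mu_init: float | str = "first_prediction",
) -> np.ndarray:
    """Model-predicted means mu_m for every non-missed trial.

    Folds :func:`model_step` over the observed rewards, keeping one learner
    state per reward distribution.  ``mu_init`` is either a number (the
    starting prediction of every pot) or ``"first_prediction"``, which pins
    each pot's initial mean to the first observed prediction of that pot -
    the convention used when fitting, as it removes an unidentified initial
    condition.  Missed trials are skipped without an update and receive no
    mu.  Returns an array aligned with the non-missed rows of ``trials``
    (in session/trial order).
    """
    ordered = _check_sorted(trials)
    states: dict[str, ModelState] = {}
    mus = []
    for row in ordered.itertuples(index=False):
        if bool(row.missed):
            continue
        state = states.get(row.dist_id)
        if state is None:
            if mu_init == "first_prediction":
                y0 = float(row.prediction)
                if math.isnan(y0):
                    raise ValueError(
                        "mu_init='first_prediction' requires observed "
                        f"predictions (pot {row.dist_id})"
                    )
                start = min(max(y0, 0.0), _SCALE)
            else:
                start = float(mu_init)
            state = _initial_state(params, start)
        mus.append(state.mu)
        state, _ = model_step(params, state, float(row.reward), float(row.sd))
        states[row.dist_id] = state
    return np.asarray(mus)


def _check_sorted(trials: pd.DataFrame) -> pd.DataFrame:
    key = trials[["session", "trial"]].to_numpy()
    if len(key) > 1:
        flat = key[:, 0] * (key[:, 1].max() + 1) + key[:, 1]
        if not np.all(np.diff(flat) > 0):
            raise ValueError("trials must be sorted by (session, trial)")
    return trials


def simulate_agent(
    params: ModelParams,
    design: pd.DataFrame,
    rng: np.random.Generator,
    mu_init: float = 50.0,
    miss_probability: float = 0.0,
) -> pd.DataFrame:
    """Simulate an agent's predictions on a task design.

    On each trial the agent emits y = mu + Gaussian(0, sigma) noise, clipped
    to the scale and rounded to £0.1, then updates on the prediction error it
    actually saw on screen (reward minus *emitted* prediction).  Missed
    trials (probability ``miss_probability``) omit the reward: prediction,
    reward and PE are set missing, the pay-off is zero, and no update occurs.
    Completes the prediction, pe and payoff columns.
    """
    from .task import payoff as _payoff

    ordered = _check_sorted(design)
    out = ordered.copy()
    states: dict[str, ModelState] = {}
    preds = np.full(len(out), np.nan)
    rewards = out["reward"].to_numpy(dtype=float).copy()
    pes = np.full(len(out), np.nan)
    missed = np.zeros(len(out), dtype=bool)
    pays = np.zeros(len(out))
    for i, row in enumerate(ordered.itertuples(index=False)):
        if miss_probability > 0 and rng.random() < miss_probability:
            missed[i] = True
            rewards[i] = np.nan
            continue
        state = states.get(row.dist_id)
        if state is None:
            state = _initial_state(params, mu_init)
        y = state.mu + rng.normal(0.0, params.sigma)
        y = round(min(max(y, 0.0), _SCALE), 1)
        r = float(row.reward)
        delta = r - y
        preds[i] = y
        pes[i] = delta
        pays[i] = _payoff(bool(row.is_control), y, r, float(row.ev),
                          float(row.sd))
        states[row.dist_id] = _update(params, state, delta, float(row.sd))
    out["prediction"] = preds
    out["reward"] = rewards
    out["pe"] = pes
    out["missed"] = missed
    out["payoff"] = np.round(pays, 1)
    return out


def running_mean_agent(
    design: pd.DataFrame, mu_init: float = 50.0
) -> pd.DataFrame:
    """Noise-free baseline agent predicting the running mean of each pot.

    The running mean is the optimal point prediction on this task, so this
    agent's |PE| profile isolates the effect of reward variability itself:
    mean |PE| grows with the SD of the distribution (the task's manipulation
    check).
    """
    from .task import payoff as _payoff

    ordered = _check_sorted(design)
    out = ordered.copy()
    sums: dict[str, tuple[float, int]] = {}
    preds = np.empty(len(out))
    pes = np.empty(len(out))
    pays = np.empty(len(out))
    for i, row in enumerate(ordered.itertuples(index=False)):
        total, n = sums.get(row.dist_id, (0.0, 0))
        y = mu_init if n == 0 else total / n
        r = float(row.reward)
        preds[i] = y
        pes[i] = r - y
        pays[i] = _payoff(bool(row.is_control), y, r, float(row.ev),
                          float(row.sd))
        sums[row.dist_id] = (total + r, n + 1)
    out["prediction"] = preds
    out["pe"] = pes
    out["missed"] = False
    out["payoff"] = np.round(pays, 1)
    return out
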