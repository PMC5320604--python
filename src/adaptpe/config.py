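"""Study configuration: task design, cohort composition, fitting, analysis.

A :class:`StudyConfig` bundles everything needed to run a full synthetic
study: the task design, per-group cohort specifications (how many agents,
which learning model generates their behaviour and from which parameter
ranges, and the parameters of their ROI forward model), the fitting options,
and analysis settings.  Defaults reproduce the study conditions: three
groups (placebo, bromocriptine, sulpiride) of 19 agents each, 186 trials per
agent, with the sulpiride-like group assigned a higher probability of being
a non-scaler (nu = 0), a lower initial learning rate and weaker neural
adaptation.

Configs round-trip through YAML; validation collects every violated field
into a single error message.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from .models import FREE_PARAMS, MODEL_IDS, ModelParams
from .neural import NeuralGenParams
from .task import TaskConfig

__all__ = ["GroupSpec", "StudyConfig", "load_config", "save_config"]


@dataclass
class GroupSpec:
    """Generating regime of one treatment group.

    Learning parameters are drawn per agent, uniformly from ``[lo, hi]``
    ranges; ``p_nonscaler`` is the probability that an agent's nu is pinned
    to 0 (no PE scaling).  ``adaptation_strength`` gives the range of the
    neural 1/SD adaptation, and ``dose_to_scan`` the (mean, sd) in minutes
    of the nuisance covariate emulating the time between dosing and scan.
    """

    n: int = 19
    model_id: str = "PH2"
    k1: tuple[float, float] = (0.5, 0.9)
    gamma: tuple[float, float] = (0.1, 0.5)
    nu: tuple[float, float] = (0.5, 1.0)
    p_nonscaler: float = 0.1
    sigma: tuple[float, float] = (2.0, 5.0)
    k: tuple[float, float] = (0.3, 0.7)
    k_pos: tuple[float, float] = (0.3, 0.7)
    k_neg: tuple[float, float] = (0.3, 0.7)
    adaptation_strength: tuple[float, float] = (0.6, 1.0)
    neural_noise_sd: float = 2.0
    beta_pe_pos: float = 1.0
    beta_pe_neg: float = 1.2
    beta_value: float = 0.02
    dose_to_scan: tuple[float, float] = (167.0, 9.0)

    def validate(self, label: str) -> list[str]:
        errors = []
        if self.n < 1:
            errors.append(f"group {label}: n must be >= 1, got {self.n}")
        if self.model_id not in MODEL_IDS:
            errors.append(
                f"group {label}: unknown model_id {self.model_id!r}"
            )
        for name in ("k1", "gamma", "nu", "k", "k_pos", "k_neg"):
            lo, hi = getattr(self, name)
            if not 0 <= lo <= hi <= 1:
                errors.append(
                    f"group {label}: {name} range [{lo}, {hi}] invalid"
                )
        lo, hi = self.sigma
        if not 0 < lo <= hi:
            errors.append(f"group {label}: sigma range [{lo}, {hi}] invalid")
        if not 0 <= self.p_nonscaler <= 1:
            errors.append(
                f"group {label}: p_nonscaler must lie in [0, 1], got "
                f"{self.p_nonscaler}"
            )
        lo, hi = self.adaptation_strength
        if not 0 <= lo <= hi <= 1:
            errors.append(
                f"group {label}: adaptation_strength range [{lo}, {hi}] invalid"
            )
        if self.neural_noise_sd <= 0:
            errors.append(
                f"group {label}: neural_noise_sd must be positive"
            )
        if self.dose_to_scan[1] <= 0:
            errors.append(f"group {label}: dose_to_scan sd must be positive")
        return errors

    def draw_model_params(self, rng: np.random.Generator) -> ModelParams:
        """Draw one agent's generating learning parameters."""
        values = {}
        for name in FREE_PARAMS[self.model_id]:
            lo, hi = getattr(self, name)
            values[name] = float(rng.uniform(lo, hi))
        if self.model_id == "PH2" and rng.random() < self.p_nonscaler:
            values["nu"] = 0.0
        sigma = float(rng.uniform(*self.sigma))
        return ModelParams(model_id=self.model_id, sigma=sigma, **values)

    def draw_neural_params(self, rng: np.random.Generator) -> NeuralGenParams:
        """Draw one agent's ROI forward-model parameters."""
        return NeuralGenParams(
            beta0=0.0,
            beta_value=self.beta_value,
            beta_pe_pos=self.beta_pe_pos,
            beta_pe_neg=self.beta_pe_neg,
            noise_sd=self.neural_noise_sd,
            adaptation_strength=float(rng.uniform(*self.adaptation_strength)),
        )


def _default_groups() -> dict[str, GroupSpec]:
    return {
        "placebo": GroupSpec(),
        "bromocriptine": GroupSpec(
            p_nonscaler=0.15,
            adaptation_strength=(0.5, 0.9),
            dose_to_scan=(168.0, 9.0),
        ),
        "sulpiride": GroupSpec(
            k1=(0.3, 0.7),
            p_nonscaler=0.4,
            sigma=(3.0, 6.0),
            adaptation_strength=(0.0, 0.25),
            dose_to_scan=(161.0, 12.0),
        ),
    }


@dataclass
class StudyConfig:
    """Complete configuration of a synthetic study run."""

    task: TaskConfig = field(default_factory=TaskConfig)
    groups: dict[str, GroupSpec] = field(default_factory=_default_groups)
    control_group: str = "placebo"
    fit_models: tuple[str, ...] = MODEL_IDS
    n_restarts: int = 20
    scaler_epsilon: float = 1e-3
    posthoc_alpha: float = 0.025
    covariate: str = "dose_to_scan"

    def validate(self) -> None:
        errors = []
        try:
            self.task.validate()
        except ValueError as exc:
            errors.append(str(exc))
        if not self.groups:
            errors.append("at least one group is required")
        for label, spec in self.groups.items():
            errors.extend(spec.validate(label))
        if self.control_group not in self.groups:
            errors.append(
                f"control_group {self.control_group!r} is not a group"
            )
        unknown = [m for m in self.fit_models if m not in MODEL_IDS]
        if unknown:
            errors.append(f"unknown fit models: {unknown}")
        if self.n_restarts < 1:
            errors.append(f"n_restarts must be >= 1, got {self.n_restarts}")
        if not 0 <= self.scaler_epsilon < 1:
            errors.append(
                f"scaler_epsilon must lie in [0, 1), got {self.scaler_epsilon}"
            )
        if not 0 < self.posthoc_alpha < 1:
            errors.append(
                f"posthoc_alpha must lie in (0, 1), got {self.posthoc_alpha}"
            )
        if errors:
            raise ValueError("invalid study config:\n  - "
                             + "\n  - ".join(errors))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["fit_models"] = list(self.fit_models)
        return d


def _tuplify(obj):
    if isinstance(obj, list):
        return tuple(obj)
    return obj


def load_config(path) -> StudyConfig:
    """Load and validate a YAML study config; missing sections use defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw)}")
    task = TaskConfig(**{k: _tuplify(v)
                         for k, v in (raw.get("task") or {}).items()})
    groups_raw = raw.get("groups")
    if groups_raw is None:
        groups = _default_groups()
    else:
        groups = {
            label: GroupSpec(**{k: _tuplify(v) for k, v in (spec or {}).items()})
            for label, spec in groups_raw.items()
        }
    top = {k: _tuplify(v) for k, v in raw.items() if k not in ("task", "groups")}
    config = StudyConfig(task=task, groups=groups, **top)
    config.validate()
    return config


def save_config(config: StudyConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
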