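"""Adaptive prediction-error coding on trial-wise ROI-like signals.

A forward model generates a scalar response per reward outcome as baseline +
outcome-value effect + a PE effect whose slope depends on the SD condition
and the sign of the PE, plus Gaussian noise.  Under full adaptation the PE
slope is proportional to 1/SD — the signature of a system that rescales its
dynamic range to the spread of outcomes.  The analysis side estimates PE
slopes per SD x sign cell (with the PE regressor orthogonalised to outcome
value), combines them with mean-centred SD^-1 weights into a scalar
adaptive-coding contrast (positive when slopes fall with SD), and compares
contrasts across groups with rank-based tests.

Trial-level signals deliberately stand in for BOLD time series: no HRF
convolution or voxel-wise machinery — the inferential chain (slopes per
condition -> weighted contrast -> rank tests) operates at the ROI-summary
level where the group statistics live.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "NeuralGenParams",
    "NeuralSeries",
    "simulate_roi_responses",
    "estimate_pe_slopes",
    "contrast_weights",
    "adaptive_contrast",
    "group_adaptive_comparison",
]

#: Reference SD: the condition whose generating PE slope equals the base slope.
SD_REF = 5.0

#: Minimum trials in an SD x sign cell for a slope estimate.
MIN_CELL_TRIALS = 5


@dataclass
class NeuralGenParams:
    """Generating parameters of the ROI forward model.

    ``adaptation_strength`` in [0, 1] interpolates between SD-independent PE
    slopes (0) and slopes fully proportional to 1/SD (1):
    beta_pe(sd) = base * (1 + strength * (SD_REF / sd - 1)).
    ``beta_pe_pos``/``beta_pe_neg`` are the base slopes at the reference SD
    for positive and negative PEs (responses tend to differ by PE sign).
    """

    beta0: float = 0.0
    beta_value: float = 0.02
    beta_pe_pos: float = 1.0
    beta_pe_neg: float = 1.0
    noise_sd: float = 1.0
    adaptation_strength: float = 0.8

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError(f"noise_sd must be positive, got {self.noise_sd}")
        if not 0.0 <= self.adaptation_strength <= 1.0:
            raise ValueError(
                f"adaptation_strength must lie in [0, 1], got "
                f"{self.adaptation_strength}"
            )

    def pe_slope(self, sd: float, sign: str) -> float:
        base = self.beta_pe_pos if sign == "pos" else self.beta_pe_neg
        return base * (1.0 + self.adaptation_strength * (SD_REF / sd - 1.0))


@dataclass
class NeuralSeries:
    """Trial-wise ROI responses plus per-cell PE slopes and contrasts."""

    responses: pd.DataFrame  # columns: agent_id, session, trial, response
    slopes: pd.DataFrame | None = None  # index (sd, sign), column slope
    adaptive_contrast: float = math.nan
    adaptive_contrast_pos: float = math.nan
    meta: dict = field(default_factory=dict)


def _pe_sign(delta: float) -> str:
    # delta == 0 counts as positive: measure-zero under continuous noise but
    # the assignment must be deterministic.
    return "pos" if delta >= 0 else "neg"


def simulate_roi_responses(
    trials: pd.DataFrame,
    gen: NeuralGenParams,
    rng: np.random.Generator,
) -> NeuralSeries:
    """Simulate one agent's trial-wise ROI responses at reward outcome.

    response = beta0 + beta_value * reward + beta_pe(sd, sign) * pe + noise,
    for every non-missed trial with a PE.
    """
    ok = trials[~trials["missed"].astype(bool)].copy()
    ok = ok[~ok["pe"].isna()]
    if ok.empty:
        raise ValueError("trials contain no prediction errors")
    pe = ok["pe"].to_numpy(dtype=float)
    r = ok["reward"].to_numpy(dtype=float)
    sd = ok["sd"].to_numpy(dtype=float)
    slopes = np.array([
        gen.pe_slope(s, _pe_sign(d)) for s, d in zip(sd, pe)
    ])
    resp = (gen.beta0 + gen.beta_value * r + slopes * pe
            + rng.normal(0.0, gen.noise_sd, size=pe.size))
    frame = ok[["agent_id", "session", "trial"]].copy()
    frame["response"] = resp
    return NeuralSeries(responses=frame.reset_index(drop=True))


def estimate_pe_slopes(
    series: NeuralSeries,
    trials: pd.DataFrame,
    min_cell_trials: int = MIN_CELL_TRIALS,
) -> pd.DataFrame:
    """Least-squares PE coding slope per SD condition and PE sign.

    Within each cell the response is regressed on an intercept, the outcome
    value, and the PE serially orthogonalised with respect to outcome value
    (so the PE regressor only captures variance not attributable to reward
    magnitude).  Cells with fewer than ``min_cell_trials`` trials get a
    missing slope.  Returns a frame indexed by (sd, sign).
    """
    ok = trials[~trials["missed"].astype(bool)].copy()
    ok = ok[~ok["pe"].isna()]
    merged = ok.merge(series.responses, on=["agent_id", "session", "trial"],
                      validate="one_to_one")
    if len(merged) != len(series.responses):
        raise ValueError("responses do not align with trials")
    pe = merged["pe"].to_numpy(dtype=float)
    signs = np.where(pe >= 0, "pos", "neg")
    rows = []
    for sd in sorted(merged["sd"].unique()):
        for sign in ("pos", "neg"):
            cell = (merged["sd"].to_numpy() == sd) & (signs == sign)
            n = int(cell.sum())
            if n < min_cell_trials:
                rows.append({"sd": sd, "sign": sign, "slope": math.nan,
                             "n_trials": n})
                continue
            y = merged.loc[cell, "response"].to_numpy(dtype=float)
            value = merged.loc[cell, "reward"].to_numpy(dtype=float)
            delta = pe[cell]
            base = np.column_stack([np.ones(n), value])
            if np.linalg.matrix_rank(base) < 2:
                raise ValueError(
                    f"outcome value is constant in cell (sd={sd}, {sign})"
                )
            # Serial orthogonalization: residualize PE against [1, value].
            coefs, *_ = np.linalg.lstsq(base, delta, rcond=None)
            pe_orth = delta - base @ coefs
            if float(pe_orth @ pe_orth) < 1e-12:
                raise ValueError(
                    f"PE is collinear with outcome value in cell "
                    f"(sd={sd}, {sign})"
                )
            X = np.column_stack([base, pe_orth])
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            rows.append({"sd": sd, "sign": sign, "slope": float(beta[2]),
                         "n_trials": n})
    return pd.DataFrame(rows).set_index(["sd", "sign"])


def contrast_weights(sds) -> np.ndarray:
    """Mean-centred SD^-1 contrast weights, in ascending SD order.

    Each level is weighted by the inverse of its SD and the weights are
    centred to sum to zero, so equal slopes across SDs yield a contrast of
    exactly zero and slopes falling with SD yield a positive contrast.
    """
    sds = np.asarray(sorted(sds), dtype=float)
    if sds.size < 2 or np.unique(sds).size != sds.size:
        raise ValueError("need at least two distinct SDs")
    if (sds <= 0).any():
        raise ValueError("SDs must be positive")
    w = 1.0 / sds
    return w - w.mean()


def adaptive_contrast(
    slopes: pd.DataFrame,
    signs: str = "both",
    weights: np.ndarray | None = None,
) -> float:
    """SD^-1-weighted adaptive-coding contrast over the PE slopes.

    ``signs`` selects which slopes enter: "both" averages the positive- and
    negative-PE slope within each SD, "pos"/"neg" use a single sign.  Raises
    if a required cell is missing.
    """
    if signs not in ("both", "pos", "neg"):
        raise ValueError(f"signs must be both|pos|neg, got {signs!r}")
    sds = sorted(slopes.index.get_level_values("sd").unique())
    if weights is None:
        weights = contrast_weights(sds)
    if len(weights) != len(sds):
        raise ValueError("weights do not match the number of SD levels")
    per_sd = []
    for sd in sds:
        if signs == "both":
            vals = [slopes.loc[(sd, s), "slope"] for s in ("pos", "neg")]
        else:
            vals = [slopes.loc[(sd, signs), "slope"]]
        if any(math.isnan(v) for v in vals):
            raise ValueError(f"missing slope in SD={sd:g} cell(s)")
        per_sd.append(float(np.mean(vals)))
    return float(np.dot(weights, per_sd))


def group_adaptive_comparison(
    contrasts,
    groups,
    control: str = "placebo",
    posthoc_alpha: float = 0.025,
) -> dict:
    """Rank-based group comparison of adaptive-coding contrasts.

    Kruskal-Wallis omnibus across groups, Wilcoxon rank-sum post hocs
    restricted to control vs each treatment group (alpha 0.025), plus a
    one-sided within-group sign-rank test that the control group's contrast
    exceeds zero (i.e. that adaptive coding is present at all under
    control conditions).  Pass residualised contrasts when a nuisance
    covariate applies.
    """
    contrasts = np.asarray(contrasts, dtype=float)
    groups = np.asarray(groups)
    labels = list(pd.unique(groups))
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    samples = {g: contrasts[groups == g] for g in labels}
    for g, v in samples.items():
        if v.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 members")
    if control not in samples:
        raise ValueError(f"control group {control!r} not present")

    stat, p = stats.kruskal(*samples.values())
    posthoc = []
    for g in labels:
        if g == control:
            continue
        z, pp = stats.ranksums(samples[control], samples[g])
        posthoc.append({"comparison": f"{control} vs {g}",
                        "test": "rank-sum", "statistic": float(z),
                        "p": float(pp),
                        "significant": bool(pp < posthoc_alpha)})
    w_stat, w_p = stats.wilcoxon(samples[control], alternative="greater")
    return {
        "omnibus": {"test": "Kruskal-Wallis", "statistic": float(stat),
                    "p": float(p)},
        "posthoc": posthoc,
        "posthoc_alpha": posthoc_alpha,
        "control_positive": {"test": "signed-rank (one-sided > 0)",
                             "statistic": float(w_stat), "p": float(w_p)},
    }
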