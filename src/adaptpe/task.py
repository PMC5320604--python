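"""Generative model of the reward-magnitude prediction task.

Participants (or simulated agents) predict, on every trial, the magnitude of
an upcoming reward drawn from one of six pseudo-Gaussian distributions that
cross a standard deviation of £5, £10 or £15 with an expected value of £35 or
£65.  An experiment consists of three sessions; each session interleaves two
of the six distributions ("pots") in short blocks of 4-6 trials, and the two
pots of a session always differ in *both* EV and SD.  Each distribution
contributes exactly 31 trials.  One fifth of the trials are control trials
paid by prediction accuracy rather than by the drawn reward, which keeps the
stated prediction incentive-compatible.

"Pseudo-Gaussian" is operationalised as moment-matched sampling: rewards are
drawn from a Gaussian truncated to the £0-£100 response scale and affinely
rescaled so that the realised sample mean and SD match the nominal EV and SD
(to within ±£0.5 after clipping and rounding to £0.1).  Every simulated agent
therefore faces the nominal reward statistics, which the downstream
behavioural metrics assume.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RewardDistribution",
    "SessionPlan",
    "TaskConfig",
    "make_distribution_set",
    "enumerate_pairings",
    "pair_sessions",
    "sample_rewards",
    "assign_control_trials",
    "control_payoff",
    "test_payoff",
    "payoff",
    "generate_experiment",
    "TRIAL_COLUMNS",
]

#: Canonical column order of a trial table.
TRIAL_COLUMNS = [
    "agent_id", "session", "block", "trial", "dist_id", "ev", "sd",
    "cue_level", "is_control", "reward", "prediction", "missed", "pe",
    "payoff",
]

_CUE_NAMES = ["small", "medium", "large"]


@dataclass(frozen=True)
class RewardDistribution:
    """One task reward distribution: a (EV, SD) pair with its variability cue.

    The cue signals only the *relative* spread (small/medium/large), never
    the EV, mirroring the task's bar cues.
    """

    id: str
    ev: float
    sd: float
    cue_level: str

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError(f"sd must be positive, got {self.sd}")
        if not 0 <= self.ev <= 100:
            raise ValueError(f"ev must lie in [0, 100], got {self.ev}")


@dataclass
class SessionPlan:
    """Blocked trial schedule for one session interleaving two pots."""

    session_index: int
    distributions: tuple[RewardDistribution, RewardDistribution]
    block_lengths: list[int] = field(default_factory=list)
    trial_order: list[str] = field(default_factory=list)

    @property
    def n_trials(self) -> int:
        return len(self.trial_order)


@dataclass
class TaskConfig:
    """Design parameters of a full experiment.

    Defaults reproduce the study design: SDs {5, 10, 15} crossed with EVs
    {35, 65}, 31 trials per distribution, blocks of 4-6 trials and a 20%
    control-trial fraction.
    """

    sds: tuple[float, ...] = (5.0, 10.0, 15.0)
    evs: tuple[float, ...] = (35.0, 65.0)
    trials_per_distribution: int = 31
    block_min: int = 4
    block_max: int = 6
    control_fraction: float = 0.20
    miss_probability: float = 0.0

    def validate(self) -> None:
        errors = []
        if len(set(self.sds)) != len(self.sds) or any(s <= 0 for s in self.sds):
            errors.append(f"sds must be distinct and positive, got {self.sds}")
        if len(set(self.evs)) != len(self.evs) or any(
            not 0 <= e <= 100 for e in self.evs
        ):
            errors.append(f"evs must be distinct and within [0, 100], got {self.evs}")
        if self.trials_per_distribution < 2:
            errors.append(
                "trials_per_distribution must be >= 2, got "
                f"{self.trials_per_distribution}"
            )
        if not 2 <= self.block_min <= self.block_max:
            errors.append(
                f"block range invalid: [{self.block_min}, {self.block_max}]"
            )
        if not 0 <= self.control_fraction < 1:
            errors.append(
                f"control_fraction must lie in [0, 1), got {self.control_fraction}"
            )
        if not 0 <= self.miss_probability < 1:
            errors.append(
                f"miss_probability must lie in [0, 1), got {self.miss_probability}"
            )
        if len(self.sds) * len(self.evs) % 2:
            errors.append("the number of distributions must be even to pair sessions")
        if errors:
            raise ValueError("invalid task config: " + "; ".join(errors))


def make_distribution_set(
    evs: tuple[float, ...] = (35.0, 65.0),
    sds: tuple[float, ...] = (5.0, 10.0, 15.0),
) -> list[RewardDistribution]:
    """Return all EV x SD reward distributions, cue level ranked by SD."""
    ranks = {sd: i for i, sd in enumerate(sorted(set(sds)))}
    if len(ranks) > len(_CUE_NAMES):
        raise ValueError(f"at most {len(_CUE_NAMES)} SD levels supported")
    return [
        RewardDistribution(
            id=f"EV{ev:g}-SD{sd:g}", ev=float(ev), sd=float(sd),
            cue_level=_CUE_NAMES[ranks[sd]],
        )
        for ev in evs
        for sd in sds
    ]


def _differs_in_both(a: RewardDistribution, b: RewardDistribution) -> bool:
    return a.ev != b.ev and a.sd != b.sd


def enumerate_pairings(
    distributions: list[RewardDistribution],
) -> list[tuple[tuple[RewardDistribution, RewardDistribution], ...]]:
    """All perfect matchings of the distributions into sessions such that the
    two pots of every session differ in both EV and SD.

    Used both by the sampler and as a brute-force oracle in tests.
    """
    dists = sorted(distributions, key=lambda d: d.id)

    def _match(remaining: tuple[RewardDistribution, ...]):
        if not remaining:
            yield ()
            return
        first, rest = remaining[0], remaining[1:]
        for j, other in enumerate(rest):
            if _differs_in_both(first, other):
                for tail in _match(rest[:j] + rest[j + 1:]):
                    yield ((first, other),) + tail

    return list(_match(tuple(dists)))


def pair_sessions(
    distributions: list[RewardDistribution], rng: np.random.Generator
) -> list[SessionPlan]:
    """Draw a session pairing uniformly from the valid perfect matchings.

    Every distribution is used in exactly one session and the two pots of a
    session differ in both EV and SD.  Session order and within-pair order
    are themselves randomised.
    """
    matchings = enumerate_pairings(distributions)
    assert matchings, "full distribution set always admits a valid pairing"
    pairs = list(matchings[rng.integers(len(matchings))])
    rng.shuffle(pairs)
    plans = []
    for i, (a, b) in enumerate(pairs, start=1):
        pair = (a, b) if rng.random() < 0.5 else (b, a)
        plans.append(SessionPlan(session_index=i, distributions=pair))
    return plans


def sample_rewards(
    dist: RewardDistribution,
    n: int,
    rng: np.random.Generator,
    lo: float = 0.0,
    hi: float = 100.0,
    tol: float = 0.5,
    max_tries: int = 200,
) -> np.ndarray:
    """Draw ``n`` moment-matched pseudo-Gaussian rewards on [lo, hi].

    Values are drawn from a Gaussian truncated to the response scale and
    affinely rescaled so that the sample mean equals ``dist.ev`` and the
    sample SD (ddof=1) equals ``dist.sd``; clipping and rounding to £0.1 may
    perturb the moments, so the draw is repeated until both land within
    ``tol``.  Order is random.
    """
    if n < 2:
        raise ValueError("need n >= 2 to match mean and SD")
    ev, sd = dist.ev, dist.sd
    for _ in range(max_tries):
        x = rng.normal(ev, sd, size=n)
        np.clip(x, lo, hi, out=x)
        # Alternate rescale-to-moments / clip; converges in a few passes.
        for _ in range(25):
            s = x.std(ddof=1)
            if s == 0:
                break
            x = (x - x.mean()) * (sd / s) + ev
            if x.min() >= lo and x.max() <= hi:
                break
            np.clip(x, lo, hi, out=x)
        x = np.round(np.clip(x, lo, hi), 1)
        if abs(x.mean() - ev) <= tol and abs(x.std(ddof=1) - sd) <= tol:
            return x
    raise RuntimeError(
        f"could not moment-match n={n} rewards to (EV={ev}, SD={sd}) "
        f"within [{lo}, {hi}]"
    )


def assign_control_trials(
    n_trials: int, fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """Boolean mask with exactly round(fraction * n) pseudo-random controls."""
    if not 0 <= fraction < 1:
        raise ValueError(f"fraction must lie in [0, 1), got {fraction}")
    n_control = int(round(fraction * n_trials))
    mask = np.zeros(n_trials, dtype=bool)
    if n_control:
        mask[rng.choice(n_trials, size=n_control, replace=False)] = True
    return mask


def control_payoff(prediction: float, ev: float, sd: float) -> float:
    """Pay-off on a control trial, graded by prediction accuracy.

    £7.50 within one SD of the EV, £5.00 within two SDs, £2.50 otherwise;
    a missed prediction pays nothing.
    """
    if prediction is None or (isinstance(prediction, float) and np.isnan(prediction)):
        return 0.0
    dist = abs(prediction - ev)
    if dist <= sd:
        return 7.50
    if dist <= 2 * sd:
        return 5.00
    return 2.50


def test_payoff(reward: float) -> float:
    """Pay-off on a test trial: 10% of the drawn reward."""
    if reward is None or (isinstance(reward, float) and np.isnan(reward)):
        return 0.0
    return 0.10 * reward


def payoff(
    is_control: bool, prediction: float, reward: float, ev: float, sd: float
) -> float:
    if is_control:
        return control_payoff(prediction, ev, sd)
    return test_payoff(reward)


def _schedule_blocks(
    plan: SessionPlan,
    trials_per_distribution: int,
    block_min: int,
    block_max: int,
    rng: np.random.Generator,
) -> None:
    """Fill a session plan with alternating blocks of 4-6 trials.

    The two pots alternate block-by-block; each block length is drawn
    uniformly from the feasible subset of [block_min, block_max] — feasible
    meaning the pot's remaining trials can still be partitioned into blocks
    within the range — so every block, including the last of each pot, stays
    in range while each pot totals exactly ``trials_per_distribution``.
    """
    if trials_per_distribution < block_min:
        raise ValueError(
            f"trials_per_distribution={trials_per_distribution} below the "
            f"minimum block length {block_min}"
        )
    remaining = {d.id: trials_per_distribution for d in plan.distributions}
    current = plan.distributions[int(rng.integers(2))].id
    other = {plan.distributions[0].id: plan.distributions[1].id,
             plan.distributions[1].id: plan.distributions[0].id}
    order: list[str] = []
    lengths: list[int] = []
    while any(remaining.values()):
        if remaining[current] == 0:
            current = other[current]
        left = remaining[current]

        def _partitionable(m: int) -> bool:
            # m splits into blocks within [block_min, block_max] iff some
            # block count k satisfies k*block_min <= m <= k*block_max.
            if m == 0:
                return True
            k = -(-m // block_max)  # smallest candidate count
            return k * block_min <= m

        feasible = [
            n for n in range(block_min, block_max + 1)
            if n <= left and _partitionable(left - n)
        ]
        assert feasible, f"no feasible block length for {left} remaining"
        length = int(rng.choice(feasible))
        order.extend([current] * length)
        lengths.append(length)
        remaining[current] -= length
        if remaining[other[current]] > 0:
            current = other[current]
    plan.block_lengths = lengths
    plan.trial_order = order


def generate_experiment(
    config: TaskConfig | None = None,
    seed: int | np.random.SeedSequence | None = None,
    agent_id: str = "agent0",
) -> pd.DataFrame:
    """Generate the design of one full experiment (predictions left empty).

    Returns a long-format trial table, one row per trial, with design columns
    filled in and ``prediction``/``pe`` missing; rewards are moment-matched
    per distribution.  Deterministic given ``seed``.
    """
    config = config or TaskConfig()
    config.validate()
    rng = np.random.default_rng(seed)

    dists = make_distribution_set(config.evs, config.sds)
    by_id = {d.id: d for d in dists}
    plans = pair_sessions(dists, rng)
    for plan in plans:
        _schedule_blocks(plan, config.trials_per_distribution,
                         config.block_min, config.block_max, rng)

    rewards = {
        d.id: list(sample_rewards(d, config.trials_per_distribution, rng))
        for d in dists
    }

    rows = []
    for plan in plans:
        control = assign_control_trials(plan.n_trials,
                                        config.control_fraction, rng)
        block_of = np.repeat(
            np.arange(1, len(plan.block_lengths) + 1), plan.block_lengths
        )
        for t, dist_id in enumerate(plan.trial_order):
            d = by_id[dist_id]
            rows.append({
                "agent_id": agent_id,
                "session": plan.session_index,
                "block": int(block_of[t]),
                "trial": t + 1,
                "dist_id": d.id,
                "ev": d.ev,
                "sd": d.sd,
                "cue_level": d.cue_level,
                "is_control": bool(control[t]),
                "reward": rewards[dist_id].pop(0),
                "prediction": np.nan,
                "missed": False,
                "pe": np.nan,
                "payoff": np.nan,
            })
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)
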