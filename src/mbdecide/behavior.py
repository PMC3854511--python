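"""Mapping learned transition probabilities to observable behavior.

Reaction times on sequential trials are modeled as a linear function of the
model's conditional probability of the displayed image (faster when more
expected), plus nuisance effects for stimulus-self transitions, image
identity, and a linear trend over trials, with Gaussian noise.

Choices between two candidate start images are modeled by a sampling rule:
the decision variable is the difference between the sample proportions of
N binomial draws around each option's learned probability of leading to the
goal image. Under a Gaussian approximation to the two binomials the
probability of choosing option a is Phi(mean / sqrt(variance)). An exact
enumeration over all draw outcomes (ties split evenly) serves as the oracle
for that approximation, and a softmax over expected values is available as an
alternative rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import binom, norm

from . import learning
from .learning import LearnerParams, TransitionStream, extract_stream
from .task import N_IMAGES, SessionLog

__all__ = [
    "RTModelParams",
    "ChoiceModelParams",
    "BehaviorData",
    "choice_prob_sampling",
    "choice_prob_exact",
    "choice_prob_softmax",
    "decision_variable",
    "rt_design",
    "rt_loglik",
    "simulate_behavior",
    "ModelChooser",
]

RIGHT_HAND_IMAGES = (2, 3)  # fixed image->hand mapping: images 2,3 answered right-handed

MIN_VALID_TRIALS = 10
_SIGMA_FLOOR = 1e-6


@dataclass(frozen=True)
class RTModelParams:
    """Linear RT model: intercept + slope * P(observed) + nuisance terms (ms)."""

    intercept: float = 650.0
    slope_prob: float = -44.0  # ms per unit conditional probability
    coef_self: float = -30.0
    coefs_image: tuple[float, float, float, float] = (0.0, 8.0, -6.0, 12.0)
    coef_trial: float = -0.02  # ms per sequential trial
    noise_sd: float = 15.0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


@dataclass(frozen=True)
class ChoiceModelParams:
    """Choice rule and its parameters; exactly one rule is active."""

    rule: str = "sampling"  # "sampling" | "softmax"
    n_draws: float = 4.675  # average number of binomial draws (may be non-integer)
    softmax_beta: float = 3.0  # inverse temperature on expected dollar value

    def __post_init__(self) -> None:
        if self.rule not in ("sampling", "softmax"):
            raise ValueError("rule must be 'sampling' or 'softmax'")
        if self.rule == "sampling" and self.n_draws <= 0:
            raise ValueError("n_draws must be positive")
        if self.rule == "softmax" and self.softmax_beta < 0:
            raise ValueError("softmax_beta must be nonnegative")

    def prob_choose_a(self, p_a: float, p_b: float, value: float) -> float:
        if self.rule == "sampling":
            return choice_prob_sampling(p_a, p_b, self.n_draws)
        return choice_prob_softmax(p_a, p_b, value, self.softmax_beta)


def decision_variable(p_a, p_b, n_draws: float):
    """Mean and variance of the difference in binomial sample proportions."""
    p_a = np.asarray(p_a, dtype=float)
    p_b = np.asarray(p_b, dtype=float)
    mean = p_a - p_b
    var = (p_a * (1.0 - p_a) + p_b * (1.0 - p_b)) / n_draws
    return mean, var


def choice_prob_sampling(p_a, p_b, n_draws: float):
    """P(choose a) under the Gaussian approximation to the two binomials.

    Returns exactly 0.5 when the means tie; collapses to a 0/1 step when both
    probabilities are degenerate (zero sampling variance).
    """
    if n_draws <= 0:
        raise ValueError("n_draws must be positive")
    mean, var = decision_variable(p_a, p_b, n_draws)
    scalar = np.ndim(mean) == 0
    mean = np.atleast_1d(mean)
    var = np.atleast_1d(var)
    out = np.full(mean.shape, 0.5)
    pos = var > 0
    out[pos] = norm.cdf(mean[pos] / np.sqrt(var[pos]))
    deg = ~pos & (mean != 0)
    out[deg] = np.where(mean[deg] > 0, 1.0, 0.0)
    return float(out[0]) if scalar else out


def choice_prob_exact(p_a: float, p_b: float, n_draws: int) -> float:
    """Enumeration oracle: P(choose a) from all (k_a, k_b) binomial outcome pairs.

    Option a is chosen when its success count is strictly larger; ties count
    one half. Requires an integer number of draws.
    """
    if not float(n_draws).is_integer() or not (1 <= int(n_draws) <= 50):
        raise ValueError("the enumeration oracle needs an integer n_draws in [1, 50]")
    n = int(n_draws)
    k = np.arange(n + 1)
    wa = binom.pmf(k, n, p_a)
    wb = binom.pmf(k, n, p_b)
    joint = np.outer(wa, wb)
    gt = np.tril(np.ones((n + 1, n + 1)), k=-1)  # k_a > k_b
    return float((joint * gt).sum() + 0.5 * np.trace(joint))


def choice_prob_softmax(p_a, p_b, value: float, beta: float):
    """Softmax over expected values: logistic(beta * value * (p_a - p_b))."""
    if beta < 0:
        raise ValueError("beta must be nonnegative")
    return expit(beta * float(value) * (np.asarray(p_a, float) - np.asarray(p_b, float)))


# --- behavioral dataset -------------------------------------------------------

@dataclass
class BehaviorData:
    """Simulated behavior: per-sequential-trial RTs and per-probe choice records."""

    trials: pd.DataFrame
    choices: pd.DataFrame
    stream: TransitionStream
    learner: LearnerParams

    @property
    def n_valid_trials(self) -> int:
        return int((self.trials.correct & ~self.trials.missed).sum())

    def write(self, trials_path, choices_path) -> None:
        self.trials.to_csv(trials_path, sep="\t", index=False, float_format="%.6f")
        self.choices.to_csv(choices_path, sep="\t", index=False, float_format="%.6f")


def rt_design(
    stream: TransitionStream, p_observed: np.ndarray, include_prob: bool = True
) -> np.ndarray:
    """Design matrix of the RT regression (columns match RTModelParams order).

    Columns: intercept, [P(observed)], self-transition flag, image-identity
    contrasts for images 1..3 (image 0 absorbed by the intercept), trial index.
    """
    n = stream.n_trials
    cols = [np.ones(n)]
    if include_prob:
        cols.append(np.asarray(p_observed, dtype=float))
    cols.append(stream.is_self.astype(float))
    for img in range(1, N_IMAGES):
        cols.append((stream.obs == img).astype(float))
    cols.append(np.arange(n, dtype=float))
    return np.column_stack(cols)


def rt_loglik(
    rts: np.ndarray,
    valid: np.ndarray,
    design: np.ndarray,
    coefs: np.ndarray,
    noise_sd: float,
) -> float:
    """Gaussian log-likelihood of observed RTs on valid trials."""
    if valid.sum() < MIN_VALID_TRIALS:
        raise ValueError(f"need at least {MIN_VALID_TRIALS} valid trials")
    sd = max(float(noise_sd), _SIGMA_FLOOR)
    resid = rts[valid] - design[valid] @ coefs
    n = resid.size
    return float(-0.5 * n * np.log(2.0 * np.pi * sd**2) - 0.5 * (resid**2).sum() / sd**2)


def _rt_mean(stream: TransitionStream, p_observed: np.ndarray, params: RTModelParams) -> np.ndarray:
    coefs = np.array(
        [params.intercept, params.slope_prob, params.coef_self]
        + list(params.coefs_image[1:])
        + [params.coef_trial]
    )
    return rt_design(stream, p_observed) @ coefs + params.coefs_image[0]


def simulate_behavior(
    sessions: Sequence[SessionLog],
    learner: LearnerParams,
    rt: RTModelParams,
    choice: ChoiceModelParams,
    rng: np.random.Generator,
    error_rate: float = 0.03,
    miss_rate: float = 0.01,
    choice_miss_rate: float = 0.02,
    resample_choices: bool = False,
) -> BehaviorData:
    """Simulate RTs and choices for an assembled task.

    RTs are Gaussian around the linear model evaluated on the two-process
    combined probability trace; a small fraction of trials are marked as
    errors or misses. Choices are taken from the session record when present
    (they then drove the outcome images at assembly time); with
    ``resample_choices=True`` they are re-drawn from the slow process and the
    active choice rule instead.
    """
    stream = extract_stream(sessions)
    trace = learning.trace_learning(stream, learner)
    n = stream.n_trials

    rts = _rt_mean(stream, trace.p_observed, rt) + rng.normal(0.0, rt.noise_sd, size=n)
    rts = np.maximum(rts, 150.0)  # physiological floor on first-keypress times
    correct = rng.random(n) >= error_rate
    missed = rng.random(n) < miss_rate

    trials = pd.DataFrame(
        {
            "session": stream.session,
            "onset": stream.onset,
            "prev_image": stream.prev,
            "image": stream.obs,
            "is_self": stream.is_self,
            "is_outcome": stream.is_outcome,
            "is_probe_round": stream.is_probe_round,
            "reward_shown": stream.reward_shown,
            "rt": rts,
            "correct": correct,
            "missed": missed,
        }
    )

    # choice records: p_a/p_b under the slow process (the rate that drives choice)
    pg = trace.slow.probe_p_goal
    p_a = pg[np.arange(stream.n_probes), stream.probe_a]
    p_b = pg[np.arange(stream.n_probes), stream.probe_b]
    p_choose_a = np.array(
        [
            choice.prob_choose_a(p_a[k], p_b[k], stream.probe_value[k])
            for k in range(stream.n_probes)
        ]
    )
    if resample_choices or np.any(stream.probe_chosen < 0):
        chose_a = rng.random(stream.n_probes) < p_choose_a
        chosen_img = np.where(chose_a, stream.probe_a, stream.probe_b)
    else:
        chosen_img = stream.probe_chosen
        chose_a = chosen_img == stream.probe_a
    outcome_img = stream.obs[stream.probe_pos]
    choices = pd.DataFrame(
        {
            "session": stream.probe_session,
            "option_a": stream.probe_a,
            "option_b": stream.probe_b,
            "goal": stream.probe_goal,
            "value": stream.probe_value,
            "chose_a": chose_a,
            "chosen_image": chosen_img,
            "outcome_image": outcome_img,
            "outcome_is_goal": outcome_img == stream.probe_goal,
            "missed": rng.random(stream.n_probes) < choice_miss_rate,
            "rt": rng.uniform(800.0, 3000.0, size=stream.n_probes),  # choice RTs (nuisance)
            "reward_onset": stream.probe_reward_onset,
            "choice_onset": stream.probe_choice_onset,
        }
    )
    return BehaviorData(trials=trials, choices=choices, stream=stream, learner=learner)


class ModelChooser:
    """Chooser driven by a single delta-rule process and a choice rule.

    Plugged into task assembly so that simulated choices and the outcome images
    they trigger are generated from one consistent belief trajectory. Uses the
    slow process only, matching the finding that choices are explained by a
    single slow learning rate.
    """

    def __init__(self, alpha: float, choice_params: ChoiceModelParams):
        if not (0.0 < alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        self.alpha = float(alpha)
        self.choice_params = choice_params
        self.belief = np.full((N_IMAGES, N_IMAGES), 1.0 / N_IMAGES)

    def observe(self, prev_image: int, image: int) -> None:
        row = self.belief[prev_image]
        row *= 1.0 - self.alpha
        row[image] += self.alpha

    def choose(self, option_a: int, option_b: int, goal: int, value: int, rng) -> int:
        p_a = self.belief[option_a, goal]
        p_b = self.belief[option_b, goal]
        p = self.choice_params.prob_choose_a(p_a, p_b, value)
        return 0 if rng.random() < p else 1
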