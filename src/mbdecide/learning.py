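"""Incremental transition learning and the decision variables derived from it.

Two independent delta-rule (Rescorla-Wagner) processes each maintain a 4x4
estimate of the image transition matrix. After observing a transition i -> j,
the row for image i moves a fraction ``alpha`` of the way toward the indicator
of j, which preserves row normalization exactly:

    T[i, :] <- (1 - alpha) * T[i, :] + alpha * onehot(j)

The behaviorally expressed conditional probability is a weighted average of
the two processes' predictions. From the learned matrix we derive, per trial:
the probability of the observed image given its predecessor, the 4-vector of
next-image probabilities, the forward entropy of that prediction, and — for
the Taylor-expansion estimator — exact partial derivatives of each quantity
with respect to the inverse-sigmoid-transformed learning rate, computed by a
parallel recursion through time (chain rule through the logistic map).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from numba import njit
from scipy.special import expit, logit

from .task import N_IMAGES, SEQUENTIAL, SessionLog

__all__ = [
    "LearnerParams",
    "BeliefState",
    "TransitionStream",
    "ProcessTrace",
    "LearningTrace",
    "sigmoid",
    "inv_sigmoid",
    "rw_update",
    "combined_prediction",
    "forward_entropy",
    "choice_difficulty",
    "per_category_difficulty",
    "reward_prediction_error",
    "extract_stream",
    "ground_truth_p_observed",
    "run_process",
    "trace_learning",
]

sigmoid = expit
inv_sigmoid = logit


@dataclass(frozen=True)
class LearnerParams:
    """Learning rates of the fast and slow processes and the weight on the slow one.

    ``w_slow`` is the mixing proportion applied to the slow process; a single-
    process learner is the degenerate case ``alpha_fast == alpha_slow``.
    """

    alpha_fast: float
    alpha_slow: float
    w_slow: float = 1.0

    def __post_init__(self) -> None:
        for a in (self.alpha_fast, self.alpha_slow):
            if not (0.0 < a < 1.0):
                raise ValueError("learning rates must lie in (0, 1)")
        if not (0.0 <= self.w_slow <= 1.0):
            raise ValueError("w_slow must lie in [0, 1]")
        if self.alpha_slow > self.alpha_fast:
            raise ValueError("alpha_slow must not exceed alpha_fast")

    @classmethod
    def single(cls, alpha: float) -> "LearnerParams":
        return cls(alpha_fast=alpha, alpha_slow=alpha, w_slow=1.0)

    @property
    def is_single(self) -> bool:
        return self.alpha_fast == self.alpha_slow


@dataclass
class BeliefState:
    """Current transition-matrix estimates of the two processes."""

    t_fast: np.ndarray
    t_slow: np.ndarray
    trial_index: int = 0

    @classmethod
    def uniform(cls) -> "BeliefState":
        return cls(
            t_fast=np.full((N_IMAGES, N_IMAGES), 1.0 / N_IMAGES),
            t_slow=np.full((N_IMAGES, N_IMAGES), 1.0 / N_IMAGES),
        )


def rw_update(belief_row: np.ndarray, observed: int, alpha: float) -> np.ndarray:
    """Delta-rule update of one conditional distribution toward the observed image."""
    row = np.asarray(belief_row, dtype=float)
    if not np.isclose(row.sum(), 1.0, atol=1e-9):
        raise ValueError("belief row must sum to 1")
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must lie in [0, 1]")
    onehot = np.zeros_like(row)
    onehot[observed] = 1.0
    return (1.0 - alpha) * row + alpha * onehot


def combined_prediction(state: BeliefState, params: LearnerParams, current: int) -> np.ndarray:
    """Weighted average of the two processes' next-image predictions."""
    return params.w_slow * state.t_slow[current] + (1.0 - params.w_slow) * state.t_fast[current]


def forward_entropy(p: np.ndarray) -> float:
    """Shannon entropy (nats) of a next-image distribution, with 0 ln 0 = 0."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValueError("probabilities must be nonnegative")
    if not np.isclose(p.sum(), 1.0, atol=1e-9):
        raise ValueError("probabilities must sum to 1")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def choice_difficulty(p_a: float, p_b: float, n_draws: float) -> float:
    """Variance of the decision variable: sum of binomial sample-proportion variances."""
    if n_draws <= 0:
        raise ValueError("n_draws must be positive")
    return (p_a * (1.0 - p_a) + p_b * (1.0 - p_b)) / n_draws


def per_category_difficulty(p: float, n_draws: float) -> float:
    """Sampling variance of a single category's goal-transition probability."""
    if n_draws <= 0:
        raise ValueError("n_draws must be positive")
    return p * (1.0 - p) / n_draws


def reward_prediction_error(outcome_is_goal: bool, value: float, p_chosen_to_goal: float) -> float:
    """Reward received minus the expected value of the chosen image (dollars)."""
    received = float(value) if outcome_is_goal else 0.0
    return received - p_chosen_to_goal * float(value)


# --- transition stream --------------------------------------------------------

@dataclass
class TransitionStream:
    """Flattened learning observations across sessions, aligned with probe queries.

    One entry per sequential trial: the predecessor context (previous image, or
    the chosen image on outcome trials) and the observed image. Probe queries
    index the transition at which each choice's outcome occurs; the belief used
    for the choice is the state just before that transition is observed.
    """

    prev: np.ndarray
    obs: np.ndarray
    onset: np.ndarray
    session: np.ndarray
    is_outcome: np.ndarray
    is_probe_round: np.ndarray
    reward_shown: np.ndarray
    # probe arrays (one entry per choice round, in stream order)
    probe_pos: np.ndarray
    probe_a: np.ndarray
    probe_b: np.ndarray
    probe_goal: np.ndarray
    probe_chosen: np.ndarray
    probe_value: np.ndarray
    probe_session: np.ndarray
    probe_reward_onset: np.ndarray
    probe_choice_onset: np.ndarray

    @property
    def n_trials(self) -> int:
        return int(self.prev.shape[0])

    @property
    def n_probes(self) -> int:
        return int(self.probe_pos.shape[0])

    @property
    def is_self(self) -> np.ndarray:
        return self.prev == self.obs


def extract_stream(sessions: Sequence[SessionLog]) -> TransitionStream:
    """Build the transition stream (and probe queries) from generated sessions."""
    prev, obs, onset, sess, is_out, in_round, reward = [], [], [], [], [], [], []
    p_pos, p_a, p_b, p_goal, p_chosen, p_val, p_sess, p_ron, p_con = (
        [], [], [], [], [], [], [], [], [],
    )
    t = 0
    for log in sessions:
        cur = log.start_image
        for e in log.events:
            if e.kind == SEQUENTIAL:
                if e.is_outcome:
                    probe = log.probes[e.probe_index]
                    if probe.chosen_image is None:
                        raise ValueError("session probes carry no recorded choices")
                    context = probe.chosen_image
                    p_pos.append(t)
                    p_a.append(probe.option_a)
                    p_b.append(probe.option_b)
                    p_goal.append(probe.rewarded_image)
                    p_chosen.append(probe.chosen_image)
                    p_val.append(probe.value)
                    p_sess.append(log.session_index)
                    p_ron.append(probe.reward_onset)
                    p_con.append(probe.choice_onset)
                else:
                    context = cur
                prev.append(context)
                obs.append(e.image)
                onset.append(e.onset)
                sess.append(log.session_index)
                is_out.append(e.is_outcome)
                in_round.append(e.is_probe_round)
                reward.append(e.reward_shown)
                cur = e.image
                t += 1
    return TransitionStream(
        prev=np.array(prev, dtype=np.int64),
        obs=np.array(obs, dtype=np.int64),
        onset=np.array(onset, dtype=float),
        session=np.array(sess, dtype=np.int64),
        is_outcome=np.array(is_out, dtype=bool),
        is_probe_round=np.array(in_round, dtype=bool),
        reward_shown=np.array(reward, dtype=np.int64),
        probe_pos=np.array(p_pos, dtype=np.int64),
        probe_a=np.array(p_a, dtype=np.int64),
        probe_b=np.array(p_b, dtype=np.int64),
        probe_goal=np.array(p_goal, dtype=np.int64),
        probe_chosen=np.array(p_chosen, dtype=np.int64),
        probe_value=np.array(p_val, dtype=np.int64),
        probe_session=np.array(p_sess, dtype=np.int64),
        probe_reward_onset=np.array(p_ron, dtype=float),
        probe_choice_onset=np.array(p_con, dtype=float),
    )


def ground_truth_p_observed(sessions: Sequence[SessionLog]) -> np.ndarray:
    """Programmed conditional probability of each observed sequential image.

    Aligned with :func:`extract_stream`; the context on outcome trials is the
    chosen image, as in the generative process.
    """
    out = []
    for log in sessions:
        cur = log.start_image
        for e in log.events:
            if e.kind == SEQUENTIAL:
                if e.is_outcome:
                    context = log.probes[e.probe_index].chosen_image
                else:
                    context = cur
                out.append(log.schedule.active(e.global_trial).probs[context, e.image])
                cur = e.image
    return np.asarray(out, dtype=float)


@njit(cache=False)
def _learn_kernel_probes(prev, obs, alpha, probe_pos, probe_goal):  # pragma: no cover
    n = prev.shape[0]
    m = probe_pos.shape[0]
    T = np.full((4, 4), 0.25)
    D = np.zeros((4, 4))
    p_obs = np.empty(n)
    dp_obs = np.empty(n)
    p_next = np.empty((n, 4))
    dp_next = np.empty((n, 4))
    H = np.empty(n)
    dH = np.empty(n)
    pg = np.empty((m, 4))
    dpg = np.empty((m, 4))
    dsig = alpha * (1.0 - alpha)
    k = 0
    for t in range(n):
        while k < m and probe_pos[k] == t:
            g = probe_goal[k]
            for c in range(4):
                pg[k, c] = T[c, g]
                dpg[k, c] = D[c, g]
            k += 1
        i = prev[t]
        j = obs[t]
        p_obs[t] = T[i, j]
        dp_obs[t] = D[i, j]
        for c in range(4):
            ind = 1.0 if c == j else 0.0
            t_old = T[i, c]
            T[i, c] = (1.0 - alpha) * t_old + alpha * ind
            D[i, c] = (1.0 - alpha) * D[i, c] + dsig * (ind - t_old)
        h = 0.0
        dh = 0.0
        for c in range(4):
            p = T[j, c]
            dp = D[j, c]
            p_next[t, c] = p
            dp_next[t, c] = dp
            if p > 1e-300:
                h -= p * np.log(p)
                dh -= (np.log(p) + 1.0) * dp
        H[t] = h
        dH[t] = dh
    while k < m:
        g = probe_goal[k]
        for c in range(4):
            pg[k, c] = T[c, g]
            dpg[k, c] = D[c, g]
        k += 1
    return p_obs, dp_obs, p_next, dp_next, H, dH, pg, dpg


@dataclass
class ProcessTrace:
    """Per-trial outputs of a single learning process at one learning rate.

    Derivatives are with respect to x = inv_sigmoid(alpha), evaluated at this
    trace's alpha (exact recursion, not finite differences).
    """

    alpha: float
    p_observed: np.ndarray
    d_p_observed: np.ndarray
    p_next: np.ndarray
    d_p_next: np.ndarray
    entropy: np.ndarray
    d_entropy: np.ndarray
    probe_p_goal: np.ndarray  # (n_probes, 4): P(goal | category) at choice time
    probe_d_p_goal: np.ndarray


def run_process(stream: TransitionStream, alpha: float) -> ProcessTrace:
    """Run one delta-rule process (with exact derivative recursion) over a stream."""
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    out = _learn_kernel_probes(
        stream.prev, stream.obs, float(alpha), stream.probe_pos, stream.probe_goal
    )
    p_obs, dp_obs, p_next, dp_next, H, dH, pg, dpg = out
    return ProcessTrace(
        alpha=float(alpha),
        p_observed=p_obs,
        d_p_observed=dp_obs,
        p_next=p_next,
        d_p_next=dp_next,
        entropy=H,
        d_entropy=dH,
        probe_p_goal=pg,
        probe_d_p_goal=dpg,
    )


@dataclass
class LearningTrace:
    """Combined two-process trace plus a reference single-process trace.

    ``p_observed`` / ``p_next`` / ``entropy`` are the behaviorally expressed
    quantities (weighted combination of the fast and slow processes; entropy is
    computed on the combined prediction). ``reference`` carries the single-
    process quantities and their exact derivatives at ``alpha_ref`` used to
    build imaging regressors.
    """

    params: LearnerParams
    p_observed: np.ndarray
    p_next: np.ndarray
    entropy: np.ndarray
    probe_p_goal: np.ndarray
    fast: ProcessTrace
    slow: ProcessTrace
    reference: Optional[ProcessTrace] = None


def trace_learning(
    stream: TransitionStream,
    params: LearnerParams,
    alpha_ref: Optional[float] = None,
) -> LearningTrace:
    """Run both processes over the stream and combine their predictions.

    When ``alpha_ref`` is given, an additional single-process trace (with
    derivatives) is computed at that rate for regressor construction.
    """
    slow = run_process(stream, params.alpha_slow)
    fast = slow if params.is_single else run_process(stream, params.alpha_fast)
    w = params.w_slow
    p_obs = w * slow.p_observed + (1.0 - w) * fast.p_observed
    p_next = w * slow.p_next + (1.0 - w) * fast.p_next
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.where(p_next > 0, np.log(np.where(p_next > 0, p_next, 1.0)), 0.0)
    entropy = -(p_next * logp).sum(axis=1)
    probe_pg = w * slow.probe_p_goal + (1.0 - w) * fast.probe_p_goal
    reference = None if alpha_ref is None else run_process(stream, alpha_ref)
    return LearningTrace(
        params=params,
        p_observed=p_obs,
        p_next=p_next,
        entropy=entropy,
        probe_p_goal=probe_pg,
        fast=fast,
        slow=slow,
        reference=reference,
    )
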