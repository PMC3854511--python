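"""Task structure for a serial reaction-time (SRT) task with interleaved reward probes.

The task presents one of four photograph categories at a time; the identity of
the next image follows a first-order Markov process over a 4x4 row-stochastic
transition matrix. Four matrices are used over the experiment, each replaced at
evenly spaced global trial positions. Interleaved choice rounds announce a
temporarily rewarded image and a dollar value, then ask which of two other
images is more likely to lead to it; the image stream restarts from the chosen
image and the next several images carry reward annotations.

This module generates the full ground-truth event stream: the stimulus
sequence, the probe schedule, and onset bookkeeping on a scanner-compatible
clock. It is the substrate every downstream stage (learning traces, behavior,
GLM designs) consumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Protocol

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "TaskConfig",
    "TransitionMatrix",
    "MatrixSchedule",
    "ChoiceProbe",
    "TrialEvent",
    "SessionLog",
    "Chooser",
    "UniformChooser",
    "sinkhorn_balance",
    "stationary_distribution",
    "generate_transition_matrix",
    "switch_points",
    "build_matrix_schedule",
    "generate_sequence",
    "schedule_probes",
    "assemble_session",
    "simulate_task",
    "truncated_exponential_rate",
    "sample_truncated_exponential",
    "events_frame",
    "write_event_table",
    "read_event_table",
]

N_IMAGES = 4

SEQUENTIAL = "sequential"
REWARD_SCREEN = "reward_screen"
CHOICE = "choice"


class ConvergenceError(RuntimeError):
    """Raised when an iterative generation procedure fails to converge."""


@dataclass(frozen=True)
class TaskConfig:
    """Structural parameters of the task.

    Defaults reproduce the published design: three 250-trial blocks, each with
    210 sequential response trials, 20 one-second reward screens and 20 choice
    screens; 80 reward-annotated trials per session spread over 20 rounds of
    length 1-8 (truncated exponential, mean 4); no probe within the first 30
    trials of a session; stimuli shown 3 s +/- up to 474 ms of jitter in 59 ms
    steps with a 237 ms inter-trial interval; TR 2.37 s, 400 volumes per scan.
    """

    n_sessions: int = 3
    trials_per_block: int = 250
    n_seq_trials: int = 210
    n_reward_screens: int = 20
    n_choice_trials: int = 20
    n_matrices: int = 4
    probe_free_prefix: int = 30
    round_min: int = 1
    round_max: int = 8
    round_mean: float = 4.0
    round_total: int = 80
    reward_min: int = 1
    reward_max: int = 5
    stim_duration: float = 3.0
    jitter_step: float = 0.059
    jitter_max: float = 0.474
    iti: float = 0.237
    reward_screen_duration: float = 1.0
    choice_window: float = 5.0
    isi_min: float = 2.0
    isi_max: float = 8.0
    isi_mean: float = 4.0
    tr: float = 2.37
    volumes_per_scan: int = 400

    def __post_init__(self) -> None:
        if self.n_seq_trials + self.n_reward_screens + self.n_choice_trials != self.trials_per_block:
            raise ValueError("sequential + reward screens + choices must equal trials_per_block")
        if self.probe_free_prefix >= self.trials_per_block:
            raise ValueError("probe_free_prefix must be smaller than the block length")
        if not (1 <= self.round_min <= self.round_mean <= self.round_max):
            raise ValueError("round length bounds must satisfy min <= mean <= max")
        if self.n_choice_trials * self.round_max < self.round_total:
            raise ValueError("round_total unreachable with the given round bounds")
        if self.n_choice_trials * self.round_min > self.round_total:
            raise ValueError("round_total unreachable with the given round bounds")

    @property
    def total_trials(self) -> int:
        """Global trial positions across all sessions (used for matrix scheduling)."""
        return self.n_sessions * self.trials_per_block

    @property
    def n_jitter_steps(self) -> int:
        return int(round(self.jitter_max / self.jitter_step))


@dataclass(frozen=True)
class TransitionMatrix:
    """4x4 row-stochastic conditional image-transition probabilities."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (N_IMAGES, N_IMAGES):
            raise ValueError(f"expected a {N_IMAGES}x{N_IMAGES} matrix, got {p.shape}")
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("transition probabilities must lie in [0, 1]")
        if not np.allclose(p.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("every row of a transition matrix must sum to 1")
        object.__setattr__(self, "probs", p)

    def stationary(self) -> np.ndarray:
        return stationary_distribution(self.probs)


def stationary_distribution(probs: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (leading left eigenvector)."""
    vals, vecs = np.linalg.eig(np.asarray(probs, dtype=float).T)
    idx = int(np.argmax(vals.real))
    v = np.abs(vecs[:, idx].real)
    return v / v.sum()


def sinkhorn_balance(
    mat: np.ndarray, tol: float = 1e-12, max_iter: int = 10_000
) -> np.ndarray:
    """Alternately normalize rows and columns until the matrix is doubly stochastic.

    The returned matrix has exact row sums of 1 (rows are normalized last) and
    column sums within ``tol`` of 1, which forces a uniform stationary
    distribution. A matrix that is already doubly stochastic is a fixed point.
    """
    m = np.asarray(mat, dtype=float).copy()
    if np.any(m <= 0):
        raise ValueError("Sinkhorn balancing requires strictly positive entries")
    for _ in range(max_iter):
        m /= m.sum(axis=1, keepdims=True)
        m /= m.sum(axis=0, keepdims=True)
        m /= m.sum(axis=1, keepdims=True)
        if np.max(np.abs(m.sum(axis=0) - 1.0)) < tol:
            return m
    raise ConvergenceError(f"Sinkhorn balancing did not converge in {max_iter} iterations")


def generate_transition_matrix(
    rng: np.random.Generator,
    tolerance: float = 0.01,
    concentration: float = 1.0,
    min_spread: float = 0.25,
    max_tries: int = 500,
) -> TransitionMatrix:
    """Draw a transition matrix with a uniform stationary distribution.

    Rows are sampled from a Dirichlet distribution and Sinkhorn-balanced so
    the matrix is doubly stochastic (hence mixing to the uniform distribution
    over images). Candidates whose off-diagonal entries span less than
    ``min_spread`` are rejected, so each matrix exposes a wide range of
    conditional probabilities.
    """
    if not (0 < tolerance <= 0.1):
        raise ValueError("tolerance must lie in (0, 0.1]")
    for _ in range(max_tries):
        rows = rng.dirichlet(np.full(N_IMAGES, concentration), size=N_IMAGES)
        rows = np.clip(rows, 1e-6, None)
        try:
            balanced = sinkhorn_balance(rows)
        except ConvergenceError:
            continue
        off = balanced[~np.eye(N_IMAGES, dtype=bool)]
        if off.max() - off.min() < min_spread:
            continue
        stat = stationary_distribution(balanced)
        if np.max(np.abs(stat - 1.0 / N_IMAGES)) < tolerance:
            return TransitionMatrix(balanced)
    raise ConvergenceError("failed to generate a transition matrix within max_tries")


def switch_points(total_trials: int, n_matrices: int = 4) -> tuple[int, ...]:
    """Global (1-based) trial positions at which each subsequent matrix takes effect.

    Quarters of the total trial count, rounded up to the next trial: with 750
    trials the switches fall at trials 188, 376 and 563.
    """
    return tuple(
        int(np.floor(k * total_trials / n_matrices)) + 1 for k in range(1, n_matrices)
    )


@dataclass(frozen=True)
class MatrixSchedule:
    """Four transition matrices plus the global trial positions where they switch."""

    matrices: tuple[TransitionMatrix, ...]
    switch_trials: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.switch_trials) != len(self.matrices) - 1:
            raise ValueError("need exactly one switch per matrix after the first")
        if any(b <= a for a, b in zip(self.switch_trials, self.switch_trials[1:])):
            raise ValueError("switch trials must be strictly increasing")

    def active_index(self, global_trial: int) -> int:
        """Index of the matrix governing the given 1-based global trial."""
        return int(np.searchsorted(np.asarray(self.switch_trials), global_trial, side="right"))

    def active(self, global_trial: int) -> TransitionMatrix:
        return self.matrices[self.active_index(global_trial)]


def build_matrix_schedule(config: TaskConfig, rng: np.random.Generator) -> MatrixSchedule:
    matrices = tuple(generate_transition_matrix(rng) for _ in range(config.n_matrices))
    return MatrixSchedule(matrices, switch_points(config.total_trials, config.n_matrices))


def generate_sequence(
    schedule: MatrixSchedule,
    n_trials: int,
    rng: np.random.Generator,
    start_image: int,
    first_global_trial: int = 1,
) -> np.ndarray:
    """Generate a Markov image sequence, honoring matrix switches mid-stream.

    Trial ``t`` (0-based) occupies global position ``first_global_trial + t``
    and is drawn from the row of the then-active matrix indexed by its
    predecessor (``start_image`` for the first trial).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be at least 1")
    out = np.empty(n_trials, dtype=np.int64)
    cur = int(start_image)
    for t in range(n_trials):
        row = schedule.active(first_global_trial + t).probs[cur]
        cur = int(rng.choice(N_IMAGES, p=row))
        out[t] = cur
    return out


# --- truncated exponential helpers -------------------------------------------

def _truncexp_mean(rate: float, lo: float, hi: float) -> float:
    za, zb = np.exp(-rate * lo), np.exp(-rate * hi)
    return 1.0 / rate + (lo * za - hi * zb) / (za - zb)


def truncated_exponential_rate(lo: float, hi: float, mean: float) -> float:
    """Rate of an exponential truncated to [lo, hi] with the requested mean."""
    if not (lo < mean < (lo + hi) / 2):
        raise ValueError("mean must lie between lo and the midpoint of [lo, hi]")
    return brentq(lambda lam: _truncexp_mean(lam, lo, hi) - mean, 1e-8, 50.0)


def sample_truncated_exponential(
    rng: np.random.Generator, size: int, lo: float, hi: float, mean: float
) -> np.ndarray:
    lam = truncated_exponential_rate(lo, hi, mean)
    u = rng.random(size)
    za, zb = np.exp(-lam * lo), np.exp(-lam * hi)
    return -np.log(za - u * (za - zb)) / lam


def _draw_round_lengths(config: TaskConfig, rng: np.random.Generator) -> np.ndarray:
    """Round lengths: truncated-exponential draws repaired by +/-1 to sum exactly 80."""
    raw = sample_truncated_exponential(
        rng, config.n_choice_trials, config.round_min, config.round_max, config.round_mean
    )
    lengths = np.clip(np.round(raw), config.round_min, config.round_max).astype(int)
    target = config.round_total
    while lengths.sum() != target:
        step = 1 if lengths.sum() < target else -1
        movable = np.flatnonzero(
            (lengths + step >= config.round_min) & (lengths + step <= config.round_max)
        )
        lengths[rng.choice(movable)] += step
    return lengths


@dataclass
class ChoiceProbe:
    """One choice round: goal image, two option images, dollar value, round length."""

    rewarded_image: int
    option_a: int
    option_b: int
    value: int
    round_length: int
    position: int  # 0-based index (within session) of the outcome sequential trial
    chosen_option: Optional[int] = None  # 0 -> option_a, 1 -> option_b
    outcome_image: Optional[int] = None
    reward_onset: Optional[float] = None
    choice_onset: Optional[float] = None

    def __post_init__(self) -> None:
        if self.option_a == self.option_b:
            raise ValueError("the two options must differ")
        if self.rewarded_image in (self.option_a, self.option_b):
            raise ValueError("options must differ from the rewarded image")

    @property
    def chosen_image(self) -> Optional[int]:
        if self.chosen_option is None:
            return None
        return self.option_a if self.chosen_option == 0 else self.option_b


@dataclass(frozen=True)
class TrialEvent:
    """One displayed event on the session clock."""

    kind: str  # sequential | reward_screen | choice
    image: int  # displayed image, or -1 for choice screens
    onset: float
    duration: float
    reward_shown: int = 0  # dollars annotated above the image (0 when unannotated)
    is_probe_round: bool = False
    is_outcome: bool = False
    probe_index: int = -1
    seq_index: int = -1  # 0-based sequential-trial counter within session
    global_trial: int = -1  # 1-based trial position across sessions


class Chooser(Protocol):
    """Callback protocol that lets a behavioral model drive choices at assembly time."""

    def observe(self, prev_image: int, image: int) -> None: ...

    def choose(
        self, option_a: int, option_b: int, goal: int, value: int, rng: np.random.Generator
    ) -> int: ...


class UniformChooser:
    """Default chooser: picks between the two options at random."""

    def observe(self, prev_image: int, image: int) -> None:
        pass

    def choose(self, option_a: int, option_b: int, goal: int, value: int, rng) -> int:
        return int(rng.integers(2))


def schedule_probes(config: TaskConfig, rng: np.random.Generator) -> list[ChoiceProbe]:
    """Draw one session's 20 choice probes with positions in sequential-trial space.

    Round lengths are adjusted to sum to exactly ``round_total`` (80); probe
    positions are uniform over the feasible slots given the probe-free prefix
    and a minimum gap of one plain sequential trial between rounds.
    """
    n = config.n_choice_trials
    lengths = _draw_round_lengths(config, rng)
    # position[i] = seq index of round i's outcome trial; rounds may not overlap
    # and must leave >= 1 plain sequential trial between consecutive rounds.
    slack = config.n_seq_trials - config.probe_free_prefix - int(lengths.sum()) - (n - 1)
    if slack < 0:
        raise ConvergenceError("probe schedule infeasible for this configuration")
    gaps = rng.multinomial(slack, np.full(n + 1, 1.0 / (n + 1)))
    probes: list[ChoiceProbe] = []
    pos = config.probe_free_prefix + gaps[0]
    for i in range(n):
        goal = int(rng.integers(N_IMAGES))
        options = rng.choice([k for k in range(N_IMAGES) if k != goal], size=2, replace=False)
        probes.append(
            ChoiceProbe(
                rewarded_image=goal,
                option_a=int(options[0]),
                option_b=int(options[1]),
                value=int(rng.integers(config.reward_min, config.reward_max + 1)),
                round_length=int(lengths[i]),
                position=int(pos),
            )
        )
        pos += int(lengths[i]) + 1 + gaps[i + 1]
    return probes


@dataclass
class SessionLog:
    """Complete record of one scanning session's generated events."""

    session_index: int
    start_image: int
    events: list[TrialEvent]
    probes: list[ChoiceProbe]
    schedule: MatrixSchedule
    config: TaskConfig

    @property
    def sequence(self) -> np.ndarray:
        return np.array([e.image for e in self.events if e.kind == SEQUENTIAL], dtype=np.int64)

    def counts(self) -> dict[str, int]:
        kinds = [e.kind for e in self.events]
        return {k: kinds.count(k) for k in (SEQUENTIAL, REWARD_SCREEN, CHOICE)}

    def validate(self) -> None:
        c = self.counts()
        cfg = self.config
        if c[SEQUENTIAL] != cfg.n_seq_trials:
            raise ValueError("wrong number of sequential trials")
        if c[REWARD_SCREEN] != cfg.n_reward_screens or c[CHOICE] != cfg.n_choice_trials:
            raise ValueError("wrong number of probe events")
        if sum(p.round_length for p in self.probes) != cfg.round_total:
            raise ValueError("round lengths do not sum to the configured total")
        onsets = np.array([e.onset for e in self.events])
        if np.any(np.diff(onsets) <= 0):
            raise ValueError("onsets must be strictly increasing")
        if min(p.position for p in self.probes) < cfg.probe_free_prefix:
            raise ValueError("probe inside the probe-free prefix")


def assemble_session(
    config: TaskConfig,
    schedule: MatrixSchedule,
    session_index: int,
    start_image: int,
    rng: np.random.Generator,
    chooser: Optional[Chooser] = None,
) -> SessionLog:
    """Interleave sequential trials, reward screens and choices into one session.

    The chooser (a behavioral model, or a uniform picker by default) is fed each
    observed transition and asked to choose at every probe; the image after the
    choice — the outcome image — is drawn from the chosen image's row of the
    then-active matrix. Onsets accumulate stimulus duration + jitter + ITI on a
    clock starting at 0 for each session.
    """
    chooser = chooser if chooser is not None else UniformChooser()
    probes = schedule_probes(config, rng)
    probe_by_pos = {p.position: (i, p) for i, p in enumerate(probes)}

    events: list[TrialEvent] = []
    clock = 0.0
    cur = int(start_image)
    global_trial = session_index * config.trials_per_block  # next event is +1
    n_steps = config.n_jitter_steps

    reward_left = 0  # remaining reward-annotated trials in the active round
    active_probe: Optional[tuple[int, ChoiceProbe]] = None

    for s in range(config.n_seq_trials):
        outcome = False
        if s in probe_by_pos:
            i, probe = probe_by_pos[s]
            # reward display screen (1 s) showing the goal image and value
            global_trial += 1
            events.append(
                TrialEvent(
                    kind=REWARD_SCREEN,
                    image=probe.rewarded_image,
                    onset=clock,
                    duration=config.reward_screen_duration,
                    reward_shown=probe.value,
                    probe_index=i,
                    global_trial=global_trial,
                )
            )
            clock += config.reward_screen_duration
            clock += float(
                sample_truncated_exponential(
                    rng, 1, config.isi_min, config.isi_max, config.isi_mean
                )[0]
            )
            # choice screen: up to 5 s to pick one of the two options
            global_trial += 1
            choice_onset = clock
            events.append(
                TrialEvent(
                    kind=CHOICE,
                    image=-1,
                    onset=clock,
                    duration=config.choice_window,
                    probe_index=i,
                    global_trial=global_trial,
                )
            )
            clock += config.choice_window + config.iti
            option = chooser.choose(
                probe.option_a, probe.option_b, probe.rewarded_image, probe.value, rng
            )
            probe.chosen_option = int(option)
            probe.reward_onset = events[-2].onset
            probe.choice_onset = choice_onset
            cur = int(probe.chosen_image)  # sequence restarts from the chosen image
            reward_left = probe.round_length
            active_probe = (i, probe)
            outcome = True

        global_trial += 1
        row = schedule.active(global_trial).probs[cur]
        img = int(rng.choice(N_IMAGES, p=row))
        chooser.observe(cur, img)
        jitter = int(rng.integers(-n_steps, n_steps + 1)) * config.jitter_step
        duration = config.stim_duration + jitter
        in_round = reward_left > 0
        probe_idx = active_probe[0] if in_round and active_probe is not None else -1
        reward = 0
        if in_round and active_probe is not None:
            if img == active_probe[1].rewarded_image:
                reward = active_probe[1].value
        events.append(
            TrialEvent(
                kind=SEQUENTIAL,
                image=img,
                onset=clock,
                duration=duration,
                reward_shown=reward,
                is_probe_round=in_round,
                is_outcome=outcome,
                probe_index=probe_idx,
                seq_index=s,
                global_trial=global_trial,
            )
        )
        if outcome and active_probe is not None:
            active_probe[1].outcome_image = img
        clock += duration + config.iti
        cur = img
        if in_round:
            reward_left -= 1
            if reward_left == 0:
                active_probe = None

    log = SessionLog(
        session_index=session_index,
        start_image=int(start_image),
        events=events,
        probes=probes,
        schedule=schedule,
        config=config,
    )
    log.validate()
    return log


def simulate_task(
    config: TaskConfig,
    rng: np.random.Generator,
    chooser: Optional[Chooser] = None,
    schedule: Optional[MatrixSchedule] = None,
) -> list[SessionLog]:
    """Generate the full multi-session task for one subject."""
    if schedule is None:
        schedule = build_matrix_schedule(config, rng)
    sessions = []
    start = int(rng.integers(N_IMAGES))
    for k in range(config.n_sessions):
        log = assemble_session(config, schedule, k, start, rng, chooser)
        sessions.append(log)
        start = int(log.sequence[-1])  # the chain continues across the rest break
    return sessions


# --- serialization ------------------------------------------------------------

_EVENT_COLUMNS = [
    "onset",
    "duration",
    "kind",
    "image",
    "reward",
    "is_probe_round",
    "is_outcome",
    "probe_index",
    "seq_index",
    "global_trial",
]


def events_frame(session: SessionLog) -> pd.DataFrame:
    """Session events as a tidy table (onsets in seconds from scan start)."""
    rows = [
        (
            e.onset,
            e.duration,
            e.kind,
            e.image,
            e.reward_shown,
            int(e.is_probe_round),
            int(e.is_outcome),
            e.probe_index,
            e.seq_index,
            e.global_trial,
        )
        for e in session.events
    ]
    return pd.DataFrame(rows, columns=_EVENT_COLUMNS)


def write_event_table(session: SessionLog, path) -> None:
    events_frame(session).to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_event_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
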