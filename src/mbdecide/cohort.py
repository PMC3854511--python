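"""Synthetic multi-subject datasets: task, behavior, and ROI-level BOLD.

Each synthetic subject gets its own transition-matrix schedule and performs
the full three-session task. Choices are generated online by a single
slow-process learner feeding the sampling choice rule (so the outcome images
are consistent with the simulated decisions); RTs come from the weighted
two-process model. Synthetic BOLD is generated at the region-of-interest
level: an HRF-convolved model regressor computed at a ground-truth learning
rate, scaled by an amplitude, plus AR(1) Gaussian noise on the TR grid.

Cross-subject parameter distributions are Gaussian, truncated to validity.
Default centers: slow rate 0.10 (SD 0.05, the cross-subject spread reported
for choice fits), fast rate 0.507, slow-process weight 0.7, sampling draws
4.675 (SD 1.25); SDs not anchored by a printed value default to 20% of the
mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .behavior import BehaviorData, ChoiceModelParams, ModelChooser, RTModelParams, simulate_behavior
from .learning import LearnerParams, LearningTrace, trace_learning
from .task import MatrixSchedule, SessionLog, TaskConfig, simulate_task

__all__ = [
    "SubjectSpec",
    "SubjectData",
    "BoldSpec",
    "CohortSpec",
    "generate_subject",
    "generate_cohort",
    "generate_bold",
]


@dataclass(frozen=True)
class SubjectSpec:
    """Ground-truth parameters and seed for one synthetic subject."""

    learner: LearnerParams = field(
        default_factory=lambda: LearnerParams(alpha_fast=0.507, alpha_slow=0.10, w_slow=0.7)
    )
    rt: RTModelParams = field(default_factory=RTModelParams)
    choice: ChoiceModelParams = field(default_factory=ChoiceModelParams)
    seed: int = 0


@dataclass
class SubjectData:
    """One synthetic subject's generated task and behavior."""

    spec: SubjectSpec
    sessions: list[SessionLog]
    behavior: BehaviorData

    def trace(self, alpha_ref: Optional[float] = None) -> LearningTrace:
        return trace_learning(self.behavior.stream, self.spec.learner, alpha_ref)


@dataclass(frozen=True)
class BoldSpec:
    """Synthetic ROI timeseries: scaled regressors plus AR(1) noise on the TR grid."""

    true_alpha: float = 0.10
    amplitudes: tuple[float, ...] = (1.0,)
    # at unit amplitude this noise level puts the single-scan t of a parametric
    # modulator near 3, typical of a well-placed ROI analysis
    noise_sd: float = 0.03
    tr: float = 2.37
    volumes_per_scan: int = 400
    n_scans: int = 3
    ar1_coef: float = 0.3
    highpass_period: float = 128.0

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if not (0.0 <= self.ar1_coef < 1.0):
            raise ValueError("ar1_coef must lie in [0, 1)")


@dataclass(frozen=True)
class CohortSpec:
    """Cross-subject parameter distributions and the shared task configuration."""

    n_subjects: int = 20
    task: TaskConfig = field(default_factory=TaskConfig)
    alpha_slow_mean: float = 0.10
    alpha_slow_sd: float = 0.05
    alpha_fast_mean: float = 0.507
    alpha_fast_sd: float = 0.10
    w_slow_mean: float = 0.7
    w_slow_sd: float = 0.14
    n_draws_mean: float = 4.675
    n_draws_sd: float = 1.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be at least 1")


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float
) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo < x < hi:
            return float(x)
    return float(np.clip(mean, lo + 1e-6, hi - 1e-6))


def generate_subject(
    spec: SubjectSpec,
    task: Optional[TaskConfig] = None,
    schedule: Optional[MatrixSchedule] = None,
) -> SubjectData:
    """Generate one subject's sessions and behavior, deterministic under the seed."""
    task = task if task is not None else TaskConfig()
    rng = np.random.default_rng(spec.seed)
    chooser = ModelChooser(spec.learner.alpha_slow, spec.choice)
    sessions = simulate_task(task, rng, chooser=chooser, schedule=schedule)
    behavior = simulate_behavior(sessions, spec.learner, spec.rt, spec.choice, rng)
    return SubjectData(spec=spec, sessions=sessions, behavior=behavior)


def generate_cohort(spec: CohortSpec) -> list[SubjectData]:
    """Generate a cohort with parameters drawn from the stated distributions."""
    rng = np.random.default_rng(spec.seed)
    subjects = []
    for s in range(spec.n_subjects):
        a_slow = _truncated_normal(rng, spec.alpha_slow_mean, spec.alpha_slow_sd, 0.01, 0.98)
        a_fast = _truncated_normal(
            rng, spec.alpha_fast_mean, spec.alpha_fast_sd, a_slow + 0.01, 0.99
        )
        w = _truncated_normal(rng, spec.w_slow_mean, spec.w_slow_sd, 0.0, 1.0)
        n_draws = _truncated_normal(rng, spec.n_draws_mean, spec.n_draws_sd, 0.5, 50.0)
        subj = SubjectSpec(
            learner=LearnerParams(alpha_fast=a_fast, alpha_slow=a_slow, w_slow=w),
            rt=RTModelParams(),
            choice=ChoiceModelParams(n_draws=n_draws),
            seed=int(rng.integers(2**31 - 1)),
        )
        subjects.append(generate_subject(subj, spec.task))
    return subjects


def generate_bold(
    regressors: np.ndarray,
    spec: BoldSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """Synthesize one scan's ROI timeseries from TR-grid regressors.

    ``regressors`` has one column per amplitude; the output is their weighted
    sum plus stationary AR(1) Gaussian noise with marginal SD ``noise_sd``.
    """
    R = np.atleast_2d(np.asarray(regressors, dtype=float))
    if R.shape[0] == 1 and R.shape[1] == spec.volumes_per_scan:
        R = R.T
    if R.shape[0] != spec.volumes_per_scan:
        raise ValueError(
            f"regressor length {R.shape[0]} does not match volumes_per_scan "
            f"{spec.volumes_per_scan}"
        )
    amps = np.asarray(spec.amplitudes, dtype=float)
    if amps.size != R.shape[1]:
        raise ValueError("one amplitude per regressor column is required")
    signal = R @ amps
    n = spec.volumes_per_scan
    if spec.noise_sd == 0:
        return signal
    innov_sd = spec.noise_sd * np.sqrt(1.0 - spec.ar1_coef**2)
    eps = rng.normal(0.0, innov_sd, size=n)
    noise = np.empty(n)
    noise[0] = rng.normal(0.0, spec.noise_sd)
    for t in range(1, n):
        noise[t] = spec.ar1_coef * noise[t - 1] + eps[t]
    return signal + noise
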