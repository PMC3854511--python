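"""GLM design construction and the Taylor-expansion learning-rate estimator.

Model-derived quantities (conditional probability, forward entropy, choice
difficulty, reward prediction error) enter the design as parametric modulators
on delta-function onsets, convolved with the canonical double-gamma HRF.
Each regressor of interest is evaluated at a reference learning rate
``alpha0`` and paired with its partial derivative with respect to the
inverse-sigmoid-transformed rate; the weighted sum of the pair linearizes how
the regressor would change at nearby rates (first-order Taylor expansion).

After fitting, the learning rate implied by a timeseries is recovered as

    x_hat = beta_deriv / k + inv_sigmoid(alpha0),    alpha_hat = sigmoid(x_hat)

where k is the group-mean coefficient of the main-effect regressor (the
common scale factor), so the derivative beta is converted into transformed
learning-rate units. Group statistics on x_hat are ordinary t-tests in
transformed space.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from nilearn.glm.first_level import compute_regressor
from scipy import stats

from .behavior import RIGHT_HAND_IMAGES, BehaviorData
from .learning import inv_sigmoid, run_process, sigmoid

__all__ = [
    "SessionModelEvents",
    "DesignMatrix",
    "GLMResult",
    "LearningRateEstimate",
    "model_event_table",
    "hrf_convolve",
    "cosine_drift",
    "build_glm1",
    "build_glm2",
    "fit_glm",
    "realized_design",
    "estimate_learning_rate",
    "compare_learning_rates",
    "simulate_entropy_alpha_recovery",
]

FIXED_EFFECT_N_DRAWS = 4.177  # sampling parameter used for regressor generation


@dataclass
class SessionModelEvents:
    """Per-session event tables carrying raw (uncentered) modulator values."""

    session: int
    seq: pd.DataFrame
    choice: pd.DataFrame
    outcome: pd.DataFrame
    alpha0: float
    n_draws: float


def model_event_table(
    behavior: BehaviorData,
    alpha0: float,
    n_draws: float = FIXED_EFFECT_N_DRAWS,
) -> list[SessionModelEvents]:
    """Evaluate every GLM modulator (and its derivative) at the reference rate.

    Sequential trials carry the conditional probability of the displayed
    image, the forward entropy, and the per-image next probabilities; choice
    onsets carry overall and per-category difficulty; outcome onsets carry the
    reward prediction error. Derivatives are with respect to the transformed
    learning rate, evaluated at ``alpha0`` by the exact recursion.
    """
    stream = behavior.stream
    ref = run_process(stream, alpha0)
    trials = behavior.trials
    idx = np.arange(stream.n_probes)
    pg = ref.probe_p_goal
    dpg = ref.probe_d_p_goal
    p_a = pg[idx, stream.probe_a]
    p_b = pg[idx, stream.probe_b]
    dp_a = dpg[idx, stream.probe_a]
    dp_b = dpg[idx, stream.probe_b]
    difficulty = (p_a * (1 - p_a) + p_b * (1 - p_b)) / n_draws
    d_difficulty = ((1 - 2 * p_a) * dp_a + (1 - 2 * p_b) * dp_b) / n_draws
    p_chosen = pg[idx, stream.probe_chosen]
    dp_chosen = dpg[idx, stream.probe_chosen]
    outcome_img = stream.obs[stream.probe_pos]
    received = np.where(outcome_img == stream.probe_goal, stream.probe_value, 0.0)
    rpe = received - p_chosen * stream.probe_value
    d_rpe = -stream.probe_value * dp_chosen

    out = []
    for s in sorted(set(stream.session.tolist())):
        m = stream.session == s
        seq = pd.DataFrame(
            {
                "onset": stream.onset[m],
                "image": stream.obs[m],
                "rt": trials.rt.to_numpy()[m],
                "correct": trials.correct.to_numpy()[m],
                "missed": trials.missed.to_numpy()[m],
                "is_self": stream.is_self[m],
                "is_outcome": stream.is_outcome[m],
                "right_hand": np.isin(stream.obs[m], RIGHT_HAND_IMAGES),
                "p_obs": ref.p_observed[m],
                "d_p_obs": ref.d_p_observed[m],
                "entropy": ref.entropy[m],
                "d_entropy": ref.d_entropy[m],
            }
        )
        for c in range(4):
            seq[f"p_next_{c}"] = ref.p_next[m, c]
            seq[f"d_p_next_{c}"] = ref.d_p_next[m, c]
        pm = stream.probe_session == s
        choice = pd.DataFrame(
            {
                "onset": stream.probe_choice_onset[pm],
                "rt": behavior.choices.rt.to_numpy()[pm],
                "missed": behavior.choices.missed.to_numpy()[pm],
                "value": stream.probe_value[pm].astype(float),
                "difficulty": difficulty[pm],
                "d_difficulty": d_difficulty[pm],
            }
        )
        for c in range(4):
            choice[f"cat_difficulty_{c}"] = (pg[pm, c] * (1 - pg[pm, c])) / n_draws
            choice[f"d_cat_difficulty_{c}"] = ((1 - 2 * pg[pm, c]) * dpg[pm, c]) / n_draws
        om = m & stream.is_outcome
        outcome = pd.DataFrame(
            {
                "onset": stream.onset[om],
                "rt": trials.rt.to_numpy()[om],
                "rpe": rpe[pm],
                "d_rpe": d_rpe[pm],
            }
        )
        out.append(
            SessionModelEvents(
                session=int(s), seq=seq, choice=choice, outcome=outcome,
                alpha0=float(alpha0), n_draws=float(n_draws),
            )
        )
    return out


def hrf_convolve(
    onsets: np.ndarray,
    amplitudes: Optional[np.ndarray],
    n_volumes: int,
    tr: float,
    durations: Optional[np.ndarray] = None,
    oversampling: int = 16,
) -> np.ndarray:
    """Convolve delta-function events with the canonical double-gamma HRF.

    Events are modeled at an oversampled grid (``oversampling`` bins per TR)
    and downsampled to the TR grid. Empty event lists give a zero column.
    """
    onsets = np.asarray(onsets, dtype=float)
    if onsets.size == 0:
        return np.zeros(n_volumes)
    if np.any(onsets < 0):
        raise ValueError("onsets must be nonnegative")
    amps = np.ones_like(onsets) if amplitudes is None else np.asarray(amplitudes, float)
    durs = np.zeros_like(onsets) if durations is None else np.asarray(durations, float)
    if np.allclose(amps, 0.0):
        return np.zeros(n_volumes)
    frame_times = np.arange(n_volumes) * tr
    cond = np.vstack([onsets, durs, amps])
    signal, _ = compute_regressor(
        cond, "spm", frame_times, oversampling=oversampling, min_onset=0.0
    )
    return signal[:, 0]


def cosine_drift(n_volumes: int, tr: float, period: float = 128.0) -> np.ndarray:
    """Discrete-cosine high-pass basis (constant plus drifts slower than ``period``)."""
    order = int(np.floor(2.0 * n_volumes * tr / period))
    t = np.arange(n_volumes)
    cols = [np.ones(n_volumes)]
    for k in range(1, order + 1):
        cols.append(np.sqrt(2.0 / n_volumes) * np.cos(np.pi * k * (2 * t + 1) / (2 * n_volumes)))
    return np.column_stack(cols)


@dataclass
class DesignMatrix:
    """Named, HRF-convolved design columns with a declared orthogonalization policy.

    ``families`` records, for each onset family, the serial order of its
    columns; under the ``serial`` policy each column is orthogonalized (after
    high-pass filtering) against the earlier columns of its own family.
    """

    columns: pd.DataFrame
    families: dict[str, list[str]]
    policy: str  # "serial" | "none"
    tr: float
    highpass_period: float = 128.0

    def __post_init__(self) -> None:
        if self.policy not in ("serial", "none"):
            raise ValueError("policy must be 'serial' or 'none'")
        if not np.all(np.isfinite(self.columns.to_numpy())):
            raise ValueError("design columns must be finite")


def _center(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return x - x.mean() if x.size else x


def _family(
    cols: dict[str, np.ndarray],
    families: dict[str, list[str]],
    name: str,
    onsets: np.ndarray,
    modulators: Sequence[tuple[str, np.ndarray]],
    n_volumes: int,
    tr: float,
    include_onset: bool = True,
) -> None:
    order = []
    if include_onset:
        cname = f"{name}_onset"
        cols[cname] = hrf_convolve(onsets, None, n_volumes, tr)
        order.append(cname)
    for label, values in modulators:
        cname = f"{name}_{label}"
        cols[cname] = hrf_convolve(onsets, _center(values), n_volumes, tr)
        order.append(cname)
    families[name] = order


def build_glm1(
    events: SessionModelEvents,
    n_volumes: int,
    tr: float,
    highpass_period: float = 128.0,
) -> DesignMatrix:
    """Main-effects design: entropy, choice difficulty and RPE with derivatives.

    Sequential onsets carry (in serial orthogonalization order) RT, the
    conditional probability of the current image, forward entropy, and the
    entropy derivative; choice onsets carry RT, reward value, difficulty and
    its derivative; outcome onsets carry RT, RPE and its derivative. Missed,
    error, self-transition and right-hand trials get nuisance onset columns.
    Modulators are mean-centered before convolution.
    """
    if events.seq["d_entropy"].isna().any():
        raise ValueError("derivative trace missing from the event table")
    seq = events.seq
    valid = (seq.correct & ~seq.missed & ~seq.is_outcome).to_numpy()
    sv = seq[valid]
    cols: dict[str, np.ndarray] = {}
    fams: dict[str, list[str]] = {}
    _family(
        cols, fams, "seq", sv.onset.to_numpy(),
        [
            ("rt", sv.rt.to_numpy()),
            ("p_obs", sv.p_obs.to_numpy()),
            ("entropy", sv.entropy.to_numpy()),
            ("d_entropy", sv.d_entropy.to_numpy()),
        ],
        n_volumes, tr,
    )
    ch = events.choice[~events.choice.missed]
    _family(
        cols, fams, "choice", ch.onset.to_numpy(),
        [
            ("rt", ch.rt.to_numpy()),
            ("value", ch.value.to_numpy()),
            ("difficulty", ch.difficulty.to_numpy()),
            ("d_difficulty", ch.d_difficulty.to_numpy()),
        ],
        n_volumes, tr,
    )
    oc = events.outcome
    _family(
        cols, fams, "outcome", oc.onset.to_numpy(),
        [("rt", oc.rt.to_numpy()), ("rpe", oc.rpe.to_numpy()), ("d_rpe", oc.d_rpe.to_numpy())],
        n_volumes, tr,
    )
    for label, mask in (
        ("missed", seq.missed.to_numpy()),
        ("error", (~seq.correct & ~seq.missed).to_numpy()),
        ("self", (seq.is_self & valid).to_numpy()),
        ("right_hand", (seq.right_hand & valid).to_numpy()),
    ):
        if mask.any():
            _family(cols, fams, label, seq.onset.to_numpy()[mask], [], n_volumes, tr)
    return DesignMatrix(
        columns=pd.DataFrame(cols), families=fams, policy="serial",
        tr=tr, highpass_period=highpass_period,
    )


def build_glm2(
    events: SessionModelEvents,
    n_volumes: int,
    tr: float,
    highpass_period: float = 128.0,
) -> DesignMatrix:
    """Image-specific design: per-image next probabilities and per-category difficulty.

    Nuisance onsets are specified per presented category (these span the
    sequential presentations, so no aggregate sequential onset column is
    added) and for right-hand responses; the four anticipated-probability
    modulators ride on the valid sequential onsets and the four per-category
    difficulty modulators on choice onsets. No serial orthogonalization.
    """
    seq = events.seq
    valid = (seq.correct & ~seq.missed & ~seq.is_outcome).to_numpy()
    sv = seq[valid]
    cols: dict[str, np.ndarray] = {}
    fams: dict[str, list[str]] = {}
    for c in range(4):
        mask = (seq.image == c).to_numpy()
        if mask.any():
            _family(cols, fams, f"cat{c}", seq.onset.to_numpy()[mask], [], n_volumes, tr)
    _family(
        cols, fams, "seq", sv.onset.to_numpy(),
        [("rt", sv.rt.to_numpy())]
        + [(f"p_next_{c}", sv[f"p_next_{c}"].to_numpy()) for c in range(4)],
        n_volumes, tr, include_onset=False,
    )
    ch = events.choice[~events.choice.missed]
    _family(
        cols, fams, "choice", ch.onset.to_numpy(),
        [("rt", ch.rt.to_numpy()), ("value", ch.value.to_numpy())]
        + [(f"cat_difficulty_{c}", ch[f"cat_difficulty_{c}"].to_numpy()) for c in range(4)],
        n_volumes, tr,
    )
    for label, mask in (
        ("missed", seq.missed.to_numpy()),
        ("error", (~seq.correct & ~seq.missed).to_numpy()),
        ("self", (seq.is_self & valid).to_numpy()),
        ("right_hand", (seq.right_hand & valid).to_numpy()),
    ):
        if mask.any():
            _family(cols, fams, label, seq.onset.to_numpy()[mask], [], n_volumes, tr)
    return DesignMatrix(
        columns=pd.DataFrame(cols), families=fams, policy="none",
        tr=tr, highpass_period=highpass_period,
    )


@dataclass
class GLMResult:
    """OLS coefficients for one timeseries under one design."""

    betas: pd.Series
    residual_var: float
    dof: int


def realized_design(design: DesignMatrix) -> pd.DataFrame:
    """High-pass filtered columns with the orthogonalization policy applied.

    The discrete-cosine drift basis (cutoff ``highpass_period``) is projected
    out of every column; under the serial policy each family's columns are
    then Gram-Schmidt orthogonalized in declared order, so a later column's
    inner product with any earlier column of its family is ~0.
    """
    X = design.columns.to_numpy().copy()
    names = list(design.columns.columns)
    drift = cosine_drift(X.shape[0], design.tr, design.highpass_period)
    proj = drift @ np.linalg.pinv(drift)
    X = X - proj @ X
    if design.policy == "serial":
        col_idx = {n: i for i, n in enumerate(names)}
        for fam_cols in design.families.values():
            for k in range(1, len(fam_cols)):
                j = col_idx[fam_cols[k]]
                earlier = [col_idx[c] for c in fam_cols[:k]]
                E = X[:, earlier]
                X[:, j] = X[:, j] - E @ np.linalg.lstsq(E, X[:, j], rcond=None)[0]
    return pd.DataFrame(X, columns=names)


def fit_glm(bold: np.ndarray, design: DesignMatrix) -> GLMResult:
    """High-pass filter data and design, apply the orthogonalization policy, OLS.

    Rank-deficient designs raise with the offending column named.
    """
    y = np.asarray(bold, dtype=float)
    if y.shape[0] != design.columns.shape[0]:
        raise ValueError("timeseries and design have different lengths")
    drift = cosine_drift(y.shape[0], design.tr, design.highpass_period)
    proj = drift @ np.linalg.pinv(drift)
    y = y - proj @ y
    realized = realized_design(design)
    X = realized.to_numpy()
    names = list(realized.columns)

    norms = np.linalg.norm(X, axis=0)
    scale = np.where(norms > 0, norms, 1.0)
    q, r = np.linalg.qr(X / scale)
    diag = np.abs(np.diag(r))
    bad = diag < 1e-8
    if bad.any():
        raise np.linalg.LinAlgError(
            "rank-deficient design; collinear column(s): "
            + ", ".join(np.array(names)[bad])
        )
    betas, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ betas
    dof = y.shape[0] - X.shape[1] - drift.shape[1]
    return GLMResult(
        betas=pd.Series(betas, index=names),
        residual_var=float((resid**2).sum() / max(dof, 1)),
        dof=dof,
    )


def simulate_entropy_alpha_recovery(
    behaviors: Sequence[BehaviorData],
    true_alpha: float,
    alpha0: float,
    rng: np.random.Generator,
    n_groups: int = 20,
    n_volumes: int = 400,
    tr: float = 2.37,
    noise_sd: float = 0.03,
    ar1_coef: float = 0.3,
) -> np.ndarray:
    """Recovery study: group learning-rate estimates from synthetic entropy BOLD.

    For each subject, BOLD is the HRF-convolved forward-entropy regressor
    computed at ``true_alpha`` plus AR(1) noise; the GLM is built at
    ``alpha0``. Each of ``n_groups`` replications redraws the noise and
    returns one group-level alpha_hat, so the spread across replications
    reflects measurement noise at fixed task structure.
    """
    from .cohort import BoldSpec, generate_bold  # local import avoids a cycle

    designs, regs = [], []
    for behav in behaviors:
        ev0 = model_event_table(behav, alpha0)[0]
        designs.append(build_glm1(ev0, n_volumes, tr))
        evt = model_event_table(behav, true_alpha)[0]
        m = (evt.seq.correct & ~evt.seq.missed & ~evt.seq.is_outcome).to_numpy()
        ent = evt.seq.entropy.to_numpy()[m]
        regs.append(
            hrf_convolve(evt.seq.onset.to_numpy()[m], ent - ent.mean(), n_volumes, tr)
        )
    spec = BoldSpec(
        true_alpha=true_alpha, amplitudes=(1.0,), noise_sd=noise_sd,
        tr=tr, volumes_per_scan=n_volumes, ar1_coef=ar1_coef,
    )
    alpha_hats = np.empty(n_groups)
    for g in range(n_groups):
        bm, bd = [], []
        for design, reg in zip(designs, regs):
            bold = generate_bold(reg[:, None], spec, rng)
            res = fit_glm(bold, design)
            bm.append(res.betas["seq_entropy"])
            bd.append(res.betas["seq_d_entropy"])
        alpha_hats[g] = estimate_learning_rate(bm, bd, alpha0).alpha_hat
    return alpha_hats


@dataclass
class LearningRateEstimate:
    """Group-level learning rate recovered from main/derivative coefficient pairs."""

    alpha0: float
    scale_k: float
    x_hat: np.ndarray  # per-subject transformed-space estimates
    alpha_hat: float
    sem_transformed: float
    alpha_low: float
    alpha_high: float


def estimate_learning_rate(
    beta_main: Sequence[float],
    beta_deriv: Sequence[float],
    alpha0: float,
) -> LearningRateEstimate:
    """Recover the learning rate implied by a timeseries from GLM coefficients.

    Per subject, the derivative beta is divided by the group-mean main-effect
    beta (the common scale factor k) and shifted by inv_sigmoid(alpha0); the
    group estimate is the sigmoid of the mean transformed value, with SEM
    bounds mapped through the sigmoid.
    """
    bm = np.asarray(beta_main, dtype=float)
    bd = np.asarray(beta_deriv, dtype=float)
    if bm.size != bd.size or bm.size < 2:
        raise ValueError("need paired main/derivative betas for at least 2 subjects")
    k = float(bm.mean())
    if abs(k) < 1e-12:
        raise ValueError("group-mean main-effect beta is ~0; normalizer undefined")
    x0 = float(inv_sigmoid(alpha0))
    x_hat = bd / k + x0
    mean_x = float(x_hat.mean())
    sem = float(np.std(x_hat, ddof=1) / np.sqrt(x_hat.size))
    return LearningRateEstimate(
        alpha0=float(alpha0),
        scale_k=k,
        x_hat=x_hat,
        alpha_hat=float(sigmoid(mean_x)),
        sem_transformed=sem,
        alpha_low=float(sigmoid(mean_x - sem)),
        alpha_high=float(sigmoid(mean_x + sem)),
    )


def compare_learning_rates(
    estimates: LearningRateEstimate,
    behavioral_rates: dict[str, float],
    other_regions: Optional[dict[str, LearningRateEstimate]] = None,
) -> pd.DataFrame:
    """t-tests of the transformed estimates against behavioral rates and regions.

    One-sample tests compare per-subject x_hat to each inverse-sigmoid
    behavioral rate; paired tests compare regions. All statistics are computed
    in transformed space.
    """
    x = estimates.x_hat
    if x.size < 3:
        raise ValueError("need at least 3 subjects")
    rows = []
    for name, rate in behavioral_rates.items():
        t, p = stats.ttest_1samp(x, popmean=float(inv_sigmoid(rate)))
        rows.append(("vs_" + name, float(t), float(p)))
    for name, other in (other_regions or {}).items():
        if other.x_hat.shape != x.shape:
            raise ValueError("paired region comparison needs matching subjects")
        if np.allclose(x, other.x_hat):
            rows.append(("paired_" + name, 0.0, 1.0))
        else:
            t, p = stats.ttest_rel(x, other.x_hat)
            rows.append(("paired_" + name, float(t), float(p)))
    return pd.DataFrame(rows, columns=["comparison", "t", "p"])
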