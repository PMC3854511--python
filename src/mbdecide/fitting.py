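"""Maximum-likelihood fitting, Laplace model evidence, and group statistics.

RT models (constant / one-process / two-process) are fit per subject by
maximizing the Gaussian likelihood of valid-trial RTs jointly over learning
parameters and regression coefficients; for any candidate learning rates the
coefficients and noise SD are profiled out in closed form (OLS), so the outer
optimization runs over the learning parameters only, in transformed space
(inverse-sigmoid rates, with the fast rate parameterized as slow + positive
gap to pin down the labels). Choice models optimize the Bernoulli likelihood
of observed choices over learning rate(s) and the sampling parameter.

Model evidence uses the Laplace approximation with uniform priors on bounded
parameters — log p(D|M) ~ ll* + (d/2) ln 2pi - 1/2 ln det(-H) - ln V — and
falls back to BIC-based scores for every model of a subject whose Hessian is
not positive definite at the optimum. Log Bayes factors sum over subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import optimize, stats
from scipy.special import expit
from statsmodels.tools.numdiff import approx_hess

from .behavior import MIN_VALID_TRIALS, BehaviorData, choice_prob_sampling, rt_design
from .learning import TransitionStream, inv_sigmoid, run_process, sigmoid

__all__ = [
    "FitResult",
    "ModelComparison",
    "PriorBounds",
    "fit_rt_model",
    "fit_choice_model",
    "laplace_evidence",
    "bic",
    "bic_evidence",
    "compare_models",
    "exclude_subjects",
    "fixed_effects_refit",
    "group_param_test",
]

RT_MODELS = ("constant", "one_process", "two_process")
CHOICE_MODELS = ("one_rate", "two_rate")

_CLIP = 1e-10
_ALPHA_EPS = 1e-9


def _safe_alpha(x: float) -> float:
    """Map a transformed rate to (0, 1), guarding float saturation of the sigmoid."""
    return float(np.clip(sigmoid(x), _ALPHA_EPS, 1.0 - _ALPHA_EPS))


@dataclass(frozen=True)
class PriorBounds:
    """Uniform prior ranges used by the Laplace evidence.

    Rates and the slow-process weight have the stated [0, 1] priors; the
    remaining parameters get broad uniform ranges recorded here (regression
    coefficients in ms, the RT noise SD in ms, draws/temperature unitless).
    """

    coef_halfwidth: float = 1000.0
    sigma_max: float = 500.0
    n_draws_max: float = 50.0
    beta_max: float = 50.0

    def volume_log(self, n_rates: int, n_weights: int, n_coefs: int,
                   n_sigma: int = 0, n_draws: int = 0, n_beta: int = 0) -> float:
        logv = 0.0  # rates and weights contribute ln 1 = 0
        logv += n_coefs * np.log(2.0 * self.coef_halfwidth)
        logv += n_sigma * np.log(self.sigma_max)
        logv += n_draws * np.log(self.n_draws_max)
        logv += n_beta * np.log(self.beta_max)
        return logv


@dataclass
class FitResult:
    """Outcome of one per-subject model fit."""

    model: str
    params: dict[str, float]
    loglik: float
    n_obs: int
    n_params: int
    hessian: Optional[np.ndarray]
    evidence: float
    evidence_kind: str  # "laplace" | "bic"
    converged: bool
    n_restarts_used: int
    prior_bounds: PriorBounds = field(default_factory=PriorBounds)

    @property
    def bic(self) -> float:
        return bic(self.loglik, self.n_params, self.n_obs)

    @property
    def bic_evidence(self) -> float:
        return bic_evidence(self.loglik, self.n_params, self.n_obs)


def bic(loglik: float, n_params: int, n_obs: int) -> float:
    """Bayesian Information Criterion, -2 ll + d ln n (lower is better)."""
    return -2.0 * loglik + n_params * np.log(n_obs)


def bic_evidence(loglik: float, n_params: int, n_obs: int) -> float:
    """BIC-based approximation to the log evidence: -BIC / 2."""
    return -0.5 * bic(loglik, n_params, n_obs)


def laplace_evidence(
    loglik_at_opt: float, hessian: np.ndarray, log_prior_volume: float
) -> float:
    """Laplace log evidence with uniform priors on bounded parameters.

    ``hessian`` is the Hessian of the *negative* log-likelihood at the optimum
    (so it must be positive definite). Raises LinAlgError otherwise; callers
    handle the BIC fallback.
    """
    h = np.asarray(hessian, dtype=float)
    if not np.all(np.isfinite(h)):
        raise np.linalg.LinAlgError("non-finite Hessian")
    h = 0.5 * (h + h.T)
    chol = np.linalg.cholesky(h)  # raises LinAlgError if not PD
    logdet = 2.0 * np.log(np.diag(chol)).sum()
    d = h.shape[0]
    return float(loglik_at_opt + 0.5 * d * np.log(2.0 * np.pi) - 0.5 * logdet - log_prior_volume)


# --- RT model -----------------------------------------------------------------

def _valid_mask(data: BehaviorData) -> np.ndarray:
    t = data.trials
    return (t.correct & ~t.missed).to_numpy()


def _profiled_rt_loglik(
    stream: TransitionStream,
    rts: np.ndarray,
    valid: np.ndarray,
    p_observed: Optional[np.ndarray],
) -> tuple[float, np.ndarray, float]:
    """Closed-form ML over coefficients and noise SD given the probability trace."""
    X = rt_design(stream, p_observed, include_prob=p_observed is not None)[valid]
    y = rts[valid]
    coefs, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coefs
    n = y.size
    sigma2 = max(float((resid**2).mean()), 1e-12)
    ll = -0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0)
    return float(ll), coefs, float(np.sqrt(sigma2))


def _rt_prob_trace(stream: TransitionStream, model: str, theta: np.ndarray) -> Optional[np.ndarray]:
    """Combined probability trace for transformed learning parameters ``theta``."""
    if model == "constant":
        return None
    if model == "one_process":
        return run_process(stream, _safe_alpha(theta[0])).p_observed
    x_slow, log_gap, w_logit = theta
    a_slow = _safe_alpha(x_slow)
    a_fast = _safe_alpha(x_slow + np.exp(log_gap))
    w = float(sigmoid(w_logit))
    slow = run_process(stream, a_slow).p_observed
    fast = run_process(stream, a_fast).p_observed
    return w * slow + (1.0 - w) * fast


def _rt_learning_params(model: str, theta: np.ndarray) -> dict[str, float]:
    if model == "constant":
        return {}
    if model == "one_process":
        return {"alpha": _safe_alpha(theta[0])}
    a_slow = _safe_alpha(theta[0])
    a_fast = _safe_alpha(theta[0] + np.exp(theta[1]))
    return {"alpha_slow": a_slow, "alpha_fast": a_fast, "w_slow": float(sigmoid(theta[2]))}


_RT_COEF_NAMES = ["intercept", "slope_prob", "coef_self", "img1", "img2", "img3", "coef_trial"]


def _rt_joint_negll(
    natural: np.ndarray, stream: TransitionStream, rts, valid, model: str
) -> float:
    """Joint negative log-likelihood over natural-space parameters (for the Hessian)."""
    k = {"constant": 0, "one_process": 1, "two_process": 3}[model]
    rates = natural[:k]
    if np.any(rates <= 0) or np.any(rates >= 1):
        return np.inf
    if model == "constant":
        p = None
    elif model == "one_process":
        p = run_process(stream, float(rates[0])).p_observed
    else:
        a_slow, a_fast, w = rates
        if a_slow >= a_fast:
            return np.inf
        p = w * run_process(stream, a_slow).p_observed + (1 - w) * run_process(
            stream, a_fast
        ).p_observed
    coefs = natural[k:-1]
    sigma = natural[-1]
    if sigma <= 0:
        return np.inf
    X = rt_design(stream, p, include_prob=p is not None)[valid]
    resid = rts[valid] - X @ coefs
    n = resid.size
    return float(0.5 * n * np.log(2 * np.pi * sigma**2) + 0.5 * (resid**2).sum() / sigma**2)


def _multistart(
    objective: Callable[[np.ndarray], float],
    draw_start: Callable[[np.random.Generator], np.ndarray],
    rng: np.random.Generator,
    n_restarts: int,
) -> tuple[optimize.OptimizeResult, int]:
    best = None
    used = 0
    for _ in range(max(1, n_restarts)):
        used += 1
        x0 = draw_start(rng)
        try:
            res = optimize.minimize(objective, x0, method="L-BFGS-B")
        except (np.linalg.LinAlgError, FloatingPointError):
            continue
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise RuntimeError("all optimization restarts failed")
    return best, used


def fit_rt_model(
    data: BehaviorData,
    model: str = "two_process",
    n_restarts: int = 10,
    rng: Optional[np.random.Generator] = None,
    prior_bounds: PriorBounds = PriorBounds(),
) -> FitResult:
    """Fit one RT model to a subject by maximum likelihood.

    Learning parameters are optimized in transformed space with multi-start
    L-BFGS; regression coefficients and the noise SD are profiled out exactly.
    The Laplace evidence is computed from the joint Hessian in natural space.
    """
    if model not in RT_MODELS:
        raise ValueError(f"unknown RT model {model!r}")
    rng = rng if rng is not None else np.random.default_rng(0)
    stream = data.stream
    rts = data.trials.rt.to_numpy()
    valid = _valid_mask(data)
    if valid.sum() < MIN_VALID_TRIALS:
        raise ValueError("too few valid trials to fit")

    if model == "constant":
        ll, coefs, sigma = _profiled_rt_loglik(stream, rts, valid, None)
        theta_opt = np.empty(0)
        used = 0
        converged = True
    else:
        def objective(theta: np.ndarray) -> float:
            p = _rt_prob_trace(stream, model, theta)
            ll, _, _ = _profiled_rt_loglik(stream, rts, valid, p)
            return -ll

        if model == "one_process":
            draw = lambda g: np.array([inv_sigmoid(g.uniform(0.02, 0.9))])
        else:
            draw = lambda g: np.array(
                [
                    inv_sigmoid(g.uniform(0.02, 0.4)),
                    np.log(g.uniform(0.5, 4.0)),
                    inv_sigmoid(g.uniform(0.2, 0.8)),
                ]
            )
        best, used = _multistart(objective, draw, rng, n_restarts)
        theta_opt = best.x
        converged = bool(best.success)
        p = _rt_prob_trace(stream, model, theta_opt)
        ll, coefs, sigma = _profiled_rt_loglik(stream, rts, valid, p)

    rates = _rt_learning_params(model, theta_opt)
    coef_names = _RT_COEF_NAMES if model != "constant" else [
        c for c in _RT_COEF_NAMES if c != "slope_prob"
    ]
    params = dict(rates)
    params.update(dict(zip(coef_names, coefs)))
    params["noise_sd"] = sigma

    natural = np.concatenate([list(rates.values()), coefs, [sigma]])
    d = natural.size
    n_obs = int(valid.sum())
    logv = prior_bounds.volume_log(
        n_rates=len([k for k in rates if k.startswith("alpha")]),
        n_weights=len([k for k in rates if k.startswith("w")]),
        n_coefs=len(coefs),
        n_sigma=1,
    )
    hessian: Optional[np.ndarray] = None
    try:
        hessian = approx_hess(
            natural, _rt_joint_negll, args=(stream, rts, valid, model)
        )
        evidence = laplace_evidence(ll, hessian, logv)
        kind = "laplace"
    except (np.linalg.LinAlgError, ValueError):
        evidence = bic_evidence(ll, d, n_obs)
        kind = "bic"

    return FitResult(
        model=model,
        params=params,
        loglik=ll,
        n_obs=n_obs,
        n_params=d,
        hessian=hessian,
        evidence=evidence,
        evidence_kind=kind,
        converged=converged,
        n_restarts_used=used,
        prior_bounds=prior_bounds,
    )


# --- choice model -------------------------------------------------------------

def _choice_probs_for(
    stream: TransitionStream, chose_a: np.ndarray, theta: np.ndarray, model: str, rule: str
) -> np.ndarray:
    """P(chosen option) per probe for transformed parameters ``theta``."""
    if model == "one_rate":
        alphas_w = (_safe_alpha(theta[0]), None, None)
        scale = np.exp(theta[1])
    else:
        a_slow = _safe_alpha(theta[0])
        a_fast = _safe_alpha(theta[0] + np.exp(theta[1]))
        w = float(sigmoid(theta[2]))
        alphas_w = (a_slow, a_fast, w)
        scale = np.exp(theta[3])

    a_slow, a_fast, w = alphas_w
    pg = run_process(stream, a_slow).probe_p_goal
    if a_fast is not None:
        pg = w * pg + (1.0 - w) * run_process(stream, a_fast).probe_p_goal
    idx = np.arange(stream.n_probes)
    p_a = pg[idx, stream.probe_a]
    p_b = pg[idx, stream.probe_b]
    if rule == "sampling":
        p_choose_a = choice_prob_sampling(p_a, p_b, scale)
    else:
        p_choose_a = expit(scale * stream.probe_value * (p_a - p_b))
    return np.where(chose_a, p_choose_a, 1.0 - p_choose_a)


def fit_choice_model(
    data: BehaviorData,
    model: str = "one_rate",
    rule: str = "sampling",
    n_restarts: int = 10,
    rng: Optional[np.random.Generator] = None,
    min_choices: int = 20,
    prior_bounds: PriorBounds = PriorBounds(),
) -> FitResult:
    """Fit a choice model (learning rate(s) plus n_draws or softmax beta)."""
    if model not in CHOICE_MODELS:
        raise ValueError(f"unknown choice model {model!r}")
    rng = rng if rng is not None else np.random.default_rng(0)
    stream = data.stream
    keep = ~data.choices.missed.to_numpy()
    if keep.sum() < min_choices:
        raise ValueError(f"need at least {min_choices} entered choices")
    chose_a = data.choices.chose_a.to_numpy()
    degenerate = bool(chose_a[keep].all() or (~chose_a[keep]).all())

    def objective(theta: np.ndarray) -> float:
        p = _choice_probs_for(stream, chose_a, theta, model, rule)[keep]
        p = np.clip(p, _CLIP, 1.0 - _CLIP)
        return -float(np.log(p).sum())

    if model == "one_rate":
        draw = lambda g: np.array(
            [inv_sigmoid(g.uniform(0.02, 0.6)), np.log(g.uniform(1.0, 12.0))]
        )
    else:
        draw = lambda g: np.array(
            [
                inv_sigmoid(g.uniform(0.02, 0.4)),
                np.log(g.uniform(0.5, 4.0)),
                inv_sigmoid(g.uniform(0.2, 0.8)),
                np.log(g.uniform(1.0, 12.0)),
            ]
        )
    best, used = _multistart(objective, draw, rng, n_restarts)
    theta = best.x
    ll = -float(best.fun)

    scale_name = "n_draws" if rule == "sampling" else "softmax_beta"
    if model == "one_rate":
        params = {"alpha": _safe_alpha(theta[0]), scale_name: float(np.exp(theta[1]))}
        natural = np.array([params["alpha"], params[scale_name]])
        n_rates, n_weights = 1, 0
    else:
        params = {
            "alpha_slow": _safe_alpha(theta[0]),
            "alpha_fast": _safe_alpha(theta[0] + np.exp(theta[1])),
            "w_slow": float(sigmoid(theta[2])),
            scale_name: float(np.exp(theta[3])),
        }
        natural = np.array(
            [params["alpha_slow"], params["alpha_fast"], params["w_slow"], params[scale_name]]
        )
        n_rates, n_weights = 2, 1

    def negll_natural(nat: np.ndarray) -> float:
        if np.any(nat[:-1] <= 0) or np.any(nat[: n_rates + n_weights] >= 1) or nat[-1] <= 0:
            return np.inf
        if model == "one_rate":
            th = np.array([inv_sigmoid(nat[0]), np.log(nat[1])])
        else:
            if nat[0] >= nat[1]:
                return np.inf
            th = np.array(
                [
                    inv_sigmoid(nat[0]),
                    np.log(inv_sigmoid(nat[1]) - inv_sigmoid(nat[0])),
                    inv_sigmoid(nat[2]),
                    np.log(nat[3]),
                ]
            )
        return objective(th)

    n_obs = int(keep.sum())
    d = natural.size
    logv = prior_bounds.volume_log(
        n_rates=n_rates,
        n_weights=n_weights,
        n_coefs=0,
        n_draws=1 if rule == "sampling" else 0,
        n_beta=0 if rule == "sampling" else 1,
    )
    hessian: Optional[np.ndarray] = None
    try:
        hessian = approx_hess(natural, negll_natural)
        evidence = laplace_evidence(ll, hessian, logv)
        kind = "laplace"
    except (np.linalg.LinAlgError, ValueError):
        evidence = bic_evidence(ll, d, n_obs)
        kind = "bic"

    params["degenerate_choices"] = float(degenerate)
    return FitResult(
        model=model,
        params=params,
        loglik=ll,
        n_obs=n_obs,
        n_params=d,
        hessian=hessian,
        evidence=evidence,
        evidence_kind=kind,
        converged=bool(best.success),
        n_restarts_used=used,
        prior_bounds=prior_bounds,
    )


# --- model comparison, exclusion, group stats ---------------------------------

@dataclass
class ModelComparison:
    """Per-subject and summed log Bayes factors for model A over model B."""

    model_a: str
    model_b: str
    per_subject: np.ndarray
    winners: list[str]

    @property
    def summed(self) -> float:
        return float(self.per_subject.sum())


def compare_models(
    fits_a: Sequence[FitResult], fits_b: Sequence[FitResult]
) -> ModelComparison:
    """Log Bayes factors of model A over model B across subjects.

    If either model's Laplace evidence failed for a subject, BIC-based scores
    are used for both models of that subject (never a mixed comparison).
    """
    if len(fits_a) != len(fits_b):
        raise ValueError("need one fit per model per subject")
    lbf = []
    winners = []
    for fa, fb in zip(fits_a, fits_b):
        if fa.evidence_kind == "laplace" and fb.evidence_kind == "laplace":
            ea, eb = fa.evidence, fb.evidence
        else:
            ea, eb = fa.bic_evidence, fb.bic_evidence
        lbf.append(ea - eb)
        winners.append(fa.model if ea >= eb else fb.model)
    return ModelComparison(
        model_a=fits_a[0].model,
        model_b=fits_b[0].model,
        per_subject=np.array(lbf),
        winners=winners,
    )


def exclude_subjects(
    constant_fits: Sequence[FitResult],
    candidate_fits: Sequence[Sequence[FitResult]],
) -> tuple[list[int], list[int]]:
    """Split subjects into (kept, excluded) by the constant-model criterion.

    A subject is excluded when the nuisance-only RT model has a lower BIC than
    every candidate model that includes the learned-probability regressor.
    """
    if len(candidate_fits) == 0:
        raise ValueError("need at least one candidate model")
    n = len(constant_fits)
    if any(len(c) != n for c in candidate_fits):
        raise ValueError("every model needs one fit per subject")
    kept, excluded = [], []
    for s in range(n):
        const_bic = constant_fits[s].bic
        if all(candidate_fits[m][s].bic > const_bic for m in range(len(candidate_fits))):
            excluded.append(s)
        else:
            kept.append(s)
    return kept, excluded


def fixed_effects_refit(
    datasets: Sequence[BehaviorData],
    kind: str = "rt",
    model: str = "two_process",
    rule: str = "sampling",
    n_restarts: int = 10,
    rng: Optional[np.random.Generator] = None,
) -> dict[str, float]:
    """One shared learning-parameter vector maximizing the pooled likelihood.

    Regression coefficients (RT) are likewise shared, estimated by pooled OLS
    given the shared rates. Used to generate imaging regressors from a single
    common baseline.
    """
    if not datasets:
        raise ValueError("need at least one dataset")
    rng = rng if rng is not None else np.random.default_rng(0)

    if kind == "rt":
        streams = [d.stream for d in datasets]
        rts = [d.trials.rt.to_numpy() for d in datasets]
        valids = [_valid_mask(d) for d in datasets]

        def objective(theta: np.ndarray) -> float:
            Xs, ys = [], []
            for st, r, v in zip(streams, rts, valids):
                p = _rt_prob_trace(st, model, theta)
                Xs.append(rt_design(st, p, include_prob=p is not None)[v])
                ys.append(r[v])
            X = np.vstack(Xs)
            y = np.concatenate(ys)
            coefs, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ coefs
            sigma2 = max(float((resid**2).mean()), 1e-12)
            return 0.5 * y.size * (np.log(2 * np.pi * sigma2) + 1.0)

        if model == "one_process":
            draw = lambda g: np.array([inv_sigmoid(g.uniform(0.02, 0.9))])
        else:
            draw = lambda g: np.array(
                [
                    inv_sigmoid(g.uniform(0.02, 0.4)),
                    np.log(g.uniform(0.5, 4.0)),
                    inv_sigmoid(g.uniform(0.2, 0.8)),
                ]
            )
        best, _ = _multistart(objective, draw, rng, n_restarts)
        out = _rt_learning_params(model, best.x)
        out["loglik"] = -float(best.fun)
        return out

    if kind != "choice":
        raise ValueError("kind must be 'rt' or 'choice'")

    streams = [d.stream for d in datasets]
    chose = [d.choices.chose_a.to_numpy() for d in datasets]
    keeps = [~d.choices.missed.to_numpy() for d in datasets]

    def objective(theta: np.ndarray) -> float:
        total = 0.0
        for st, ch, kp in zip(streams, chose, keeps):
            p = _choice_probs_for(st, ch, theta, model, rule)[kp]
            total -= float(np.log(np.clip(p, _CLIP, 1 - _CLIP)).sum())
        return total

    if model == "one_rate":
        draw = lambda g: np.array(
            [inv_sigmoid(g.uniform(0.02, 0.6)), np.log(g.uniform(1.0, 12.0))]
        )
    else:
        draw = lambda g: np.array(
            [
                inv_sigmoid(g.uniform(0.02, 0.4)),
                np.log(g.uniform(0.5, 4.0)),
                inv_sigmoid(g.uniform(0.2, 0.8)),
                np.log(g.uniform(1.0, 12.0)),
            ]
        )
    best, _ = _multistart(objective, draw, rng, n_restarts)
    theta = best.x
    scale_name = "n_draws" if rule == "sampling" else "softmax_beta"
    if model == "one_rate":
        out = {"alpha": _safe_alpha(theta[0]), scale_name: float(np.exp(theta[1]))}
    else:
        out = {
            "alpha_slow": _safe_alpha(theta[0]),
            "alpha_fast": _safe_alpha(theta[0] + np.exp(theta[1])),
            "w_slow": float(sigmoid(theta[2])),
            scale_name: float(np.exp(theta[3])),
        }
    out["loglik"] = -float(best.fun)
    return out


def group_param_test(
    estimates: Sequence[float],
    reference: float = 0.0,
    paired_with: Optional[Sequence[float]] = None,
) -> tuple[float, float]:
    """One-sample (or paired) two-tailed t-test on per-subject estimates."""
    x = np.asarray(estimates, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 subjects")
    if paired_with is not None:
        y = np.asarray(paired_with, dtype=float)
        if y.shape != x.shape:
            raise ValueError("paired samples must have equal length")
        d = x - y
        if np.allclose(d, d[0]) and np.isclose(d[0], 0.0):
            return 0.0, 1.0
        if np.std(d, ddof=1) == 0:
            raise ValueError("zero variance in paired differences")
        t, p = stats.ttest_rel(x, y)
        return float(t), float(p)
    if np.allclose(x, reference):
        return 0.0, 1.0
    if np.std(x, ddof=1) == 0:
        raise ValueError("zero variance across subjects")
    t, p = stats.ttest_1samp(x, popmean=reference)
    return float(t), float(p)
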