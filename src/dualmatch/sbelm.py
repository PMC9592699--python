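"""Sparse Bayesian extreme learning machine (ELM) and bagging ensemble.

An ELM projects raw features through a fixed random hidden layer
(weights and biases drawn once from a standard normal) and learns only
the hidden-to-output weights w.  Here w carries an automatic relevance
determination (ARD) prior: an independent zero-mean Gaussian per weight
with precision alpha_i, plus Gaussian observation noise with precision
beta.  Binary labels are treated as {0, 1} regression targets under the
Gaussian likelihood; scores are thresholded at 0.5.

With A = diag(alpha) the posterior over w is Gaussian with

    Sigma = (A + beta X^T X)^{-1},       m = beta Sigma X^T t,

and evidence maximization iterates the classical ARD re-estimates

    gamma_i = 1 - alpha_i Sigma_ii,
    alpha_i <- gamma_i / m_i^2,
    beta^{-1} <- ||t - X m||^2 / (N - sum_i gamma_i),

until the weight vector stops moving.  Weights whose alpha reaches
alpha_max are pruned (posterior pinned at zero), which is what makes the
model sparse.

The ensemble bags M such machines on bootstrap subsets and feeds their
continuous scores, as the hidden-layer output, to one more sparse Bayes
fit that acts as the combiner.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg


@dataclass
class SBELMConfig:
    hidden_width: int = 100
    activation: str = "sigmoid"       # "sigmoid" | "linear" | "identity"
    alpha_init: float = 1.0
    beta_init: float | None = None    # default 1/var(t)
    alpha_max: float = 1e8
    beta_max: float = 1e10
    max_iter: int = 300
    tol: float = 1e-6
    rho: float = 0.0                  # l1 coefficient, recorded as metadata only
    seed: int = 0


@dataclass
class ELMModel:
    """Fixed random hidden layer plus the ARD posterior over output weights."""

    w_in: np.ndarray | None           # (D_raw, L_h); None for identity hidden
    b_in: np.ndarray | None
    activation: str
    m: np.ndarray | None = None       # posterior mean = w-hat after fit
    sigma: np.ndarray | None = None   # posterior covariance
    alpha: np.ndarray | None = None
    beta: float | None = None
    config: SBELMConfig | None = None
    fitted: bool = False

    @property
    def pruned(self) -> np.ndarray:
        if self.alpha is None:
            raise ValueError("model not fitted")
        return self.alpha >= self.config.alpha_max


@dataclass
class FitTrace:
    log_evidence: list = field(default_factory=list)
    converged: bool = False


@dataclass
class EnsembleModel:
    bases: list
    bag_indices: list
    combiner: ELMModel


# --------------------------------------------------------------- hidden

def init_hidden(d_raw: int, config: SBELMConfig) -> ELMModel:
    if config.activation == "identity":
        return ELMModel(w_in=None, b_in=None, activation="identity",
                        config=config)
    rng = np.random.default_rng(config.seed)
    w = rng.standard_normal((d_raw, config.hidden_width))
    b = rng.standard_normal(config.hidden_width)
    return ELMModel(w_in=w, b_in=b, activation=config.activation, config=config)


def hidden_output(raw: np.ndarray, model: ELMModel) -> np.ndarray:
    """Design matrix X (N x L_h): activation(raw @ W_in + b_in)."""
    raw = np.asarray(raw, dtype=float)
    if model.activation == "identity":
        return raw
    if raw.shape[1] != model.w_in.shape[0]:
        raise ValueError(
            f"feature count {raw.shape[1]} does not match init {model.w_in.shape[0]}")
    z = raw @ model.w_in + model.b_in
    if model.activation == "sigmoid":
        return 1.0 / (1.0 + np.exp(-z))
    if model.activation == "linear":
        return z
    raise ValueError(f"unknown activation {model.activation!r}")


# -------------------------------------------------------------- posterior

def posterior(x: np.ndarray, t: np.ndarray, alpha: np.ndarray, beta: float):
    """Gaussian posterior of the output weights:
    Sigma = (A + beta X^T X)^{-1}, m = beta Sigma X^T t, via an SPD solve."""
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(t))):
        raise ValueError("non-finite design or targets")
    if np.any(np.asarray(alpha) <= 0) or beta <= 0:
        raise ValueError("alpha and beta must be positive")
    a = np.atleast_1d(np.asarray(alpha, dtype=float))
    prec = np.diag(a) + beta * (x.T @ x)
    try:
        cho = linalg.cho_factor(prec, lower=True)
    except np.linalg.LinAlgError:
        # near-singular at extreme beta: regularize relative to scale
        jitter = 1e-10 * max(np.trace(prec) / len(a), 1.0)
        cho = linalg.cho_factor(prec + jitter * np.eye(len(a)), lower=True)
    sigma = linalg.cho_solve(cho, np.eye(len(a)))
    m = beta * (sigma @ (x.T @ t))
    return m, sigma


def log_evidence(x, t, alpha, beta, m, sigma) -> float:
    """Log marginal likelihood
    (sum ln alpha + N ln beta + ln|Sigma| - beta||t-Xm||^2 - m^T A m
     - N ln 2pi) / 2."""
    a = np.atleast_1d(np.asarray(alpha, dtype=float))
    n = len(t)
    prec = np.diag(a) + beta * (x.T @ x)
    sign, logdet_prec = np.linalg.slogdet(prec)
    if sign <= 0:
        raise ValueError("posterior precision not positive definite")
    resid = t - x @ m
    return 0.5 * (np.log(a).sum() + n * np.log(beta) - logdet_prec
                  - beta * (resid @ resid) - m @ (a * m) - n * np.log(2 * np.pi))


def update_hyperparams(m, sigma, x, t, alpha, alpha_max: float = 1e8):
    """ARD re-estimates: gamma_i = 1 - alpha_i Sigma_ii,
    alpha_new = gamma_i / m_i^2 (capped at alpha_max; exact zeros prune),
    beta_new = (N - sum gamma) / ||t - Xm||^2."""
    a = np.atleast_1d(np.asarray(alpha, dtype=float))
    gamma = 1.0 - a * np.diag(sigma)
    n = len(t)
    if n <= gamma.sum():
        raise ValueError("degenerate noise update: N <= sum(gamma)")
    m = np.asarray(m, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_new = np.where(np.abs(m) > 0,
                             gamma / np.maximum(m ** 2, 1e-300), alpha_max)
    alpha_new = np.clip(alpha_new, 1e-12, alpha_max)
    resid = t - x @ m
    rss = float(resid @ resid)
    beta_new = (n - gamma.sum()) / max(rss, 1e-300)
    return alpha_new, float(beta_new), gamma


# ------------------------------------------------------------------ fit

def fit_sbelm(raw: np.ndarray, t: np.ndarray, config: SBELMConfig | None = None):
    """Fit a sparse Bayes ELM by alternating posterior / hyperparameter
    updates until ||w_new - w||_inf < tol or max_iter; returns
    (ELMModel, FitTrace).  Non-convergence leaves the flag unset rather
    than raising."""
    config = config or SBELMConfig()
    raw = np.asarray(raw, dtype=float)
    t = np.asarray(t, dtype=float)
    if raw.shape[0] < 2:
        raise ValueError("need at least two samples")
    model = init_hidden(raw.shape[1], config)
    x = hidden_output(raw, model)
    d = x.shape[1]
    alpha = np.full(d, config.alpha_init, dtype=float)
    var_t = t.var()
    beta = config.beta_init if config.beta_init is not None else 1.0 / max(var_t, 1e-9)
    trace = FitTrace()
    m_prev = np.zeros(d)
    for _ in range(config.max_iter):
        m, sigma = posterior(x, t, alpha, beta)
        trace.log_evidence.append(log_evidence(x, t, alpha, beta, m, sigma))
        if np.max(np.abs(m - m_prev)) < config.tol:
            trace.converged = True
            break
        m_prev = m
        try:
            alpha, beta, _ = update_hyperparams(m, sigma, x, t, alpha,
                                                config.alpha_max)
            beta = min(beta, config.beta_max)
        except ValueError:
            break
    model.m = np.where(alpha >= config.alpha_max, 0.0, m)
    model.sigma = sigma
    model.alpha = alpha
    model.beta = float(beta)
    model.fitted = True
    return model, trace


def predict(model: ELMModel, raw: np.ndarray) -> np.ndarray:
    """Real-valued scores X w-hat; threshold at 0.5 for a class decision."""
    if not model.fitted:
        raise ValueError("model is not fitted")
    return hidden_output(np.asarray(raw, dtype=float), model) @ model.m


# -------------------------------------------------------------- ensemble

def fit_ensemble(raw: np.ndarray, t: np.ndarray, m_bases: int = 10,
                 bag_fraction: float = 1.0,
                 config: SBELMConfig | None = None) -> EnsembleModel:
    """Bag ``m_bases`` sparse Bayes ELMs on bootstrap subsets (sampling
    with replacement, size bag_fraction * N) and fit a sparse Bayes
    combiner on the N x M matrix of base scores."""
    if m_bases < 1:
        raise ValueError("need at least one base model")
    config = config or SBELMConfig()
    raw = np.asarray(raw, dtype=float)
    t = np.asarray(t, dtype=float)
    n = raw.shape[0]
    size = max(2, int(round(bag_fraction * n)))
    rng = np.random.default_rng(config.seed)
    bases, bags = [], []
    for b in range(m_bases):
        for attempt in range(10):
            idx = rng.integers(0, n, size=size)
            if len(np.unique(t[idx])) > 1:
                break
        else:
            raise ValueError("could not draw a two-class bootstrap subset")
        base_cfg = SBELMConfig(**{**vars(config), "seed": config.seed + 1000 + b})
        base, _ = fit_sbelm(raw[idx], t[idx], base_cfg)
        bases.append(base)
        bags.append(idx)
    scores = np.column_stack([predict(b, raw) for b in bases])
    comb_cfg = SBELMConfig(**{**vars(config), "activation": "identity",
                              "seed": config.seed + 99})
    combiner, _ = fit_sbelm(scores, t, comb_cfg)
    return EnsembleModel(bases=bases, bag_indices=bags, combiner=combiner)


def predict_ensemble(ensemble: EnsembleModel, raw: np.ndarray) -> np.ndarray:
    """Base scores -> combiner score."""
    scores = np.column_stack([predict(b, raw) for b in ensemble.bases])
    return predict(ensemble.combiner, scores)
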