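"""Interpersonal Gaussian mixture (Inter-GM).

Two agents share one latent sign s_n per object.  Each agent * in {A, B}
owns a sign-to-category table Theta* (L rows, each a categorical over K
categories with Dirichlet(alpha) prior), per-category Gaussian parameters
Phi* = {(mu_k, Lambda_k)} with a normal-Wishart prior, a categorization
c_n* ~ Cat(theta_{s_n}), and an observation x_n* ~ N(mu_{c_n}, Lambda_{c_n}^-1).

Inference is by Gibbs sampling of the conjugate full conditionals.  Signs are
*not* resampled here: in the naming game they are only exchanged through
speaker proposals and Metropolis-Hastings acceptance (see :mod:`mhng.game`).

All density work is done in log space with Cholesky factorizations; sampled
precision matrices are symmetric positive definite by construction and every
sampled Theta row is stochastic (Dirichlet draws).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import wishart

__all__ = [
    "Hyperparameters",
    "AgentState",
    "sample_generative",
    "category_likelihood",
    "gibbs_conditional_theta",
    "gibbs_conditional_phi",
    "gibbs_conditional_c",
    "gibbs_sweep",
]

_DIM = 3  # stimuli live in L*u*v*


@dataclass(frozen=True)
class Hyperparameters:
    """Priors of the Inter-GM.

    Defaults are the study configuration: K = L = 5 categories/signs,
    alpha = 0.1 per category, beta = 1, m = (50, 0, 0),
    W^-1 = diag(200, 200, 200), uniform sign prior pi.  The Wishart degrees
    of freedom nu default to dim + 1 = 4, the smallest integer giving a
    finite prior mean precision.
    """

    K: int = 5
    L: int = 5
    alpha: np.ndarray = None  # type: ignore[assignment]
    beta: float = 1.0
    m: np.ndarray = None  # type: ignore[assignment]
    W: np.ndarray = None  # type: ignore[assignment]
    nu: float = 4.0
    pi: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        a = np.full(self.K, 0.1) if self.alpha is None else np.asarray(self.alpha, float)
        m = np.array([50.0, 0.0, 0.0]) if self.m is None else np.asarray(self.m, float)
        W = np.diag([1 / 200.0] * _DIM) if self.W is None else np.asarray(self.W, float)
        pi = np.full(self.L, 1.0 / self.L) if self.pi is None else np.asarray(self.pi, float)
        if a.shape != (self.K,) or np.any(a <= 0):
            raise ValueError("alpha must be a length-K vector of positive entries")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if m.shape != (_DIM,):
            raise ValueError("m must be a 3-vector")
        if W.shape != (_DIM, _DIM) or not np.allclose(W, W.T):
            raise ValueError("W must be a symmetric 3x3 matrix")
        if np.any(np.linalg.eigvalsh(W) <= 0):
            raise ValueError("W must be positive definite")
        if self.nu <= _DIM - 1:
            raise ValueError("nu must exceed dim - 1")
        if pi.shape != (self.L,) or np.any(pi < 0) or not np.isclose(pi.sum(), 1.0):
            raise ValueError("pi must be a length-L probability vector")
        object.__setattr__(self, "alpha", a)
        object.__setattr__(self, "m", m)
        object.__setattr__(self, "W", W)
        object.__setattr__(self, "pi", pi)

    def to_dict(self) -> dict:
        return {
            "K": self.K,
            "L": self.L,
            "alpha": self.alpha.tolist(),
            "beta": float(self.beta),
            "m": self.m.tolist(),
            "W": self.W.tolist(),
            "nu": float(self.nu),
            "pi": self.pi.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Hyperparameters":
        return cls(**{k: d[k] for k in ("K", "L", "alpha", "beta", "m", "W", "nu", "pi") if k in d})


@dataclass
class AgentState:
    """One agent's categorization, sign assignments and parameters."""

    c: np.ndarray  # (N,) category indices
    s: np.ndarray  # (N,) sign indices
    theta: np.ndarray  # (L, K) row-stochastic
    mu: np.ndarray  # (K, 3)
    lam: np.ndarray  # (K, 3, 3) precisions

    def validate(self, hyper: Hyperparameters) -> None:
        if len(self.c) != len(self.s):
            raise ValueError("c and s must have equal length")
        if self.theta.shape != (hyper.L, hyper.K):
            raise ValueError("theta must be (L, K)")
        if not np.allclose(self.theta.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("theta rows must sum to 1")
        for k in range(hyper.K):
            if not np.allclose(self.lam[k], self.lam[k].T):
                raise ValueError("precision matrices must be symmetric")
            if np.any(np.linalg.eigvalsh(self.lam[k]) <= 0):
                raise ValueError("precision matrices must be positive definite")

    def copy(self) -> "AgentState":
        return AgentState(
            c=self.c.copy(), s=self.s.copy(), theta=self.theta.copy(),
            mu=self.mu.copy(), lam=self.lam.copy(),
        )

    def to_dict(self) -> dict:
        return {
            "c": self.c.tolist(), "s": self.s.tolist(), "theta": self.theta.tolist(),
            "mu": self.mu.tolist(), "lam": self.lam.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AgentState":
        return cls(
            c=np.asarray(d["c"], int), s=np.asarray(d["s"], int),
            theta=np.asarray(d["theta"], float), mu=np.asarray(d["mu"], float),
            lam=np.asarray(d["lam"], float),
        )


# ---------------------------------------------------------------------------
# prior sampling

def sample_prior_theta(hyper: Hyperparameters, rng: np.random.Generator) -> np.ndarray:
    return rng.dirichlet(hyper.alpha, size=hyper.L)


def sample_prior_phi(hyper: Hyperparameters, rng: np.random.Generator):
    """Draw K (mu_k, Lambda_k) pairs from the normal-Wishart prior."""
    mu = np.empty((hyper.K, _DIM))
    lam = np.empty((hyper.K, _DIM, _DIM))
    for k in range(hyper.K):
        lam[k] = wishart.rvs(df=hyper.nu, scale=hyper.W, random_state=rng)
        cov = np.linalg.inv(hyper.beta * lam[k])
        mu[k] = rng.multivariate_normal(hyper.m, cov, method="cholesky")
    return mu, lam


def sample_generative(hyper: Hyperparameters, n_items: int, seed: int):
    """Sample the full generative process for a pair of agents.

    Returns ``(s, state_A, state_B, x_A, x_B)``: the shared signs, the two
    agent states, and each agent's observations.
    """
    from .random import derive_rng

    rng = derive_rng(seed, "generative")
    s = rng.choice(hyper.L, size=n_items, p=hyper.pi)
    out_states, out_x = [], []
    for _agent in ("A", "B"):
        theta = sample_prior_theta(hyper, rng)
        mu, lam = sample_prior_phi(hyper, rng)
        c = np.array([rng.choice(hyper.K, p=theta[s[n]]) for n in range(n_items)])
        x = np.empty((n_items, _DIM))
        for n in range(n_items):
            cov = np.linalg.inv(lam[c[n]])
            x[n] = rng.multivariate_normal(mu[c[n]], cov, method="cholesky")
        out_states.append(AgentState(c=c, s=s.copy(), theta=theta, mu=mu, lam=lam))
        out_x.append(x)
    return s, out_states[0], out_states[1], out_x[0], out_x[1]


# ---------------------------------------------------------------------------
# likelihood and Gibbs conditionals

def category_likelihood(theta: np.ndarray, sign: int, category: int) -> float:
    """P(c | Theta, s): probability of ``category`` under sign ``sign``."""
    theta = np.asarray(theta)
    L, K = theta.shape
    if not (0 <= sign < L) or not (0 <= category < K):
        raise IndexError(f"sign {sign} or category {category} out of range ({L}, {K})")
    return float(theta[sign, category])


def sign_category_counts(c: np.ndarray, s: np.ndarray, L: int, K: int) -> np.ndarray:
    """(L, K) table of item counts by (sign, category)."""
    c = np.asarray(c, int)
    s = np.asarray(s, int)
    if c.shape != s.shape:
        raise ValueError("c and s must have equal length")
    counts = np.zeros((L, K))
    np.add.at(counts, (s, c), 1.0)
    return counts


def gibbs_conditional_theta(
    c: np.ndarray, s: np.ndarray, alpha: np.ndarray, L: int, K: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample Theta rows from Dirichlet(alpha + per-sign category counts)."""
    counts = sign_category_counts(c, s, L, K)
    theta = np.empty((L, K))
    for l in range(L):
        theta[l] = rng.dirichlet(alpha + counts[l])
    return theta


def posterior_mean_theta(c, s, alpha, L, K) -> np.ndarray:
    """Posterior-mean estimate (alpha_k + n_lk) / (sum alpha + n_l) per row."""
    counts = sign_category_counts(c, s, L, K)
    num = alpha[None, :] + counts
    return num / num.sum(axis=1, keepdims=True)


def normal_wishart_posterior(x_k: np.ndarray, hyper: Hyperparameters):
    """Closed-form posterior (m_n, beta_n, nu_n, W_n) given component data."""
    n = len(x_k)
    if n == 0:
        return hyper.m, hyper.beta, hyper.nu, hyper.W
    xbar = x_k.mean(axis=0)
    diff = x_k - xbar
    scatter = diff.T @ diff
    beta_n = hyper.beta + n
    m_n = (hyper.beta * hyper.m + n * xbar) / beta_n
    nu_n = hyper.nu + n
    dm = (xbar - hyper.m)[:, None]
    W_inv_n = np.linalg.inv(hyper.W) + scatter + (hyper.beta * n / beta_n) * (dm @ dm.T)
    W_n = np.linalg.inv(W_inv_n)
    W_n = 0.5 * (W_n + W_n.T)
    return m_n, beta_n, nu_n, W_n


def gibbs_conditional_phi(
    x: np.ndarray, c: np.ndarray, hyper: Hyperparameters, rng: np.random.Generator,
):
    """Sample all (mu_k, Lambda_k) from their normal-Wishart full conditionals.

    Components with no assigned items are drawn from the prior.
    """
    x = np.asarray(x, float)
    c = np.asarray(c, int)
    mu = np.empty((hyper.K, _DIM))
    lam = np.empty((hyper.K, _DIM, _DIM))
    for k in range(hyper.K):
        m_n, beta_n, nu_n, W_n = normal_wishart_posterior(x[c == k], hyper)
        lam_k = wishart.rvs(df=nu_n, scale=W_n, random_state=rng)
        lam[k] = 0.5 * (lam_k + lam_k.T)
        mu[k] = rng.multivariate_normal(m_n, np.linalg.inv(beta_n * lam[k]), method="cholesky")
    return mu, lam


def _log_gauss(x: np.ndarray, mu: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """log N(x | mu_k, Lambda_k^-1) for one x against all K components."""
    K = len(mu)
    out = np.empty(K)
    for k in range(K):
        chol = np.linalg.cholesky(lam[k])
        d = chol.T @ (x - mu[k])
        logdet = 2.0 * np.sum(np.log(np.diag(chol)))
        out[k] = 0.5 * (logdet - _DIM * np.log(2 * np.pi) - d @ d)
    return out


def gibbs_conditional_c(
    x_n: np.ndarray, s_n: int, theta: np.ndarray, mu: np.ndarray, lam: np.ndarray,
) -> np.ndarray:
    """Normalized P(c_n = k) ∝ theta[s_n, k] * N(x_n | mu_k, Lambda_k^-1)."""
    with np.errstate(divide="ignore"):
        logp = np.log(theta[s_n]) + _log_gauss(np.asarray(x_n, float), mu, lam)
    finite = logp[np.isfinite(logp)]
    if finite.size == 0:
        raise FloatingPointError("all categories have zero posterior mass (underflow)")
    logp = logp - finite.max()
    p = np.exp(np.clip(logp, -700, 0))
    total = p.sum()
    if total <= 0 or not np.isfinite(total):
        raise FloatingPointError("category posterior underflowed")
    return p / total


def gibbs_sweep(
    state: AgentState, x: np.ndarray, hyper: Hyperparameters, rng: np.random.Generator,
) -> AgentState:
    """One full Gibbs scan: resample every c_n, then Theta, then Phi.

    Signs are held fixed; they belong to the game, not the sampler.
    """
    new = state.copy()
    n_items = len(new.c)
    for n in range(n_items):
        p = gibbs_conditional_c(x[n], new.s[n], new.theta, new.mu, new.lam)
        new.c[n] = rng.choice(hyper.K, p=p)
    new.theta = gibbs_conditional_theta(new.c, new.s, hyper.alpha, hyper.L, hyper.K, rng)
    new.mu, new.lam = gibbs_conditional_phi(x, new.c, hyper, rng)
    return new


def init_agent_state(
    hyper: Hyperparameters, x: np.ndarray, rng: np.random.Generator,
    n_init_sweeps: int = 1,
) -> AgentState:
    """Prior-draw parameters, sample signs from pi, categorize, then sweep.

    Stands in for a participant's initial manual categorization: parameters
    come from the prior, each item gets a provisional sign from Cat(pi), the
    categorization is sampled from its conditional, and ``n_init_sweeps``
    perception sweeps settle the state.  Finally each item's sign is reset to
    the agent's own most probable sign for its category,
    argmax_l pi_l * theta[l, c_n] (ties to the lowest index).
    """
    n_items = len(x)
    theta = sample_prior_theta(hyper, rng)
    mu, lam = sample_prior_phi(hyper, rng)
    s = rng.choice(hyper.L, size=n_items, p=hyper.pi)
    c = np.empty(n_items, dtype=int)
    state = AgentState(c=c, s=s, theta=theta, mu=mu, lam=lam)
    for n in range(n_items):
        p = gibbs_conditional_c(x[n], s[n], theta, mu, lam)
        c[n] = rng.choice(hyper.K, p=p)
    for _ in range(n_init_sweeps):
        state = gibbs_sweep(state, x, hyper, rng)
    weights = hyper.pi[:, None] * state.theta  # (L, K)
    state.s = weights[:, state.c].argmax(axis=0)
    return state
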