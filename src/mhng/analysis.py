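"""Behavioral analysis: r_MH inference, the biased-Bernoulli test, and the
five-model precision comparison.

Test 1 (is acceptance behavior predicted by r_MH?).  Per trial n a listener
accepted (z_n = 1) or rejected (z_n = 0) a proposed name.  A biased Bernoulli
model Bern(z_n | a * r_n_MH + b) is fitted by bounded maximum likelihood
(0 <= b, a + b <= 1).  The null "acceptance is constant" is tested by a
randomization scheme: decisions are redrawn 1,000 times from Bern(b_bar)
with b_bar the observed acceptance rate, the slope is refitted each time,
and the one-sided empirical p-value is the fraction of null slopes >= the
observed slope.

Test 2 (does the MH model beat heuristic alternatives?).  For each response
model, 100 pseudo-decision replicates are drawn from the model's per-trial
probabilities; each replicate's precision is its agreement rate with the
human decisions.  Ordered model pairs are compared with one-sided
Mann-Whitney U-tests at significance level 0.001.

The MLE is computed by deterministic adaptive grid refinement of the
log-likelihood over the feasible polytope.  The log-likelihood
sum z log(a r + b) + (1 - z) log(1 - a r - b) is concave in (a, b) (each term
is the log of an affine function), so refining around the grid argmax
converges to the global optimum; the search is vectorized across replicate
decision streams, which is what makes the 1,000-replicate null cheap.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .game import GameLog
from .intergm import Hyperparameters, posterior_mean_theta, sign_category_counts
from .participants import MODEL_NAMES, BehaviorModelSpec, response_probability
from .random import derive_rng

__all__ = [
    "BehaviorLog",
    "game_log_to_behavior_logs",
    "infer_rmh_for_log",
    "fit_biased_bernoulli",
    "randomization_test_a",
    "model_precision",
    "pairwise_u_tests",
    "report_tables",
    "AnalysisResult",
]

# slope floor: admits the slightly negative boundary estimates that bounded
# optimization produces for always-accept participants, while keeping
# predicted rates within clipping distance of [0, 1]
A_FLOOR = -0.01
_EPS = 1e-12


# ---------------------------------------------------------------------------
# behavior logs (listener-centric view of a game)

@dataclass
class BehaviorLog:
    """One participant's listener-side record of a session.

    ``initial_c`` / ``initial_s`` are the participant's item-wise category
    and sign assignments at session start; ``trials`` is the time-ordered
    listener trial table with columns
    (pass, item_id, proposed_sign, own_sign_before, own_category,
    decision, own_category_after) plus, when available, ground-truth
    annotations (r_mh_true, p_num_true, p_den_true, model_prob).
    """

    participant_id: str
    pair_id: str
    dataset_label: str
    trials: pd.DataFrame
    initial_c: np.ndarray
    initial_s: np.ndarray
    n_items: int = 0

    def __post_init__(self):
        self.initial_c = np.asarray(self.initial_c, int)
        self.initial_s = np.asarray(self.initial_s, int)
        if not self.n_items:
            self.n_items = len(self.initial_c)
        if len(self.trials) and not self.trials["decision"].isin([0, 1]).all():
            raise ValueError("decisions must be binary")

    def decisions(self) -> np.ndarray:
        return self.trials["decision"].to_numpy(int)


def game_log_to_behavior_logs(
    log: GameLog, pair_id: str = "pair0",
) -> dict[str, BehaviorLog]:
    """Split a game log into the two participants' listener-side views."""
    rows: dict[str, list] = {"A": [], "B": []}
    for t in log.trials:
        listener = "B" if t.speaker == "A" else "A"
        rows[listener].append(
            {
                "pass": t.pass_index,
                "item_id": t.item_id,
                "proposed_sign": t.proposed_sign,
                "own_sign_before": t.listener_sign_before,
                "own_category": t.listener_category,
                "decision": t.decision,
                "own_category_after": t.listener_category_after,
                "r_mh_true": t.r_mh,
                "p_num_true": t.p_num,
                "p_den_true": t.p_den,
                "model_prob": t.model_prob,
            }
        )
    out = {}
    for agent in ("A", "B"):
        out[agent] = BehaviorLog(
            participant_id=f"{pair_id}{agent}",
            pair_id=pair_id,
            dataset_label=log.stimuli.dataset_label,
            trials=pd.DataFrame(rows[agent]),
            initial_c=log.initial_states[agent].c,
            initial_s=log.initial_states[agent].s,
        )
    return out


# ---------------------------------------------------------------------------
# r_MH inference from a log

def infer_rmh_for_log(
    log: BehaviorLog,
    hyper: Hyperparameters | None = None,
    mode: str = "online",
    estimator: str = "mean",
    gibbs_iters: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-trial (r_mh, p_num, p_den) inferred from the participant's log.

    Theta is estimated from the listener's own (category, sign) assignments
    — under the Inter-GM factorization Theta's conditional depends only on
    those counts, so the color vectors never enter.  ``mode='online'``
    re-estimates from the assignments current at each trial (participants
    relabel during the session); ``mode='final'`` uses the end-of-session
    state for every trial.  ``estimator='mean'`` uses the Dirichlet
    posterior-mean table; ``estimator='sample'`` averages r_mh over
    ``gibbs_iters`` posterior draws of Theta.
    """
    hyper = hyper or Hyperparameters()
    if log.trials.empty:
        raise ValueError("empty behavior log")
    if mode not in ("online", "final"):
        raise ValueError("mode must be 'online' or 'final'")
    if estimator not in ("mean", "sample"):
        raise ValueError("estimator must be 'mean' or 'sample'")
    rng = derive_rng(seed, "infer_rmh", log.participant_id)

    c = log.initial_c.copy()
    s = log.initial_s.copy()
    n_items = log.n_items

    states = []  # (c, s, item, s_star, s_own, c_own) per trial
    for t in log.trials.itertuples(index=False):
        item = int(t.item_id)
        if not 0 <= item < n_items:
            raise ValueError(f"trial references unknown item {item}")
        c[item] = int(t.own_category)
        s[item] = int(t.own_sign_before)
        states.append((c.copy(), s.copy(), item, int(t.proposed_sign),
                       int(t.own_sign_before), int(t.own_category)))
        if t.decision:
            s[item] = int(t.proposed_sign)
        c[item] = int(t.own_category_after)

    if mode == "final":
        states = [(c.copy(), s.copy(), it, st, so, co)
                  for (_, _, it, st, so, co) in states]

    def theta_hat(cc, ss):
        if estimator == "mean":
            return posterior_mean_theta(cc, ss, hyper.alpha, hyper.L, hyper.K)[None]
        counts = sign_category_counts(cc, ss, hyper.L, hyper.K)
        draws = np.stack([
            np.stack([rng.dirichlet(hyper.alpha + counts[l]) for l in range(hyper.L)])
            for _ in range(gibbs_iters)
        ])
        return draws

    recs = []
    for cc, ss, item, s_star, s_own, c_own in states:
        thetas = theta_hat(cc, ss)
        p_num = thetas[:, s_star, c_own]
        p_den = thetas[:, s_own, c_own]
        r = np.minimum(1.0, p_num / p_den)
        recs.append({"item_id": item, "r_mh": float(r.mean()),
                     "p_num": float(p_num.mean()), "p_den": float(p_den.mean())})
    out = pd.DataFrame(recs)
    out["decision"] = log.decisions()
    return out


# ---------------------------------------------------------------------------
# biased-Bernoulli maximum likelihood

def _loglik_grid(Z: np.ndarray, r: np.ndarray, ab: np.ndarray) -> np.ndarray:
    """Log-likelihood of each (a, b) grid point for each decision stream.

    Z: (m, n) binary; r: (n,); ab: (G, 2).  Returns (m, G).
    """
    rates = np.clip(ab[:, 0][:, None] * r[None, :] + ab[:, 1][:, None], _EPS, 1 - _EPS)
    lp, lq = np.log(rates), np.log1p(-rates)  # (G, n)
    return Z @ lp.T + (1.0 - Z) @ lq.T


def _feasible(ab: np.ndarray) -> np.ndarray:
    a, b = ab[:, 0], ab[:, 1]
    return (b >= 0) & (a >= A_FLOOR) & (a + b <= 1 + 1e-12)


def _suff_stats(Z: np.ndarray, r: np.ndarray):
    """Collapse trials onto unique r values: accept/reject counts per value.

    The log-likelihood depends on the data only through the number of
    accepts and rejects at each distinct r_MH, and r_MH streams are heavily
    tied (ratios of small-count Dirichlet posterior means, plus the mass at
    exactly 1), so this shrinks the evaluation cost by orders of magnitude
    without any approximation.
    """
    u, inv = np.unique(r, return_inverse=True)
    M = np.zeros((r.size, u.size))
    M[np.arange(r.size), inv] = 1.0
    return u, Z @ M, (1.0 - Z) @ M


def _tie_penalty(a, b):
    # resolves likelihood plateaus (e.g. all-accept streams, where every
    # parameter giving unit predicted rates is equivalent) to a canonical point
    return 1e-9 * (np.asarray(a) ** 2 + (np.asarray(b) - 0.5) ** 2)


def _ll_rows(K1, K0, u, a, b):
    """Penalized log-likelihood for per-replicate parameters a, b (m,)."""
    rho = np.clip(a[:, None] * u[None, :] + b[:, None], _EPS, 1 - _EPS)
    ll = np.einsum("mu,mu->m", K1, np.log(rho)) + np.einsum(
        "mu,mu->m", K0, np.log1p(-rho)
    )
    return ll - _tie_penalty(a, b)


_COMPASS = np.array(
    [(da, db) for da in (-1.0, 0.0, 1.0) for db in (-1.0, 0.0, 1.0) if da or db]
)


def _fit_many(Z: np.ndarray, r: np.ndarray, tol: float = 1e-5) -> np.ndarray:
    """Bounded MLE of (a, b) for each row of Z; returns (m, 2).

    Dense shared grid over the feasible polytope, then per-stream compass
    search (move to a strictly better neighbor at the current spacing; halve
    the spacing when no neighbor improves).  Concavity of the objective
    makes this ascent converge to the constrained global optimum.
    """
    Z = np.atleast_2d(np.asarray(Z, float))
    r = np.asarray(r, float)
    m = Z.shape[0]
    u, K1, K0 = _suff_stats(Z, r)

    step0 = 0.01
    a0 = np.arange(A_FLOOR, 1.0 + step0 / 2, step0)
    b0 = np.arange(0.0, 1.0 + step0 / 2, step0)
    grid = np.array(list(itertools.product(a0, b0)))
    grid = grid[_feasible(grid)]
    rho = np.clip(grid[:, 0][:, None] * u[None, :] + grid[:, 1][:, None], _EPS, 1 - _EPS)
    ll = K1 @ np.log(rho).T + K0 @ np.log1p(-rho).T - _tie_penalty(grid[:, 0], grid[:, 1])
    idx = np.argmax(ll, axis=1)
    best = grid[idx]
    best_val = np.take_along_axis(ll, idx[:, None], axis=1)[:, 0]

    span = np.full(m, step0)
    for _ in range(200):
        active = span >= tol
        if not active.any():
            break
        improved = np.zeros(m, dtype=bool)
        for da, db in _COMPASS:
            a = best[:, 0] + da * span
            b = best[:, 1] + db * span
            ok = active & (b >= 0) & (a >= A_FLOOR) & (a + b <= 1 + 1e-12)
            if not ok.any():
                continue
            val = np.full(m, -np.inf)
            val[ok] = _ll_rows(K1[ok], K0[ok], u, a[ok], b[ok])
            upd = val > best_val
            best[upd, 0], best[upd, 1] = a[upd], b[upd]
            best_val[upd] = val[upd]
            improved |= upd
        span[active & ~improved] /= 2.0
    return best


def biased_bernoulli_loglik(z: np.ndarray, r: np.ndarray, a: float, b: float) -> float:
    """Sum_n z log(a r + b) + (1 - z) log(1 - a r - b), rates clipped."""
    rates = np.clip(a * np.asarray(r, float) + b, _EPS, 1 - _EPS)
    z = np.asarray(z, float)
    return float(np.sum(z * np.log(rates) + (1 - z) * np.log1p(-rates)))


def fit_biased_bernoulli(z: np.ndarray, r_mh: np.ndarray):
    """Bounded MLE of Bern(z | a r_MH + b); returns (a, b, loglik, flag).

    ``flag`` is True when the slope is unidentifiable (all r_MH equal), in
    which case a = 0 and b is the acceptance rate.
    """
    z = np.asarray(z, float)
    r = np.asarray(r_mh, float)
    if z.shape != r.shape or z.size == 0:
        raise ValueError("z and r_mh must be equal-length, non-empty")
    if not np.isin(z, [0, 1]).all():
        raise ValueError("decisions must be binary")
    if np.any((r < 0) | (r > 1)):
        raise ValueError("r_mh values must lie in [0, 1]")
    if np.ptp(r) < 1e-12:
        b = float(np.clip(z.mean(), 0.0, 1.0))
        warnings.warn("all r_mh identical: slope unidentifiable, returning a = 0")
        return 0.0, b, biased_bernoulli_loglik(z, r, 0.0, b), True
    a, b = _fit_many(z[None, :], r)[0]
    return float(a), float(b), biased_bernoulli_loglik(z, r, a, b), False


def empirical_p(null_samples: np.ndarray, observed: float) -> float:
    """One-sided empirical CDF tail: fraction of null values >= observed."""
    null_samples = np.asarray(null_samples, float)
    return float(np.mean(null_samples >= observed))


def randomization_test_a(
    z: np.ndarray, r_mh: np.ndarray, n_null: int = 1000, seed: int = 0,
):
    """Randomization test of the slope a against the constant-rate null.

    Decisions are redrawn ``n_null`` times from Bern(b_bar) with r_MH held
    fixed; the slope is refitted on each replicate.  Returns
    ``(a_hat, p_value, null_a, null_b)``.  An observed slope above every
    null sample yields p = 0 (reportable as < 1/n_null).
    """
    z = np.asarray(z, int)
    r = np.asarray(r_mh, float)
    a_hat, b_hat, _, _ = fit_biased_bernoulli(z, r)
    b_bar = float(z.mean())
    rng = derive_rng(seed, "randomization_test")
    Z_null = (rng.random((n_null, z.size)) < b_bar).astype(float)
    fitted = _fit_many(Z_null, r)
    p = empirical_p(fitted[:, 0], a_hat)
    return float(a_hat), float(p), fitted[:, 0], fitted[:, 1]


# ---------------------------------------------------------------------------
# model precision and pairwise U-tests

def model_probabilities(
    model: BehaviorModelSpec, r_mh: np.ndarray, p_num: np.ndarray, p_den: np.ndarray,
) -> np.ndarray:
    return np.array([
        response_probability(model, r, pn, pd_)
        for r, pn, pd_ in zip(r_mh, p_num, p_den)
    ])


def model_precision(
    z: np.ndarray,
    r_mh: np.ndarray,
    p_num: np.ndarray,
    p_den: np.ndarray,
    model: BehaviorModelSpec,
    n_replicates: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Precision samples: agreement of model-sampled decisions with ``z``.

    Each of ``n_replicates`` pseudo-decision streams is drawn trial-wise
    from Bern(model probability); its precision is the fraction of trials
    matching the human decision.
    """
    z = np.asarray(z, int)
    probs = model_probabilities(model, r_mh, p_num, p_den)
    rng = derive_rng(seed, "precision", model.name)
    draws = rng.random((n_replicates, z.size)) < probs[None, :]
    return (draws == z[None, :].astype(bool)).mean(axis=1)


def pairwise_u_tests(
    precision: dict[str, np.ndarray], alpha: float = 0.001,
):
    """One-sided Mann-Whitney U-tests for every ordered model pair.

    Entry (m, m') is the p-value for H1 "model m's precision stochastically
    dominates model m's'".  All-tied pairs get p = 0.5 (the degenerate
    normal-approximation convention) and are flagged.  Returns
    ``(p_matrix, reject_matrix, flagged_pairs)`` as DataFrames/list.
    """
    names = list(precision)
    if len(names) < 2:
        raise ValueError("need at least two models")
    sizes = {len(v) for v in precision.values()}
    if len(sizes) != 1:
        raise ValueError("all models need equal replicate counts")
    p = pd.DataFrame(np.nan, index=names, columns=names)
    flagged = []
    for m, m2 in itertools.permutations(names, 2):
        x, y = precision[m], precision[m2]
        if np.ptp(np.concatenate([x, y])) < 1e-15:
            p.loc[m, m2] = 0.5
            flagged.append((m, m2))
            continue
        p.loc[m, m2] = mannwhitneyu(x, y, alternative="greater", method="asymptotic").pvalue
    reject = p < alpha
    np.fill_diagonal(reject.values, False)
    return p, reject, flagged


# ---------------------------------------------------------------------------
# orchestration and report tables

@dataclass
class AnalysisResult:
    """Fitted parameters, p-values, precision samples, and U-test matrices."""

    per_participant: pd.DataFrame  # participant, dataset, a, b, p_a, n_trials
    pooled: pd.DataFrame  # dataset ('hard' | 'easy' | 'all'), a, b, p_a, n_trials
    precision: dict[str, dict[str, np.ndarray]]  # scope -> model -> samples
    u_pvalues: pd.DataFrame  # pooled scope
    u_reject: pd.DataFrame
    rejection_counts: dict[str, pd.DataFrame] = field(default_factory=dict)
    null_samples: dict[str, np.ndarray] = field(default_factory=dict)
    binned: pd.DataFrame | None = None


def binned_acceptance(z: np.ndarray, r_mh: np.ndarray, n_bins: int = 10) -> pd.DataFrame:
    """Observed acceptance rate within equal-width r_MH bins covering [0, 1]."""
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(r_mh, edges[1:-1]), 0, n_bins - 1)
    rows = []
    for bi in range(n_bins):
        mask = idx == bi
        rows.append({
            "bin_left": edges[bi], "bin_right": edges[bi + 1],
            "n_trials": int(mask.sum()), "n_accepted": int(np.asarray(z)[mask].sum()),
            "acceptance_rate": float(np.asarray(z)[mask].mean()) if mask.any() else np.nan,
        })
    return pd.DataFrame(rows)


def report_tables(result: AnalysisResult) -> dict[str, pd.DataFrame]:
    """Formatted output tables: per-participant fits (+ pooled rows), the
    pairwise p-value matrix, rejection-count matrices, and the binned
    acceptance summary."""
    fits = result.per_participant.copy()
    pooled = result.pooled.copy()
    pooled.insert(0, "participant", "all")
    fit_table = pd.concat([fits, pooled], ignore_index=True)
    tables = {
        "fits": fit_table,
        "u_pvalues": result.u_pvalues.copy(),
        "u_reject": result.u_reject.astype(int),
    }
    for scope, mat in result.rejection_counts.items():
        tables[f"rejections_{scope}"] = mat
    if result.binned is not None:
        tables["binned_acceptance"] = result.binned
    return tables


def analyze_cohort(
    behavior_logs: list[BehaviorLog],
    hyper: Hyperparameters | None = None,
    n_null: int = 1000,
    n_model_reps: int = 100,
    alpha: float = 0.001,
    seed: int = 0,
    use_true_rmh: bool = False,
    rmh_mode: str = "online",
) -> AnalysisResult:
    """Run both hypothesis-testing pipelines over a cohort of behavior logs.

    Per participant and pooled (per dataset and overall): biased-Bernoulli
    fit and randomization test of the slope.  Pooled across all trials: the
    five-model precision comparison with pairwise one-sided U-tests; the
    per-participant U-tests are aggregated into rejection-count matrices.
    """
    hyper = hyper or Hyperparameters()
    frames = []
    for i, log in enumerate(behavior_logs):
        inf = (
            log.trials[["item_id", "r_mh_true", "p_num_true", "p_den_true"]]
            .rename(columns={"r_mh_true": "r_mh", "p_num_true": "p_num", "p_den_true": "p_den"})
            .assign(decision=log.decisions())
            if use_true_rmh
            else infer_rmh_for_log(log, hyper, mode=rmh_mode, seed=seed)
        )
        inf = inf.assign(participant=log.participant_id, dataset=log.dataset_label)
        frames.append(inf)
    trials = pd.concat(frames, ignore_index=True)

    def fit_and_test(df, test_seed):
        a, p, null_a, null_b = randomization_test_a(
            df["decision"].to_numpy(), df["r_mh"].to_numpy(), n_null=n_null, seed=test_seed,
        )
        _, b, _, _ = fit_biased_bernoulli(df["decision"].to_numpy(), df["r_mh"].to_numpy())
        # P'_b is reported alongside but plays no role in any decision
        p_b = empirical_p(null_b, b)
        return a, b, p, p_b, null_a

    per_rows = []
    for i, ((pid, ds), df) in enumerate(trials.groupby(["participant", "dataset"], sort=False)):
        a, b, p, p_b, _ = fit_and_test(df, seed * 1000 + i + 1)
        per_rows.append({"participant": pid, "dataset": ds, "a": a, "b": b,
                         "p_a": p, "p_b": p_b, "n_trials": len(df)})
    per_participant = pd.DataFrame(per_rows)

    pooled_rows, null_store = [], {}
    scopes = [(ds, trials[trials["dataset"] == ds]) for ds in trials["dataset"].unique()]
    scopes.append(("all", trials))
    for i, (name, df) in enumerate(scopes):
        a, b, p, p_b, null_a = fit_and_test(df, seed * 1000 + 500 + i)
        pooled_rows.append({"dataset": name, "a": a, "b": b, "p_a": p, "p_b": p_b,
                            "n_trials": len(df)})
        null_store[name] = null_a
    pooled = pd.DataFrame(pooled_rows)

    def models_for(df):
        b_bar = float(df["decision"].mean())
        return [BehaviorModelSpec("constant", b_bar=b_bar)] + [
            BehaviorModelSpec(n) for n in MODEL_NAMES if n != "constant"
        ]

    def precision_for(df, scope_seed):
        return {
            m.name: model_precision(
                df["decision"].to_numpy(), df["r_mh"].to_numpy(),
                df["p_num"].to_numpy(), df["p_den"].to_numpy(),
                m, n_replicates=n_model_reps, seed=scope_seed,
            )
            for m in models_for(df)
        }

    precision = {"pooled": precision_for(trials, seed * 1000 + 900)}
    u_p, u_rej, _ = pairwise_u_tests(precision["pooled"], alpha=alpha)

    counts = pd.DataFrame(0, index=list(MODEL_NAMES), columns=list(MODEL_NAMES))
    for i, (pid, df) in enumerate(trials.groupby("participant", sort=False)):
        prec = precision_for(df, seed * 1000 + 910 + i)
        precision[pid] = prec
        _, rej, _ = pairwise_u_tests(prec, alpha=alpha)
        counts += rej.astype(int)

    return AnalysisResult(
        per_participant=per_participant,
        pooled=pooled,
        precision=precision,
        u_pvalues=u_p,
        u_reject=u_rej,
        rejection_counts={"all": counts},
        null_samples=null_store,
        binned=binned_acceptance(trials["decision"].to_numpy(), trials["r_mh"].to_numpy()),
    )
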