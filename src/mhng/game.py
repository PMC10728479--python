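"""The Metropolis-Hastings naming game between two simulated agents.

Protocol per pass (one full traversal of the 15 items, in reshuffled order):

1. perception — both agents resample their categorizations c given their
   current Theta, Phi;
2. communication — for each item the speaker proposes a sign sampled from
   P(s | Theta_sp, c_sp) ∝ pi_s * theta_sp[s, c]; the listener accepts with
   probability r_MH = min(1, theta_li[s*, c] / theta_li[s_li, c]) and on
   acceptance overwrites its own sign for the item;
3. learning — both agents resample Theta and Phi from their conditionals.

Roles swap after each full pass; ``n_passes`` passes are played per role, so
a study-shaped game (15 items, 3 passes per role) yields 45 accept/reject
decisions per participant.

Because acceptance is the Metropolis-Hastings rule for the shared sign
variable, the pair as a whole performs approximate decentralized Bayesian
inference of P(s | x_A, x_B).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .intergm import (
    AgentState,
    Hyperparameters,
    gibbs_conditional_c,
    gibbs_conditional_phi,
    gibbs_conditional_theta,
    init_agent_state,
)
from .random import derive_rng
from .stimuli import StimulusSet

__all__ = [
    "TrialRecord",
    "GameLog",
    "speaker_propose",
    "mh_acceptance_probability",
    "play_game",
    "agreement_metrics",
]

AGENTS = ("A", "B")


@dataclass
class TrialRecord:
    """One communication event (a proposal and the listener's decision)."""

    pass_index: int
    item_id: int
    speaker: str
    proposed_sign: int
    listener_sign_before: int
    listener_category: int
    r_mh: float
    decision: int
    listener_category_after: int
    # ground-truth annotations (present in simulated-participant logs)
    p_num: float = np.nan
    p_den: float = np.nan
    model_name: str = ""
    model_prob: float = np.nan


@dataclass
class GameLog:
    """The ordered trial stream of one game plus state provenance."""

    trials: list[TrialRecord]
    stimuli: StimulusSet
    hyper: Hyperparameters
    seed: int
    n_passes: int
    initial_states: dict[str, AgentState]
    final_states: dict[str, AgentState]
    snapshots: list[dict[str, AgentState]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.trials)

    def decisions(self) -> np.ndarray:
        return np.array([t.decision for t in self.trials], dtype=int)

    def r_mh(self) -> np.ndarray:
        return np.array([t.r_mh for t in self.trials], dtype=float)

    def listener_of(self, pass_index: int) -> str:
        return AGENTS[(pass_index + 1) % 2]


def speaker_propose(
    state: AgentState, item: int, pi: np.ndarray, rng: np.random.Generator,
) -> int:
    """Sample a sign from P(s | Theta, c_item) ∝ pi_s * theta[s, c_item]."""
    weights = pi * state.theta[:, state.c[item]]
    total = weights.sum()
    if total <= 0 or not np.isfinite(total):
        raise FloatingPointError("degenerate proposal weights (all zero)")
    return int(rng.choice(len(pi), p=weights / total))


def speaker_proposal_distribution(state: AgentState, item: int, pi: np.ndarray) -> np.ndarray:
    weights = pi * state.theta[:, state.c[item]]
    return weights / weights.sum()


def mh_acceptance_probability(
    theta_listener: np.ndarray, listener_category: int,
    proposed_sign: int, listener_sign: int,
) -> float:
    """r_MH = min(1, theta[s*, c] / theta[s_li, c])."""
    if proposed_sign == listener_sign:
        return 1.0
    num = theta_listener[proposed_sign, listener_category]
    den = theta_listener[listener_sign, listener_category]
    if den <= 0:
        raise ZeroDivisionError("degenerate Theta: listener's own sign has zero mass")
    return float(min(1.0, num / den))


def play_game(
    stimuli: StimulusSet,
    hyper: Hyperparameters | None = None,
    n_passes: int = 3,
    seed: int = 0,
    listener_model=None,
    keep_snapshots: bool = True,
) -> GameLog:
    """Play the naming game and return its log.

    ``n_passes`` is the number of passes per role (two agents alternate, so
    2 * n_passes passes are played in total).  When ``listener_model`` is
    given (a :class:`mhng.participants.BehaviorModelSpec`), the listener's MH
    acceptance rule is replaced by a Bernoulli draw at that model's response
    probability and each trial carries ground-truth annotations.
    """
    hyper = hyper or Hyperparameters()
    x = stimuli.luv  # both agents observe the same patches
    rng_init = {a: derive_rng(seed, "game", "init", a) for a in AGENTS}
    rng_perc = derive_rng(seed, "game", "perception")
    rng_prop = derive_rng(seed, "game", "proposals")
    rng_dec = derive_rng(seed, "game", "decisions")
    rng_order = derive_rng(seed, "game", "order")

    states = {a: init_agent_state(hyper, x, rng_init[a]) for a in AGENTS}
    initial = {a: states[a].copy() for a in AGENTS}

    trials: list[TrialRecord] = []
    snapshots: list[dict[str, AgentState]] = []
    n_items = len(stimuli)
    for p in range(2 * n_passes):
        speaker, listener = (AGENTS[p % 2], AGENTS[(p + 1) % 2])
        # perception: both agents refresh c given current Theta, Phi
        for a in AGENTS:
            st = states[a]
            for n in range(n_items):
                probs = gibbs_conditional_c(x[n], st.s[n], st.theta, st.mu, st.lam)
                st.c[n] = rng_perc.choice(hyper.K, p=probs)
        # communication
        order = rng_order.permutation(n_items)
        for n in order:
            sp, li = states[speaker], states[listener]
            s_star = speaker_propose(sp, n, hyper.pi, rng_prop)
            c_li = int(li.c[n])
            s_li = int(li.s[n])
            p_num = float(li.theta[s_star, c_li])
            p_den = float(li.theta[s_li, c_li])
            r = mh_acceptance_probability(li.theta, c_li, s_star, s_li)
            if listener_model is None:
                prob = r
                model_name = ""
                model_prob = np.nan
            else:
                from .participants import response_probability

                prob = response_probability(listener_model, r, p_num, p_den)
                model_name = listener_model.name
                model_prob = prob
            decision = int(rng_dec.random() < prob)
            if decision:
                li.s[n] = s_star
            trials.append(
                TrialRecord(
                    pass_index=p, item_id=int(n), speaker=speaker,
                    proposed_sign=int(s_star), listener_sign_before=s_li,
                    listener_category=c_li, r_mh=r, decision=decision,
                    listener_category_after=int(li.c[n]),
                    p_num=p_num, p_den=p_den,
                    model_name=model_name, model_prob=model_prob,
                )
            )
        # learning: both agents refresh Theta, Phi from updated (c, s)
        for a in AGENTS:
            st = states[a]
            st.theta = gibbs_conditional_theta(st.c, st.s, hyper.alpha, hyper.L, hyper.K, rng_perc)
            st.mu, st.lam = gibbs_conditional_phi(x, st.c, hyper, rng_perc)
        if keep_snapshots:
            snapshots.append({a: states[a].copy() for a in AGENTS})

    return GameLog(
        trials=trials, stimuli=stimuli, hyper=hyper, seed=seed, n_passes=n_passes,
        initial_states=initial, final_states={a: states[a] for a in AGENTS},
        snapshots=snapshots,
    )


def agreement_metrics(log: GameLog) -> tuple[float, float, float]:
    """(final sign agreement rate, category ARI, overall acceptance rate)."""
    if not log.trials:
        raise ValueError("empty game log")
    sa, sb = log.final_states["A"].s, log.final_states["B"].s
    agreement = float(np.mean(sa == sb))
    ari = float(adjusted_rand_score(log.final_states["A"].c, log.final_states["B"].c))
    acceptance = float(np.mean(log.decisions()))
    return agreement, ari, acceptance


def sign_agreement(states: dict[str, AgentState]) -> float:
    return float(np.mean(states["A"].s == states["B"].s))
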