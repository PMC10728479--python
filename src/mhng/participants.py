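"""Pseudo-participants: behavioral logs generated under known response models.

Five response models map a trial's MH acceptance probability r_MH (and the
listener-side likelihoods p_num = P(c | Theta, s*), p_den = P(c | Theta, s))
to an acceptance probability:

====== ============ ==========================================
name    params       acceptance probability
====== ============ ==========================================
constant  b_bar      b_bar
mh        (a, b)     a * r_MH + b          (defaults a=1, b=0)
numerator —          p_num
subtraction —        (p_num - p_den) / 2 + 1/2
binary    —          0.1 if r_MH <= 0.5 else 0.9
====== ============ ==========================================

Two simulation modes are provided.  ``simulate_participant_log`` runs the
full game loop with the listener's accept rule replaced by the model, so
decisions feed back into sign state as they would for a human.
``resample_decisions_only`` keeps an existing log's state evolution fixed and
redraws only the decision stream at the model's probabilities — the
pseudo-experiment used for the model-comparison test.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .game import GameLog, play_game
from .intergm import Hyperparameters
from .random import derive_rng, spawn_seeds
from .stimuli import StimulusSet, generate_dataset, get_spec

__all__ = [
    "MODEL_NAMES",
    "BehaviorModelSpec",
    "response_probability",
    "simulate_participant_log",
    "resample_decisions_only",
    "simulate_cohort",
]

MODEL_NAMES = ("constant", "mh", "numerator", "subtraction", "binary")


@dataclass(frozen=True)
class BehaviorModelSpec:
    """One of the five response models with its parameters."""

    name: str
    b_bar: float = 0.5  # constant model's rate
    a: float = 1.0  # mh model's weight on r_MH
    b: float = 0.0  # mh model's bias

    def __post_init__(self):
        if self.name not in MODEL_NAMES:
            raise ValueError(f"unknown model {self.name!r}; expected one of {MODEL_NAMES}")
        if not 0.0 <= self.b_bar <= 1.0:
            raise ValueError("b_bar must lie in [0, 1]")
        if self.name == "mh" and not (self.b >= 0 and self.a + self.b <= 1):
            raise ValueError("biased mh model requires 0 <= b and a + b <= 1")


def response_probability(
    model: BehaviorModelSpec, r_mh: float, p_num: float, p_den: float,
) -> float:
    """The model's acceptance probability for one trial."""
    if model.name == "constant":
        return float(model.b_bar)
    if model.name == "mh":
        return float(np.clip(model.a * r_mh + model.b, 0.0, 1.0))
    if model.name == "numerator":
        return float(p_num)
    if model.name == "subtraction":
        return float((p_num - p_den) / 2.0 + 0.5)
    if model.name == "binary":
        return 0.1 if r_mh <= 0.5 else 0.9
    raise ValueError(f"unknown model {model.name!r}")


def simulate_participant_log(
    stimuli: StimulusSet,
    hyper: Hyperparameters | None,
    model: BehaviorModelSpec,
    n_passes: int = 3,
    seed: int = 0,
) -> GameLog:
    """Full game with the listener's accept rule replaced by ``model``.

    Every trial carries ground-truth annotations (r_mh, p_num, p_den,
    model_prob), so the model probability can be recomputed exactly from the
    logged quantities.
    """
    return play_game(stimuli, hyper, n_passes=n_passes, seed=seed, listener_model=model)


def resample_decisions_only(
    log: GameLog, model: BehaviorModelSpec, seed: int,
) -> GameLog:
    """Redraw only decisions at ``model``'s probabilities; state is frozen.

    The returned log shares stimuli and state snapshots with the input; its
    trials are copies whose decisions come from Bernoulli draws at the
    model's per-trial response probability computed from the logged
    (r_mh, p_num, p_den).
    """
    rng = derive_rng(seed, "resample", model.name)
    trials = []
    for t in log.trials:
        prob = response_probability(model, t.r_mh, t.p_num, t.p_den)
        trials.append(
            replace(
                t, decision=int(rng.random() < prob),
                model_name=model.name, model_prob=prob,
            )
        )
    return GameLog(
        trials=trials, stimuli=log.stimuli, hyper=log.hyper, seed=log.seed,
        n_passes=log.n_passes, initial_states=log.initial_states,
        final_states=log.final_states, snapshots=log.snapshots,
    )


def simulate_cohort(
    model: BehaviorModelSpec,
    n_pairs: int = 10,
    datasets: tuple[str, ...] = ("hard", "easy"),
    n_passes: int = 3,
    seed: int = 0,
    hyper: Hyperparameters | None = None,
) -> dict[str, list[GameLog]]:
    """Simulate a study-shaped cohort: ``n_pairs`` pairs play every dataset.

    Defaults mirror the study: 10 pairs (20 participants), two 15-item
    datasets, 3 passes per role, hence 45 listener decisions per participant
    per dataset.  Returns one list of game logs per dataset label.
    """
    logs: dict[str, list[GameLog]] = {}
    for d_idx, name in enumerate(datasets):
        stim_seed, *pair_seeds = spawn_seeds(seed, n_pairs + 1, "cohort", name)
        stimuli = generate_dataset(get_spec(name), n_items=15, seed=stim_seed)
        logs[name] = [
            simulate_participant_log(stimuli, hyper, model, n_passes=n_passes, seed=ps)
            for ps in pair_seeds
        ]
    return logs
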