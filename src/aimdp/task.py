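"""The instrumental-conditioning task: true environment and agent priors.

The task is a six-epoch trace-conditioning trial. The agent starts in the
first of two pre-cue states, one of two cues is then shown (equiprobably),
the agent makes one of two responses, waits through two delay epochs, and
finally lands probabilistically in a "win" or "no win" outcome state. There
is a separate pair of delay states for every cue-response combination, so
the hidden state itself carries the memory of what was seen and done — the
temporal credit assignment problem is solved by perceptual inference rather
than by an eligibility trace.

State space (14 states, 0-based):

====  ==========================================
 0    pre-cue 1
 1    pre-cue 2
 2,3  cue 1, cue 2
 4+   delay step 1 / step 2 for each (cue, response) pair
 12   win outcome
 13   no-win outcome
====  ==========================================

Observations (5): null (emitted by pre-cue and delay states), the two cues,
and the two outcomes. Controls (3): do nothing, response 1, response 2.

This module also doubles as the synthetic-data generator: the true
environment (``true_A``/``true_B``) is sampled from directly, while
:func:`build_agent_model` constructs the agent's generative model and its
Dirichlet priors over the same structure, with the delay-to-outcome
transitions left to be learnt.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .model_core import DirichletBeliefs, GenerativeModel

__all__ = [
    "STATE_LABELS",
    "AgentConfig",
    "TaskSpec",
    "make_default_contingencies",
    "make_single_cue_task",
    "build_agent_model",
    "environment_step",
    "initial_observation",
    "correct_response",
    "outcome_estimates",
    "make_toy_chain_task",
]

N_STATES = 14
N_OBS = 5
N_CONTROLS = 3
T_EPOCHS = 6

# state indices
PRE1, PRE2 = 0, 1
CUE = (2, 3)
WIN, NOWIN = 12, 13
# observation indices
OBS_NULL = 0
OBS_CUE = (1, 2)
OBS_WIN, OBS_NOWIN = 3, 4
# control indices
CTRL_NONE = 0
CTRL_RESP = (1, 2)
# the response is taken at this 0-based transition (epoch 3 -> 4)
CHOICE_TRANSITION = 2


def delay_state(cue: int, resp: int, step: int) -> int:
    """State index of delay ``step`` (0 or 1) for a (cue, response) pair."""
    return 4 + 2 * (2 * cue + resp) + step


STATE_LABELS = (
    ["pre-cue 1", "pre-cue 2", "cue 1", "cue 2"]
    + [
        f"delay {step + 1} (cue {c + 1}, resp {r + 1})"
        for c in range(2)
        for r in range(2)
        for step in range(2)
    ]
    + ["win", "no win"]
)


@dataclass
class AgentConfig:
    """Tunable parameters of the agent's priors and inference loop.

    conc_floor
        Negligible concentration on transitions believed (near) impossible;
        small enough to be inert under accumulation.
    conc_strong
        Concentration on transitions known to high certainty; dominates a
        session's worth of evidence so those entries stay effectively fixed.
    a_conc_floor
        Floor for the observation-matrix priors. Kept well above conc_floor:
        the digamma scale of the expected-log likelihood sets how many nats
        of counter-evidence a precision clamp must explain away, and an
        astronomically confident observation model would make observation
        evidence unconditionally decisive.
    win_preference
        Probability mass the terminal preference exp(C) places on the win
        state (about three nats of utility difference at the default).
    prec_shape, prec_rate
        Gamma hyperparameters of the precision prior; prior mean precision
        is their ratio.
    iters_per_epoch
        Variational iterations per epoch; matches the deconvolution kernel's
        time constant so one epoch spans one kernel time constant.
    """

    conc_floor: float = 1e-6
    conc_strong: float = 512.0
    a_conc_floor: float = 1.0 / 16.0
    win_preference: float = 0.95
    pref_floor: float = 1e-6
    prec_shape: float = 8.0
    prec_rate: float = 1.0
    iters_per_epoch: int = 16
    learn_A: bool = True
    learn_B: bool = True
    outcome_prior_win: float = 0.4
    outcome_prior_nowin: float = 1.0
    include_do_nothing_policy: bool = False


@dataclass
class TaskSpec:
    """True structure of the conditioning environment.

    reward_probs maps (cue, response) — both 0-based — to the probability of
    reaching the win state from that pair's second delay state. cue_probs is
    the distribution over cues shown after the second pre-cue state.
    """

    reward_probs: dict
    cue_probs: tuple = (0.5, 0.5)
    T: int = T_EPOCHS
    labels: list = field(default_factory=lambda: list(STATE_LABELS))
    true_A: np.ndarray = field(init=False, repr=False)
    true_B: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        for key, p in self.reward_probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"reward probability out of [0,1] for {key}: {p}")
        if abs(sum(self.cue_probs) - 1.0) > 1e-12:
            raise ValueError("cue probabilities must sum to 1")
        self.true_A = self._build_true_A()
        self.true_B = self._build_true_B()

    def _build_true_A(self) -> np.ndarray:
        A = np.zeros((N_OBS, N_STATES))
        A[OBS_NULL, [PRE1, PRE2]] = 1.0
        for c in range(2):
            A[OBS_CUE[c], CUE[c]] = 1.0
            for r in range(2):
                for step in range(2):
                    A[OBS_NULL, delay_state(c, r, step)] = 1.0
        A[OBS_WIN, WIN] = 1.0
        A[OBS_NOWIN, NOWIN] = 1.0
        return A

    def _build_true_B(self) -> np.ndarray:
        B = np.zeros((N_CONTROLS, N_STATES, N_STATES))
        for u in range(N_CONTROLS):
            B[u, PRE2, PRE1] = 1.0
            for c in range(2):
                B[u, CUE[c], PRE2] = self.cue_probs[c]
            for c in range(2):
                # at the cue, a response moves to that pair's first delay
                # state; doing nothing leaves the agent at the cue
                if u == CTRL_NONE:
                    B[u, CUE[c], CUE[c]] = 1.0
                else:
                    B[u, delay_state(c, u - 1, 0), CUE[c]] = 1.0
                for r in range(2):
                    B[u, delay_state(c, r, 1), delay_state(c, r, 0)] = 1.0
                    p = self.reward_probs[(c, r)]
                    B[u, WIN, delay_state(c, r, 1)] = p
                    B[u, NOWIN, delay_state(c, r, 1)] = 1.0 - p
            B[u, WIN, WIN] = 1.0
            B[u, NOWIN, NOWIN] = 1.0
        return B

    def to_yaml(self, path) -> None:
        doc = {
            "reward_probs": {f"{c + 1},{r + 1}": float(p) for (c, r), p in self.reward_probs.items()},
            "cue_probs": [float(p) for p in self.cue_probs],
            "T": self.T,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh)

    @classmethod
    def from_yaml(cls, path) -> "TaskSpec":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        reward_probs = {
            (int(k.split(",")[0]) - 1, int(k.split(",")[1]) - 1): float(v)
            for k, v in doc["reward_probs"].items()
        }
        return cls(reward_probs=reward_probs, cue_probs=tuple(doc["cue_probs"]), T=doc.get("T", T_EPOCHS))


def make_default_contingencies(high: float = 0.8, low: float = 0.2) -> TaskSpec:
    """Symmetric two-cue task: each cue has one high- and one low-reward response.

    Cue 1 rewards response 1 with probability ``high`` and response 2 with
    ``low``; cue 2 is the mirror image.
    """
    return TaskSpec(
        reward_probs={(0, 0): high, (0, 1): low, (1, 0): low, (1, 1): high}
    )


def make_single_cue_task(p_resp1: float = 0.0, p_resp2: float = 0.5) -> TaskSpec:
    """Single-cue variant used for the stimulation-learning experiment.

    Only cue 1 is ever presented; response 1 is rewarded with ``p_resp1``
    (never, by default) and response 2 with ``p_resp2``. Cue-2 contingencies
    exist structurally but are unreachable.
    """
    return TaskSpec(
        reward_probs={(0, 0): p_resp1, (0, 1): p_resp2, (1, 0): p_resp1, (1, 1): p_resp2},
        cue_probs=(1.0, 0.0),
    )


def build_agent_model(
    spec: TaskSpec, cfg: AgentConfig | None = None
) -> tuple[GenerativeModel, DirichletBeliefs]:
    """Construct the agent's generative model and Dirichlet priors.

    All transitions the agent knows with certainty get ``conc_strong`` on the
    true entry and ``conc_floor`` elsewhere; the unknown delay-to-outcome
    columns get weak priors (``outcome_prior_nowin`` on no-win,
    ``outcome_prior_win`` on win — a weak belief that reward is unlikely,
    prior mean win probability 0.4/1.4 ≈ 0.286). Observation priors are
    strong and accurate. The preference exp(C) places ``win_preference`` mass
    on the win state and nearly all the remainder on no-win.
    """
    cfg = cfg or AgentConfig()

    # --- observation priors: strong and accurate ---
    a_prior = np.full((N_OBS, N_STATES), cfg.a_conc_floor)
    true_rows = spec.true_A.argmax(axis=0)
    a_prior[true_rows, np.arange(N_STATES)] = cfg.conc_strong

    # --- transition priors ---
    b_prior = np.full((N_CONTROLS, N_STATES, N_STATES), cfg.conc_floor)
    for u in range(N_CONTROLS):
        b_prior[u, PRE2, PRE1] = cfg.conc_strong
        for c in range(2):
            # the cue frequencies are known (equal concentrations -> mean 0.5)
            if spec.cue_probs[c] > 0:
                b_prior[u, CUE[c], PRE2] = cfg.conc_strong * spec.cue_probs[c]
            if u == CTRL_NONE:
                b_prior[u, CUE[c], CUE[c]] = cfg.conc_strong
            else:
                b_prior[u, delay_state(c, u - 1, 0), CUE[c]] = cfg.conc_strong
            for r in range(2):
                b_prior[u, delay_state(c, r, 1), delay_state(c, r, 0)] = cfg.conc_strong
                # unknown outcome transitions: weak pessimistic prior
                b_prior[u, WIN, delay_state(c, r, 1)] = cfg.outcome_prior_win
                b_prior[u, NOWIN, delay_state(c, r, 1)] = cfg.outcome_prior_nowin
        b_prior[u, WIN, WIN] = cfg.conc_strong
        b_prior[u, NOWIN, NOWIN] = cfg.conc_strong

    # --- terminal preference ---
    pref = np.full(N_STATES, cfg.pref_floor)
    pref[WIN] = cfg.win_preference
    pref[NOWIN] = 1.0 - cfg.win_preference - (N_STATES - 2) * cfg.pref_floor
    pref = pref / pref.sum()
    C = np.log(pref)

    # --- policy set: respond k at the choice transition, otherwise nothing ---
    policies = []
    for k in CTRL_RESP:
        pol = [CTRL_NONE] * (spec.T - 1)
        pol[CHOICE_TRANSITION] = k
        policies.append(pol)
    if cfg.include_do_nothing_policy:
        policies.append([CTRL_NONE] * (spec.T - 1))

    d_init = np.zeros(N_STATES)
    d_init[PRE1] = 1.0

    model = GenerativeModel(
        n_states=N_STATES,
        n_obs=N_OBS,
        n_controls=N_CONTROLS,
        T=spec.T,
        C=C,
        policies=np.array(policies),
        prec_shape=cfg.prec_shape,
        prec_rate=cfg.prec_rate,
        d_init=d_init,
    )
    beliefs = DirichletBeliefs(a_prior=a_prior, b_prior=b_prior)
    return model, beliefs


def environment_step(
    spec: TaskSpec, s_true: int, a: int, rng: np.random.Generator
) -> tuple[int, int]:
    """Sample the next true state and its emitted observation."""
    if not 0 <= s_true < N_STATES:
        raise ValueError(f"invalid state index {s_true}")
    if not 0 <= a < N_CONTROLS:
        raise ValueError(f"invalid control index {a}")
    s_next = int(rng.choice(N_STATES, p=spec.true_B[a][:, s_true]))
    o_next = int(rng.choice(N_OBS, p=spec.true_A[:, s_next]))
    return s_next, o_next


def initial_observation(spec: TaskSpec, rng: np.random.Generator) -> int:
    """Observation emitted by the initial (first pre-cue) state."""
    return int(rng.choice(N_OBS, p=spec.true_A[:, PRE1]))


def correct_response(spec: TaskSpec, cue: int) -> int:
    """Control index of the objectively best response for ``cue``.

    Argmax of the true reward probability; ties break toward the lower
    response index.
    """
    probs = [spec.reward_probs[(cue, r)] for r in range(2)]
    return CTRL_RESP[int(np.argmax(probs))]


def outcome_estimates(beliefs: DirichletBeliefs) -> dict:
    """Posterior-expected win probability for each (cue, response) pair.

    Read from the do-nothing transition matrix, which carries the
    delay-to-outcome transition (no response is made at that point).
    """
    EB = beliefs.expected_B(CTRL_NONE)
    return {
        (c, r): float(EB[WIN, delay_state(c, r, 1)])
        for c in range(2)
        for r in range(2)
    }


# ---------------------------------------------------------------------------
# tiny fixtures for oracle tests in other modules
# ---------------------------------------------------------------------------

def make_toy_chain_task(n_states: int = 2, T: int = 3, conc: float = 1e6):
    """A deterministic toy chain model for closed-form oracle tests.

    Two controls: "stay" (identity) and "swap" (cyclic shift). Observations
    mirror states one-to-one with near-deterministic concentrations. The
    preference is a near-delta on the last state.
    """
    a_prior = np.full((n_states, n_states), 1e-3)
    a_prior[np.arange(n_states), np.arange(n_states)] = conc
    stay = np.full((n_states, n_states), 1e-3)
    stay[np.arange(n_states), np.arange(n_states)] = conc
    swap = np.full((n_states, n_states), 1e-3)
    swap[(np.arange(n_states) + 1) % n_states, np.arange(n_states)] = conc
    b_prior = np.stack([stay, swap])
    pref = np.full(n_states, 0.001 / (n_states - 1))
    pref[-1] = 1.0 - pref[:-1].sum()
    policies = np.array([[0] * (T - 1), [1] + [0] * (T - 2)])
    model = GenerativeModel(
        n_states=n_states,
        n_obs=n_states,
        n_controls=2,
        T=T,
        C=np.log(pref),
        policies=policies,
    )
    beliefs = DirichletBeliefs(a_prior=a_prior, b_prior=b_prior)
    return model, beliefs
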