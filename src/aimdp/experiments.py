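"""Experiment runners: learning, depletion, stimulation and dopamine readouts.

Every experiment is a pure function of its arguments and a seed: sessions
draw their randomness from independent child streams spawned from the seed,
so fixed-seed runs are bit-reproducible and arms of an experiment are
statistically independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .dopamine import deconvolve_precision, epoch_responses
from .inference import (
    DEFAULT_ITERS_PER_EPOCH,
    TrialRecord,
    compute_free_energy,
    compute_policy_values,
    infer_epoch,
    sample_action,
)
from .interventions import ClampSchedule, depletion_schedule, stimulation_schedule
from .learning import end_of_trial_update
from .model_core import BeliefState, DirichletBeliefs, GenerativeModel
from .task import (
    CHOICE_TRANSITION,
    CTRL_NONE,
    CTRL_RESP,
    CUE,
    NOWIN,
    OBS_CUE,
    OBS_NOWIN,
    OBS_NULL,
    OBS_WIN,
    WIN,
    AgentConfig,
    TaskSpec,
    build_agent_model,
    correct_response,
    environment_step,
    initial_observation,
    make_default_contingencies,
    make_single_cue_task,
    outcome_estimates,
)

__all__ = [
    "ExperimentConfig",
    "SessionResult",
    "run_session",
    "replay_trial",
    "condition_sequences",
    "learning_experiment",
    "depletion_experiment",
    "stimulation_inference_experiment",
    "stimulation_learning_experiment",
    "dopamine_dynamics_experiment",
]

#: order in which (cue, response) contingency estimates are reported
CONTINGENCY_ORDER = ((0, 0), (0, 1), (1, 0), (1, 1))


@dataclass
class ExperimentConfig:
    """Bundled experiment settings (used by the CLI and YAML configs)."""

    n_sessions: int = 256
    n_trials: int = 128
    seed: int = 0
    high: float = 0.8
    low: float = 0.2
    agent: AgentConfig = field(default_factory=AgentConfig)

    def __post_init__(self) -> None:
        if self.n_sessions < 1 or self.n_trials < 1:
            raise ValueError("n_sessions and n_trials must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        agent = AgentConfig(**doc.pop("agent", {}))
        return cls(agent=agent, **doc)


@dataclass
class SessionResult:
    """Per-session log: trial records, estimates and summary arrays."""

    records: list
    estimates: np.ndarray  # (n_trials, 4) expected win prob per contingency
    free_energy: np.ndarray  # (n_trials,) per-trial accumulated free energy
    correct: np.ndarray  # (n_trials,) bool
    choices: np.ndarray  # (n_trials,) control index at the choice transition
    beliefs: DirichletBeliefs


def run_session(
    spec: TaskSpec,
    model: GenerativeModel,
    beliefs: DirichletBeliefs,
    cfg: AgentConfig,
    n_trials: int,
    rng: np.random.Generator,
    schedule: ClampSchedule | None = None,
    compute_fe: bool = True,
    keep_records: bool = True,
    after_trial=None,
) -> SessionResult:
    """Run one session: alternate environment steps and variational inference.

    Each trial runs ``T`` epochs of inference, samples actions from the
    policy posterior at every transition, and applies the Dirichlet update
    once at trial end. ``schedule`` may clamp precision; ``after_trial`` is
    an optional callback ``(trial_index, beliefs)`` invoked after each
    trial's learning update (used e.g. for replay probes during learning).
    """
    schedule = schedule or ClampSchedule.none()
    T = model.T
    records: list[TrialRecord] = []
    estimates = np.empty((n_trials, len(CONTINGENCY_ORDER)))
    free_energy = np.full(n_trials, np.nan)
    correct = np.zeros(n_trials, dtype=bool)
    choices = np.full(n_trials, -1, dtype=int)

    for trial in range(n_trials):
        state = BeliefState.initial(model)
        rec = TrialRecord()
        s_true = 0
        o = initial_observation(spec, rng)
        rec.observations.append(o)
        a_prev: int | None = None
        chosen: int | None = None
        cue: int | None = None

        for t in range(T):
            clamp = schedule.clamp_value(trial, t, chosen)
            Q = compute_policy_values(model, beliefs, t)
            infer_epoch(
                model, beliefs, state, t, o, a_prev,
                Q=Q, clamp=clamp, iters=cfg.iters_per_epoch,
            )
            if compute_fe:
                rec.free_energy.append(
                    compute_free_energy(
                        model, beliefs, state, t, o, a_prev, Q=Q,
                        include_parameter_complexity=False,
                    )
                )
            if t < T - 1:
                a = sample_action(model, state.pi_hat, t, rng)
                if t == CHOICE_TRANSITION:
                    chosen = a
                s_true, o = environment_step(spec, s_true, a, rng)
                if s_true in CUE:
                    cue = s_true - CUE[0]
                rec.actions.append(a)
                rec.observations.append(o)
                a_prev = a

        rec.s_hat_final = state.s_hat
        rec.gamma_trace = state.gamma_trace
        rec.cue = cue
        rec.correct = chosen == correct_response(spec, cue)
        rec.finalize()

        end_of_trial_update(beliefs, rec, learn_A=cfg.learn_A, learn_B=cfg.learn_B)

        est = outcome_estimates(beliefs)
        estimates[trial] = [est[key] for key in CONTINGENCY_ORDER]
        free_energy[trial] = rec.action_S
        correct[trial] = rec.correct
        choices[trial] = chosen
        if keep_records:
            records.append(rec)
        if after_trial is not None:
            after_trial(trial, beliefs)

    return SessionResult(records, estimates, free_energy, correct, choices, beliefs)


def replay_trial(
    model: GenerativeModel,
    beliefs: DirichletBeliefs,
    observations: list,
    actions: list,
    cfg: AgentConfig | None = None,
    schedule: ClampSchedule | None = None,
) -> TrialRecord:
    """Run inference over a fixed observation/action sequence (no learning).

    Used to probe precision dynamics under controlled trial types and to
    simulate stimulation on specific trials. Beliefs are not modified.
    """
    cfg = cfg or AgentConfig()
    schedule = schedule or ClampSchedule.none()
    state = BeliefState.initial(model)
    rec = TrialRecord()
    chosen = actions[CHOICE_TRANSITION] if len(actions) > CHOICE_TRANSITION else None
    a_prev: int | None = None
    for t in range(model.T):
        clamp = schedule.clamp_value(0, t, chosen)
        infer_epoch(
            model, beliefs, state, t, observations[t], a_prev,
            clamp=clamp, iters=cfg.iters_per_epoch,
        )
        if t < model.T - 1:
            a_prev = actions[t]
    rec.observations = list(observations)
    rec.actions = list(actions)
    rec.s_hat_final = state.s_hat
    rec.gamma_trace = state.gamma_trace
    rec.finalize()
    return rec


def condition_sequences(cue: int, resp: int, win: bool) -> tuple[list, list]:
    """Observation and action sequences for a fixed six-epoch trial type."""
    observations = [
        OBS_NULL, OBS_NULL, OBS_CUE[cue], OBS_NULL, OBS_NULL,
        OBS_WIN if win else OBS_NOWIN,
    ]
    actions = [CTRL_NONE] * 5
    actions[CHOICE_TRANSITION] = CTRL_RESP[resp]
    return observations, actions


def _session_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# experiments
# ---------------------------------------------------------------------------

def learning_experiment(
    n_sessions: int = 256,
    n_trials: int = 128,
    seed: int = 0,
    high: float = 0.8,
    low: float = 0.2,
    cfg: AgentConfig | None = None,
) -> dict:
    """Contingency learning: estimate trajectories and mean free energy.

    Returns per-trial mean (across sessions) posterior-expected win
    probabilities for the four (cue, response) contingencies, the mean
    per-trial free energy, and the true contingencies.
    """
    cfg = cfg or AgentConfig()
    spec = make_default_contingencies(high, low)
    est = np.empty((n_sessions, n_trials, 4))
    fe = np.empty((n_sessions, n_trials))
    for i, rng in enumerate(_session_rngs(seed, n_sessions)):
        model, beliefs = build_agent_model(spec, cfg)
        res = run_session(spec, model, beliefs, cfg, n_trials, rng, keep_records=False)
        est[i] = res.estimates
        fe[i] = res.free_energy
    truth = np.array([spec.reward_probs[key] for key in CONTINGENCY_ORDER])
    return {
        "estimates": est.mean(axis=0),
        "free_energy": fe.mean(axis=0),
        "truth": truth,
        "contingencies": CONTINGENCY_ORDER,
    }


def depletion_experiment(
    n_sessions: int = 256,
    n_trials_lesion: int = 32,
    n_trials_restore: int = 16,
    clamp: float = 0.1,
    seed: int = 0,
    high: float = 0.8,
    low: float = 0.2,
    cfg: AgentConfig | None = None,
) -> dict:
    """Simulated dopamine depletion, restoration, and an unlesioned control.

    The lesioned arm runs with precision clamped at ``clamp`` for the first
    ``n_trials_lesion`` trials of each session, then with free precision for
    ``n_trials_restore`` further trials. The control arm never clamps.
    Returns per-trial proportion correct and mean estimate trajectories for
    both arms.
    """
    cfg = cfg or AgentConfig()
    spec = make_default_contingencies(high, low)
    n_trials = n_trials_lesion + n_trials_restore
    schedule = depletion_schedule(clamp, trial_range=(0, n_trials_lesion), T=spec.T)

    out = {}
    for arm, arm_schedule in (("lesioned", schedule), ("control", None)):
        correct = np.empty((n_sessions, n_trials), dtype=bool)
        est = np.empty((n_sessions, n_trials, 4))
        for i, rng in enumerate(_session_rngs(seed + (0 if arm == "lesioned" else 1), n_sessions)):
            model, beliefs = build_agent_model(spec, cfg)
            res = run_session(
                spec, model, beliefs, cfg, n_trials, rng,
                schedule=arm_schedule, compute_fe=False, keep_records=False,
            )
            correct[i] = res.correct
            est[i] = res.estimates
        out[arm] = {
            "proportion_correct": correct.mean(axis=0),
            "estimates": est.mean(axis=0),
        }
    out["n_trials_lesion"] = n_trials_lesion
    out["n_trials_restore"] = n_trials_restore
    return out


def stimulation_inference_experiment(
    clamp_values: np.ndarray | None = None,
    clamp: float = 16.0,
    cfg: AgentConfig | None = None,
) -> dict:
    """Effect of final-epoch precision clamps on outcome-state inference.

    A naive agent observes cue 1, takes response 1 and receives a no-win
    observation. Unclamped, it correctly infers the no-win state; clamping
    final-epoch precision forces it to explain the impossible confidence by
    inferring a win. Returns the final-epoch posterior mass on the win and
    no-win states, unclamped and across the clamp sweep. Deterministic (no
    sampling is involved).
    """
    cfg = cfg or AgentConfig()
    if clamp_values is None:
        clamp_values = np.linspace(8.0, 16.0, 81)
    clamp_values = np.asarray(clamp_values, dtype=float)
    spec = make_default_contingencies()
    observations, actions = condition_sequences(cue=0, resp=0, win=False)

    model, beliefs = build_agent_model(spec, cfg)
    rec = replay_trial(model, beliefs, observations, actions, cfg)
    unclamped = rec.s_hat_final[model.T - 1]

    win_post = np.empty(clamp_values.size)
    nowin_post = np.empty(clamp_values.size)
    for i, v in enumerate(clamp_values):
        model, beliefs = build_agent_model(spec, cfg)
        rec = replay_trial(
            model, beliefs, observations, actions, cfg,
            schedule=stimulation_schedule(v, T=spec.T),
        )
        s_final = rec.s_hat_final[model.T - 1]
        win_post[i] = s_final[WIN]
        nowin_post[i] = s_final[NOWIN]
    return {
        "clamp_values": clamp_values,
        "win_posterior": win_post,
        "nowin_posterior": nowin_post,
        "unclamped_win": float(unclamped[WIN]),
        "unclamped_nowin": float(unclamped[NOWIN]),
        "clamp_default": clamp,
    }


def stimulation_learning_experiment(
    n_sessions: int = 256,
    n_trials: int = 48,
    clamp: float = 16.0,
    seed: int = 0,
    p_resp1: float = 0.0,
    p_resp2: float = 0.5,
    cfg: AgentConfig | None = None,
) -> dict:
    """Action-contingent stimulation versus control on a single-cue task.

    Response 1 never leads to reward but is followed by a final-epoch
    precision clamp (simulated stimulation); response 2 is rewarded half the
    time. Returns the per-trial frequency of response 1 for both arms.
    """
    cfg = cfg or AgentConfig()
    spec = make_single_cue_task(p_resp1, p_resp2)
    schedule = stimulation_schedule(clamp, contingent_on=CTRL_RESP[0], T=spec.T)

    out = {}
    for arm, arm_schedule in (("stimulated", schedule), ("control", None)):
        resp1 = np.empty((n_sessions, n_trials), dtype=bool)
        for i, rng in enumerate(_session_rngs(seed + (0 if arm == "stimulated" else 1), n_sessions)):
            model, beliefs = build_agent_model(spec, cfg)
            res = run_session(
                spec, model, beliefs, cfg, n_trials, rng,
                schedule=arm_schedule, compute_fe=False, keep_records=False,
            )
            resp1[i] = res.choices == CTRL_RESP[0]
        out[arm] = {"resp1_frequency": resp1.mean(axis=0)}
    return out


def dopamine_dynamics_experiment(
    n_sessions: int = 256,
    n_trials: int = 64,
    seed: int = 0,
    session_index: int = 0,
    high: float = 0.8,
    low: float = 0.2,
    cfg: AgentConfig | None = None,
) -> dict:
    """Simulated dopamine before/after learning, and its transfer over learning.

    Four fixed trial types are replayed through naive and learned agents:
    the high-expectancy cue (cue 1) and the low-expectancy cue (cue 2), each
    followed by a win or a no-win, with response 1 taken in all four so the
    conditions differ only in expectancy. (Post-learning beliefs come from
    session ``session_index`` of the seeded learning run.) In addition, the
    high-cue/response-1/win trial is replayed after every one of the first
    ``n_trials`` trials of each session and the per-epoch phasic responses
    averaged across sessions — the transfer curves of the response from
    outcome to cue.

    Epoch responses use the tonic-corrected innovation sum; the first epoch
    carries the deconvolution boundary artifact and is reported as zero.
    """
    cfg = cfg or AgentConfig()
    spec = make_default_contingencies(high, low)
    T = spec.T
    iters = cfg.iters_per_epoch
    probe_obs, probe_actions = condition_sequences(cue=0, resp=0, win=True)

    transfer = np.empty((n_sessions, n_trials, T))
    learned_beliefs: DirichletBeliefs | None = None
    probe_model, _ = build_agent_model(spec, cfg)
    gamma0 = probe_model.prior_precision

    for i, rng in enumerate(_session_rngs(seed, n_sessions)):
        model, beliefs = build_agent_model(spec, cfg)

        def probe(trial: int, current_beliefs: DirichletBeliefs, _row=transfer[i]) -> None:
            rec = replay_trial(probe_model, current_beliefs, probe_obs, probe_actions, cfg)
            _row[trial] = epoch_responses(rec.gamma_trace, iters, gamma_init=gamma0)

        res = run_session(
            spec, model, beliefs, cfg, n_trials, rng,
            compute_fe=False, keep_records=False, after_trial=probe,
        )
        if i == session_index:
            learned_beliefs = res.beliefs
    transfer_mean = transfer.mean(axis=0)
    transfer_mean[:, 0] = 0.0  # boundary artifact

    conditions = {
        "expected_reward": (0, True),
        "unexpected_reward": (1, True),
        "expected_omission": (1, False),
        "unexpected_omission": (0, False),
    }
    naive_beliefs = build_agent_model(spec, cfg)[1]
    traces: dict = {}
    for label, (cue, win) in conditions.items():
        obs, acts = condition_sequences(cue=cue, resp=0, win=win)
        traces[label] = {}
        for phase, bel in (("pre", naive_beliefs), ("post", learned_beliefs)):
            rec = replay_trial(probe_model, bel, obs, acts, cfg)
            dec = deconvolve_precision(
                rec.gamma_trace, iters_per_epoch=iters, drop_first_epoch=True
            )
            resp = epoch_responses(rec.gamma_trace, iters, gamma_init=gamma0)
            resp[0] = 0.0
            traces[label][phase] = {
                "signal": dec.signal,
                "gamma_trace": np.asarray(rec.gamma_trace),
                "epoch_responses": resp,
            }
    return {
        "conditions": traces,
        "transfer": transfer_mean,
        "cue_epoch": 2,
        "outcome_epoch": T - 1,
        "delay_epochs": (3, 4),
    }
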