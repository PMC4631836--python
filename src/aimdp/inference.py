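"""Within-trial variational inference: state, policy and precision updates.

One epoch of inference interleaves three fixed-point updates until (near)
convergence:

1. state estimation  ``s_hat = sigma(A_elog[o,:] + B_elog(a_prev) s_prev + gamma * Q pi_hat)``
2. policy evaluation ``pi_hat = sigma(gamma * Q^T s_hat)``
3. precision         ``gamma = prec_shape / (prec_rate - pi_hat . Q^T s_hat)``

The last term of the state update is an *optimism bias*: with high precision,
perception is pulled toward valuable states. Policy values Q(s, k) are the
negative KL divergence between the predictive distribution over final states
(starting from s under policy k) and the preferred terminal distribution
exp(C) — a form of KL control.

Precision may be clamped externally (see :mod:`aimdp.interventions`), in
which case the precision update is skipped and the clamp value is recorded
at every iteration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import xlogy

from .model_core import (
    KL_FLOOR,
    BeliefState,
    DirichletBeliefs,
    GenerativeModel,
    dirichlet_kl,
    gamma_kl,
    kl_divergence,
    normalized_exponential,
)

__all__ = [
    "QMatrix",
    "TrialRecord",
    "compute_policy_values",
    "update_states",
    "update_policies",
    "update_precision",
    "infer_epoch",
    "sample_action",
    "compute_free_energy",
    "trial_records_to_frame",
    "gamma_traces_to_frame",
]

#: default number of variational iterations per epoch; one epoch then spans
#: one time constant of the dopamine deconvolution kernel
DEFAULT_ITERS_PER_EPOCH = 16


@dataclass
class QMatrix:
    """Policy values, one column per policy, one row per hidden state.

    Entry (s, k) = -KL[ P(s_T | s_t = s, policy k) || exp(C) ] <= 0, zero only
    when the predictive terminal distribution matches the preference exactly.
    The matrix form keeps both contractions well-typed: ``values @ pi_hat``
    is a state-space vector (state update) and ``values.T @ s_hat`` is a
    policy-space vector (policy and precision updates).
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def n_states(self) -> int:
        return self.values.shape[0]

    @property
    def n_policies(self) -> int:
        return self.values.shape[1]


@dataclass
class TrialRecord:
    """Everything observed, chosen and believed during one trial."""

    observations: list = field(default_factory=list)
    actions: list = field(default_factory=list)
    s_hat_final: list = field(default_factory=list)
    gamma_trace: list = field(default_factory=list)
    free_energy: list = field(default_factory=list)
    action_S: float = 0.0
    correct: bool | None = None
    cue: int | None = None

    def finalize(self) -> None:
        self.action_S = float(np.sum(self.free_energy))


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def compute_policy_values(
    model: GenerativeModel, beliefs: DirichletBeliefs, t: int
) -> QMatrix:
    """Value of every policy from every hidden state at epoch ``t``.

    A delta at each state is propagated through the posterior-mean transition
    matrices E[B(u)] for the policy's remaining controls (probability-domain
    expectations, not expected logs) to obtain P(s_T | s_t, policy), and the
    negative KL divergence against the terminal preference exp(C) is returned.
    """
    if t >= model.T:
        raise ValueError("t must index an epoch within the trial")
    if model.n_policies == 0:
        raise ValueError("empty policy set")
    log_pref = np.log(np.maximum(np.exp(model.C), KL_FLOOR))
    EB = beliefs.expected_B()  # (n_controls, n, n)
    values = np.empty((model.n_states, model.n_policies))
    cache: dict = {}  # policies sharing a remaining-control tail share a column
    for k, policy in enumerate(model.policies):
        tail = tuple(policy[t:])
        if tail not in cache:
            # propagate the identity through the remaining controls: columns
            # of P are P(s_T | s_t = s, policy k)
            P = np.eye(model.n_states)
            for u in tail:
                P = EB[u] @ P
            cache[tail] = -(
                xlogy(P, P).sum(axis=0) - (P * log_pref[:, None]).sum(axis=0)
            )
        values[:, k] = cache[tail]
    return QMatrix(values)


def update_states(
    beliefs: DirichletBeliefs,
    o_t: int,
    s_prev: np.ndarray | None,
    a_prev: int | None,
    Q: QMatrix,
    pi_hat: np.ndarray,
    gamma_hat: float,
    log_prior: np.ndarray | None = None,
) -> np.ndarray:
    """State estimation: evidence, prediction and optimism combined.

    Returns ``sigma(A_elog[o_t, :] + B_elog(a_prev) @ s_prev + gamma_hat * Q @ pi_hat)``.
    The likelihood term is the row of the expected-log observation matrix
    selected by the observed outcome, read as a vector over states. At the
    first epoch there is no prediction; pass ``log_prior`` (the log of the
    known initial-state distribution) instead of ``s_prev``/``a_prev``.
    """
    n_obs, n_states = beliefs.A_elog.shape
    if not 0 <= o_t < n_obs:
        raise ValueError(f"invalid outcome index {o_t}")
    evidence = beliefs.A_elog[o_t, :]
    if log_prior is not None:
        prediction = np.asarray(log_prior, dtype=float)
    else:
        if a_prev is None or not 0 <= a_prev < beliefs.B_elog.shape[0]:
            raise ValueError(f"invalid action index {a_prev}")
        prediction = beliefs.B_elog[a_prev] @ np.asarray(s_prev, dtype=float)
    optimism = gamma_hat * (Q.values @ pi_hat)
    return normalized_exponential(evidence + prediction + optimism)


def update_policies(Q: QMatrix, s_hat: np.ndarray, gamma_hat: float) -> np.ndarray:
    """Policy posterior: softmax of expected policy value at precision gamma."""
    return normalized_exponential(gamma_hat * (Q.values.T @ s_hat))


def update_precision(
    model: GenerativeModel, Q: QMatrix, s_hat: np.ndarray, pi_hat: np.ndarray
) -> float:
    """Expected precision ``prec_shape / (prec_rate - pi_hat . Q^T s_hat)``.

    Because Q <= 0 the denominator is at least ``prec_rate``, so the result
    is positive and bounded above by the prior mean ``prec_shape/prec_rate``;
    precision rises as the expected value of the policies rises.
    """
    expected_value = float(pi_hat @ (Q.values.T @ s_hat))
    gamma = model.prec_shape / (model.prec_rate - expected_value)
    assert gamma > 0
    return gamma


def infer_epoch(
    model: GenerativeModel,
    beliefs: DirichletBeliefs,
    state: BeliefState,
    t: int,
    o_t: int,
    a_prev: int | None,
    Q: QMatrix | None = None,
    clamp: float | None = None,
    iters: int = DEFAULT_ITERS_PER_EPOCH,
) -> BeliefState:
    """Run one epoch's fixed-point iteration, mutating ``state`` in place.

    Each of the ``iters`` rounds applies the state, policy and precision
    updates in that order and appends the resulting precision to
    ``state.gamma_trace``. If ``clamp`` is given, precision is fixed to that
    value every round and the precision update is skipped entirely (so the
    trace shows a flat plateau at the clamp).
    """
    if Q is None:
        Q = compute_policy_values(model, beliefs, t)
    if t == 0:
        s_prev = None
        log_prior = np.log(np.maximum(model.d_init, KL_FLOOR))
    else:
        s_prev = state.s_hat[t - 1]
        log_prior = None

    if clamp is not None:
        state.gamma_hat = float(clamp)
    s_hat = None
    for _ in range(iters):
        s_hat = update_states(
            beliefs, o_t, s_prev, a_prev, Q, state.pi_hat, state.gamma_hat,
            log_prior=log_prior,
        )
        state.pi_hat = update_policies(Q, s_hat, state.gamma_hat)
        if clamp is None:
            state.gamma_hat = update_precision(model, Q, s_hat, state.pi_hat)
        state.gamma_trace.append(state.gamma_hat)

    if len(state.s_hat) == t:
        state.s_hat.append(s_hat)
    else:
        state.s_hat[t] = s_hat
    state.clamped.append(clamp is not None)
    return state


def sample_action(
    model: GenerativeModel, pi_hat: np.ndarray, t: int, rng: np.random.Generator
) -> int:
    """Sample the control at transition ``t`` from the policy posterior.

    The posterior over policies is marginalized onto the control each policy
    prescribes at transition ``t`` and the control is drawn from that
    marginal.
    """
    if t >= model.T - 1:
        raise ValueError("t must index a transition (t < T - 1)")
    marginal = np.zeros(model.n_controls)
    np.add.at(marginal, model.policies[:, t], pi_hat)
    marginal = marginal / marginal.sum()
    return int(rng.choice(model.n_controls, p=marginal))


def compute_free_energy(
    model: GenerativeModel,
    beliefs: DirichletBeliefs,
    state: BeliefState,
    t: int,
    o_t: int,
    a_prev: int | None,
    Q: QMatrix | None = None,
    include_parameter_complexity: bool = True,
) -> float:
    """Variational free energy of epoch ``t`` (complexity minus accuracy).

    Terms:

    * accuracy — expected log-likelihood of the observation,
      ``s_hat . A_elog[o_t, :]`` (entering with a minus sign);
    * state complexity — KL between the state posterior and the predictive
      prior ``E[B(a_prev)] s_prev`` (the initial-state distribution at the
      first epoch);
    * policy complexity — KL between the policy posterior and the
      value-based policy prior ``sigma(gamma * Q^T s_hat)`` implied by the
      generative model (approximately zero at the fixed point);
    * precision complexity — KL between Gamma(prec_shape, prec_shape/gamma)
      and the Gamma(prec_shape, prec_rate) prior;
    * parameter complexity — closed-form Dirichlet KL between posterior and
      prior concentrations. With online per-trial accumulation this is zero
      within a trial (the trial's effective prior is the running posterior),
      so session runners may skip it.

    Free energy is minimized: it falls as the model improves.
    """
    if Q is None:
        Q = compute_policy_values(model, beliefs, t)
    s_hat = state.s_hat[t]

    accuracy = float(s_hat @ beliefs.A_elog[o_t, :])

    if t == 0:
        pred = model.d_init
    else:
        pred = beliefs.expected_B(a_prev) @ state.s_hat[t - 1]
    kl_states = kl_divergence(s_hat, pred)

    policy_prior = normalized_exponential(state.gamma_hat * (Q.values.T @ s_hat))
    kl_policies = kl_divergence(state.pi_hat, policy_prior)

    kl_precision = gamma_kl(
        model.prec_shape,
        model.prec_shape / state.gamma_hat,
        model.prec_shape,
        model.prec_rate,
    )

    kl_params = 0.0
    if include_parameter_complexity:
        kl_params = dirichlet_kl(beliefs.a_post, beliefs.a_prior)
        for u in range(beliefs.b_post.shape[0]):
            kl_params += dirichlet_kl(beliefs.b_post[u], beliefs.b_prior[u])

    return -accuracy + kl_states + kl_policies + kl_precision + kl_params


# ---------------------------------------------------------------------------
# tabular export
# ---------------------------------------------------------------------------

def trial_records_to_frame(records: list[TrialRecord]) -> pd.DataFrame:
    """One row per epoch: trial, epoch, observation, action, gamma, free_energy.

    Epoch-level gamma is the precision after the epoch's final variational
    iteration. Trial and epoch indices are 1-based in the output.
    """
    rows = []
    for trial, rec in enumerate(records, start=1):
        T = len(rec.observations)
        iters = len(rec.gamma_trace) // T
        for t in range(T):
            rows.append(
                {
                    "trial": trial,
                    "epoch": t + 1,
                    "observation": rec.observations[t] + 1,
                    "action": rec.actions[t] + 1 if t < len(rec.actions) else 0,
                    "gamma": rec.gamma_trace[(t + 1) * iters - 1],
                    "free_energy": rec.free_energy[t],
                }
            )
    return pd.DataFrame(rows)


def gamma_traces_to_frame(records: list[TrialRecord]) -> pd.DataFrame:
    """Long-format precision traces: trial, iteration (1-based), gamma."""
    rows = []
    for trial, rec in enumerate(records, start=1):
        for i, g in enumerate(rec.gamma_trace, start=1):
            rows.append({"trial": trial, "iteration": i, "gamma": g})
    return pd.DataFrame(rows)
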