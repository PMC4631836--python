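"""Core domain types and elementary operations for discrete active inference.

This module defines the agent's generative model for a finite-horizon,
controlled hidden Markov process, Dirichlet beliefs over its unknown
parameters, and the handful of mathematical primitives (normalized
exponential, Dirichlet expected logs, discrete KL divergences) that the
inference, learning and readout modules are built from.

Conventions
-----------
* The observation model ``A`` is an (n_obs, n_states) column-stochastic
  matrix: column *j* is the outcome distribution given hidden state *j*.
* Each transition model ``B(u)`` is an (n_states, n_states) column-stochastic
  matrix: entry (i, j) is P(next = i | current = j, control = u).
* The terminal preference ``C`` is a log-probability vector over hidden
  states; exp(C) sums to one and encodes which final states the agent
  expects (equivalently prefers) to end the trial in.
* States, outcomes and controls are 0-based in code; user-facing logs use
  1-based labels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import digamma, gammaln

__all__ = [
    "SIMPLEX_TOL",
    "KL_FLOOR",
    "GenerativeModel",
    "DirichletBeliefs",
    "BeliefState",
    "normalized_exponential",
    "dirichlet_expected_log",
    "kl_divergence",
    "dirichlet_kl",
    "gamma_kl",
    "save_model",
    "load_model",
]

#: tolerance used when validating that vectors lie on the probability simplex
SIMPLEX_TOL = 1e-10

#: floor applied to the *second* argument of kl_divergence before the log;
#: predictive distributions can carry exact zeros from deterministic
#: transitions, so only q is floored
KL_FLOOR = 1e-16


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def normalized_exponential(v: np.ndarray) -> np.ndarray:
    """Softmax of ``v``: exp(v) normalized to the probability simplex.

    Stable under large inputs (max subtraction) and invariant to adding a
    constant to ``v``.

    Raises
    ------
    ValueError
        If ``v`` contains non-finite entries (an invalid belief update).
    """
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("normalized_exponential: non-finite input (invalid belief update)")
    w = np.exp(v - v.max())
    return w / w.sum()


def dirichlet_expected_log(conc: np.ndarray) -> np.ndarray:
    """Expected log-probabilities under column-wise Dirichlet distributions.

    For concentrations ``conc`` with columns on the simplex family,
    entry (i, j) is ``psi(conc[i, j]) - psi(sum_k conc[k, j])`` — the
    expectation of ``ln p_ij`` when column j is Dirichlet distributed.
    All entries are <= 0.

    Raises
    ------
    ValueError
        If any concentration is not strictly positive (degenerate Dirichlet).
    """
    conc = np.asarray(conc, dtype=float)
    if np.any(conc <= 0):
        raise ValueError("dirichlet_expected_log: concentrations must be strictly positive")
    return digamma(conc) - digamma(conc.sum(axis=0, keepdims=True))


def kl_divergence(p: np.ndarray, q: np.ndarray) -> float:
    """Discrete KL divergence ``sum_i p_i ln(p_i / q_i)``.

    ``q`` is floored at :data:`KL_FLOOR` before the log so that exact zeros
    arising from deterministic transitions do not produce infinities; terms
    with ``p_i = 0`` contribute zero.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError(f"kl_divergence: length mismatch {p.shape} vs {q.shape}")
    qf = np.maximum(q, KL_FLOOR)
    mask = p > 0
    return float(np.sum(p[mask] * (np.log(p[mask]) - np.log(qf[mask]))))


def dirichlet_kl(post: np.ndarray, prior: np.ndarray) -> float:
    """Closed-form KL divergence between column-wise Dirichlet distributions.

    Both arguments are concentration arrays of identical shape whose columns
    parameterize independent Dirichlet distributions; the column KLs are
    summed.
    """
    post = np.asarray(post, dtype=float)
    prior = np.asarray(prior, dtype=float)
    if post.shape != prior.shape:
        raise ValueError("dirichlet_kl: shape mismatch")
    a0 = post.sum(axis=0)
    b0 = prior.sum(axis=0)
    per_col = (
        gammaln(a0)
        - gammaln(post).sum(axis=0)
        - gammaln(b0)
        + gammaln(prior).sum(axis=0)
        + ((post - prior) * (digamma(post) - digamma(a0))).sum(axis=0)
    )
    return float(per_col.sum())


def gamma_kl(shape_q: float, rate_q: float, shape_p: float, rate_p: float) -> float:
    """KL divergence between Gamma(shape_q, rate_q) and Gamma(shape_p, rate_p)."""
    return float(
        (shape_q - shape_p) * digamma(shape_q)
        - gammaln(shape_q)
        + gammaln(shape_p)
        + shape_p * (np.log(rate_q) - np.log(rate_p))
        + shape_q * (rate_p - rate_q) / rate_q
    )


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class GenerativeModel:
    """The agent's generative model of a finite-horizon controlled MDP.

    Parameters
    ----------
    n_states, n_obs, n_controls : int
        Sizes of the hidden-state, observation and control spaces.
    T : int
        Number of epochs per trial (T observations, T-1 transitions).
    C : ndarray, shape (n_states,)
        Log-preference vector over terminal hidden states; exp(C) is a
        probability distribution (the states the agent expects to end in,
        whose log corresponds to utility).
    policies : ndarray of int, shape (n_policies, T-1)
        Allowable control sequences over the T-1 transitions (0-based
        control indices).
    prec_shape, prec_rate : float
        Shape and rate of the Gamma prior on the precision of beliefs about
        control states (the inverse-temperature on policy selection). Named
        longhand to avoid collision with Dirichlet concentrations.
    d_init : ndarray, shape (n_states,)
        Known initial-state distribution (enters the first epoch's state
        update in place of the transition prediction).
    """

    n_states: int
    n_obs: int
    n_controls: int
    T: int
    C: np.ndarray
    policies: np.ndarray
    prec_shape: float = 8.0
    prec_rate: float = 1.0
    d_init: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=float)
        self.policies = np.asarray(self.policies, dtype=int)
        if self.d_init is None:
            d = np.zeros(self.n_states)
            d[0] = 1.0
            self.d_init = d
        else:
            self.d_init = np.asarray(self.d_init, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.C.shape != (self.n_states,):
            raise ValueError("C must have length n_states")
        if abs(np.exp(self.C).sum() - 1.0) > 1e-8:
            raise ValueError("exp(C) must sum to 1 (C is a log-probability vector)")
        if self.policies.ndim != 2 or self.policies.shape[1] != self.T - 1:
            raise ValueError("every policy must have length T-1")
        if self.policies.min() < 0 or self.policies.max() >= self.n_controls:
            raise ValueError("policy entries must be valid control indices")
        if not (self.prec_shape > 0 and self.prec_rate > 0):
            raise ValueError("precision hyperparameters must be positive")
        if abs(self.d_init.sum() - 1.0) > 1e-8:
            raise ValueError("d_init must be a probability distribution")

    @property
    def n_policies(self) -> int:
        return self.policies.shape[0]

    @property
    def prior_precision(self) -> float:
        """Prior mean of the precision, prec_shape / prec_rate."""
        return self.prec_shape / self.prec_rate


@dataclass
class DirichletBeliefs:
    """Dirichlet beliefs over the observation and transition matrices.

    ``a_*`` arrays have shape (n_obs, n_states); ``b_*`` arrays have shape
    (n_controls, n_states, n_states). Posterior concentrations start equal
    to the priors and only ever gain mass. The expected-log matrices
    (digamma form) are cached and refreshed after every accumulation.
    """

    a_prior: np.ndarray
    b_prior: np.ndarray
    a_post: np.ndarray = None  # type: ignore[assignment]
    b_post: np.ndarray = None  # type: ignore[assignment]
    A_elog: np.ndarray = field(init=False, repr=False, default=None)  # type: ignore[assignment]
    B_elog: np.ndarray = field(init=False, repr=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.a_prior = np.asarray(self.a_prior, dtype=float)
        self.b_prior = np.asarray(self.b_prior, dtype=float)
        if np.any(self.a_prior <= 0) or np.any(self.b_prior <= 0):
            raise ValueError("all concentrations must be strictly positive")
        if self.a_post is None:
            self.a_post = self.a_prior.copy()
        else:
            self.a_post = np.asarray(self.a_post, dtype=float)
        if self.b_post is None:
            self.b_post = self.b_prior.copy()
        else:
            self.b_post = np.asarray(self.b_post, dtype=float)
        if np.any(self.a_post - self.a_prior < -1e-12) or np.any(self.b_post - self.b_prior < -1e-12):
            raise ValueError("posterior concentrations cannot fall below the prior")
        self.refresh()

    def refresh(self) -> None:
        """Recompute the cached expected-log matrices from the posteriors."""
        self.A_elog = dirichlet_expected_log(self.a_post)
        self.B_elog = np.stack([dirichlet_expected_log(b) for b in self.b_post])

    def expected_A(self) -> np.ndarray:
        """Posterior mean observation matrix (column-normalized a_post)."""
        return self.a_post / self.a_post.sum(axis=0, keepdims=True)

    def expected_B(self, u: int | None = None) -> np.ndarray:
        """Posterior mean transition matrix for control ``u`` (or all)."""
        if u is None:
            return self.b_post / self.b_post.sum(axis=1, keepdims=True)
        return self.b_post[u] / self.b_post[u].sum(axis=0, keepdims=True)

    def copy(self) -> "DirichletBeliefs":
        return DirichletBeliefs(
            a_prior=self.a_prior.copy(),
            b_prior=self.b_prior.copy(),
            a_post=self.a_post.copy(),
            b_post=self.b_post.copy(),
        )


@dataclass
class BeliefState:
    """Per-trial posterior beliefs and their within-trial iteration traces.

    Attributes
    ----------
    s_hat : list of ndarray
        Posterior over hidden states, one simplex vector per completed epoch.
    pi_hat : ndarray
        Posterior over the policy set.
    gamma_hat : float
        Expected precision (inverse temperature on policy selection).
    gamma_trace : list of float
        gamma_hat after every variational iteration, concatenated across
        epochs.
    clamped : list of bool
        Per-epoch flag: was precision externally fixed at that epoch?
    """

    s_hat: list = field(default_factory=list)
    pi_hat: np.ndarray = None  # type: ignore[assignment]
    gamma_hat: float = 1.0
    gamma_trace: list = field(default_factory=list)
    clamped: list = field(default_factory=list)

    @classmethod
    def initial(cls, model: GenerativeModel) -> "BeliefState":
        """Fresh state: uniform policy posterior, prior-mean precision."""
        return cls(
            s_hat=[],
            pi_hat=np.full(model.n_policies, 1.0 / model.n_policies),
            gamma_hat=model.prior_precision,
            gamma_trace=[],
            clamped=[],
        )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def model_to_dict(model: GenerativeModel, beliefs: DirichletBeliefs) -> dict:
    """JSON-serializable document fully describing a model and its beliefs."""
    return {
        "dims": {
            "n_states": model.n_states,
            "n_obs": model.n_obs,
            "n_controls": model.n_controls,
            "T": model.T,
        },
        "C": model.C.tolist(),
        "policies": model.policies.tolist(),
        "prec_shape": model.prec_shape,
        "prec_rate": model.prec_rate,
        "d_init": model.d_init.tolist(),
        "a_prior": beliefs.a_prior.tolist(),
        "b_prior": beliefs.b_prior.tolist(),
        "a_post": beliefs.a_post.tolist(),
        "b_post": beliefs.b_post.tolist(),
    }


def model_from_dict(doc: dict) -> tuple[GenerativeModel, DirichletBeliefs]:
    dims = doc["dims"]
    model = GenerativeModel(
        n_states=dims["n_states"],
        n_obs=dims["n_obs"],
        n_controls=dims["n_controls"],
        T=dims["T"],
        C=np.array(doc["C"]),
        policies=np.array(doc["policies"]),
        prec_shape=doc["prec_shape"],
        prec_rate=doc["prec_rate"],
        d_init=np.array(doc["d_init"]),
    )
    beliefs = DirichletBeliefs(
        a_prior=np.array(doc["a_prior"]),
        b_prior=np.array(doc["b_prior"]),
        a_post=np.array(doc.get("a_post")) if doc.get("a_post") is not None else None,
        b_post=np.array(doc.get("b_post")) if doc.get("b_post") is not None else None,
    )
    return model, beliefs


def save_model(model: GenerativeModel, beliefs: DirichletBeliefs, path) -> None:
    with open(path, "w") as fh:
        json.dump(model_to_dict(model, beliefs), fh)


def load_model(path) -> tuple[GenerativeModel, DirichletBeliefs]:
    with open(path) as fh:
        return model_from_dict(json.load(fh))
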