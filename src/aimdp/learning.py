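"""Across-trial Dirichlet learning of the observation and transition models.

Learning is plain conjugate accumulation: every epoch adds the (soft) outer
product of inferred causes and observed outcomes to the corresponding
concentration parameters — a Hebbian coincidence rule with no explicit
learning rate. The implicit rate is set by the total concentration mass:
beliefs grounded in more evidence move less. Expected precision never enters
these updates (it is separated from the parameters by a Markov blanket), so
the accumulation functions deliberately do not take a precision argument.
"""

from __future__ import annotations

import gzip
import json

import numpy as np

from .inference import TrialRecord
from .model_core import DirichletBeliefs

__all__ = [
    "accumulate_observation_counts",
    "accumulate_transition_counts",
    "end_of_trial_update",
    "write_belief_snapshots",
]


def accumulate_observation_counts(
    beliefs: DirichletBeliefs, o_t: int, s_hat: np.ndarray
) -> DirichletBeliefs:
    """Add ``s_hat`` to row ``o_t`` of the observation concentrations.

    Exactly one unit of mass is added per epoch (s_hat is on the simplex).
    The cached expected-log matrices are refreshed.
    """
    n_obs = beliefs.a_post.shape[0]
    if not 0 <= o_t < n_obs:
        raise ValueError(f"invalid outcome index {o_t}")
    beliefs.a_post[o_t, :] += s_hat
    beliefs.refresh()
    return beliefs


def accumulate_transition_counts(
    beliefs: DirichletBeliefs,
    a_prev: int,
    s_hat_t: np.ndarray,
    s_hat_prev: np.ndarray,
) -> DirichletBeliefs:
    """Add the outer product ``s_hat_t (x) s_hat_prev`` to B(a_prev) counts.

    Only the transition matrix selected by the action actually taken is
    updated; total added mass per transition is one unit.
    """
    if not 0 <= a_prev < beliefs.b_post.shape[0]:
        raise ValueError(f"invalid control index {a_prev}")
    beliefs.b_post[a_prev] += np.outer(s_hat_t, s_hat_prev)
    beliefs.refresh()
    return beliefs


def end_of_trial_update(
    beliefs: DirichletBeliefs,
    record: TrialRecord,
    learn_A: bool = True,
    learn_B: bool = True,
) -> DirichletBeliefs:
    """Apply the accumulation rules over all epochs/transitions of a trial.

    Uses the final (most informed) per-epoch state posteriors from the
    completed trial, applied once at trial end so that within-trial revisions
    of the posteriors are not double counted. Flags allow freezing either
    model component (with strong accurate priors, leaving A learning on is
    effectively inert anyway).
    """
    if not learn_A and not learn_B:
        return beliefs
    T = len(record.observations)
    # accumulate without refreshing the digamma caches until the end
    if learn_A:
        for t in range(T):
            beliefs.a_post[record.observations[t], :] += record.s_hat_final[t]
    if learn_B:
        for t in range(1, T):
            a_prev = record.actions[t - 1]
            beliefs.b_post[a_prev] += np.outer(
                record.s_hat_final[t], record.s_hat_final[t - 1]
            )
    beliefs.refresh()
    return beliefs


def write_belief_snapshots(snapshots: list[dict], path) -> None:
    """Write per-trial belief snapshots as JSON lines (gzipped if ``*.gz``)."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for snap in snapshots:
            fh.write(json.dumps(snap) + "\n")
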