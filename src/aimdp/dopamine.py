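"""Simulated dopamine readout: kernel deconvolution and Poisson spikes.

The hypothesis linking precision to phasic dopamine is that dopamine release
*drives up* expected precision, which then decays with a fixed time constant.
The simulated dopamine signal is therefore obtained by deconvolving the
per-iteration precision trace with an exponentially decaying kernel
``K(tau) = exp(-tau / time_constant)`` — recovering the innovation impulses
that would have produced the observed precision time series. Spike-count
histograms are generated by mapping the (rectified) innovations to a Poisson
rate on top of a background rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular

__all__ = [
    "DopamineTrace",
    "deconvolve_precision",
    "convolve_signal",
    "epoch_responses",
    "simulate_spikes",
    "trace_to_frame",
]

DEFAULT_TIME_CONSTANT = 16.0


@dataclass
class DopamineTrace:
    """Deconvolved phasic signal, one sample per variational iteration.

    ``signal`` is in units of precision-innovation: convolving it with the
    exponential kernel reconstructs the input precision trace. ``spikes``
    (optional) holds simulated per-bin Poisson counts.
    """

    signal: np.ndarray
    time_constant: float
    spikes: np.ndarray | None = None
    drop_first_epoch: bool = False


def _kernel(n: int, tau: float) -> np.ndarray:
    return np.exp(-np.arange(n) / tau)


def deconvolve_precision(
    gamma_trace: np.ndarray,
    tau: float = DEFAULT_TIME_CONSTANT,
    iters_per_epoch: int | None = None,
    drop_first_epoch: bool = False,
) -> DopamineTrace:
    """Solve ``gamma = K * d`` for the innovations ``d``.

    The convolution matrix is lower-triangular Toeplitz, so the system is
    solved exactly by forward substitution. If ``drop_first_epoch`` is set,
    samples from the first epoch (``iters_per_epoch`` of them) are zeroed:
    the deconvolution assumes zero signal before the trace starts, so the
    first epoch carries a boundary artifact.
    """
    if tau <= 0:
        raise ValueError("time constant must be positive")
    g = np.asarray(gamma_trace, dtype=float)
    if g.size == 0:
        raise ValueError("empty precision trace")
    n = g.size
    k = _kernel(n, tau)
    K = np.zeros((n, n))
    for i in range(n):
        K[i, : i + 1] = k[: i + 1][::-1]
    d = solve_triangular(K, g, lower=True)
    if drop_first_epoch:
        if iters_per_epoch is None:
            raise ValueError("drop_first_epoch requires iters_per_epoch")
        d = d.copy()
        d[:iters_per_epoch] = 0.0
    return DopamineTrace(signal=d, time_constant=tau, drop_first_epoch=drop_first_epoch)


def convolve_signal(signal: np.ndarray, tau: float) -> np.ndarray:
    """Inverse of :func:`deconvolve_precision`: reconstruct the precision trace."""
    signal = np.asarray(signal, dtype=float)
    r = np.exp(-1.0 / tau)
    out = np.empty_like(signal)
    acc = 0.0
    for i, d in enumerate(signal):
        acc = d + r * acc
        out[i] = acc
    return out


def epoch_responses(
    gamma_trace: np.ndarray,
    iters_per_epoch: int,
    tau: float = DEFAULT_TIME_CONSTANT,
    gamma_init: float = 0.0,
) -> np.ndarray:
    """Phasic response per epoch: innovation in excess of the tonic level.

    For each epoch block the deconvolved innovations are summed and the
    innovation a *constant* precision (at the value holding when the epoch
    began) would have required is subtracted. The result is ~0 for epochs
    where precision does not move, positive for precision bursts and
    negative for dips, and proportional to the within-epoch precision change
    for step-like traces. ``gamma_init`` sets the tonic reference for the
    first epoch (the prior-mean precision, in a trial context).

    Note the first epoch additionally carries the deconvolution boundary
    artifact; experiment code discards it.
    """
    g = np.asarray(gamma_trace, dtype=float)
    if g.size % iters_per_epoch != 0:
        raise ValueError("trace length must be a multiple of iters_per_epoch")
    d = deconvolve_precision(g, tau=tau).signal
    n_epochs = g.size // iters_per_epoch
    leak = 1.0 - np.exp(-1.0 / tau)
    responses = np.empty(n_epochs)
    entry = gamma_init
    for e in range(n_epochs):
        block = slice(e * iters_per_epoch, (e + 1) * iters_per_epoch)
        tonic = entry * leak * iters_per_epoch
        responses[e] = d[block].sum() - tonic
        entry = g[block][-1]
    return responses


def simulate_spikes(
    trace: DopamineTrace,
    scale: float = 4.0,
    background: float = 4.0,
    n_trials: int = 64,
    rng: np.random.Generator | None = None,
    dip_mode: str = "rectify",
) -> tuple[np.ndarray, np.ndarray]:
    """Poisson spike counts per bin (one bin per variational iteration).

    A unit precision-innovation corresponds to ``scale`` spikes per bin on
    top of ``background`` spikes per bin. ``dip_mode`` controls how negative
    innovations map to rates:

    * ``"rectify"`` (default): ``rate = background + scale * max(d, 0)`` —
      dips cannot push the rate below background;
    * ``"baseline"``: ``rate = max(background + scale * d, 0)`` — dips show
      as below-background firing.

    Returns (mean counts per bin over trials, counts array of shape
    (n_trials, n_bins)). The raw signed signal remains available on the
    trace for population-level summaries.
    """
    if scale < 0 or background < 0:
        raise ValueError("scale and background must be nonnegative")
    if rng is None:
        rng = np.random.default_rng()
    d = np.asarray(trace.signal, dtype=float)
    if dip_mode == "rectify":
        rate = background + scale * np.maximum(d, 0.0)
    elif dip_mode == "baseline":
        rate = np.maximum(background + scale * d, 0.0)
    else:
        raise ValueError(f"unknown dip_mode {dip_mode!r}")
    counts = rng.poisson(rate, size=(n_trials, rate.size))
    trace.spikes = counts
    return counts.mean(axis=0), counts


def trace_to_frame(
    trace: DopamineTrace, condition: str = "", trial_block: int = 0,
    mean_spikes: np.ndarray | None = None,
) -> pd.DataFrame:
    """Long-format table: condition, trial_block, iteration, signal, mean_spikes."""
    n = trace.signal.size
    return pd.DataFrame(
        {
            "condition": [condition] * n,
            "trial_block": [trial_block] * n,
            "iteration": np.arange(1, n + 1),
            "signal": trace.signal,
            "mean_spikes": mean_spikes if mean_spikes is not None else [np.nan] * n,
        }
    )
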