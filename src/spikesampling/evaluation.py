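"""Sampling-quality diagnostics: empirical distributions, KL divergence, rates.

The central figure of merit is the Kullback-Leibler divergence of the
sampled distribution ``q`` from the target ``p``, normalized by the target's
entropy so that networks of different sizes are comparable:

    D_KL^norm(q ‖ p) = D_KL(q ‖ p) / H(p) ,
    D_KL(q ‖ p) = Σ_z q(z) log[q(z)/p(z)] ,
    H(p) = −Σ_z p(z) log p(z) .

Natural logarithms are used throughout; the normalization cancels the base.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "EmpiricalDistribution",
    "empirical_distribution",
    "kl_divergence",
    "entropy",
    "dkl_norm",
    "dkl_time_course",
    "rate_from_spikes",
]


@dataclass(frozen=True)
class EmpiricalDistribution:
    """Occupancy counts over joint binary states (state 0's bit = unit 0)."""

    counts: np.ndarray
    total: float

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=float).ravel()
        if np.any(c < 0):
            raise ValueError("counts must be nonnegative")
        object.__setattr__(self, "counts", c)

    @property
    def probabilities(self) -> np.ndarray:
        if self.total <= 0:
            raise ValueError("empty observation")
        return self.counts / self.total


def empirical_distribution(
    trace: np.ndarray, principal_indices: Sequence[int] | None = None
) -> EmpiricalDistribution:
    """Occupancy of joint states in a (steps, units) binary trace.

    Each time step contributes one count to the joint state formed by the
    selected columns (column order defines the bit order, first = LSB).  For
    LIF traces discretized on a regular grid this is the time-weighted state
    occupancy.
    """
    trace = np.asarray(trace)
    if trace.ndim != 2:
        raise ValueError("trace must be a (steps, units) array")
    if principal_indices is not None:
        trace = trace[:, list(principal_indices)]
    K = trace.shape[1]
    weights = (2 ** np.arange(K)).astype(np.int64)
    idx = trace.astype(np.int64) @ weights
    counts = np.bincount(idx, minlength=2**K).astype(float)
    return EmpiricalDistribution(counts=counts, total=float(trace.shape[0]))


def kl_divergence(q: np.ndarray, p: np.ndarray) -> float:
    """``Σ q log(q/p)`` with the convention ``0 · log 0 = 0``; p must be > 0."""
    q = np.asarray(q, dtype=float).ravel()
    p = np.asarray(p, dtype=float).ravel()
    if q.shape != p.shape:
        raise ValueError("q and p must have the same length")
    if np.any(p <= 0):
        raise ValueError("target distribution must be strictly positive")
    mask = q > 0
    return float(np.sum(q[mask] * np.log(q[mask] / p[mask])))


def entropy(p: np.ndarray) -> float:
    """Shannon entropy in nats, ``0 · log 0 = 0``."""
    p = np.asarray(p, dtype=float).ravel()
    mask = p > 0
    return float(-np.sum(p[mask] * np.log(p[mask])))


def dkl_norm(q: np.ndarray, p: np.ndarray) -> float:
    """KL divergence normalized by the target entropy."""
    H = entropy(p)
    if H <= 0:
        raise ValueError("normalized KL undefined for a point-mass target")
    return kl_divergence(q, p) / H


def dkl_time_course(
    trace: np.ndarray,
    p: np.ndarray,
    checkpoints: Sequence[int] | None = None,
    principal_indices: Sequence[int] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized KL of the cumulative empirical distribution vs. time.

    ``checkpoints`` are step counts (defaults to 20 log-spaced points up to
    the trace length); returns ``(checkpoints, dkl_norm values)``.
    """
    trace = np.asarray(trace)
    n = trace.shape[0]
    if checkpoints is None:
        checkpoints = np.unique(
            np.round(np.logspace(np.log10(max(10, n // 1000)), np.log10(n), 20)).astype(int)
        )
    checkpoints = np.asarray(sorted(int(c) for c in checkpoints))
    if np.any(checkpoints < 1) or np.any(checkpoints > n):
        raise ValueError("checkpoints must lie in [1, len(trace)]")
    if principal_indices is not None:
        trace = trace[:, list(principal_indices)]
    K = trace.shape[1]
    weights = (2 ** np.arange(K)).astype(np.int64)
    idx = trace.astype(np.int64) @ weights
    values = np.empty(checkpoints.size)
    counts = np.zeros(2**K)
    prev = 0
    for ci, c in enumerate(checkpoints):
        counts += np.bincount(idx[prev:c], minlength=2**K)
        prev = c
        values[ci] = dkl_norm(counts / c, p)
    return checkpoints, values


def save_curve(path, x: np.ndarray, y: np.ndarray, header: str = "x,y") -> None:
    """Two-column CSV output for convergence curves and rate traces."""
    np.savetxt(path, np.column_stack([x, y]), delimiter=",",
               header=header, comments="")


def rate_from_spikes(
    spike_times: np.ndarray,
    t_grid: np.ndarray,
    window: float = 8000.0,
    height: float = 1.0 / 8.0,
    causal: bool = False,
) -> np.ndarray:
    """Instantaneous firing rate by convolution with a box kernel.

    The default kernel is ``1/8 Hz`` on ``−8 s < t < 0`` (times in ms), i.e.
    a spike contributes to the rate estimate during the 8 s *preceding* it
    (forward-looking window); ``causal=True`` flips the window so a spike
    contributes for the 8 s after it.  ``n`` spikes inside one window yield
    ``n/8`` Hz.
    """
    spike_times = np.asarray(spike_times, dtype=float).ravel()
    t_grid = np.asarray(t_grid, dtype=float).ravel()
    rate = np.zeros_like(t_grid)
    for ts in spike_times:
        if causal:
            lo, hi = ts, ts + window
        else:
            lo, hi = ts - window, ts
        rate += height * ((t_grid > lo) & (t_grid < hi))
    return rate
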