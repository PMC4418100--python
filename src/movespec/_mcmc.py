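"""Shared MCMC machinery: wrapping, circular means, adaptation, split-R-hat.

The samplers in :mod:`movespec.synchrony` and :mod:`movespec.colour` are
adaptive random-walk Metropolis-within-Gibbs schemes vectorised over chains,
over the parameter axis (frequencies or individuals) and, for simulation
studies, over an optional leading replicate axis. Everything here operates on
arrays whose last axes are the parameter axes and whose leading axes are
(replicate, chain).
"""

from __future__ import annotations

import numpy as np

TWO_PI = 2.0 * np.pi

# Robbins-Monro-style step adaptation (burn-in only)
ADAPT_INTERVAL = 50
TARGET_ACCEPT = 0.3
ADAPT_FACTOR = 1.35


def wrap_angle(theta: np.ndarray) -> np.ndarray:
    """Wrap angles to (-pi, pi]."""
    out = np.mod(-np.asarray(theta) + np.pi, TWO_PI)
    return -(out - np.pi)


def circular_mean(theta: np.ndarray, axis=None) -> np.ndarray:
    """Mean direction of angles (radians), in (-pi, pi]."""
    theta = np.asarray(theta, dtype=float)
    s = np.sin(theta).mean(axis=axis)
    c = np.cos(theta).mean(axis=axis)
    return wrap_angle(np.arctan2(s, c))


def resultant_length(theta: np.ndarray, axis=None) -> np.ndarray:
    """Mean resultant length R in [0, 1]; 1 = perfectly concentrated."""
    theta = np.asarray(theta, dtype=float)
    s = np.sin(theta).mean(axis=axis)
    c = np.cos(theta).mean(axis=axis)
    return np.hypot(s, c)


def adapt_steps(steps: np.ndarray, accept_counts: np.ndarray, window: int) -> None:
    """Multiplicatively adjust proposal scales toward the target rate, in place."""
    rate = accept_counts / max(window, 1)
    steps *= np.where(rate < 0.2, 1.0 / ADAPT_FACTOR, np.where(rate > 0.4, ADAPT_FACTOR, 1.0))
    np.clip(steps, 1e-4, 20.0, out=steps)


def split_rhat(draws: np.ndarray) -> np.ndarray:
    """Split-chain potential scale reduction factor.

    Parameters
    ----------
    draws:
        Array of shape (..., chains, iterations); R-hat is computed over the
        last two axes after splitting each chain in half.

    Returns
    -------
    R-hat with the trailing (chains, iterations) axes removed. NaN-safe for
    zero-variance chains (returns 1.0 there: a constant chain is "converged"
    in the degenerate sense that arises for deterministic parameters).
    """
    draws = np.asarray(draws, dtype=float)
    n = draws.shape[-1] // 2
    halves = np.concatenate([draws[..., :n], draws[..., n : 2 * n]], axis=-2)
    m = halves.shape[-2]
    chain_means = halves.mean(axis=-1)
    chain_vars = halves.var(axis=-1, ddof=1)
    w = chain_vars.mean(axis=-1)
    b = n * chain_means.var(axis=-1, ddof=1)
    var_plus = (n - 1) / n * w + b / n
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.sqrt(var_plus / w)
    rhat = np.where(w <= 1e-300, 1.0, rhat)
    return rhat if m > 1 else np.ones_like(w)


def logit(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    return np.log(p) - np.log1p(-p)


def expit(x: np.ndarray) -> np.ndarray:
    # scipy.special.expit without the import; keeps this module numpy-only
    return 0.5 * (1.0 + np.tanh(0.5 * np.asarray(x, dtype=float)))
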